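"""End-to-end pipeline: simulate -> profile -> quantify -> annotate -> concord -> enrich.

The pipeline is deterministic for a fixed config (seed included); every stage
writes plain TSV/CSV artifacts into the run directory and the summary JSON
collects the headline statistics (per-pair species-profile correlations,
Mantel r/p between layers, coverage tables, enrichment counts). Every output
is tagged with a hash of the config used.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance, enrichment, io, metabolites, profiles, proteomics
from .community import build_community, build_design
from .errors import InsufficientDataError, InvalidDesignError
from .simulate import (
    GroundTruth,
    NoiseParams,
    PerturbationParams,
    build_metabolite_reference,
    simulate_layer_observations,
    simulate_timecourse,
)


@dataclass
class PipelineConfig:
    """All knobs of the demo pipeline; seed is mandatory."""

    seed: int = 1
    n_species: int = 32
    depth: int = 100_000
    depth_16s: int = 100_000
    n_perm: int = 199
    #: the transcript pFDR cut (0.001) needs fine p resolution from the
    #: sign-flip test, hence the larger count here (it is fully vectorised)
    feature_test_n_perm: int = 19_999
    zero_noise: bool = False
    layers: tuple[str, ...] = ("16S", "metagenome", "metatranscriptome", "metaproteome", "metabolome")
    perturbation: dict = field(default_factory=dict)
    mantel_floor_default: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise InvalidDesignError("seed is mandatory")
        if self.depth < 1 or self.n_perm < 1:
            raise InvalidDesignError("depth and n_perm must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidDesignError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if k == "layers" else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every enabled stage and return the machine-readable summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    summary: dict = {"config_hash": chash, "seed": config.seed}

    community = build_community(n_species=config.n_species, seed=config.seed)
    design = build_design()
    params = PerturbationParams(**config.perturbation)
    noise = NoiseParams()
    if config.zero_noise:
        noise = noise.noise_free()
    refs = build_metabolite_reference(seed=config.seed)
    truth = simulate_timecourse(community, design, params, seed=config.seed, metabolite_refs=refs)

    io.write_community(community, outdir / "community")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    io.write_matrix(truth.abundance, outdir / "true_abundance.tsv", "species_id")

    prof: dict[str, profiles.SpeciesProfile] = {}
    counts_by_layer: dict[str, profiles.LayerCounts] = {}

    if "metagenome" in config.layers:
        asg = simulate_layer_observations(
            truth, community, "metagenome", config.depth, noise, config.seed
        )
        io.write_assignments(asg, outdir / "metagenome_assignments.tsv")
        counts = profiles.distribute_multimapped(asg, community)
        counts_by_layer["metagenome"] = counts
        io.write_layer_counts(counts, outdir)
        prof["metagenome"] = profiles.metagenome_species_abundance(counts, community)

    if "metatranscriptome" in config.layers:
        asg = simulate_layer_observations(
            truth, community, "metatranscriptome", config.depth, noise, config.seed
        )
        counts = profiles.distribute_multimapped(asg, community)
        counts_by_layer["metatranscriptome"] = counts
        io.write_layer_counts(counts, outdir)
        prof["metatranscriptome"] = profiles.metatranscriptome_species_abundance(
            counts, community
        )

    if "16S" in config.layers:
        c16 = simulate_layer_observations(
            truth, community, "16S", config.depth_16s, noise, config.seed
        )
        io.write_matrix(c16, outdir / "16S_counts.tsv", "species_id")
        prof["16S"] = profiles.amplicon_species_abundance(c16)

    quant = None
    if "metaproteome" in config.layers:
        report = simulate_layer_observations(
            truth, community, "metaproteome", config.depth, noise, config.seed
        )
        io.write_peptide_report(report, outdir / "peptide_report.tsv")
        quant, prot_species = proteomics.quantify_report(report, community)
        io.write_matrix(quant, outdir / "protein_quant.tsv", "protein_id")
        if len(quant):
            prof["metaproteome"] = profiles.proteome_species_abundance(
                quant, prot_species, community.species_ids
            )
            counts_by_layer["metaproteome"] = profiles.LayerCounts(
                "metaproteome",
                quant.fillna(0.0),
                community.feature_map().loc[quant.index],
            )

    ions = rep_map = annotations = None
    if "metabolome" in config.layers:
        ions = simulate_layer_observations(
            truth, community, "metabolome", config.depth, noise, config.seed,
            metabolite_refs=refs,
        )
        io.write_ion_table(ions, outdir / "ions_unfiltered.csv")
        sample_cols = list(truth.abundance.columns)
        ions[sample_cols] = metabolites.quantile_normalize(
            ions.set_index("ion_id")[sample_cols], ions.set_index("ion_id")["polarity"]
        ).to_numpy()
        annotations = metabolites.annotate_ions(ions, refs)
        annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        filtered, rep_map = metabolites.filter_annotated_ions(ions, annotations, sample_cols)
        io.write_ion_table(filtered, outdir / "ions_filtered.csv")
        summary["n_ions"] = int(len(ions))
        summary["n_annotated_ions"] = int(annotations["ion_id"].nunique())
        summary["n_retained_ions"] = int(len(filtered))

    # tidy concatenated profile table and cross-omics agreement
    tidy = pd.concat([profiles.profile_to_tidy(p) for p in prof.values()], ignore_index=True)
    tidy.to_csv(outdir / "species_profiles.tsv", sep="\t", index=False)
    pair_rows = []
    names = sorted(prof)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            try:
                rho = concordance.cross_omics_spearman(prof[a], prof[b])
            except InsufficientDataError:
                rho = np.nan
            pair_rows.append((a, b, rho))
    pairs = pd.DataFrame(pair_rows, columns=["layer_a", "layer_b", "spearman_rho"])
    pairs.to_csv(outdir / "cross_omics_spearman.tsv", sep="\t", index=False)
    summary["cross_omics_spearman"] = {
        f"{r.layer_a}|{r.layer_b}": None if pd.isna(r.spearman_rho) else round(r.spearman_rho, 4)
        for r in pairs.itertuples(index=False)
    }

    # coverage
    coverage = {}
    for layer, counts in counts_by_layer.items():
        cov, cov_max = concordance.gene_coverage(counts, community)
        io.write_matrix(cov, outdir / f"{layer}_gene_coverage.tsv", "species_id")
        coverage[layer] = {s: round(v, 4) for s, v in cov_max.items()}
        detected_kos = set(
            profiles.aggregate_by_ortholog(counts, "KO")
            .pipe(lambda df: df[(df > 0).any(axis=1)])
            .index
        ) - {profiles.UNANNOTATED}
        pcov = concordance.pathway_coverage(detected_kos, community.pathways)
        pcov.to_csv(outdir / f"{layer}_pathway_coverage.tsv", sep="\t")
    summary["max_gene_coverage"] = coverage
    if rep_map is not None:
        detected_mets = set(rep_map["metabolite_id"])
        met_paths: dict[str, set[str]] = {}
        for _, ref in refs.iterrows():
            for pid in str(ref["pathway_ids"]).split(";"):
                met_paths.setdefault(pid, set()).add(ref["metabolite_id"])
        pcov = concordance.pathway_coverage(detected_mets, met_paths)
        pcov.to_csv(outdir / "metabolome_pathway_coverage.tsv", sep="\t")
        summary["metabolome_mean_pathway_coverage"] = round(float(pcov.mean()), 4)

    # Mantel tests between sample-distance matrices of each layer
    mantel_rows = []
    layer_names = sorted(counts_by_layer)
    dms = {}
    for layer in layer_names:
        floor = concordance.MANTEL_FLOORS.get(layer, config.mantel_floor_default)
        frac = counts_by_layer[layer].values
        frac = frac / frac.sum(axis=0)
        dms[layer] = concordance.sample_distance(frac, floor)
    for i, a in enumerate(layer_names):
        for b in layer_names[i + 1 :]:
            try:
                r, p = concordance.mantel(dms[a], dms[b], n_perm=config.n_perm, seed=config.seed)
            except InsufficientDataError:
                r, p = np.nan, np.nan
            mantel_rows.append((a, b, r, p))
    mt = pd.DataFrame(mantel_rows, columns=["layer_a", "layer_b", "mantel_r", "p"])
    mt.to_csv(outdir / "mantel.tsv", sep="\t", index=False)
    summary["mantel"] = {
        f"{r.layer_a}|{r.layer_b}": [round(r.mantel_r, 4), round(r.p, 4)]
        for r in mt.itertuples(index=False)
        if np.isfinite(r.mantel_r)
    }

    # differential features + enrichment per functional layer
    enr_summary = {}
    targets: dict[str, tuple[pd.DataFrame, dict]] = {}
    if "metatranscriptome" in counts_by_layer:
        ko = profiles.aggregate_by_ortholog(counts_by_layer["metatranscriptome"], "KO")
        ko = ko.drop(index=profiles.UNANNOTATED, errors="ignore")
        targets["metatranscriptome"] = (ko, dict(community.pathways))
    if quant is not None and len(quant):
        ko = profiles.aggregate_by_ortholog(counts_by_layer["metaproteome"], "KO")
        ko = ko.drop(index=profiles.UNANNOTATED, errors="ignore")
        targets["metaproteome"] = (ko, dict(community.pathways))
    if ions is not None and rep_map is not None and len(rep_map):
        kept = ions.set_index("ion_id").loc[sorted(set(rep_map["ion_id"]))]
        sample_cols = list(truth.abundance.columns)
        met_paths = {}
        for _, ref in refs.iterrows():
            for pid in str(ref["pathway_ids"]).split(";"):
                met_paths.setdefault(pid, set()).add(ref["metabolite_id"])
        ann_kept = annotations[annotations["ion_id"].isin(kept.index)]
        ion_sets = enrichment.deduplicate_ion_features(ann_kept, met_paths)
        targets["metabolome"] = (kept[sample_cols], ion_sets)

    drug_conditions = [c for c in design["condition"].unique() if c != "control"]
    for layer, (values, set_map) in targets.items():
        for cond in drug_conditions:
            fc = enrichment.fold_change_vs_control(values, design, cond)
            fc.to_csv(outdir / f"{layer}_{cond}_log2fc.tsv", sep="\t")
            test = enrichment.permutation_feature_test(
                values, design, cond, n_perm=config.feature_test_n_perm, seed=config.seed
            )
            sel = enrichment.select_differential(fc, test["p_adj"], layer)
            universe = set(values.index[(values.fillna(0) > 0).any(axis=1)])
            enr_frames = []
            for direction in ("up", "down"):
                res = enrichment.fisher_enrichment(
                    sel[direction] & universe, universe, set_map
                )
                res.insert(1, "direction", direction)
                enr_frames.append(res)
            enr = pd.concat(enr_frames, ignore_index=True)
            enr.to_csv(outdir / f"{layer}_{cond}_enrichment.tsv", sep="\t", index=False)
            enr_summary[f"{layer}|{cond}"] = {
                "n_up": len(sel["up"]),
                "n_down": len(sel["down"]),
                "n_enriched_sets": int((enr["p_adj"] < 0.05).sum()),
            }
    summary["differential"] = enr_summary

    io.dump_json(summary, outdir / "summary.json")
    return summary
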