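"""Ground-truthed simulation of the drug-perturbation time course.

The generator emulates the study design: a stabilised community of 32 gut
species with a few dominant members, drug added during exponential growth,
sampling at 0/15/30 min and 1/3/43/91 h, two experimental runs in duplicate.
The perturbation model has three effects, each with a known ground truth so
downstream estimators can be scored against it:

* phylum-selective depletion — susceptible (Bacteroidota) species' relative
  abundances shrink multiplicatively per unit time under the drug;
* stress-response induction — transcripts of a designated KO set are induced
  by a fixed fold from the first post-treatment timepoint;
* transcript -> protein lag — the same induction appears in the proteome
  ``lag`` timepoints later.

Observation models per layer: multinomial read sampling proportional to
abundance x gene length (metagenome; a configurable fraction of reads maps to
two genes of the same species, exercising the multi-map splitting rule),
abundance x expression with rRNA removed (metatranscriptome), multinomial
over species (16S), peptide intensities with detection truncation so only the
most-expressed fraction of proteins is seen (metaproteome), ions from
metabolite masses via adduct rules plus Gaussian mass error (metabolome), and
a logistic OD curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import SUSCEPTIBLE_PHYLUM, CommunitySpec
from .errors import InvalidDesignError, UnsupportedLayerError
from .metabolites import ADDUCTS, C13_SHIFT, mass_tolerance
from .profiles import LAYERS, ReadAssignments


@dataclass(frozen=True)
class PerturbationParams:
    """Ground-truth perturbation parameters.

    depletion
        Multiplicative survival factor of susceptible-phylum abundance per
        ``t_ref_h`` hours under the drug; 1.0 = no depletion.
    induced_pathway
        Pathway id whose KO members are transcriptionally induced (None picks
        the community's first pathway).
    fold
        Induction fold applied to transcripts of induced-KO genes from the
        first post-treatment timepoint.
    lag
        Number of timepoints by which the proteome induction trails the
        transcriptome.
    """

    depletion: float = 0.25
    t_ref_h: float = 24.0
    induced_pathway: str | None = None
    fold: float = 8.0
    lag: int = 1
    susceptible_phylum: str = SUSCEPTIBLE_PHYLUM
    abundance_sigma: float = 2.0
    expression_sigma: float = 1.0

    def validate(self) -> None:
        if not 0 < self.depletion <= 1:
            raise InvalidDesignError("depletion must be in (0, 1]")
        if self.lag < 0:
            raise InvalidDesignError("lag must be >= 0")
        if self.fold <= 0:
            raise InvalidDesignError("fold must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Observation-noise settings; zeros give the noise-free regime."""

    multimap_fraction: float = 0.05
    detection_fraction: float = 0.3  # fraction of proteins per species observed
    intensity_sigma: float = 0.2  # lognormal sigma on intensities
    peptide_factor_sigma: float = 0.5  # peptide ionisation-efficiency spread
    peptide_dropout: float = 0.1  # per (peptide, sample) missingness
    mass_error_scale: float = 1 / 3  # mass-error sigma as a fraction of tol(mz)
    od_sigma: float = 0.02

    def noise_free(self) -> "NoiseParams":
        return replace(
            self,
            intensity_sigma=0.0,
            peptide_factor_sigma=0.0,
            peptide_dropout=0.0,
            mass_error_scale=0.0,
            od_sigma=0.0,
        )


@dataclass
class GroundTruth:
    """True abundances and expression plus the parameters that produced them."""

    abundance: pd.DataFrame = field(repr=False)  # species x sample fractions
    expression: pd.DataFrame = field(repr=False)  # gene x sample, fractions within species
    protein_expression: pd.DataFrame = field(repr=False)  # lagged induction
    metabolite_conc: pd.DataFrame = field(repr=False)  # metabolite x sample
    design: pd.DataFrame = field(repr=False)
    params: PerturbationParams = PerturbationParams()
    rng_seed: int = 0
    induced_kos: frozenset[str] = frozenset()


def _stream(seed: int, key: str) -> np.random.Generator:
    """Independent, reproducible stream per layer derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, _KEY_IDS[key]]))


_KEY_IDS = {
    "truth": 0,
    "16S": 1,
    "metagenome": 2,
    "metatranscriptome": 3,
    "metaproteome": 4,
    "metabolome": 5,
    "OD": 6,
    "reference": 7,
}


def build_metabolite_reference(
    n_metabolites: int = 60,
    seed: int = 0,
    pathway_ids: tuple[str, ...] = tuple(f"path{1 + p:03d}" for p in range(12)),
    mass_range: tuple[float, float] = (80.0, 600.0),
    min_candidate_separation: float = 0.02,
) -> pd.DataFrame:
    """Synthetic metabolite reference (id, name, monoisotopic_mass, pathways).

    Masses are rejection-sampled so that every enumerated candidate m/z (all
    adducts, 0-2 13C substitutions, both polarities) of distinct metabolites
    stays >= ``min_candidate_separation`` apart — annotations of noise-free
    ions are then unambiguous, giving the generator a clean recall oracle.
    """
    rng = _stream(seed, "reference")
    masses: list[float] = []
    taken: list[float] = []

    def candidates(m: float) -> list[float]:
        out = []
        for pol in ADDUCTS:
            for _, charge, offset in ADDUCTS[pol]:
                for n in range(3):
                    out.append((m + n * C13_SHIFT + offset) / charge)
        return out

    while len(masses) < n_metabolites:
        m = float(rng.uniform(*mass_range))
        cs = candidates(m)
        if all(abs(c - t) >= min_candidate_separation for c in cs for t in taken):
            masses.append(m)
            taken.extend(cs)
    rows = []
    for i, m in enumerate(masses):
        k = int(rng.integers(1, 4))
        paths = sorted(rng.choice(pathway_ids, size=min(k, len(pathway_ids)), replace=False))
        rows.append((f"met{1 + i:03d}", f"metabolite_{1 + i:03d}", m, ";".join(paths)))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "name", "monoisotopic_mass", "pathway_ids"]
    )


def simulate_timecourse(
    community: CommunitySpec,
    design: pd.DataFrame,
    params: PerturbationParams = PerturbationParams(),
    seed: int = 0,
    metabolite_refs: pd.DataFrame | None = None,
) -> GroundTruth:
    """Generate the ground truth for a sample design.

    Baseline species abundances are log-normal (few dominant species) and
    shared within a run; under the drug the susceptible phylum is multiplied
    by depletion^(t / t_ref) and the column renormalised. Transcript induction
    of the designated KO set starts at the first post-treatment timepoint; the
    proteome copy of the induction is shifted ``lag`` timepoints later.
    """
    params.validate()
    if "control" not in set(design["condition"]):
        raise InvalidDesignError("design lacks control samples")
    for (run, t), grp in design.groupby(["run", "timepoint_h"]):
        if "control" not in set(grp["condition"]):
            raise InvalidDesignError(f"no control counterpart for run={run}, t={t}")

    rng = _stream(seed, "truth")
    genes = community.genes
    species_ids = community.species_ids
    timepoints = sorted(design["timepoint_h"].unique())
    post = [t for t in timepoints if t > 0]
    first_post_idx = timepoints.index(post[0]) if post else len(timepoints)

    pathway = params.induced_pathway or next(iter(sorted(community.pathways)))
    induced_kos = frozenset(community.pathways.get(pathway, frozenset()))
    induced_gene = genes["ko_id"].isin(induced_kos).to_numpy()
    susceptible = np.array(
        [sp.phylum == params.susceptible_phylum for sp in community.species]
    )

    # per-run baseline abundance and per-species expression weights
    runs = sorted(design["run"].unique())
    base_ab = {
        r: np.exp(rng.normal(0.0, params.abundance_sigma, size=len(species_ids)))
        for r in runs
    }
    weights = np.exp(rng.normal(0.0, params.expression_sigma, size=len(genes)))
    weights[genes["is_rrna"].to_numpy()] = 0.0  # expression fractions are coding-only

    # gene x timepoint induction exponents: induction strength varies over the
    # time course (a stress response, not a permanent switch), so the protein
    # profile is exactly the transcript profile shifted by `lag` timepoints
    n_induced = int(induced_gene.sum())
    exponents = np.zeros((n_induced, len(timepoints)))
    if n_induced and params.fold != 1.0:
        exponents[:, first_post_idx:] = rng.uniform(
            0.5, 1.5, size=(n_induced, len(timepoints) - first_post_idx)
        )

    def induction_factor(t_idx: int, lag: int) -> np.ndarray:
        src = t_idx - lag
        if src < first_post_idx:
            return np.ones(n_induced)
        return params.fold ** exponents[:, src]

    sp_of_gene = genes["species_id"].to_numpy()
    sp_index = pd.Index(species_ids)

    def species_normalise(w: np.ndarray) -> np.ndarray:
        sums = pd.Series(w).groupby(sp_of_gene).transform("sum").to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, w / sums, 0.0)

    ab_cols, ex_cols, px_cols = {}, {}, {}
    for row in design.itertuples(index=False):
        ab = base_ab[row.run].copy()
        treated = row.condition != "control"
        if treated and row.timepoint_h > 0:
            ab[susceptible] *= params.depletion ** (row.timepoint_h / params.t_ref_h)
        ab_cols[row.sample_id] = ab / ab.sum()

        t_idx = timepoints.index(row.timepoint_h)
        w_t = weights.copy()
        w_p = weights.copy()
        if treated:
            w_t[induced_gene] *= induction_factor(t_idx, 0)
            w_p[induced_gene] *= induction_factor(t_idx, params.lag)
        ex_cols[row.sample_id] = species_normalise(w_t)
        px_cols[row.sample_id] = species_normalise(w_p)

    sample_ids = design["sample_id"].tolist()
    abundance = pd.DataFrame(ab_cols, index=sp_index)[sample_ids]
    expression = pd.DataFrame(ex_cols, index=genes.index)[sample_ids]
    protein_expression = pd.DataFrame(px_cols, index=genes.index)[sample_ids]

    if metabolite_refs is None:
        metabolite_refs = build_metabolite_reference(seed=seed)
    base_conc = np.exp(rng.normal(2.0, 1.0, size=len(metabolite_refs)))
    responsive = (
        metabolite_refs["pathway_ids"].str.split(";").apply(lambda p: pathway in p).to_numpy()
    )
    conc_cols = {}
    for row in design.itertuples(index=False):
        c = base_conc.copy()
        t_idx = timepoints.index(row.timepoint_h)
        if row.condition != "control" and t_idx >= first_post_idx:
            c[responsive] *= params.fold
        conc_cols[row.sample_id] = c
    metabolite_conc = pd.DataFrame(
        conc_cols, index=pd.Index(metabolite_refs["metabolite_id"], name="metabolite_id")
    )[sample_ids]

    return GroundTruth(
        abundance=abundance,
        expression=expression,
        protein_expression=protein_expression,
        metabolite_conc=metabolite_conc,
        design=design.copy(),
        params=params,
        rng_seed=seed,
        induced_kos=induced_kos,
    )


# --------------------------------------------------------------------------
# per-layer observation models
# --------------------------------------------------------------------------


def _sequencing_reads(
    truth: GroundTruth,
    community: CommunitySpec,
    layer: str,
    depth: int,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> ReadAssignments:
    genes = community.genes
    sp_of_gene = genes["species_id"].to_numpy()
    ab = truth.abundance
    if layer == "metagenome":
        base = genes["length_bp"].to_numpy(float)
        expr = None
    else:
        base = np.ones(len(genes))
        expr = truth.expression
        base[genes["is_rrna"].to_numpy()] = 0.0

    # same-species partner gene per gene, for multi-mapped reads
    partner = np.arange(len(genes))
    by_sp: dict[str, np.ndarray] = {
        sp: np.flatnonzero(sp_of_gene == sp) for sp in community.species_ids
    }
    for sp, idx in by_sp.items():
        if len(idx) > 1:
            shift = idx[(np.arange(len(idx)) + 1) % len(idx)]
            partner[idx] = shift

    gene_ids = genes.index.to_numpy()
    rows = []
    for sample in ab.columns:
        p = ab.loc[sp_of_gene, sample].to_numpy() * base
        if expr is not None:
            p = ab.loc[sp_of_gene, sample].to_numpy() * expr[sample].to_numpy()
        total = p.sum()
        if total <= 0:
            raise InvalidDesignError(f"sample {sample}: zero sampling probability")
        p = p / total
        n_multi = rng.binomial(depth, noise.multimap_fraction)
        uni = rng.multinomial(depth - n_multi, p)
        nz = np.flatnonzero(uni)
        for g in nz:
            rows.append((sample, gene_ids[g], int(uni[g])))
        if n_multi:
            mm = rng.multinomial(n_multi, p)
            for g in np.flatnonzero(mm):
                pair = f"{gene_ids[g]};{gene_ids[partner[g]]}"
                if partner[g] == g:  # single-gene species: effectively unique
                    pair = gene_ids[g]
                rows.append((sample, pair, int(mm[g])))
    table = pd.DataFrame(rows, columns=["sample_id", "gene_ids", "n_reads"])
    return ReadAssignments(layer, table)


def _amplicon_counts(
    truth: GroundTruth, depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    ab = truth.abundance
    counts = {
        s: rng.multinomial(depth, ab[s].to_numpy() / ab[s].sum()) for s in ab.columns
    }
    return pd.DataFrame(counts, index=ab.index)


def _peptide_report(
    truth: GroundTruth,
    community: CommunitySpec,
    noise: NoiseParams,
    rng: np.random.Generator,
    intensity_scale: float = 1e9,
) -> pd.DataFrame:
    genes = community.genes
    coding = genes.index[~genes["is_rrna"]]
    px = truth.protein_expression
    ab = truth.abundance
    sp_of_gene = genes["species_id"]

    # detection truncation: per species keep the top `detection_fraction`
    # proteins by mean expression (low proteome depth)
    mean_expr = px.loc[coding].mean(axis=1)
    detected: list[str] = []
    for sp, idx in mean_expr.groupby(sp_of_gene.loc[coding]).groups.items():
        k = max(1, int(np.floor(noise.detection_fraction * len(idx))))
        top = mean_expr.loc[idx].sort_values(ascending=False).index[:k]
        detected.extend(top)
    detected_set = set(detected)

    peps = community.peptides
    peps = peps[peps["protein_id"].isin(detected_set)]
    # peptide-level response factor (ionisation efficiency), fixed per peptide
    seqs = sorted(peps["peptide_seq"].unique())
    factor = pd.Series(
        np.exp(rng.normal(0.0, noise.peptide_factor_sigma, size=len(seqs))), index=seqs
    )

    samples = ab.columns
    # protein signal per sample = species abundance x protein expression
    prot_signal = px.loc[sorted(detected_set)].mul(
        ab.loc[sp_of_gene.loc[sorted(detected_set)]].set_axis(sorted(detected_set)), axis=0
    )

    rows = []
    for seq, grp in peps.groupby("peptide_seq"):
        prots = sorted(grp["protein_id"].unique())
        sps = sorted(grp["species_id"].unique())
        signal = prot_signal.loc[[p for p in prots if p in prot_signal.index]].sum(axis=0)
        inten = signal.to_numpy() * float(factor[seq]) * intensity_scale
        if noise.intensity_sigma > 0:
            inten = inten * np.exp(rng.normal(0.0, noise.intensity_sigma, size=len(inten)))
        if noise.peptide_dropout > 0:
            drop = rng.random(len(inten)) < noise.peptide_dropout
            inten = np.where(drop, np.nan, inten)
        rows.append([seq, ";".join(prots), ";".join(sps), *inten])
    report = pd.DataFrame(rows, columns=["peptide_seq", "protein_matches", "species_matches", *samples])
    return report.sort_values("peptide_seq").reset_index(drop=True)


def _ion_table(
    truth: GroundTruth,
    refs: pd.DataFrame,
    noise: NoiseParams,
    rng: np.random.Generator,
    isotope_fraction: float = 0.3,
    n_decoys: int = 10,
    intensity_scale: float = 1e5,
) -> pd.DataFrame:
    conc = truth.metabolite_conc
    samples = conc.columns
    rows = []
    ion_no = 0

    def emit(mz0: float, polarity: str, inten: np.ndarray, met: str, adduct: str, n13c: int):
        nonlocal ion_no
        ion_no += 1
        mz = mz0
        if noise.mass_error_scale > 0:
            mz = mz0 + rng.normal(0.0, noise.mass_error_scale * float(mass_tolerance(mz0)))
        vals = inten
        if noise.intensity_sigma > 0:
            vals = vals * np.exp(rng.normal(0.0, noise.intensity_sigma, size=len(vals)))
        rows.append([f"ion{ion_no:04d}", mz, polarity, met, adduct, n13c, *vals])

    adduct_offsets = {pol: dict((a[0], a) for a in ADDUCTS[pol]) for pol in ADDUCTS}
    pos_half = set(
        rng.choice(refs["metabolite_id"], size=len(refs) // 2, replace=False).tolist()
    )
    iso_set = set(
        rng.choice(
            refs["metabolite_id"], size=int(isotope_fraction * len(refs)), replace=False
        ).tolist()
    )
    for _, ref in refs.iterrows():
        met, mass = ref["metabolite_id"], float(ref["monoisotopic_mass"])
        inten = conc.loc[met].to_numpy() * intensity_scale
        _, charge, off = adduct_offsets["negative"]["[M-H]"]
        emit((mass + off) / charge, "negative", inten, met, "[M-H]", 0)
        if met in pos_half:
            _, charge, off = adduct_offsets["positive"]["[M+H]"]
            emit((mass + off) / charge, "positive", 0.8 * inten, met, "[M+H]", 0)
        if met in iso_set:
            _, charge, off = adduct_offsets["negative"]["[M-H]"]
            emit((mass + C13_SHIFT + off) / charge, "negative", 0.05 * inten, met, "[M-H]", 1)

    # unannotatable decoy ions, kept clear of every candidate m/z
    cand_mz = np.sort(
        np.concatenate(
            [
                [
                    (m + n * C13_SHIFT + off) / charge
                    for pol in ADDUCTS
                    for _, charge, off in ADDUCTS[pol]
                    for n in range(3)
                ]
                for m in refs["monoisotopic_mass"].astype(float)
            ]
        )
    )
    made = 0
    while made < n_decoys:
        mz = float(rng.uniform(60.0, 900.0))
        k = np.searchsorted(cand_mz, mz)
        near = cand_mz[max(0, k - 1) : k + 1]
        if all(abs(mz - c) > 0.02 for c in near):
            made += 1
            ion_no += 1
            vals = np.exp(rng.normal(2.0, 1.0)) * intensity_scale * np.ones(len(samples))
            rows.append([f"ion{ion_no:04d}", mz, "negative", "", "", -1, *vals])

    cols = ["ion_id", "mz", "polarity", "true_metabolite", "true_adduct", "true_n13c", *samples]
    return pd.DataFrame(rows, columns=cols)


def _od_curve(
    noise: NoiseParams,
    rng: np.random.Generator,
    L: float = 2.5,
    k: float = 0.8,
    t0: float = 5.0,
    t_max: float = 24.0,
) -> pd.DataFrame:
    t = np.arange(0.0, t_max + 0.5, 1.0)
    od = L / (1.0 + np.exp(-k * (t - t0)))
    if noise.od_sigma > 0:
        od = od + rng.normal(0.0, noise.od_sigma, size=len(t))
    return pd.DataFrame({"time_h": t, "od": od})


def simulate_layer_observations(
    truth: GroundTruth,
    community: CommunitySpec,
    layer: str,
    depth: int = 100_000,
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
    metabolite_refs: pd.DataFrame | None = None,
):
    """Simulate raw observations for one omics layer.

    Returns :class:`ReadAssignments` for metagenome/metatranscriptome, a
    species x sample count table for 16S, a peptide report for metaproteome,
    an ion table (with hidden ``true_*`` columns) for metabolome, and a
    (time, OD) series for OD.
    """
    if layer not in LAYERS:
        raise UnsupportedLayerError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    rng = _stream(seed, layer)
    if layer in ("metagenome", "metatranscriptome"):
        return _sequencing_reads(truth, community, layer, depth, noise, rng)
    if layer == "16S":
        return _amplicon_counts(truth, depth, rng)
    if layer == "metaproteome":
        return _peptide_report(truth, community, noise, rng)
    if layer == "metabolome":
        if metabolite_refs is None:
            metabolite_refs = build_metabolite_reference(seed=truth.rng_seed)
        return _ion_table(truth, metabolite_refs, noise, rng)
    return _od_curve(noise, rng)
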