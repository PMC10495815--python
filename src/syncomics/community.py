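"""Synthetic community specification.

A community is a fixed reference that every omics layer maps back to: species
with phylum labels and genome sizes, per-species gene models (length, rRNA
flag, KO/COG assignment), a pathway vocabulary grouping KOs, and a tryptic
peptide catalogue with a configurable fraction of peptides shared between
species (the structure that makes the species-uniqueness filter of
metaproteomic quantification non-trivial).

The generator emulates a defined gut community of 32 cultured strains in which
a handful of Bacteroidota members are susceptible to the perturbing drug.
Everything is drawn from a single seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import InvalidCommunityError, InvalidDesignError

SUSCEPTIBLE_PHYLUM = "Bacteroidota"

_OTHER_PHYLA = (
    "Bacillota",
    "Pseudomonadota",
    "Fusobacteriota",
    "Actinomycetota",
    "Verrucomicrobiota",
)

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # no K/R inside tryptic peptides

#: Experimental sampling grid: hours relative to drug addition.
DEFAULT_TIMEPOINTS_H = (0.0, 0.25, 0.5, 1.0, 3.0, 43.0, 91.0)


@dataclass(frozen=True)
class GeneSpec:
    """One gene model of one species."""

    gene_id: str
    length_bp: int
    is_rrna: bool = False
    ko_id: str | None = None
    cog_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise InvalidCommunityError(f"gene {self.gene_id}: length_bp must be >= 1")


@dataclass(frozen=True)
class SpeciesSpec:
    """One species: phylum label, genome size and its gene models."""

    species_id: str
    phylum: str
    genome_length_bp: int
    genes: tuple[GeneSpec, ...]

    def __post_init__(self) -> None:
        total = sum(g.length_bp for g in self.genes)
        if total > self.genome_length_bp:
            raise InvalidCommunityError(
                f"{self.species_id}: gene lengths ({total}) exceed genome "
                f"({self.genome_length_bp})"
            )
        if not any(g.is_rrna for g in self.genes):
            raise InvalidCommunityError(f"{self.species_id}: needs >= 1 rRNA gene")

    @property
    def coding_bases(self) -> int:
        """Total gene length excluding rRNA regions (transcript denominator)."""
        return sum(g.length_bp for g in self.genes if not g.is_rrna)


@dataclass
class CommunitySpec:
    """The full reference: species, pathway vocabulary, peptide catalogue."""

    species: tuple[SpeciesSpec, ...]
    pathways: dict[str, frozenset[str]]
    #: one row per (peptide, protein) pair; shared peptides occur in >1 row
    peptides: pd.DataFrame = field(repr=False)

    @cached_property
    def genes(self) -> pd.DataFrame:
        """Flat gene table indexed by gene_id."""
        rows = [
            (g.gene_id, sp.species_id, g.length_bp, g.is_rrna, g.ko_id, g.cog_id)
            for sp in self.species
            for g in sp.genes
        ]
        df = pd.DataFrame(
            rows, columns=["gene_id", "species_id", "length_bp", "is_rrna", "ko_id", "cog_id"]
        )
        return df.set_index("gene_id")

    @cached_property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]

    @cached_property
    def genome_lengths(self) -> pd.Series:
        return pd.Series(
            {sp.species_id: sp.genome_length_bp for sp in self.species}, name="genome_length_bp"
        )

    @cached_property
    def coding_bases(self) -> pd.Series:
        return pd.Series(
            {sp.species_id: sp.coding_bases for sp in self.species}, name="coding_bases"
        )

    def feature_map(self) -> pd.DataFrame:
        """gene -> (species, KO, COG) mapping used by LayerCounts."""
        return self.genes[["species_id", "ko_id", "cog_id"]].copy()


def _unique_peptide_seqs(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(8, 16))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length)) + "K"
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def build_community(
    n_species: int = 32,
    genes_per_species: tuple[int, int] = (100, 200),
    seed: int = 0,
    *,
    n_susceptible: int = 6,
    n_pathways: int = 12,
    kos_per_pathway: int = 10,
    annotation_rate: float = 0.75,
    n_cogs: int = 80,
    peptides_per_protein: tuple[int, int] = (4, 9),
    shared_peptide_fraction: float = 0.10,
) -> CommunitySpec:
    """Build a reproducible synthetic community.

    Parameters
    ----------
    n_species
        Number of species; at least 2. ``n_susceptible`` of them are labelled
        Bacteroidota (the drug-susceptible phylum).
    genes_per_species
        Inclusive range for the per-species gene count.
    seed
        Single seed; all randomness derives from it.
    annotation_rate
        Probability that a protein-coding gene carries a KO (and independently
        a COG) assignment from the synthetic vocabulary.
    shared_peptide_fraction
        Fraction of peptides additionally attached to a protein of a second
        species, exercising the species-uniqueness filter.
    """
    if n_species < 2:
        raise InvalidDesignError("n_species must be >= 2")
    if not 0 <= shared_peptide_fraction < 1:
        raise InvalidDesignError("shared_peptide_fraction must be in [0, 1)")
    n_susceptible = min(max(n_susceptible, 4 if n_species >= 4 else 1), n_species - 1)
    rng = np.random.default_rng(seed)

    ko_vocab = [f"K{1 + i:05d}" for i in range(n_pathways * kos_per_pathway)]
    pathways = {
        f"path{1 + p:03d}": frozenset(ko_vocab[p * kos_per_pathway : (p + 1) * kos_per_pathway])
        for p in range(n_pathways)
    }
    cog_vocab = [f"COG{1 + i:04d}" for i in range(n_cogs)]

    species: list[SpeciesSpec] = []
    protein_rows: list[tuple[str, str]] = []  # (protein gene_id, species_id)
    lo, hi = genes_per_species
    for s in range(n_species):
        sp_id = f"sp{1 + s:02d}"
        phylum = (
            SUSCEPTIBLE_PHYLUM
            if s < n_susceptible
            else _OTHER_PHYLA[(s - n_susceptible) % len(_OTHER_PHYLA)]
        )
        n_genes = int(rng.integers(lo, hi + 1))
        lengths = rng.integers(300, 3001, size=n_genes)
        n_rrna = int(rng.integers(3, 7))
        rrna_idx = set(rng.choice(n_genes, size=min(n_rrna, n_genes), replace=False).tolist())
        genes = []
        for g in range(n_genes):
            gene_id = f"{sp_id}_g{1 + g:04d}"
            if g in rrna_idx:
                genes.append(GeneSpec(gene_id, int(lengths[g]) + 1200, is_rrna=True))
                continue
            ko = rng.choice(ko_vocab) if rng.random() < annotation_rate else None
            cog = rng.choice(cog_vocab) if rng.random() < annotation_rate else None
            genes.append(GeneSpec(gene_id, int(lengths[g]), ko_id=ko, cog_id=cog))
            protein_rows.append((gene_id, sp_id))
        total = sum(g.length_bp for g in genes)
        genome_len = int(total * (1.0 + rng.uniform(0.10, 0.25)))
        species.append(SpeciesSpec(sp_id, phylum, genome_len, tuple(genes)))

    # peptide catalogue: per protein, a handful of tryptic peptides
    plo, phi = peptides_per_protein
    pep_counts = rng.integers(plo, phi + 1, size=len(protein_rows))
    n_pep = int(pep_counts.sum())
    seqs = _unique_peptide_seqs(rng, n_pep)
    rows = []
    k = 0
    for (prot, sp_id), c in zip(protein_rows, pep_counts):
        for _ in range(int(c)):
            rows.append((seqs[k], prot, sp_id))
            k += 1
    peptides = pd.DataFrame(rows, columns=["peptide_seq", "protein_id", "species_id"])

    # share a fraction of peptides with a protein from a different species
    n_shared = int(round(shared_peptide_fraction * len(peptides)))
    if n_shared and n_species >= 2:
        shared_idx = rng.choice(len(peptides), size=n_shared, replace=False)
        prot_arr = np.array([p for p, _ in protein_rows])
        sp_arr = np.array([s for _, s in protein_rows])
        extra = []
        for i in shared_idx:
            own_sp = peptides.iloc[i]["species_id"]
            other = np.flatnonzero(sp_arr != own_sp)
            j = int(rng.choice(other))
            extra.append((peptides.iloc[i]["peptide_seq"], prot_arr[j], sp_arr[j]))
        peptides = pd.concat(
            [peptides, pd.DataFrame(extra, columns=peptides.columns)], ignore_index=True
        )
    peptides = peptides.sort_values(["peptide_seq", "protein_id"]).reset_index(drop=True)

    return CommunitySpec(tuple(species), pathways, peptides)


def build_design(
    runs: tuple[str, ...] = ("A", "B"),
    conditions: tuple[str, ...] = ("control", "drug"),
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Sample sheet for the time-course: run x condition x timepoint x replicate.

    Timepoints are hours since drug addition; the community was treated in
    exponential phase and sampled at 0/15/30 min, 1/3/43/91 h, with the whole
    experiment run twice (runs A and B) in duplicate.
    """
    if "control" not in conditions:
        raise InvalidDesignError("design must include a 'control' condition")
    rows = []
    for run in runs:
        for cond in conditions:
            for t in timepoints_h:
                for r in range(1, n_replicates + 1):
                    tag = f"{t:g}h".replace(".", "p")
                    rows.append((f"{run}_{cond}_{tag}_r{r}", run, cond, float(t), r))
    df = pd.DataFrame(
        rows, columns=["sample_id", "run", "condition", "timepoint_h", "replicate"]
    )
    if df["sample_id"].duplicated().any():
        raise InvalidDesignError("duplicate sample_id in design")
    return df
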