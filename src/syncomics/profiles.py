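"""Per-layer species and ortholog abundance profiles.

Implements the counting and normalization rules used to estimate relative
species abundance from each omics layer:

* multi-mapped reads are split evenly over the genes they map to (a read
  hitting k genes contributes 1/k to each);
* metagenome: per-species counts normalised by genome size (bp);
* metatranscriptome: per-species counts normalised by total coding bases after
  excluding rRNA regions;
* 16S amplicon: plain read-count fractions (no copy-number or length
  correction);
* metaproteome: summed filtered protein intensities per species over the
  per-sample total;
* taxon-specific scaling: a feature's relative abundance divided by its
  species' relative abundance, decoupling within-species functional
  composition from taxon abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunitySpec
from .errors import (
    EmptySampleError,
    InvalidCommunityError,
    InvalidIntensityError,
    UnknownFeatureError,
    UnsupportedLayerError,
)

LAYERS = ("16S", "metagenome", "metatranscriptome", "metaproteome", "metabolome", "OD")

UNANNOTATED = "unannotated"


@dataclass
class LayerCounts:
    """Feature x sample abundance table for one omics layer."""

    layer: str
    values: pd.DataFrame = field(repr=False)
    #: feature -> species_id / ko_id / cog_id, indexed like ``values``
    feature_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise UnsupportedLayerError(f"unknown layer {self.layer!r}")
        vals = self.values.to_numpy()
        if np.nanmin(vals, initial=0.0) < 0:
            raise InvalidIntensityError("negative values in LayerCounts")
        missing = self.values.index.difference(self.feature_map.index)
        if len(missing):
            raise UnknownFeatureError(f"features without mapping: {list(missing)[:5]}")


@dataclass
class SpeciesProfile:
    """Species x sample relative abundances for one layer; columns sum to 1."""

    layer: str
    values: pd.DataFrame = field(repr=False)
    #: optional detection mask (False = species not detected in that sample)
    detected: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ReadAssignments:
    """Aggregated read-to-gene assignments for one sequencing layer.

    ``table`` has columns sample_id, gene_ids (';'-joined identifiers a read
    maps to) and n_reads (how many reads share that exact assignment set).
    """

    layer: str
    table: pd.DataFrame = field(repr=False)


def distribute_multimapped(
    assignments: ReadAssignments, community: CommunitySpec
) -> LayerCounts:
    """Split multi-mapped reads evenly: a read over k genes adds 1/k to each.

    Conserves total read count exactly per sample.
    """
    tab = assignments.table
    if tab.empty:
        raise EmptySampleError("no read assignments")
    parts = tab["gene_ids"].str.split(";")
    k = parts.str.len().to_numpy()
    if (parts.apply(lambda g: len(set(g))) != k).any():
        raise UnknownFeatureError("duplicate gene_id within an assignment record")
    expanded = pd.DataFrame(
        {
            "sample_id": tab["sample_id"].repeat(k).to_numpy(),
            "gene_id": np.concatenate(parts.to_numpy()),
            "count": (tab["n_reads"].to_numpy() / k).repeat(k),
        }
    )
    known = community.genes.index
    unknown = set(expanded["gene_id"]).difference(known)
    if unknown:
        raise UnknownFeatureError(f"unknown gene_ids: {sorted(unknown)[:5]}")
    values = (
        expanded.pivot_table(
            index="gene_id", columns="sample_id", values="count", aggfunc="sum", fill_value=0.0
        )
        .reindex(known, fill_value=0.0)
    )
    values.columns.name = None
    return LayerCounts(assignments.layer, values, community.feature_map())


def _column_fractions(values: pd.DataFrame) -> pd.DataFrame:
    totals = values.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise EmptySampleError(f"samples with zero total counts: {list(empty.index)[:5]}")
    return values / totals


def metagenome_species_abundance(
    counts: LayerCounts, community: CommunitySpec
) -> SpeciesProfile:
    """Species fractions from metagenomic counts, genome-size normalised."""
    if counts.layer != "metagenome":
        raise UnsupportedLayerError(f"expected metagenome counts, got {counts.layer}")
    per_species = counts.values.groupby(counts.feature_map["species_id"]).sum()
    per_species = per_species.reindex(community.species_ids, fill_value=0.0)
    density = per_species.div(community.genome_lengths, axis=0)
    return SpeciesProfile("metagenome", _column_fractions(density))


def metatranscriptome_species_abundance(
    counts: LayerCounts, community: CommunitySpec
) -> SpeciesProfile:
    """Species fractions from metatranscriptomic counts.

    Normalised by total coding bases per genome after excluding rRNA regions.
    """
    if counts.layer != "metatranscriptome":
        raise UnsupportedLayerError(f"expected metatranscriptome counts, got {counts.layer}")
    coding = community.coding_bases
    if (coding <= 0).any():
        bad = coding[coding <= 0].index.tolist()
        raise InvalidCommunityError(f"species with zero coding bases: {bad}")
    per_species = counts.values.groupby(counts.feature_map["species_id"]).sum()
    per_species = per_species.reindex(community.species_ids, fill_value=0.0)
    density = per_species.div(coding, axis=0)
    return SpeciesProfile("metatranscriptome", _column_fractions(density))


def amplicon_species_abundance(counts16s: pd.DataFrame) -> SpeciesProfile:
    """Species fractions from 16S read counts; deliberately no length or
    copy-number correction (one count = one read)."""
    if (counts16s.to_numpy() < 0).any():
        raise InvalidIntensityError("negative 16S counts")
    return SpeciesProfile("16S", _column_fractions(counts16s))


def proteome_species_abundance(
    quant: pd.DataFrame, protein_species: pd.Series, species_ids: list[str] | None = None
) -> SpeciesProfile:
    """Species fractions from filtered protein intensities.

    Sums all filtered protein intensities per species and divides by the total
    summed intensity per sample. Species with no detected protein get fraction
    0 and are flagged not-detected in the ``detected`` mask.
    """
    arr = quant.to_numpy()
    if np.nanmin(arr, initial=0.0) < 0:
        raise InvalidIntensityError("negative protein intensity")
    sums = quant.fillna(0.0).groupby(protein_species.reindex(quant.index)).sum()
    if species_ids is not None:
        sums = sums.reindex(species_ids, fill_value=0.0)
    fractions = _column_fractions(sums)
    detected = sums > 0
    return SpeciesProfile("metaproteome", fractions, detected=detected)


def taxon_specific_scaling(
    counts: LayerCounts, profile: SpeciesProfile | None = None
) -> LayerCounts:
    """Divide each feature's relative abundance by its species' relative
    abundance in the same sample.

    With the default profile (the species' share of the same count table) the
    result is exactly the feature's within-species fraction: invariant to
    rescaling a species' total abundance while its within-species composition
    is held fixed. A layer-specific profile (e.g. genome-size normalised) may
    be passed instead. Features of species undetected in a sample become NaN
    (masked), never zero.
    """
    species = counts.feature_map["species_id"]
    if profile is None:
        sp_counts = counts.values.groupby(species).sum()
        profile = SpeciesProfile(counts.layer, _column_fractions(sp_counts))
    missing = set(species).difference(profile.values.index)
    if missing:
        raise UnknownFeatureError(f"species absent from profile: {sorted(missing)[:5]}")
    feat_frac = _column_fractions(counts.values)
    sp_frac = profile.values.reindex(species.to_numpy())
    sp_frac.index = counts.values.index
    sp_frac = sp_frac.reindex(columns=counts.values.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = feat_frac / sp_frac.where(sp_frac > 0)
    return LayerCounts(counts.layer, scaled, counts.feature_map)


def aggregate_by_ortholog(counts: LayerCounts, level: str = "KO") -> pd.DataFrame:
    """Sum feature values sharing an ortholog identifier.

    Features without annotation are collected under an 'unannotated' bucket so
    column sums are conserved.
    """
    col = {"KO": "ko_id", "COG": "cog_id"}.get(level)
    if col is None:
        raise UnsupportedLayerError(f"ortholog level must be KO or COG, got {level!r}")
    keys = counts.feature_map[col].reindex(counts.values.index).fillna(UNANNOTATED)
    out = counts.values.groupby(keys).sum()
    out.index.name = col
    return out


def profile_to_tidy(profile: SpeciesProfile) -> pd.DataFrame:
    """Long-format (layer, species, sample, abundance) table; profiles from
    all layers concatenate into one tidy table."""
    tidy = profile.values.stack().rename("abundance").reset_index()
    tidy.columns = ["species_id", "sample_id", "abundance"]
    tidy.insert(0, "layer", profile.layer)
    return tidy
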