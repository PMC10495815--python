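"""Peptide filtering and top-3 protein quantification.

Input is a peptide-level DIA report: one row per peptide with its protein and
species match lists and per-sample intensities (missing allowed). Only
peptides matching exactly one species are used for quantification; within a
protein, peptides are ranked by the number of samples they were detected in
and the protein abundance per sample is the mean of its three most commonly
measured peptides. Proteins with fewer than three species-unique peptides are
discarded.

Ties in "most commonly measured" are broken by higher mean intensity, then by
peptide sequence, giving a total order so results are independent of input
row order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import CommunitySpec
from .errors import UnknownFeatureError

N_TOP_PEPTIDES = 3


def n_samples_detected(report: pd.DataFrame, sample_cols: list[str]) -> pd.Series:
    """Per row, the count of samples with a positive, non-missing intensity."""
    vals = report[sample_cols].to_numpy(float)
    return pd.Series((~np.isnan(vals) & (vals > 0)).sum(axis=1), index=report.index)


def filter_species_unique_peptides(report: pd.DataFrame) -> pd.DataFrame:
    """Keep only peptides whose species match list has exactly one species.

    Peptides shared among several proteins of that single species are
    retained; the uniqueness constraint is at the species level only.
    """
    if report.empty:
        warnings.warn("empty peptide report")
        return report.copy()
    n_species = report["species_matches"].str.split(";").str.len()
    n_species = n_species.where(report["species_matches"].str.len() > 0, 0)
    return report[n_species == 1].copy()


def top3_quantify(
    peptides: pd.DataFrame, sample_cols: list[str]
) -> pd.Series | None:
    """Quantify one protein from its species-unique peptides.

    Sort by detection count (descending; ties: higher mean intensity, then
    lexicographic peptide sequence), take the top three, and average their
    intensities per sample with missing values excluded from the mean.
    Returns None (discarded) when fewer than three peptides are available.
    """
    if len(peptides) < N_TOP_PEPTIDES:
        return None
    detected = n_samples_detected(peptides, sample_cols)
    mean_int = peptides[sample_cols].mean(axis=1, skipna=True).fillna(0.0)
    order = (
        pd.DataFrame(
            {
                "detected": detected,
                "mean_int": mean_int,
                "peptide_seq": peptides["peptide_seq"],
            }
        )
        .sort_values(
            ["detected", "mean_int", "peptide_seq"], ascending=[False, False, True]
        )
        .index[:N_TOP_PEPTIDES]
    )
    top = peptides.loc[order, sample_cols].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN columns
        return top.mean(axis=0, skipna=True)


def quantify_report(
    report: pd.DataFrame,
    community: CommunitySpec,
    sample_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full quantification: filter, explode to proteins, top-3 per protein.

    Returns the protein x sample abundance table (only proteins with >= 3
    species-unique peptides) and a protein -> species mapping aligned to it.
    Duplicate peptide rows are dropped first, so the result is idempotent
    under row duplication and row order.
    """
    if sample_cols is None:
        sample_cols = [
            c
            for c in report.columns
            if c not in ("peptide_seq", "protein_matches", "species_matches")
        ]
    filtered = filter_species_unique_peptides(report)
    filtered = filtered.drop_duplicates(subset=["peptide_seq", "protein_matches"])
    if filtered.empty:
        return pd.DataFrame(columns=sample_cols), pd.Series(dtype=object)

    known = set(community.genes.index)
    exploded = filtered.assign(
        protein_id=filtered["protein_matches"].str.split(";")
    ).explode("protein_id")
    unknown = set(exploded["protein_id"]).difference(known)
    if unknown:
        raise UnknownFeatureError(f"proteins not in community: {sorted(unknown)[:5]}")

    rows, species = {}, {}
    for protein_id, grp in exploded.groupby("protein_id", sort=True):
        quant = top3_quantify(grp, sample_cols)
        if quant is not None:
            rows[protein_id] = quant
            species[protein_id] = grp["species_matches"].iloc[0]
    if not rows:
        return pd.DataFrame(columns=sample_cols), pd.Series(dtype=object)
    table = pd.DataFrame(rows).T[sample_cols]
    table.index.name = "protein_id"
    return table, pd.Series(species, name="species_id")
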