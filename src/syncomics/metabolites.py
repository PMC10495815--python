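"""Accurate-mass metabolite annotation for flow-injection MS ion tables.

Ions (m/z, polarity, per-sample intensities) are quantile-normalised per
polarity, then tentatively annotated against a reference of monoisotopic
metabolite masses. Matching uses a dynamic tolerance growing linearly with
m/z (1 mDa at m/z 50 to 5 mDa at m/z 1000, tracking instrument resolving
power), enumerating [M-H]/[M-2H] adducts in negative mode, [M+]/[M+H]/
[M+Na]/[M+K] in positive mode, each with up to two 12C->13C substitutions.
One ion may receive many annotations and one metabolite many ions: this is
the tentative, isomer-ambiguous regime of MS1-only acquisition.

Filtering then keeps annotated ions only, drops ions explainable solely as
13C isotopologues, and retains one representative ion per metabolite (the one
tracking the total ion current best, falling back to largest mean intensity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

# masses in Da
PROTON = 1.007276
ELECTRON = 0.000549
NA_ADDUCT = 22.989218  # [M+Na] offset
K_ADDUCT = 38.963158  # [M+K] offset
C13_SHIFT = 1.003355  # 13C - 12C

MZ_MIN, MZ_MAX = 50.0, 1000.0
TOL_MIN_DA, TOL_MAX_DA = 1e-3, 5e-3

POLARITIES = ("negative", "positive")

#: (label, charge, neutral-mass offset applied before dividing by charge)
ADDUCTS: dict[str, tuple[tuple[str, int, float], ...]] = {
    "negative": (
        ("[M-H]", 1, -PROTON),
        ("[M-2H]", 2, -2 * PROTON),
    ),
    "positive": (
        ("[M+]", 1, -ELECTRON),
        ("[M+H]", 1, PROTON),
        ("[M+Na]", 1, NA_ADDUCT),
        ("[M+K]", 1, K_ADDUCT),
    ),
}


@dataclass(frozen=True)
class Annotation:
    """One tentative ion-metabolite match."""

    ion_id: str
    metabolite_id: str
    adduct: str
    n_13c: int
    delta_mda: float


def mass_tolerance(mz: float | np.ndarray) -> float | np.ndarray:
    """Dynamic matching tolerance in Da, linear in m/z.

    1 mDa at m/z = 50 rising to 5 mDa at m/z = 1000; clamped outside the
    acquisition range.
    """
    mz = np.clip(mz, MZ_MIN, MZ_MAX)
    return TOL_MIN_DA + (TOL_MAX_DA - TOL_MIN_DA) * (mz - MZ_MIN) / (MZ_MAX - MZ_MIN)


def enumerate_candidate_mz(
    mass: float, polarity: str, max_13c: int = 2
) -> pd.DataFrame:
    """All candidate m/z values for one neutral monoisotopic mass.

    Each adduct is replicated with 0..max_13c 13C substitutions; the isotope
    shift is applied to the neutral mass before the adduct transform, so a
    singly-charged candidate moves by exactly 1.003355 Da per substitution.
    """
    rows = []
    for label, charge, offset in ADDUCTS[polarity]:
        for n in range(max_13c + 1):
            mz = (mass + n * C13_SHIFT + offset) / charge
            rows.append((mz, label, n))
    return pd.DataFrame(rows, columns=["mz", "adduct", "n_13c"])


def quantile_normalize(
    intensities: pd.DataFrame, polarity: pd.Series
) -> pd.DataFrame:
    """Quantile-normalise ion intensities separately per polarity block.

    Within each block every sample's sorted values are replaced by the
    across-sample mean of order statistics; tied values receive the mean of
    the values they would have been assigned.
    """
    out = intensities.copy().astype(float)
    for pol in polarity.reindex(intensities.index).unique():
        idx = polarity.index[polarity == pol].intersection(intensities.index)
        block = intensities.loc[idx]
        if block.shape[1] < 2:
            warnings.warn(f"single-sample block {pol!r}: identity transform")
            continue
        arr = block.to_numpy(float)
        ref = np.sort(arr, axis=0).mean(axis=1)
        norm = np.empty_like(arr)
        for j in range(arr.shape[1]):
            order = np.argsort(arr[:, j], kind="stable")
            norm[order, j] = ref
        # ties: average the assigned reference values within each tie group
        frame = pd.DataFrame(norm, index=block.index, columns=block.columns)
        for j, col in enumerate(block.columns):
            tied = pd.Series(norm[:, j]).groupby(arr[:, j]).transform("mean")
            frame[col] = tied.to_numpy()
        out.loc[idx] = frame
    return out


def annotate_ions(
    ions: pd.DataFrame, refs: pd.DataFrame, max_13c: int = 2
) -> pd.DataFrame:
    """Tentatively annotate ions by accurate mass.

    Parameters
    ----------
    ions
        Table with columns ion_id, mz, polarity.
    refs
        Metabolite reference with columns metabolite_id, monoisotopic_mass.

    Returns
    -------
    One row per (ion, metabolite, adduct, n_13c) match within the dynamic
    tolerance at the ion's m/z; column delta_mda is the signed matching error
    (ion minus candidate) in mDa.
    """
    if refs.empty:
        raise InsufficientDataError("empty metabolite reference")
    out_rows = []
    for pol in POLARITIES:
        sub = ions[ions["polarity"] == pol]
        if sub.empty:
            continue
        cand = []
        for _, ref in refs.iterrows():
            c = enumerate_candidate_mz(float(ref["monoisotopic_mass"]), pol, max_13c)
            c["metabolite_id"] = ref["metabolite_id"]
            cand.append(c)
        cand = pd.concat(cand, ignore_index=True).sort_values("mz").reset_index(drop=True)
        cmz = cand["mz"].to_numpy()
        for ion_id, mz in zip(sub["ion_id"], sub["mz"].astype(float)):
            tol = float(mass_tolerance(mz))
            lo = np.searchsorted(cmz, mz - tol, side="left")
            hi = np.searchsorted(cmz, mz + tol, side="right")
            for k in range(lo, hi):
                out_rows.append(
                    (
                        ion_id,
                        cand.at[k, "metabolite_id"],
                        cand.at[k, "adduct"],
                        int(cand.at[k, "n_13c"]),
                        (mz - cmz[k]) * 1e3,
                    )
                )
    return pd.DataFrame(
        out_rows, columns=["ion_id", "metabolite_id", "adduct", "n_13c", "delta_mda"]
    )


def total_ion_current(ions: pd.DataFrame, sample_cols: list[str]) -> pd.Series:
    """Per-sample sum of all ion intensities (computed before filtering)."""
    return ions[sample_cols].sum(axis=0)


def _spearman_vs_tic(row: np.ndarray, tic: np.ndarray) -> float:
    ok = ~(np.isnan(row) | np.isnan(tic))
    if ok.sum() < 3 or np.unique(row[ok]).size < 2 or np.unique(tic[ok]).size < 2:
        return np.nan
    rho, _ = stats.spearmanr(row[ok], tic[ok])
    return float(rho)


def filter_annotated_ions(
    ions: pd.DataFrame,
    annotations: pd.DataFrame,
    sample_cols: list[str],
    tic: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the ion-filtering rules.

    1. Drop unannotated ions.
    2. Drop ions whose every annotation carries a 13C substitution.
    3. Per metabolite keep one representative ion: highest Spearman
       correlation with the total ion current when computable, else largest
       mean intensity (ties: lower \\|delta\\|, then lower m/z).

    Returns the filtered ion table (unique retained ions) and the
    metabolite -> representative-ion mapping.
    """
    if tic is None:
        tic = total_ion_current(ions, sample_cols)
    ions = ions.set_index("ion_id", drop=False) if ions.index.name != "ion_id" else ions
    ann = annotations
    annotated = set(ann["ion_id"])
    has_mono = set(ann.loc[ann["n_13c"] == 0, "ion_id"])
    keep_ids = annotated & has_mono  # (1) + (2)
    ann = ann[ann["ion_id"].isin(keep_ids) & (ann["n_13c"] == 0)]

    tic_arr = tic.reindex(sample_cols).to_numpy(float)
    stats_rows = []
    for ion_id in sorted(keep_ids):
        row = ions.loc[ion_id, sample_cols].to_numpy(float)
        stats_rows.append(
            (ion_id, _spearman_vs_tic(row, tic_arr), float(np.nanmean(row)))
        )
    ion_stats = pd.DataFrame(stats_rows, columns=["ion_id", "tic_rho", "mean_int"]).set_index(
        "ion_id"
    )

    reps = []
    for met, grp in ann.groupby("metabolite_id"):
        cand = grp.merge(ion_stats, left_on="ion_id", right_index=True)
        cand = cand.assign(
            abs_delta=cand["delta_mda"].abs(),
            mz=ions.loc[cand["ion_id"], "mz"].to_numpy(float),
        )
        if cand["tic_rho"].notna().any():
            cand = cand.sort_values(
                ["tic_rho", "abs_delta", "mz"], ascending=[False, True, True]
            )
        else:
            cand = cand.sort_values(
                ["mean_int", "abs_delta", "mz"], ascending=[False, True, True]
            )
        reps.append((met, cand.iloc[0]["ion_id"]))
    rep_map = pd.DataFrame(reps, columns=["metabolite_id", "ion_id"])
    retained = ions.loc[sorted(set(rep_map["ion_id"]))].reset_index(drop=True)
    return retained, rep_map
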