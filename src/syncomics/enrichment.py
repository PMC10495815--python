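"""Differential abundance selection and set enrichment.

Fold changes are computed on raw values against matched controls (same run,
timepoint, replicate) with a small pseudocount. Features are selected per
layer at the study's thresholds — transcripts |log2FC| > 2 at pFDR < 0.001,
proteins and metabolites |log2FC| > log2(1.5) at pFDR < 0.05 — using, per
feature, the single measurement with the maximum absolute fold change over
time. Selected sets are tested for pathway/COG over-representation with
Fisher's exact test and Benjamini-Hochberg adjustment across sets; for
metabolomics each ion contributes once even when annotated to several
metabolites of a pathway.

The permutation feature test is plumbing: a paired sign-flip test standing in
for the external differential machinery (DESeq2 / mixed models) the original
analysis called, so the pipeline runs end-to-end on synthetic data. It is not
a reimplementation of those tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, PairingError, UnsupportedLayerError

#: per-layer (|log2FC| cut, pFDR cut)
SELECTION_THRESHOLDS = {
    "metatranscriptome": (2.0, 0.001),
    "metaproteome": (float(np.log2(1.5)), 0.05),
    "metabolome": (float(np.log2(1.5)), 0.05),
}


def _match_pairs(design: pd.DataFrame, condition: str) -> pd.DataFrame:
    treated = design[design["condition"] == condition]
    control = design[design["condition"] == "control"]
    merged = treated.merge(
        control,
        on=["run", "timepoint_h", "replicate"],
        suffixes=("_treated", "_control"),
    )
    missing = len(treated) - len(merged)
    if missing:
        raise PairingError(
            f"{missing} treated samples lack a matched control (run/timepoint/replicate)"
        )
    return merged


def fold_change_vs_control(
    values: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """log2 fold change of raw values vs matched controls.

    log2((treated + eps) / (control + eps)), averaged over replicate pairs,
    one column per timepoint. eps defaults to half the smallest nonzero value
    of the table, so zero-vs-zero comparisons give fold change 0.
    """
    if pseudocount is None:
        arr = values.to_numpy(float)
        nz = arr[np.isfinite(arr) & (arr > 0)]
        pseudocount = float(nz.min()) / 2 if nz.size else 1.0
    pairs = _match_pairs(design, condition)
    out = {}
    for t, grp in pairs.groupby("timepoint_h"):
        fcs = []
        for row in grp.itertuples(index=False):
            tr = values[row.sample_id_treated].to_numpy(float)
            ct = values[row.sample_id_control].to_numpy(float)
            fcs.append(np.log2(tr + pseudocount) - np.log2(ct + pseudocount))
        out[t] = np.nanmean(np.column_stack(fcs), axis=1)
    fc = pd.DataFrame(out, index=values.index)
    fc.columns.name = "timepoint_h"
    return fc


def max_abs_fold_change(fc: pd.DataFrame) -> pd.Series:
    """Per feature, the signed fold change with maximum |value| over time."""
    arr = fc.to_numpy(float)
    arr = np.where(np.isnan(arr), 0.0, arr)
    idx = np.argmax(np.abs(arr), axis=1)
    return pd.Series(arr[np.arange(len(fc)), idx], index=fc.index, name="log2fc")


def select_differential(
    fc: pd.DataFrame, padj: pd.Series, layer: str
) -> dict[str, set[str]]:
    """Apply the layer's fold-change and pFDR cuts; split by direction.

    Uses per feature the measurement with maximum absolute log2 fold change
    over time. Returns {'up': set, 'down': set}.
    """
    if layer not in SELECTION_THRESHOLDS:
        raise UnsupportedLayerError(
            f"no selection thresholds for layer {layer!r}; "
            f"expected one of {sorted(SELECTION_THRESHOLDS)}"
        )
    fc_cut, p_cut = SELECTION_THRESHOLDS[layer]
    rep = max_abs_fold_change(fc)
    padj = padj.reindex(rep.index)
    passing = (rep.abs() > fc_cut) & (padj < p_cut)
    return {
        "up": set(rep.index[passing & (rep > 0)]),
        "down": set(rep.index[passing & (rep < 0)]),
    }


def benjamini_hochberg(pvalues: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    arr = np.asarray(pvalues, float)
    adj = multipletests(arr, method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(adj, index=pvalues.index, name="p_adj")
    return adj


def fisher_enrichment(
    selected: set[str],
    universe: set[str],
    set_map: dict[str, frozenset[str] | set[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher exact over-representation of each set within the selection.

    The 2x2 table per set is (in-set & selected, in-set & not, out-of-set &
    selected, out-of-set & not) over the universe; p-values are BH-adjusted
    across sets. Callers testing up- and down-regulated features run this
    once per direction.
    """
    if not selected <= universe:
        raise ConsistencyError("selected features must be a subset of the universe")
    rows = []
    for set_id in sorted(set_map):
        members = set(set_map[set_id]) & universe
        a = len(members & selected)
        b = len(members) - a
        c = len(selected) - a
        d = len(universe) - a - b - c
        if not selected:
            p = 1.0
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        rows.append((set_id, a, b, c, d, p))
    out = pd.DataFrame(rows, columns=["set_id", "a", "b", "c", "d", "p"])
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out


def deduplicate_ion_features(
    annotations: pd.DataFrame, set_map: dict[str, frozenset[str] | set[str]]
) -> dict[str, set[str]]:
    """Pathway -> ion-id membership for metabolite-mode enrichment.

    Enrichment runs on ion features: an ion annotated to two or more
    metabolites of the same pathway is counted only once, because sets are
    keyed by ion_id.
    """
    met_to_paths: dict[str, set[str]] = {}
    for pid, mets in set_map.items():
        for m in mets:
            met_to_paths.setdefault(m, set()).add(pid)
    out: dict[str, set[str]] = {pid: set() for pid in set_map}
    for ion_id, met in zip(annotations["ion_id"], annotations["metabolite_id"]):
        for pid in met_to_paths.get(met, ()):
            out[pid].add(ion_id)
    return out


def permutation_feature_test(
    values: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired sign-flip permutation test per feature (plumbing, not a method
    from the study): statistic = mean matched-pair difference (treated -
    control on log1p values); two-sided p with the add-one estimator;
    BH-adjusted across features.
    """
    pairs = _match_pairs(design, condition)
    treated = np.log1p(values[pairs["sample_id_treated"]].to_numpy(float))
    control = np.log1p(values[pairs["sample_id_control"]].to_numpy(float))
    diffs = treated - control  # features x pairs
    n_valid = np.maximum((~np.isnan(diffs)).sum(axis=1), 1)
    filled = np.nan_to_num(diffs, nan=0.0)
    obs = filled.sum(axis=1) / n_valid
    rng = np.random.default_rng(seed)
    n_pairs = diffs.shape[1]
    # vectorised sign flips: (features x pairs) @ (pairs x n_perm)
    signs = rng.choice([-1.0, 1.0], size=(n_pairs, n_perm))
    perm = (filled @ signs) / n_valid[:, None]
    hits = (np.abs(perm) >= np.abs(obs)[:, None]).sum(axis=1)
    p = (1 + hits) / (1 + n_perm)
    return pd.DataFrame(
        {"p": p, "p_adj": benjamini_hochberg(p)}, index=values.index
    )
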