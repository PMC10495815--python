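"""Cross-omics concordance statistics.

Coverage metrics (what fraction of a species' genes, or a pathway's members,
each layer detects), pooled Spearman agreement between species profiles from
different layers, sample-distance matrices (1 - Spearman) with per-layer
abundance floors, the Mantel permutation test between them, diversity indices
(inverse Simpson, Bray-Curtis), logistic growth-curve fitting, and the lagged
transcript-protein fold-change correlation that exposes the delay between
transcription and translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import braycurtis

from .community import CommunitySpec
from .errors import AlignmentError, InsufficientDataError, InvalidCommunityError
from .profiles import LayerCounts, SpeciesProfile

#: per-layer mean-abundance floors for sample-distance construction
MANTEL_FLOORS = {"metagenome": 1e-7, "metatranscriptome": 1e-7, "metaproteome": 1e-5}

DEFAULT_N_PERM = 999


@dataclass
class DistanceMatrix:
    """Symmetric sample-distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise AlignmentError("distance matrix shape does not match sample_ids")
        if not np.allclose(np.diag(v), 0.0, equal_nan=True):
            raise AlignmentError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-12:
                raise AlignmentError("distance matrix must be symmetric")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]


def gene_coverage(
    counts: LayerCounts, community: CommunitySpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of each species' predicted genes detected (count > 0).

    Returns the per-sample species x sample coverage table and, per species,
    the maximum coverage over samples.
    """
    genes_per_species = community.genes.groupby("species_id").size()
    if (genes_per_species == 0).any():
        raise InvalidCommunityError("species with zero genes")
    hit = (counts.values > 0).groupby(counts.feature_map["species_id"]).sum()
    hit = hit.reindex(genes_per_species.index, fill_value=0)
    cov = hit.div(genes_per_species, axis=0)
    return cov, cov.max(axis=1)


def pathway_coverage(
    detected: set[str], pathway_map: dict[str, frozenset[str] | set[str]]
) -> pd.Series:
    """Per pathway, detected members / pathway size.

    Works for KO-mode (detected KOs vs KO members) and metabolite-mode
    (unique metabolites via retained annotations vs pathway metabolites);
    membership sets define the mode. Empty pathways are excluded with a
    warning.
    """
    out = {}
    for pid, members in pathway_map.items():
        if not members:
            warnings.warn(f"pathway {pid} is empty; excluded")
            continue
        out[pid] = len(detected & set(members)) / len(members)
    return pd.Series(out, name="coverage").sort_index()


def cross_omics_spearman(
    profile_a: SpeciesProfile,
    profile_b: SpeciesProfile,
    min_abundance: float | None = None,
) -> float:
    """Pooled Spearman correlation between two layers' species profiles.

    Pools (species, sample) pairs present in both layers; the optional floor
    keeps pairs where both abundances reach it (mirroring the low-abundance
    cutoffs applied when comparing 16S with metagenomics). Masked values are
    excluded pairwise.
    """
    samples = profile_a.values.columns.intersection(profile_b.values.columns)
    species = profile_a.values.index.intersection(profile_b.values.index)
    if len(samples) < 3:
        raise InsufficientDataError("need >= 3 shared samples")
    a = profile_a.values.loc[species, samples].to_numpy(float).ravel()
    b = profile_b.values.loc[species, samples].to_numpy(float).ravel()
    ok = ~(np.isnan(a) | np.isnan(b))
    if min_abundance is not None:
        ok &= (a >= min_abundance) & (b >= min_abundance)
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 shared (species, sample) pairs")
    rho, _ = stats.spearmanr(a[ok], b[ok])
    return float(rho)


def sample_distance(
    features: pd.DataFrame, mean_abundance_floor: float = 0.0
) -> DistanceMatrix:
    """1 - Spearman distance between samples over feature vectors.

    Features whose mean abundance falls below the floor are excluded first.
    Pairs involving a constant sample vector are undefined and masked NaN.
    """
    if features.shape[1] < 2:
        raise InsufficientDataError("need >= 2 samples")
    kept = features[features.mean(axis=1, skipna=True) >= mean_abundance_floor]
    rho = kept.corr(method="spearman")  # pairwise NaN deletion
    d = 1.0 - rho.to_numpy(float)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(features.columns), d)


def mantel(
    da: DistanceMatrix,
    db: DistanceMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test between two distance matrices over the same samples.

    r is the Pearson correlation of the upper triangles; the one-sided
    p-value permutes rows/columns of the second matrix jointly and uses the
    add-one estimator p = (1 + #{r_perm >= r}) / (1 + n_perm).
    """
    if da.sample_ids != db.sample_ids:
        if set(da.sample_ids) != set(db.sample_ids):
            raise AlignmentError("distance matrices have different sample sets")
        order = [db.sample_ids.index(s) for s in da.sample_ids]
        db = DistanceMatrix(da.sample_ids, db.values[np.ix_(order, order)])
    n = len(da.sample_ids)
    if n < 4:
        raise InsufficientDataError("Mantel test needs >= 4 samples")
    iu = np.triu_indices(n, k=1)
    x = da.values[iu]
    y = db.values[iu]
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("NaN entries in distance matrices")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = db.values[np.ix_(perm, perm)][iu]
        if stats.pearsonr(x, yp)[0] >= r:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return r, p


def inverse_simpson(p: np.ndarray | pd.Series) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2); input renormalised to 1."""
    p = np.asarray(p, float)
    p = p[p > 0]
    if p.size == 0:
        raise InsufficientDataError("empty abundance vector")
    p = p / p.sum()
    return float(1.0 / np.sum(p**2))


def bray_curtis(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    return float(braycurtis(np.asarray(x, float), np.asarray(y, float)))


@dataclass
class SigmoidFit:
    """Least-squares logistic fit L / (1 + exp(-k (t - t0)))."""

    L: float
    k: float
    t0: float
    success: bool
    message: str = ""
    normalized: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.L / (1.0 + np.exp(-self.k * (np.asarray(t, float) - self.t0)))


def _logistic(t, L, k, t0):
    return L / (1.0 + np.exp(-k * (t - t0)))


def fit_sigmoid_growth(time_h: np.ndarray, od: np.ndarray) -> SigmoidFit:
    """Fit a logistic growth curve to OD measurements and normalise by L.

    Initialisation is deterministic: L = max(OD), t0 = time of half-max,
    k from the finite-difference slope at t0 (slope at midpoint = L k / 4).
    Degenerate series (too few points, non-increasing) return a fit-failure
    flag with diagnostics instead of raising.
    """
    t = np.asarray(time_h, float)
    y = np.asarray(od, float)
    if t.size < 4:
        return SigmoidFit(np.nan, np.nan, np.nan, False, "need >= 4 points")
    if y[-1] <= y[0]:
        return SigmoidFit(np.nan, np.nan, np.nan, False, "series not increasing")
    L0 = float(np.max(y))
    i0 = int(np.argmin(np.abs(y - L0 / 2)))
    t0 = float(t[i0])
    lo, hi = max(i0 - 1, 0), min(i0 + 1, t.size - 1)
    slope = (y[hi] - y[lo]) / (t[hi] - t[lo]) if t[hi] > t[lo] else 0.0
    k0 = max(4.0 * slope / L0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            _logistic, t, y, p0=(L0, k0, t0), maxfev=10_000
        )
    except RuntimeError as exc:
        return SigmoidFit(np.nan, np.nan, np.nan, False, f"non-convergence: {exc}")
    L, k, t0 = map(float, popt)
    if L <= 0 or k <= 0:
        return SigmoidFit(L, k, t0, False, "non-physical parameters")
    norm = pd.DataFrame({"time_h": t, "od_normalized": _logistic(t, L, k, t0) / L})
    return SigmoidFit(L, k, t0, True, "", norm)


def lagged_fc_correlation(
    transcript_fc: pd.DataFrame, protein_fc: pd.DataFrame, min_features: int = 10
) -> pd.DataFrame:
    """Spearman rho between transcript fold changes at timepoint i and protein
    fold changes at timepoint j, for all (i, j).

    Rows index transcript timepoints, columns protein timepoints. A protein
    response lagging the transcript response by one timepoint shows up as the
    argmax of each row sitting one column to the right of the diagonal.
    """
    shared = transcript_fc.index.intersection(protein_fc.index)
    if len(shared) < min_features:
        raise InsufficientDataError(
            f"only {len(shared)} shared features; need >= {min_features}"
        )
    tf = transcript_fc.loc[shared]
    pf = protein_fc.loc[shared]
    out = pd.DataFrame(index=tf.columns, columns=pf.columns, dtype=float)
    for i in tf.columns:
        for j in pf.columns:
            a, b = tf[i].to_numpy(float), pf[j].to_numpy(float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < min_features or np.unique(a[ok]).size < 2 or np.unique(b[ok]).size < 2:
                out.loc[i, j] = np.nan
                continue
            out.loc[i, j] = stats.spearmanr(a[ok], b[ok])[0]
    out.index.name = "transcript_t"
    out.columns.name = "protein_t"
    return out
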