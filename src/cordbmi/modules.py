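"""Weighted-correlation-network metabolite modules.

An unsigned weighted network is built from pairwise Pearson correlations of
the transformed metabolite columns, ``a_ij = |cor(x_i, x_j)|^beta``.  The
soft-thresholding power ``beta`` is chosen so the connectivity distribution
approximates scale-free topology (fit index plateauing near a target,
default 0.80); the clustering similarity is the topological overlap measure

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with ``TOM_ii = 1`` and connectivity ``k_i = sum_j a_ij``.  Modules are
branches of the average-linkage dendrogram of ``1 - TOM``, cut at a fixed
fraction of the maximum merge height (a "tree"-style static variant of
dynamic tree cut); branches smaller than the minimum module size stay
unassigned ("grey").  Module colors follow the conventional size-ordered
color sequence, and each module is summarized by an eigen-metabolite: the
first principal component of its standardized members, scaled to unit
variance and oriented to correlate positively with the members' mean
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

GREY = "grey"

#: conventional module color sequence, assigned in decreasing size order
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


def adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """Unsigned soft-thresholded adjacency |corr|^beta with zero diagonal."""
    a = np.abs(np.asarray(corr, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal."""
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-frequency regression.

    Connectivities are binned into ``n_bins`` equal-width bins; the log10
    frequency is regressed on the log10 mean connectivity over non-empty
    bins.  The squared correlation is returned, negated when the slope is
    positive (scale-free topology implies a falling frequency).  Fewer than
    three non-empty bins -> NaN (fit undefined).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 3 or np.ptp(k) == 0:
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    nonempty = counts > 0
    if nonempty.sum() < 3:
        return np.nan
    mean_k = sums[nonempty] / counts[nonempty]
    freq = counts[nonempty] / counts.sum()
    fit = linregress(np.log10(mean_k), np.log10(freq))
    r2 = fit.rvalue**2
    return -r2 if fit.slope > 0 else r2


def pick_power(
    corr: np.ndarray,
    candidate_powers=range(1, 21),
    target_r2: float = 0.80,
    plateau_increment: float = 0.02,
    n_bins: int = 10,
    min_mean_connectivity: float = 1.0,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches the target on a plateau.

    The plateau rule accepts the smallest beta with fit >= target whose
    improvement over beta-1 is below ``plateau_increment``; if no power
    qualifies, falls back to the argmax of the fit index among powers whose
    mean connectivity stays at or above ``min_mean_connectivity`` (a
    soft-thresholded network with mean connectivity well below one is
    effectively empty and its fit index is not meaningful).  Returns the
    power and a diagnostics frame (power, r2, mean connectivity).
    """
    powers = list(candidate_powers)
    rows = []
    fits = {}
    for b in powers:
        a = adjacency(corr, b)
        k = a.sum(axis=1)
        r2 = scale_free_fit(k, n_bins=n_bins)
        fits[b] = r2
        rows.append({"power": b, "r2": r2, "mean_k": float(k.mean())})
    diag = pd.DataFrame(rows)
    mean_k = dict(zip(diag["power"], diag["mean_k"]))
    for b in powers:
        prev = fits.get(b - 1, np.nan)
        if (
            np.isfinite(fits[b])
            and mean_k[b] >= min_mean_connectivity
            and fits[b] >= target_r2
            and np.isfinite(prev)
            and fits[b] - prev < plateau_increment
        ):
            return b, diag
    finite = diag.dropna(subset=["r2"])
    dense = finite[finite["mean_k"] >= min_mean_connectivity]
    if len(dense):
        finite = dense
    if len(finite) == 0:
        return powers[0], diag
    return int(finite.loc[finite["r2"].idxmax(), "power"]), diag


def module_eigenscore(X: pd.DataFrame, members) -> tuple[pd.Series, float]:
    """Eigen-metabolite of a member set: oriented, unit-variance PC1.

    Returns (per-child score, fraction of member variance explained by PC1).
    The sign is chosen so the score correlates positively with the mean of
    the standardized member columns.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("eigenscore requires at least two members")
    M = X[members].to_numpy(float)
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    score = U[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    if np.corrcoef(score, M.mean(axis=1))[0, 1] < 0:
        score = -score
    score = score / score.std(ddof=0)
    return pd.Series(score, index=X.index), var_explained


@dataclass
class ModulePartition:
    """Metabolite -> module-color map with eigen-scores and diagnostics."""

    membership: pd.Series  # metabolite_id -> color (grey = unassigned)
    eigenscores: pd.DataFrame  # children x module colors
    var_explained: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def colors(self) -> list[str]:
        return list(self.eigenscores.columns)

    def members(self, color: str) -> list[str]:
        return list(self.membership.index[self.membership == color])

    @property
    def n_grey(self) -> int:
        return int((self.membership == GREY).sum())


def detect_modules(
    X: pd.DataFrame,
    beta: float,
    min_size: int = 15,
    cut_height_fraction: float = 0.99,
    merge_eigen_correlation: float | None = None,
) -> ModulePartition:
    """Detect co-abundance modules in a complete children x metabolites frame.

    Branches of the average-linkage tree of ``1 - TOM`` are cut at
    ``cut_height_fraction`` of the maximum merge height; clusters smaller
    than ``min_size`` are left grey.  ``merge_eigen_correlation`` (off by
    default) merges module pairs whose eigen-scores correlate above the
    given value, as a post-processing step.
    """
    cols = list(X.columns)
    M = X.to_numpy(float)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero-variance metabolites: {bad[:5]}")
    corr = np.corrcoef(M, rowvar=False)
    a = adjacency(corr, beta)
    tom = tom_similarity(a)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    Z = linkage(squareform(dissim, checks=False), method="average")
    cut_height = cut_height_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=cut_height, criterion="distance")

    membership = pd.Series(GREY, index=cols, dtype=object)
    clusters = []
    for lab in np.unique(raw):
        idx = np.where(raw == lab)[0]
        if len(idx) >= min_size:
            clusters.append(idx)
    # decreasing size; ties broken by first member position for determinism
    clusters.sort(key=lambda idx: (-len(idx), idx[0]))
    for color, idx in zip(COLOR_SEQUENCE, clusters):
        membership.iloc[idx] = color

    if merge_eigen_correlation is not None:
        membership = _merge_close(X, membership, merge_eigen_correlation)

    eigen = {}
    var_explained = {}
    sizes = membership[membership != GREY].value_counts()
    ordered = sorted(sizes.index, key=lambda c: COLOR_SEQUENCE.index(c))
    for color in ordered:
        score, ve = module_eigenscore(X, membership.index[membership == color])
        eigen[color] = score
        var_explained[color] = ve
    eigenscores = pd.DataFrame(eigen, index=X.index)

    k = a.sum(axis=1)
    return ModulePartition(
        membership=membership,
        eigenscores=eigenscores,
        var_explained=var_explained,
        diagnostics={
            "power": beta,
            "min_size": min_size,
            "cut_height": float(cut_height),
            "scale_free_r2": scale_free_fit(k),
            "n_modules": len(eigen),
            "n_grey": int((membership == GREY).sum()),
        },
    )


def _merge_close(X: pd.DataFrame, membership: pd.Series, threshold: float) -> pd.Series:
    """Iteratively merge the most-correlated eigen-score pair above threshold."""
    membership = membership.copy()
    while True:
        colors = [c for c in membership.unique() if c != GREY]
        if len(colors) < 2:
            return membership
        scores = {
            c: module_eigenscore(X, membership.index[membership == c])[0] for c in colors
        }
        best, best_r = None, threshold
        for i, ci in enumerate(colors):
            for cj in colors[i + 1 :]:
                r = float(np.corrcoef(scores[ci], scores[cj])[0, 1])
                if r > best_r:
                    best, best_r = (ci, cj), r
        if best is None:
            return membership
        keep, drop = sorted(
            best, key=lambda c: -int((membership == c).sum())
        )
        membership[membership == drop] = keep
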