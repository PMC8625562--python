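"""Longitudinal BMI-trajectory classification.

Irregular visit sequences are partitioned into constrained time-windows
(each with visits from at least ``min_n`` distinct children and no wider
than ``max_width`` months), values are averaged per child within windows,
gaps are filled by averaging the last and next observed window values, and
children are grouped by k-means (k=2) on the complete percentile matrix
crossed with the sign of their second principal component:

* cluster 1 (higher overall percentile) x positive PC2 -> early-OWO
* cluster 1 x negative PC2                            -> late-OWO
* cluster 2 (normal range) x positive / negative PC2  -> NW-A / NW-B

NW-A and NW-B collapse to a single NW group for analysis.  PC signs are
fixed deterministically: PC1 correlates positively with per-child mean
percentile; PC2 is oriented so its mean loading over the earliest third of
windows exceeds the mean loading over the latest third, which places
children whose BMI rises sharply within the observed span (late onset) at
negative PC2 and children already at high percentiles throughout (early
onset) at positive PC2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .growth import MIN_PERCENTILE_AGE, GrowthSeries, LMSReference, bmi_percentile

GROUP4_LEVELS = ["early-OWO", "late-OWO", "NW-A", "NW-B"]
GROUP3_LEVELS = ["early-OWO", "late-OWO", "NW"]

OBSERVED, INTERPOLATED, EDGE_FILLED = "observed", "interpolated", "edge_filled"


@dataclass(frozen=True)
class WindowSpec:
    """One time-window: half-open [age_lo, age_hi) except the last, which is
    closed on the right."""

    index: int
    age_lo: float
    age_hi: float
    n_children: int
    closed_right: bool = False

    @property
    def width(self) -> float:
        return self.age_hi - self.age_lo

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)

    def contains(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.closed_right:
            return (age >= self.age_lo) & (age <= self.age_hi)
        return (age >= self.age_lo) & (age < self.age_hi)


def _visit_frame(series_list) -> pd.DataFrame:
    frames = [
        pd.DataFrame({"child_id": s.child_id, "age_months": s.ages, "bmi": s.bmi})
        for s in series_list
        if len(s)
    ]
    return pd.concat(frames, ignore_index=True)


def build_windows(
    series_list,
    min_n: int = 30,
    max_width: float = 12.0,
    n_windows_hint: int | None = 36,
    age_range: tuple[float, float] | None = None,
) -> list[WindowSpec]:
    """Greedy left-to-right construction of constrained time-windows.

    The current window is extended until it holds visits from >= ``min_n``
    distinct children and has reached the hint-derived target width
    (span / ``n_windows_hint``), then closed at the next visit age; it is
    force-closed at ``max_width``.  Spans with no visits are skipped rather
    than emitted as empty windows, and an under-populated terminal window is
    merged into its predecessor.
    """
    visits = _visit_frame(series_list)
    if age_range is not None:
        lo, hi = age_range
        visits = visits[(visits["age_months"] >= lo) & (visits["age_months"] <= hi)]
    if visits["child_id"].nunique() < min_n:
        raise ValueError(f"cohort has fewer than min_n={min_n} children with visits")

    order = np.argsort(visits["age_months"].to_numpy(), kind="stable")
    ages = visits["age_months"].to_numpy()[order]
    kids = visits["child_id"].to_numpy()[order]
    uniq_ages, starts = np.unique(ages, return_index=True)
    starts = list(starts) + [len(ages)]
    child_sets = [set(kids[starts[i] : starts[i + 1]]) for i in range(len(uniq_ages))]

    span = uniq_ages[-1] - uniq_ages[0]
    target = span / n_windows_hint if n_windows_hint else 0.0
    target = min(target, max_width)

    raw: list[tuple[float, float, set]] = []  # (lo, hi, members)
    K = len(uniq_ages)
    k = 0
    while k < K:
        lo = uniq_ages[k]
        members: set = set()
        while k < K:
            if uniq_ages[k] - lo > max_width:
                break  # force-close before this age
            members |= child_sets[k]
            k += 1
            if (
                k < K
                and len(members) >= min_n
                and uniq_ages[k] - lo >= target
            ):
                break
        if k < K:
            hi = min(uniq_ages[k], lo + max_width)
        else:
            hi = uniq_ages[K - 1]
        raw.append((lo, hi, members))

    # merge an under-populated terminal window into its predecessor
    while len(raw) > 1 and len(raw[-1][2]) < min_n:
        lo2, hi2, m2 = raw.pop()
        lo1, _, m1 = raw.pop()
        raw.append((lo1, hi2, m1 | m2))

    return [
        WindowSpec(
            index=i + 1,
            age_lo=lo,
            age_hi=hi,
            n_children=len(members),
            closed_right=(i == len(raw) - 1),
        )
        for i, (lo, hi, members) in enumerate(raw)
    ]


def build_standard_windows(
    series_list, min_n: int = 30, max_width: float = 12.0,
    split_age: float = MIN_PERCENTILE_AGE, hints: tuple[int, int] = (8, 28),
) -> list[WindowSpec]:
    """Windows spanning birth-18y with a forced boundary at 24 months.

    Percentiles exist only from 24 months, so the percentile matrix uses the
    windows at or above the split; the full set serves the raw-BMI analyses.
    """
    visits = _visit_frame(series_list)
    amin, amax = visits["age_months"].min(), visits["age_months"].max()
    early = build_windows(
        series_list, min_n, max_width, hints[0], age_range=(amin, split_age - 1e-9)
    )
    late = build_windows(
        series_list, min_n, max_width, hints[1], age_range=(split_age, amax)
    )
    out = []
    for i, w in enumerate(early + late):
        out.append(
            WindowSpec(
                index=i + 1, age_lo=w.age_lo, age_hi=w.age_hi,
                n_children=w.n_children,
                closed_right=(i == len(early) + len(late) - 1),
            )
        )
    return out


@dataclass
class WindowedMatrix:
    """Children x windows matrix of window-averaged values."""

    values: pd.DataFrame  # children x window index
    observed: pd.DataFrame  # bool mask, pre-imputation
    mean_age: pd.DataFrame  # mean visit age per cell (NaN where unobserved)
    windows: list
    kind: str  # "BMI" | "BMIPCT"
    provenance: pd.DataFrame = None  # observed | interpolated | edge_filled

    def subset_windows(self, keep) -> "WindowedMatrix":
        idx = [w.index for w in keep]
        return WindowedMatrix(
            values=self.values[idx],
            observed=self.observed[idx],
            mean_age=self.mean_age[idx],
            windows=list(keep),
            kind=self.kind,
            provenance=None if self.provenance is None else self.provenance[idx],
        )


def window_average(
    series_list, windows, kind: str = "BMI", ref: LMSReference | None = None
) -> WindowedMatrix:
    """Average each child's values within each window (BMI, or percentile via
    an LMS reference for kind="BMIPCT")."""
    child_ids = [s.child_id for s in series_list]
    idx = [w.index for w in windows]
    values = pd.DataFrame(np.nan, index=child_ids, columns=idx)
    mean_age = pd.DataFrame(np.nan, index=child_ids, columns=idx)
    for s in series_list:
        if kind == "BMIPCT":
            if ref is None:
                raise ValueError("BMIPCT averaging requires an LMS reference")
            per_visit = bmi_percentile(s, ref)
            ages = per_visit["age_months"].to_numpy()
            vals = per_visit["bmipct"].to_numpy()
        else:
            ages, vals = s.ages, s.bmi
        for w in windows:
            inside = w.contains(ages)
            if inside.any():
                values.loc[s.child_id, w.index] = vals[inside].mean()
                mean_age.loc[s.child_id, w.index] = ages[inside].mean()
    return WindowedMatrix(
        values=values,
        observed=values.notna(),
        mean_age=mean_age,
        windows=list(windows),
        kind=kind,
    )


def impute_adjacent(matrix: WindowedMatrix) -> WindowedMatrix:
    """Fill missing windows: interior gaps with the mean of the last and next
    observed values (regardless of gap length); leading/trailing gaps carry
    the first/last observed value outward.  Provenance is recorded per cell;
    observed cells are never touched."""
    vals = matrix.values.to_numpy(float).copy()
    prov = np.full(vals.shape, OBSERVED, dtype=object)
    for i in range(vals.shape[0]):
        row = vals[i]
        obs = np.flatnonzero(~np.isnan(row))
        if len(obs) == 0:
            raise ValueError(
                f"child {matrix.values.index[i]!r} has no observed windows"
            )
        first, last = obs[0], obs[-1]
        for j in range(vals.shape[1]):
            if not np.isnan(row[j]):
                continue
            if j < first:
                row[j] = row[first]
                prov[i, j] = EDGE_FILLED
            elif j > last:
                row[j] = row[last]
                prov[i, j] = EDGE_FILLED
            else:
                prev = obs[obs < j].max()
                nxt = obs[obs > j].min()
                row[j] = 0.5 * (row[prev] + row[nxt])
                prov[i, j] = INTERPOLATED
    return WindowedMatrix(
        values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        observed=matrix.observed,
        mean_age=matrix.mean_age,
        windows=matrix.windows,
        kind=matrix.kind,
        provenance=pd.DataFrame(prov, index=matrix.values.index, columns=matrix.values.columns),
    )


def classify_trajectories(
    matrix: WindowedMatrix, seed: int = 0, n_init: int = 25
) -> pd.DataFrame:
    """k-means (k=2) + PC2 grouping of a complete windowed percentile matrix.

    Returns a frame indexed by child with kmeans_cluster (1 = higher overall
    percentile), pc1_score, pc2_score, and group4; variance fractions for
    PC1/PC2 are stored in ``result.attrs["var_explained"]``.
    """
    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("matrix must be imputed (complete) before classification")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate matrix: no variance across children")

    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed, tol=1e-6)
    labels = km.fit_predict(X)
    # cluster 1 = the cluster with higher grand-mean value
    means = [X[labels == c].mean() for c in (0, 1)]
    high = int(np.argmax(means))
    cluster = np.where(labels == high, 1, 2)

    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s
    var_frac = s**2 / (s**2).sum()
    pc1, pc2 = scores[:, 0].copy(), scores[:, 1].copy()
    load1, load2 = Vt[0].copy(), Vt[1].copy()
    if np.corrcoef(pc1, X.mean(axis=1))[0, 1] < 0:
        pc1, load1 = -pc1, -load1
    third = max(1, X.shape[1] // 3)
    if load2[:third].mean() - load2[-third:].mean() < 0:
        pc2, load2 = -pc2, -load2

    positive = pc2 >= 0
    group4 = np.where(
        cluster == 1,
        np.where(positive, "early-OWO", "late-OWO"),
        np.where(positive, "NW-A", "NW-B"),
    )
    out = pd.DataFrame(
        {
            "kmeans_cluster": cluster,
            "pc1_score": pc1,
            "pc2_score": pc2,
            "group4": group4,
        },
        index=matrix.values.index,
    )
    out.attrs["var_explained"] = {"pc1": float(var_frac[0]), "pc2": float(var_frac[1])}
    out.attrs["pc2_loadings"] = load2
    return out


def collapse_groups(assignments: pd.DataFrame) -> pd.DataFrame:
    """Add the 3-level analysis grouping: NW-A and NW-B merge into NW."""
    out = assignments.copy()
    out["group3"] = out["group4"].replace({"NW-A": "NW", "NW-B": "NW"})
    out.attrs = dict(assignments.attrs)
    return out


def lowess_curve(ages, values, frac: float = 0.3) -> pd.DataFrame:
    """Tricube-weighted local-linear smoother over pooled (age, value) points."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 5:
        raise ValueError("lowess requires at least 5 points")
    sm = _sm_lowess(values, ages, frac=frac, return_sorted=True)
    return pd.DataFrame({"age_months": sm[:, 0], "value": sm[:, 1]})


def group_curves(
    matrix: WindowedMatrix, assignments: pd.DataFrame, frac: float = 0.3,
    group_col: str = "group4",
) -> dict[str, pd.DataFrame]:
    """LOWESS curve per trajectory group over window-midpoint ages."""
    mids = np.array([w.midpoint for w in matrix.windows])
    curves = {}
    for g, sub in assignments.groupby(group_col):
        V = matrix.values.loc[sub.index].to_numpy(float)
        ages = np.tile(mids, V.shape[0])
        curves[g] = lowess_curve(ages, V.ravel(), frac=frac)
    return curves
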