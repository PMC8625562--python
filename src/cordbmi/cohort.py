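"""Group-stratified descriptive statistics for the cohort table.

Continuous variables are summarized as mean +/- SD and compared by one-way
ANOVA, or — for skewed variables such as last-visit anthropometrics — as
median (IQR) with a Kruskal-Wallis test; categorical variables as count (%)
with Pearson's chi-squared test.  Explicit "Unknown" categories are shown
in the table but excluded from the chi-squared test by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, f_oneway, kruskal

#: published overweight/obese-at-last-visit counts by trajectory group for
#: the Boston Birth Cohort sample the synthetic generator emulates:
#: group -> (n overweight/obese at last visit, group N)
BBC_OWO_LAST_VISIT = {
    "early-OWO": (252, 388),
    "late-OWO": (170, 254),
    "NW-A": (0, 186),
    "NW-B": (3, 118),
}


def summarize_groups(
    data: pd.DataFrame,
    group: pd.Series,
    continuous: list[str] = (),
    skewed: list[str] = (),
    categorical: list[str] = (),
    exclude_unknown_from_test: bool = True,
) -> pd.DataFrame:
    """Stratified descriptive table with per-variable tests.

    Returns tidy rows: variable, level (categorical only), one formatted
    column per group, test name and p-value.
    """
    groups = sorted(group.dropna().unique())
    sizes = group.value_counts()
    if len(groups) < 2 or any(sizes.get(g, 0) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    rows = []

    def by_group(col):
        aligned = data[col].groupby(group)
        return {g: aligned.get_group(g).dropna() for g in groups}

    for col in continuous:
        vals = by_group(col)
        stats = {g: f"{v.mean():.1f} ± {v.std(ddof=1):.1f}" for g, v in vals.items()}
        _, p = f_oneway(*[v.to_numpy(float) for v in vals.values()])
        rows.append({"variable": col, "level": "", **stats, "test": "ANOVA", "p": p})

    for col in skewed:
        vals = by_group(col)
        stats = {
            g: f"{v.median():.1f} ({v.quantile(0.25):.1f}–{v.quantile(0.75):.1f})"
            for g, v in vals.items()
        }
        _, p = kruskal(*[v.to_numpy(float) for v in vals.values()])
        rows.append({"variable": col, "level": "", **stats, "test": "Kruskal-Wallis", "p": p})

    for col in categorical:
        obs = pd.crosstab(data[col].astype(str), group)
        obs = obs.reindex(columns=groups, fill_value=0)
        test_tab = obs.drop(index="Unknown", errors="ignore") if exclude_unknown_from_test else obs
        stat, p = chi2_statistic(test_tab.to_numpy(float))
        totals = obs.sum(axis=0)
        for level, counts in obs.iterrows():
            stats = {
                g: f"{int(counts[g])} ({100.0 * counts[g] / totals[g]:.1f}%)"
                for g in groups
            }
            rows.append(
                {"variable": col, "level": level, **stats, "test": "chi-squared", "p": p}
            )
    return pd.DataFrame(rows)


def chi2_statistic(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared statistic and p for a contingency table.

    No continuity correction by default (matching the base-R default for
    tables larger than 2x2); set ``correction=True`` for Yates on 2x2.
    """
    stat, p, _, _ = chi2_contingency(np.asarray(table, float), correction=correction)
    return float(stat), float(p)


def owo_percentages_from_counts(counts: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Exact percentages overweight/obese per trajectory group and cluster.

    ``counts`` maps 4-level group -> (n OWO at last visit, group N); cluster
    1 pools early-OWO and late-OWO, cluster 2 pools NW-A and NW-B.
    """
    out = {}
    for g, (k, n) in counts.items():
        out[g] = 100.0 * k / n
    k1 = counts["early-OWO"][0] + counts["late-OWO"][0]
    n1 = counts["early-OWO"][1] + counts["late-OWO"][1]
    k2 = counts["NW-A"][0] + counts["NW-B"][0]
    n2 = counts["NW-A"][1] + counts["NW-B"][1]
    out["cluster1"] = 100.0 * k1 / n1
    out["cluster2"] = 100.0 * k2 / n2
    return out


def owo_percentages(owo_flags: pd.Series, group4: pd.Series) -> dict[str, float]:
    """Percentages overweight/obese at last visit, computed from data flags."""
    counts = {}
    for g in ["early-OWO", "late-OWO", "NW-A", "NW-B"]:
        members = group4.index[group4 == g]
        flags = owo_flags.reindex(members).astype(bool)
        counts[g] = (int(flags.sum()), len(members))
    return owo_percentages_from_counts(counts)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero, for table presentation."""
    factor = 10.0**ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))
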