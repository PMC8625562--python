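"""Multinomial logistic association of trajectory groups with metabolites.

Baseline-category logit models (NW, or NW-A for the exploratory four-group
models, as the reference) regress trajectory group on one exposure — a
module eigen-score or a single transformed metabolite — with covariate
adjustment for sex, race, preterm birth, maternal smoking, maternal
adiposity and maternal education.  Odds ratios are per unit of the
transformed exposure (one SD after inverse normal transformation or
eigen-score standardization), with Wald 95% intervals exp(beta +/- 1.96 SE).
Benjamini-Hochberg q-values are computed within the declared family for
each contrast (all modules, or all metabolites tested in that model set).

Sex-specific sensitivity refits each model with an exposure x sex
interaction and tests exposure + interaction jointly with a likelihood
ratio test on 2 x (levels - 1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.api as sm

Z95 = 1.959963984540054  # Phi^{-1}(0.975)
SEPARATION_BETA = 20.0

#: covariate columns expected in an analysis covariate table
COVARIATE_COLUMNS = [
    "sex", "race", "preterm", "mat_smoking", "mat_owo", "mat_educ",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; the family is the full input."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = sm.stats.multipletests(p[ok], method="fdr_bh")[1]
    return q


def covariate_design(covariates: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Dummy-code an analysis covariate table.

    Categorical covariates are expanded against their reference level
    (Black for race, female for sex, Never for smoking, No for maternal
    adiposity); an explicit "Unknown" category becomes its own dummy so
    children with a missing covariate stay in the model.
    """
    columns = columns or [c for c in COVARIATE_COLUMNS if c in covariates.columns]
    refs = {
        "sex": "F", "race": "Black", "mat_smoking": "Never",
        "mat_owo": "No", "breastfeeding": "Both",
    }
    parts = []
    for c in columns:
        col = covariates[c]
        if pd.api.types.is_numeric_dtype(col) and col.dropna().nunique() > 2:
            parts.append(col.astype(float).rename(c))
            continue
        col = col.astype(str)
        levels = [l for l in sorted(col.unique()) if l != refs.get(c)]
        ref = refs.get(c)
        if ref is None and levels:
            ref = sorted(col.unique())[0]
            levels = [l for l in sorted(col.unique()) if l != ref]
        for l in levels:
            parts.append((col == l).astype(float).rename(f"{c}[{l}]"))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=covariates.index)


@dataclass
class MultinomialFit:
    """One baseline-category logit fit for a single exposure."""

    reference: str
    contrasts: pd.DataFrame  # index: level; beta, se, or_, ci_lo, ci_hi, p
    loglik: float
    n: int
    converged: bool = True
    separation: bool = False
    extra_params: pd.DataFrame = field(default=None, repr=False)


def _mnlogit(y_codes: np.ndarray, X: pd.DataFrame, maxiter: int = 100):
    exog = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(y_codes, exog)
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=0, tol=1e-10)
            if not np.all(np.isfinite(np.asarray(res.params))):
                raise np.linalg.LinAlgError("non-finite Newton estimate")
        except np.linalg.LinAlgError:
            # singular observed information or a diverged Newton step
            # (typically separation): fall back to a quasi-Newton fit so the
            # estimate can be reported and flagged
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
    return res


def fit_multinomial(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: str = "NW",
    levels: list[str] | None = None,
    maxiter: int = 100,
) -> MultinomialFit:
    """ML fit of trajectory group on one exposure with covariate adjustment.

    ``outcome`` holds group labels; ``levels`` fixes the non-reference
    contrast order (defaults to sorted observed labels minus the
    reference).  Complete cases only.
    """
    data = pd.DataFrame({"y": outcome, "x": exposure})
    design = None
    if covariates is not None:
        design = (
            covariates
            if all(pd.api.types.is_numeric_dtype(covariates[c]) for c in covariates)
            else covariate_design(covariates)
        )
        data = data.join(design, how="inner")
    data = data.dropna()
    if levels is None:
        levels = [l for l in sorted(data["y"].unique()) if l != reference]
    order = [reference] + list(levels)
    codes = pd.Categorical(data["y"], categories=order).codes
    if (codes < 0).any():
        raise ValueError("outcome contains labels outside the declared levels")
    counts = pd.Series(codes).value_counts()
    if counts.min() < 10 or len(counts) < len(order):
        raise ValueError("each outcome level needs at least 10 observations")

    X = data.drop(columns="y")
    if float(np.std(data["x"])) == 0.0:
        # degenerate exposure: the model reduces to covariates-only
        res0 = _mnlogit(codes, X.drop(columns="x"))
        contrasts = pd.DataFrame(
            {
                "contrast": [f"{l} vs {reference}" for l in levels],
                "level": levels,
                "beta": 0.0, "se": np.nan, "or_": 1.0,
                "ci_lo": np.nan, "ci_hi": np.nan, "p": 1.0,
            }
        ).set_index("level")
        return MultinomialFit(
            reference=reference, contrasts=contrasts, loglik=float(res0.llf),
            n=len(data), converged=True, separation=False,
        )
    res = _mnlogit(codes, X)
    params = res.params  # rows: const + columns of X; cols: levels 1..K-1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bse = res.bse
            pvals = res.pvalues
    except np.linalg.LinAlgError:
        bse = params * np.nan
        pvals = params * np.nan
    rows = []
    np_err = np.seterr(over="ignore")  # inf CI bounds are meaningful under separation
    for j, level in enumerate(levels):
        beta = float(params.loc["x", j])
        se = min(float(bse.loc["x", j]), 1e3)  # cap blown-up SEs (separation)
        rows.append(
            {
                "contrast": f"{level} vs {reference}",
                "level": level,
                "beta": beta,
                "se": se,
                "or_": np.exp(beta),
                "ci_lo": np.exp(beta - Z95 * se),
                "ci_hi": np.exp(beta + Z95 * se),
                "p": float(pvals.loc["x", j]),
            }
        )
    np.seterr(**np_err)
    contrasts = pd.DataFrame(rows).set_index("level")
    return MultinomialFit(
        reference=reference,
        contrasts=contrasts,
        loglik=float(res.llf),
        n=len(data),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=bool((contrasts["beta"].abs() > SEPARATION_BETA).any()),
        extra_params=params,
    )


def _tidy(fits: dict, levels, reference) -> pd.DataFrame:
    rows = []
    for exposure_id, fit in fits.items():
        if fit is None:
            continue
        for level in levels:
            c = fit.contrasts.loc[level]
            rows.append(
                {
                    "exposure": exposure_id,
                    "contrast": f"{level} vs {reference}",
                    "level": level,
                    "beta": c["beta"],
                    "se": c["se"],
                    "or": c["or_"],
                    "ci_lo": c["ci_lo"],
                    "ci_hi": c["ci_hi"],
                    "p": c["p"],
                    "n": fit.n,
                    "converged": fit.converged,
                    "separation": fit.separation,
                }
            )
    columns = ["exposure", "contrast", "level", "beta", "se", "or",
               "ci_lo", "ci_hi", "p", "n", "converged", "separation"]
    return pd.DataFrame(rows, columns=columns if not rows else None)


def _add_q_per_contrast(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["q"] = np.nan
    for level in table["level"].unique():
        mask = table["level"] == level
        table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    return table


def module_association(
    eigenscores: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = "NW",
) -> pd.DataFrame:
    """Three-group association per module eigen-score; FDR family = modules
    per contrast; rows ordered by the early-onset contrast's q."""
    outcome = assignments["group3"]
    levels = ["early-OWO", "late-OWO"]
    design = covariate_design(covariates) if covariates is not None else None
    fits = {
        m: fit_multinomial(outcome, eigenscores[m], design, reference, levels)
        for m in eigenscores.columns
    }
    table = _add_q_per_contrast(_tidy(fits, levels, reference))
    order = (
        table[table["level"] == "early-OWO"]
        .sort_values("q")["exposure"]
        .tolist()
    )
    table["exposure"] = pd.Categorical(table["exposure"], categories=order)
    return table.sort_values(["exposure", "level"]).reset_index(drop=True)


def explore_four_groups(
    metabolites: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Exploratory four-group models per metabolite (reference NW-A).

    Returns the tidy table plus a summary with per-contrast counts of
    p <= alpha and q <= alpha and a collapse recommendation: True when the
    NW-B vs NW-A contrast shows no q <= alpha finding, the empirical
    justification for merging the two normal-weight subgroups.
    """
    outcome = assignments["group4"]
    levels = ["early-OWO", "late-OWO", "NW-B"]
    design = covariate_design(covariates) if covariates is not None else None
    fits = {
        m: fit_multinomial(outcome, metabolites[m], design, "NW-A", levels)
        for m in metabolites.columns
    }
    table = _add_q_per_contrast(_tidy(fits, levels, "NW-A"))
    counts = {
        level: {
            "n_p": int((table.loc[table["level"] == level, "p"] <= alpha).sum()),
            "n_q": int((table.loc[table["level"] == level, "q"] <= alpha).sum()),
        }
        for level in levels
    }
    summary = {
        "counts": counts,
        "collapse_recommended": counts["NW-B"]["n_q"] == 0,
    }
    return table, summary


def member_followup(
    metabolites: pd.DataFrame,
    partition,
    module_table: pd.DataFrame,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    select_p: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite follow-up within modules significant at p <= select_p
    on either contrast; the FDR family is the union of their members."""
    selected = sorted(
        module_table.loc[module_table["p"] <= select_p, "exposure"].unique().tolist()
    )
    members: list[str] = []
    for color in selected:
        members.extend(partition.members(color))
    members = [m for m in dict.fromkeys(members) if m in metabolites.columns]
    if not members:
        return pd.DataFrame(
            columns=["exposure", "contrast", "level", "beta", "se", "or",
                     "ci_lo", "ci_hi", "p", "n", "converged", "separation", "q"]
        )
    outcome = assignments["group3"]
    levels = ["early-OWO", "late-OWO"]
    design = covariate_design(covariates) if covariates is not None else None
    fits = {
        m: fit_multinomial(outcome, metabolites[m], design, "NW", levels)
        for m in members
    }
    return _add_q_per_contrast(_tidy(fits, levels, "NW"))


def sex_interaction_lrt(
    outcome: pd.Series,
    exposure: pd.Series,
    sex: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference: str = "NW",
    levels: list[str] | None = None,
) -> dict:
    """LRT for the joint exposure main effect + exposure x sex interaction.

    The full model holds exposure, sex, covariates and exposure x sex; the
    null drops exposure and the interaction.  df = 2 x (levels - 1).
    Also reports per-contrast Wald p-values of the interaction term.
    """
    if sex.nunique() < 2:
        raise ValueError("both sexes must be present for the interaction test")
    data = pd.DataFrame({"y": outcome, "x": exposure, "sexM": (sex == "M").astype(float)})
    if covariates is not None:
        design = covariate_design(covariates, [c for c in covariates.columns if c != "sex"])
        data = data.join(design, how="inner")
    data = data.dropna()
    data["x_sexM"] = data["x"] * data["sexM"]
    if levels is None:
        levels = [l for l in sorted(data["y"].unique()) if l != reference]
    order = [reference] + list(levels)
    codes = pd.Categorical(data["y"], categories=order).codes

    full = _mnlogit(codes, data.drop(columns="y"))
    null = _mnlogit(codes, data.drop(columns=["y", "x", "x_sexM"]))
    stat = 2.0 * (full.llf - null.llf)
    df = 2 * len(levels)
    inter = {
        level: float(full.pvalues.loc["x_sexM", j]) for j, level in enumerate(levels)
    }
    return {
        "lrt_stat": float(max(stat, 0.0)),
        "df": df,
        "p": float(chi2.sf(max(stat, 0.0), df)),
        "interaction_p": inter,
        "n": len(data),
    }
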