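"""Time-window-specific linear models of BMI on cord metabolites.

For every time-window, ordinary least squares regresses the child's
window-averaged BMI on one exposure (metabolite or module eigen-score),
sex, their interaction, the child's mean visit age within the window, and
covariates:

    BMI_w ~ exposure + sex + exposure:sex + mean_age + covariates (+ extra)

Only children with an observed (non-imputed) value in the window enter.
The exposure's overall effect (main + interaction) is screened with a
likelihood ratio test on 2 df; sex-specific slopes are reported for both
sexes and standardized by the within-sex SD of window BMI so effects are
comparable across ages.  FDR families are per window.  Sensitivity
variants add cesarean section, breastfeeding, or birthweight (the latter
skipped in the first window, where birthweight and the outcome coincide).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.api as sm

from .association import bh_fdr, covariate_design

EXTRA_ADJUST = ("none", "cesarean", "breastfeeding", "birthweight")
MIN_WINDOW_N = 20


def fit_window_model(
    bmi: pd.Series,
    exposure: pd.Series,
    sex: pd.Series,
    mean_age: pd.Series,
    covariates: pd.DataFrame | None = None,
    extra: pd.Series | pd.DataFrame | None = None,
) -> dict | None:
    """OLS window model with sex interaction and a 2-df exposure LRT.

    Returns a dict of effects and flags, or None when fewer than
    ``MIN_WINDOW_N`` complete cases remain.  With a single sex present the
    interaction is dropped and the result flagged.
    """
    data = pd.DataFrame(
        {"bmi": bmi, "x": exposure, "sexM": (sex == "M").astype(float), "age": mean_age}
    )
    if covariates is not None:
        data = data.join(covariates, how="inner")
    if extra is not None:
        data = data.join(extra, how="inner")
    data = data.dropna()
    flags = []
    if len(data) < MIN_WINDOW_N:
        return None
    single_sex = data["sexM"].nunique() < 2
    if single_sex:
        flags.append("single_sex")
        data = data.drop(columns="sexM")
    else:
        data["x_sexM"] = data["x"] * data["sexM"]

    y = data["bmi"].to_numpy(float)
    Xfull = sm.add_constant(data.drop(columns="bmi"), has_constant="add")
    drop = ["x"] + (["x_sexM"] if not single_sex else [])
    Xnull = Xfull.drop(columns=drop)
    full = sm.OLS(y, Xfull).fit()
    null = sm.OLS(y, Xnull).fit()
    if np.linalg.matrix_rank(Xfull.to_numpy()) < Xfull.shape[1]:
        flags.append("rank_deficient")

    lrt = 2.0 * (full.llf - null.llf)
    df = len(drop)
    beta_f = float(full.params["x"])
    se_f = float(full.bse["x"])
    if single_sex:
        beta_m, inter_p = beta_f, np.nan
    else:
        beta_m = beta_f + float(full.params["x_sexM"])
        inter_p = float(full.pvalues["x_sexM"])
    return {
        "beta_F": beta_f,
        "beta_M": beta_m,
        "se_F": se_f,
        "lrt_stat": float(max(lrt, 0.0)),
        "lrt_df": df,
        "lrt_p": float(chi2.sf(max(lrt, 0.0), df)),
        "interaction_p": inter_p,
        "n": len(data),
        "flags": ";".join(flags),
    }


def standardize_effects(effects: pd.DataFrame, sd_by_sex: pd.DataFrame) -> pd.DataFrame:
    """Divide each sex-specific beta by that sex's window BMI SD.

    ``sd_by_sex`` is indexed by window with columns sd_F, sd_M.  A zero or
    missing SD leaves the standardized beta missing and flags the row.
    """
    out = effects.copy()
    out["std_beta_F"] = np.nan
    out["std_beta_M"] = np.nan
    for i, row in out.iterrows():
        w = row["window"]
        for s in ("F", "M"):
            sd = sd_by_sex.loc[w, f"sd_{s}"] if w in sd_by_sex.index else np.nan
            if pd.notna(sd) and sd > 0:
                out.loc[i, f"std_beta_{s}"] = row[f"beta_{s}"] / sd
            else:
                out.loc[i, "flags"] = (row.get("flags") or "") + ";zero_sd"
    return out


def window_bmi_sd(matrix, sex: pd.Series) -> pd.DataFrame:
    """Within-sex SD of observed window BMI, per window."""
    rows = []
    for w in matrix.windows:
        obs = matrix.observed[w.index]
        vals = matrix.values[w.index][obs]
        rows.append(
            {
                "window": w.index,
                "sd_F": vals[sex.reindex(vals.index) == "F"].std(ddof=1),
                "sd_M": vals[sex.reindex(vals.index) == "M"].std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("window")


def run_window_analysis(
    matrix,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    extra_adjust: str = "none",
    extra_data: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every exposure in every window; per-window BH families.

    ``matrix`` is a windowed BMI matrix (observed cells only are used);
    ``covariates`` is the raw covariate table (sex is taken from it and the
    remainder dummy-coded); ``extra_adjust`` selects the sensitivity
    variant, with ``extra_data`` supplying the cesarean / breastfeeding /
    birthweight columns.  Birthweight adjustment is skipped for the first
    window by construction.
    """
    if extra_adjust not in EXTRA_ADJUST:
        raise ValueError(f"extra_adjust must be one of {EXTRA_ADJUST}")
    sex = covariates["sex"]
    design = covariate_design(
        covariates, [c for c in covariates.columns if c != "sex"]
    )
    sd_by_sex = window_bmi_sd(matrix, sex)

    first_window = matrix.windows[0].index
    rows = []
    for w in matrix.windows:
        obs = matrix.observed[w.index]
        children = matrix.values.index[obs]
        bmi = matrix.values.loc[children, w.index]
        age = matrix.mean_age.loc[children, w.index]
        extra = None
        skipped = ""
        if extra_adjust != "none":
            if extra_adjust == "birthweight" and w.index == first_window:
                skipped = "birthweight_skipped_first_window"
            else:
                col = (
                    extra_data[extra_adjust]
                    if extra_data is not None
                    else covariates[extra_adjust]
                )
                if col.dtype == object:
                    extra = covariate_design(col.to_frame(), [extra_adjust])
                else:
                    extra = col.astype(float).to_frame()
        for m in exposures.columns:
            res = fit_window_model(
                bmi, exposures[m].reindex(children), sex.reindex(children),
                age, design.reindex(children), extra,
            )
            if res is None:
                continue
            if skipped:
                res["flags"] = (res["flags"] + ";" + skipped).strip(";")
            res.update({"window": w.index, "exposure": m, "mid_age": w.midpoint})
            rows.append(res)
    effects = pd.DataFrame(rows)
    if effects.empty:
        return effects
    effects["lrt_q"] = np.nan
    effects["interaction_q"] = np.nan
    for w in effects["window"].unique():
        mask = effects["window"] == w
        effects.loc[mask, "lrt_q"] = bh_fdr(effects.loc[mask, "lrt_p"].to_numpy())
        pint = effects.loc[mask, "interaction_p"].to_numpy()
        effects.loc[mask, "interaction_q"] = bh_fdr(pint)
    return standardize_effects(effects, sd_by_sex)


def count_significant(
    effects: pd.DataFrame, criterion: str = "lrt_fdr", alpha: float = 0.05,
    lowess_frac: float = 0.3,
) -> pd.DataFrame:
    """Per-window counts of significant exposures plus a LOWESS trend.

    ``criterion`` is "lrt_fdr" (overall-effect q) or "interaction_fdr"
    (sex-interaction q).
    """
    col = {"lrt_fdr": "lrt_q", "interaction_fdr": "interaction_q"}[criterion]
    if effects.empty:
        return pd.DataFrame(columns=["window", "mid_age", "count", "smoothed"])
    grouped = (
        effects.assign(sig=effects[col] <= alpha)
        .groupby("window")
        .agg(mid_age=("mid_age", "first"), count=("sig", "sum"))
        .reset_index()
    )
    grouped["count"] = grouped["count"].astype(int)
    if len(grouped) >= 5:
        from .trajectory import lowess_curve

        sm_curve = lowess_curve(grouped["mid_age"], grouped["count"], frac=lowess_frac)
        grouped["smoothed"] = np.interp(
            grouped["mid_age"], sm_curve["age_months"], sm_curve["value"]
        )
    else:
        grouped["smoothed"] = grouped["count"].astype(float)
    return grouped


def effect_heatmap_matrix(
    effects: pd.DataFrame,
    sex: str = "F",
    mask: str = "lrt_fdr",
    annotations: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metabolites x windows matrix of standardized betas plus a mask.

    Masked cells (q > alpha under the chosen criterion) should render grey;
    values themselves are untouched.  Rows are ordered platform-then-type
    when annotations are supplied.
    """
    col = {"lrt_fdr": "lrt_q", "interaction_fdr": "interaction_q"}[mask]
    values = effects.pivot(index="exposure", columns="window", values=f"std_beta_{sex}")
    masked = effects.pivot(index="exposure", columns="window", values=col) > alpha
    masked = masked.fillna(True)
    if annotations is not None:
        ann = annotations.set_index("metabolite_id") if "metabolite_id" in annotations else annotations
        order = (
            ann.loc[ann.index.intersection(values.index)]
            .sort_values(["platform", "type"], kind="stable")
            .index
        )
        order = [m for m in order if m in values.index]
        values = values.loc[order]
        masked = masked.loc[order]
    return values, masked
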