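"""Seeded synthetic birth-cohort generator with known ground truth.

Emulates the data structure of an urban US birth cohort followed from birth
to age 18: three latent BMI-trajectory classes (early-onset OWO, late-onset
OWO, normal weight) with clinic-style irregular visit schedules and
age-increasing dropout; a cord-plasma metabolite panel organized into
correlated blocks whose latent factors shift by trajectory class (TAG/DAG
blocks lower in early-OWO, a CE block higher, half-sized shifts in
late-OWO); non-detects below a per-metabolite detection limit; a handful of
high-variability junk metabolites to exercise the CV filter; and a
covariate table whose birthweight is correlated with both the early-OWO
class and the TAG factor so birthweight-adjustment sensitivity behavior is
testable.

Trajectory classes are simulated on the percentile scale and mapped to BMI
through a smooth synthetic LMS reference, so the planted truth lives on the
same scale the trajectory classifier operates on.  Everything is
deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .growth import GrowthSeries, LMSReference, percentile_to_bmi
from .metabolome import MetabolitePanel

CLASSES = ["early-OWO", "late-OWO", "NW"]


@dataclass
class BlockSpec:
    size: int
    mtype: str
    shift_early: float = 0.0  # latent-factor shift (SD units) in early-OWO
    shift_late: float = 0.0


def default_blocks() -> list[BlockSpec]:
    # seven correlated blocks + independent leftovers, echoing a lipid-heavy
    # panel: two TAG blocks and one DAG block depressed in early-OWO, one CE
    # block elevated; late-OWO gets half-sized shifts
    return [
        BlockSpec(60, "PC"),
        BlockSpec(50, "SM"),
        BlockSpec(43, "TAG", -0.25, -0.125),
        BlockSpec(25, "TAG", -0.25, -0.125),
        BlockSpec(23, "DAG", -0.25, -0.125),
        BlockSpec(20, "CE", 0.25, 0.125),
        BlockSpec(20, "AC"),
    ]


@dataclass
class SyntheticConfig:
    n_children: int = 900
    class_probs: tuple = (0.41, 0.27, 0.32)  # early, late, NW
    # growth
    intercept_sd: float = 5.0  # child-level percentile offset
    visit_noise_sd: float = 4.0  # per-visit percentile noise
    visit_miss_prob: float = 0.10
    full_followup_prob: float = 0.12
    # dropout end-ages are uniform on [min_dropout_age, 217); the floor sits
    # past the late-onset inflection so every child's class is identifiable
    # from their observed span
    min_dropout_age: float = 120.0
    # metabolome
    blocks: list = field(default_factory=default_blocks)
    n_independent: int = 135  # unclustered ("grey-like") metabolites
    n_highcv: int = 19  # junk metabolites exceeding the CV filter
    rho: float = 0.5  # within-block pairwise correlation
    log_scale: float = 0.1  # log-intensity SD of clean metabolites
    highcv_log_scale: float = 0.5
    nondetect_quantile: float = 0.02
    n_c8: int = 194  # panel columns assigned to the C8-pos platform
    # covariates / birthweight mediation
    female_prob: float = 0.448
    birthweight_class_effect: float = 150.0  # g, early-OWO vs NW
    birthweight_tag_effect: float = -120.0  # g per SD of the first TAG factor
    birthweight_noise_sd: float = 600.0
    bmi_birthweight_effect: float = 0.9  # kg/m^2 per birthweight SD at birth
    bmi_birthweight_fade_age: float = 48.0  # months; effect fades linearly to 0
    seed: int = 1


def class_mean_percentile(cls: str, age_months: np.ndarray) -> np.ndarray:
    """Planted mean BMI-percentile curve per trajectory class."""
    age = np.asarray(age_months, dtype=float)
    if cls == "NW":
        return np.full_like(age, 40.0)
    if cls == "early-OWO":
        # rises early, ~85 by age 4, plateau near 90
        return 40.0 + 50.0 * expit((age - 28.0) / 8.0)
    if cls == "late-OWO":
        # near 50 until ~age 6, rising to ~88 by age 12
        return 50.0 + 38.0 * expit((age - 110.0) / 14.0)
    raise ValueError(cls)


def generate_reference() -> pd.DataFrame:
    """Smooth synthetic LMS reference over 24-216 months for both sexes.

    M rises monotonically with age (slightly higher for males), S widens
    with age, and L stays mildly negative — the qualitative shape of
    pediatric BMI references."""
    ages = np.arange(24.0, 217.0, 6.0)
    rows = []
    for sex, m_off in (("F", 0.0), ("M", 0.2)):
        t = (ages - 24.0) / 192.0
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age_months": ages,
                    "L": -1.0 - 0.6 * t,
                    "M": 15.5 + 5.5 * t**1.3 + m_off,
                    "S": 0.08 + 0.05 * t,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _visit_schedule(rng: np.random.Generator) -> np.ndarray:
    """Clinic-like nominal ages: dense before 2y, roughly annual after."""
    nominal = np.array(
        [0.5, 2, 4, 6, 9, 12, 15, 18, 24] + list(range(36, 217, 12)), dtype=float
    )
    jitter = rng.uniform(-1.0, 1.0, size=len(nominal))
    ages = np.maximum(nominal + jitter, 0.1)
    return np.sort(ages)


def _infant_bmi(cls: str, age: np.ndarray) -> np.ndarray:
    """Mean BMI below 24 months (no percentile reference there)."""
    base = 13.5 + 2.5 * age / 24.0
    boost = {"early-OWO": 1.5, "late-OWO": 0.3, "NW": 0.0}[cls]
    return base + boost * age / 24.0


def generate_classes(config: SyntheticConfig, rng: np.random.Generator) -> pd.Series:
    ids = [f"C{i:04d}" for i in range(config.n_children)]
    classes = rng.choice(CLASSES, size=config.n_children, p=config.class_probs)
    return pd.Series(classes, index=ids, name="true_class")


def generate_metabolome(
    config: SyntheticConfig, classes: pd.Series, rng: np.random.Generator
) -> tuple[MetabolitePanel, dict]:
    """Block-factor metabolite panel with planted class shifts.

    Each block has a latent factor f_b ~ N(shift_b(class), 1); member
    metabolites are sqrt(rho)*f_b + sqrt(1-rho)*noise, exponentiated to a
    positive intensity scale.  Values below the per-metabolite detection
    quantile become non-detects; junk metabolites get heavy log-noise so
    their CV exceeds the filter threshold.
    """
    n = len(classes)
    cols, types, block_of = [], [], {}
    X = []
    factors = {}
    for b, spec in enumerate(config.blocks):
        shift = np.where(
            classes.values == "early-OWO", spec.shift_early,
            np.where(classes.values == "late-OWO", spec.shift_late, 0.0),
        )
        f = shift + rng.standard_normal(n)
        factors[b] = f
        for j in range(spec.size):
            name = f"{spec.mtype}_b{b}_{j:02d}"
            eps = rng.standard_normal(n)
            X.append(np.sqrt(config.rho) * f + np.sqrt(1 - config.rho) * eps)
            cols.append(name)
            types.append(spec.mtype)
            block_of[name] = b
    for j in range(config.n_independent):
        name = f"other_{j:03d}"
        X.append(rng.standard_normal(n))
        cols.append(name)
        types.append("other")
        block_of[name] = -1
    X = np.column_stack(X)

    base = rng.uniform(3.0, 6.0, size=X.shape[1])  # per-metabolite log10-ish level
    intens = np.exp(np.log(10.0) * base[None, :] * 0.3 + config.log_scale * X)

    # junk metabolites: heavy multiplicative noise -> CV above the filter
    junk = np.exp(
        np.log(10.0) * rng.uniform(3.0, 6.0, size=config.n_highcv)[None, :] * 0.3
        + config.highcv_log_scale * rng.standard_normal((n, config.n_highcv))
    )
    junk_cols = [f"junk_{j:02d}" for j in range(config.n_highcv)]
    intens = np.hstack([intens, junk])
    cols = cols + junk_cols
    types = types + ["other"] * config.n_highcv
    for c in junk_cols:
        block_of[c] = -2

    df = pd.DataFrame(intens, index=classes.index, columns=cols)
    # plant non-detects below the detection limit
    for j, c in enumerate(df.columns):
        if c.startswith("junk"):
            continue
        limit = df[c].quantile(config.nondetect_quantile)
        df.loc[df[c] < limit, c] = np.nan

    platform = ["C8-pos" if i < config.n_c8 else "HILIC-pos" for i in range(len(cols))]
    ann = pd.DataFrame({"metabolite_id": cols, "type": types, "platform": platform})
    truth = {
        "block_of": block_of,
        "factors": factors,
        "shifts": {
            b: {"early": s.shift_early, "late": s.shift_late, "type": s.mtype}
            for b, s in enumerate(config.blocks)
        },
    }
    return MetabolitePanel(intensities=df, annotations=ann), truth


def generate_covariates(
    config: SyntheticConfig,
    classes: pd.Series,
    metab_truth: dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Covariate table with birthweight tied to class and the TAG factor."""
    n = len(classes)
    tag_blocks = [
        b for b, s in metab_truth["shifts"].items()
        if s["type"] == "TAG" and s["early"] != 0
    ]
    f_tag = metab_truth["factors"][tag_blocks[0]] if tag_blocks else np.zeros(n)
    early = (classes.values == "early-OWO").astype(float)
    bw = (
        3000.0
        + config.birthweight_class_effect * early
        + config.birthweight_tag_effect * f_tag
        + config.birthweight_noise_sd * rng.standard_normal(n)
    )
    cov = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n, p=[config.female_prob, 1 - config.female_prob]),
            "race": rng.choice(
                ["Black", "Hispanic", "White", "Others"], n, p=[0.60, 0.23, 0.05, 0.12]
            ),
            "preterm": rng.choice([0, 1], n, p=[0.82, 0.18]),
            "mat_smoking": rng.choice(
                ["Never", "Intermittent", "Continuous", "Unknown"],
                n, p=[0.82, 0.07, 0.10, 0.01],
            ),
            "mat_owo": rng.choice(["No", "Yes", "Unknown"], n, p=[0.45, 0.50, 0.05]),
            "mat_educ": rng.choice([1, 0], n, p=[0.72, 0.28]),
            "cesarean": rng.choice([0, 1], n, p=[0.67, 0.33]),
            "breastfeeding": rng.choice(
                ["Both", "Bottle", "Breast"], n, p=[0.66, 0.26, 0.08]
            ),
            "birthweight": bw,
        },
        index=classes.index,
    )
    return cov


def generate_growth(
    config: SyntheticConfig,
    classes: pd.Series,
    covariates: pd.DataFrame,
    ref: LMSReference,
    rng: np.random.Generator,
) -> list[GrowthSeries]:
    """Irregular per-child visit series on the BMI scale.

    Percentile-scale class curves (plus a child intercept and visit noise)
    are mapped to BMI through the LMS reference for ages >= 24 months; an
    infant BMI curve covers younger visits.  Birthweight adds a fading BMI
    offset before ``bmi_birthweight_fade_age`` so early windows carry a
    birthweight-mediated metabolite signal.
    """
    bw_z = (
        (covariates["birthweight"] - covariates["birthweight"].mean())
        / covariates["birthweight"].std(ddof=0)
    )
    series = []
    for cid, cls in classes.items():
        ages = _visit_schedule(rng)
        keep = rng.uniform(size=len(ages)) > config.visit_miss_prob
        if rng.uniform() > config.full_followup_prob:
            end = rng.uniform(config.min_dropout_age, 217.0)
            keep &= ages <= end
        ages = ages[keep]
        if len(ages) == 0:
            ages = np.array([rng.uniform(2.0, 24.0)])
        sex = covariates.loc[cid, "sex"]
        intercept = config.intercept_sd * rng.standard_normal()
        fade = np.clip(1.0 - ages / config.bmi_birthweight_fade_age, 0.0, 1.0)
        bmi = np.empty_like(ages)
        young = ages < 24.0
        if young.any():
            bmi[young] = (
                _infant_bmi(cls, ages[young])
                + 0.04 * intercept
                + 0.8 * rng.standard_normal(young.sum())
            )
        if (~young).any():
            pct = (
                class_mean_percentile(cls, ages[~young])
                + intercept
                + config.visit_noise_sd * rng.standard_normal((~young).sum())
            )
            pct = np.clip(pct, 0.5, 99.5)
            bmi[~young] = percentile_to_bmi(pct, sex, ages[~young], ref)
        bmi += config.bmi_birthweight_effect * bw_z[cid] * fade
        bmi = np.maximum(bmi, 8.0)
        series.append(GrowthSeries(child_id=cid, sex=sex, ages=ages, bmi=bmi))
    return series


@dataclass
class SyntheticCohort:
    growth: list
    panel: MetabolitePanel
    covariates: pd.DataFrame
    reference: pd.DataFrame
    truth: dict
    config: SyntheticConfig


def generate_cohort(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate the full cohort: growth, metabolome, covariates, reference."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
        config.blocks = [BlockSpec(**b) if isinstance(b, dict) else b for b in config.blocks]
    rng = np.random.default_rng(config.seed)
    classes = generate_classes(config, rng)
    panel, metab_truth = generate_metabolome(config, classes, rng)
    covariates = generate_covariates(config, classes, metab_truth, rng)
    ref_table = generate_reference()
    ref = LMSReference(ref_table)
    growth = generate_growth(config, classes, covariates, ref, rng)
    truth = {
        "classes": classes,
        "block_of": metab_truth["block_of"],
        "shifts": metab_truth["shifts"],
        "seed": config.seed,
    }
    return SyntheticCohort(
        growth=growth, panel=panel, covariates=covariates,
        reference=ref_table, truth=truth, config=config,
    )


def growth_long_table(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for a, b in zip(s.ages, s.bmi):
            rows.append({"child_id": s.child_id, "sex": s.sex, "age_months": a, "bmi": b})
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write the four pipeline input files plus a truth JSON; returns paths."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "growth": out / "growth.tsv",
        "metabolome": out / "metabolome.tsv",
        "annotations": out / "metabolite_annotations.tsv",
        "covariates": out / "covariates.tsv",
        "reference": out / "lms_reference.tsv",
        "truth": out / "truth.json",
    }
    growth_long_table(cohort.growth).to_csv(paths["growth"], sep="\t", index=False)
    cohort.panel.intensities.rename_axis("child_id").to_csv(paths["metabolome"], sep="\t")
    cohort.panel.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    cohort.covariates.rename_axis("child_id").to_csv(paths["covariates"], sep="\t")
    cohort.reference.to_csv(paths["reference"], sep="\t", index=False)
    truth = {
        "classes": cohort.truth["classes"].to_dict(),
        "block_of": cohort.truth["block_of"],
        "shifts": {str(k): v for k, v in cohort.truth["shifts"].items()},
        "seed": cohort.truth["seed"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
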