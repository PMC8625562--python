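"""End-to-end analysis pipeline over the four delimited input files.

Stages, in order: metabolite QC/transformation -> per-visit percentiles ->
time-window construction -> trajectory grouping -> co-abundance modules ->
trajectory-group associations (modules, then member follow-up) ->
time-window linear models -> sensitivity variants -> summary report.
Outputs are plain delimited text and JSON under a run directory; the
effective configuration is serialized alongside so a run is reproducible
from config + inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, cohort, metabolome, modules, timewindows, trajectory
from .growth import GrowthSeries, LMSReference, load_lms_reference

log = logging.getLogger("cordbmi")

GROWTH_COLUMNS = ["child_id", "sex", "age_months", "bmi"]
COVARIATE_REQUIRED = ["sex", "race", "preterm", "mat_smoking", "mat_owo", "mat_educ"]


@dataclass
class PipelineConfig:
    growth: str = "growth.tsv"
    metabolome: str = "metabolome.tsv"
    annotations: str | None = "metabolite_annotations.tsv"
    covariates: str = "covariates.tsv"
    reference: str = "lms_reference.tsv"
    out_dir: str = "run"
    # parameters
    cv_threshold: float = 20.0
    int_offset: float = 0.375
    window_min_n: int = 30
    window_max_width: float = 12.0
    window_hints: tuple = (8, 28)
    kmeans_seed: int = 0
    kmeans_restarts: int = 25
    power: int | None = None  # None -> choose by scale-free fit
    target_scale_free_r2: float = 0.80
    min_module_size: int = 15
    cut_height_fraction: float = 0.99
    alpha: float = 0.05
    sensitivity: tuple = ("cesarean", "breastfeeding", "birthweight")
    run_four_group_exploration: bool = False
    run_time_windows: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_growth(path) -> list[GrowthSeries]:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth table missing columns: {missing}")
    series = []
    for cid, sub in df.groupby("child_id", sort=True):
        sub = sub.sort_values("age_months")
        series.append(
            GrowthSeries(
                child_id=str(cid),
                sex=str(sub["sex"].iloc[0]),
                ages=sub["age_months"].to_numpy(float),
                bmi=sub["bmi"].to_numpy(float),
            )
        )
    return series


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and cross-reference checks over the four inputs."""
    report = {"errors": [], "warnings": []}
    try:
        growth = pd.read_csv(config.growth, sep=None, engine="python")
        missing = [c for c in GROWTH_COLUMNS if c not in growth.columns]
        if missing:
            report["errors"].append(f"growth: missing columns {missing}")
    except Exception as e:  # noqa: BLE001
        report["errors"].append(f"growth: {e}")
        growth = None
    try:
        metab = pd.read_csv(config.metabolome, sep=None, engine="python")
        if "child_id" not in metab.columns:
            report["errors"].append("metabolome: missing child_id column")
    except Exception as e:  # noqa: BLE001
        report["errors"].append(f"metabolome: {e}")
        metab = None
    try:
        cov = pd.read_csv(config.covariates, sep=None, engine="python")
        missing = [c for c in COVARIATE_REQUIRED if c not in cov.columns]
        if missing:
            report["errors"].append(f"covariates: missing columns {missing}")
    except Exception as e:  # noqa: BLE001
        report["errors"].append(f"covariates: {e}")
        cov = None
    try:
        load_lms_reference(config.reference)
    except Exception as e:  # noqa: BLE001
        report["errors"].append(f"reference: {e}")
    if growth is not None and metab is not None:
        g_ids = set(growth["child_id"].astype(str))
        m_ids = set(metab["child_id"].astype(str))
        orphans = sorted(m_ids - g_ids)
        if orphans:
            report["warnings"].append(
                f"{len(orphans)} children in metabolome absent from growth: {orphans[:5]}"
            )
    report["ok"] = not report["errors"]
    return report


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {}

    report = validate_inputs(config)
    if not report["ok"]:
        raise ValueError(f"input validation failed: {report['errors']}")

    # --- metabolite prep
    panel = metabolome.load_panel(config.metabolome, config.annotations)
    panel = metabolome.prepare_panel(panel, config.cv_threshold, config.int_offset)
    X = panel.retained_matrix()
    panel.qc.rename_axis("metabolite_id").to_csv(out / "metabolite_qc.tsv", sep="\t")
    summary["n_metabolites_retained"] = X.shape[1]
    summary["n_metabolites_excluded_cv"] = int(
        (panel.qc["status"] == metabolome.STATUS_EXCLUDED_CV).sum()
    )
    log.info("metabolite prep: %s retained", X.shape[1])

    # --- growth, windows, trajectories
    growth = load_growth(config.growth)
    ref = LMSReference(load_lms_reference(config.reference))
    windows = trajectory.build_standard_windows(
        growth, config.window_min_n, config.window_max_width, hints=config.window_hints
    )
    pd.DataFrame(
        [
            {"window": w.index, "age_lo": w.age_lo, "age_hi": w.age_hi,
             "n_children": w.n_children, "width": w.width}
            for w in windows
        ]
    ).to_csv(out / "windows.tsv", sep="\t", index=False)
    pct_windows = [w for w in windows if w.age_lo >= 24.0 - 1e-9]
    pct_matrix = trajectory.window_average(growth, pct_windows, kind="BMIPCT", ref=ref)
    pct_matrix = trajectory.impute_adjacent(pct_matrix)
    assignments = trajectory.classify_trajectories(
        pct_matrix, seed=config.kmeans_seed, n_init=config.kmeans_restarts
    )
    assignments = trajectory.collapse_groups(assignments)
    assignments.rename_axis("child_id").to_csv(out / "trajectory_groups.tsv", sep="\t")
    summary["group_sizes"] = assignments["group4"].value_counts().to_dict()
    summary["pc_variance"] = assignments.attrs["var_explained"]
    curves = trajectory.group_curves(pct_matrix, assignments)
    pd.concat(
        [c.assign(group=g) for g, c in curves.items()], ignore_index=True
    ).to_csv(out / "lowess_curves.tsv", sep="\t", index=False)
    log.info("trajectory groups: %s", summary["group_sizes"])

    # --- align children present in both growth and metabolome
    common = X.index.intersection(assignments.index)
    X = X.loc[common]
    assignments = assignments.loc[common]
    covariates = pd.read_csv(config.covariates, sep=None, engine="python").set_index(
        "child_id"
    ).loc[common]
    analysis_cov = covariates[COVARIATE_REQUIRED]

    # --- modules
    corr = np.corrcoef(X.to_numpy(float), rowvar=False)
    if config.power is None:
        beta, power_diag = modules.pick_power(
            corr, target_r2=config.target_scale_free_r2
        )
        power_diag.to_csv(out / "power_diagnostics.tsv", sep="\t", index=False)
    else:
        beta = config.power
    partition = modules.detect_modules(
        X, beta, config.min_module_size, config.cut_height_fraction
    )
    partition.membership.rename("module").rename_axis("metabolite_id").to_csv(
        out / "module_membership.tsv", sep="\t"
    )
    partition.eigenscores.rename_axis("child_id").to_csv(
        out / "module_eigenscores.tsv", sep="\t"
    )
    with open(out / "module_diagnostics.json", "w") as fh:
        json.dump(partition.diagnostics, fh, indent=1)
    summary["modules"] = {
        c: int((partition.membership == c).sum()) for c in partition.colors
    }
    summary["n_grey"] = partition.n_grey
    log.info("modules: %s (+%s grey), power=%s", summary["modules"], partition.n_grey, beta)

    # --- associations
    if config.run_four_group_exploration:
        four_table, four_summary = association.explore_four_groups(
            X, assignments, analysis_cov, alpha=config.alpha
        )
        four_table.to_csv(out / "four_group_exploration.tsv", sep="\t", index=False)
        summary["four_group"] = four_summary

    module_table = association.module_association(
        partition.eigenscores, assignments, analysis_cov
    )
    module_table.to_csv(out / "module_associations.tsv", sep="\t", index=False)
    followup = association.member_followup(
        X, partition, module_table, assignments, analysis_cov, select_p=config.alpha
    )
    followup.to_csv(out / "member_followup.tsv", sep="\t", index=False)
    summary["significant_modules"] = sorted(
        module_table.loc[module_table["q"] <= config.alpha, "exposure"]
        .astype(str).unique().tolist()
    )
    lrt_rows = []
    for m in partition.colors:
        res = association.sex_interaction_lrt(
            assignments["group3"], partition.eigenscores[m],
            covariates["sex"], analysis_cov,
        )
        lrt_rows.append({"module": m, **{k: v for k, v in res.items() if k != "interaction_p"}})
    pd.DataFrame(lrt_rows).to_csv(out / "module_sex_lrt.tsv", sep="\t", index=False)

    # --- time-window analysis (module eigen-scores; metabolite-level runs
    # are available through the library API)
    if config.run_time_windows:
        bmi_matrix = trajectory.window_average(growth, windows, kind="BMI")
        bmi_matrix.values.index = bmi_matrix.values.index.astype(str)
        for attr in ("observed", "mean_age"):
            getattr(bmi_matrix, attr).index = bmi_matrix.values.index
        effects = timewindows.run_window_analysis(
            bmi_matrix, partition.eigenscores, covariates[COVARIATE_REQUIRED],
        )
        effects.to_csv(out / "window_effects_modules.tsv", sep="\t", index=False)
        counts = timewindows.count_significant(effects, "lrt_fdr", config.alpha)
        counts.to_csv(out / "window_significance_counts.tsv", sep="\t", index=False)
        for extra in config.sensitivity:
            eff = timewindows.run_window_analysis(
                bmi_matrix, partition.eigenscores, covariates[COVARIATE_REQUIRED],
                extra_adjust=extra, extra_data=covariates,
            )
            eff.to_csv(out / f"window_effects_modules_{extra}.tsv", sep="\t", index=False)

    # --- cohort table
    group_stats = cohort.summarize_groups(
        covariates.join(assignments["group4"]),
        assignments["group4"],
        continuous=["birthweight"],
        categorical=["sex", "race", "mat_smoking", "mat_owo"],
    )
    group_stats.to_csv(out / "cohort_table.tsv", sep="\t", index=False)

    with open(out / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=str)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    log.info("pipeline complete: %s", out)
    return out
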