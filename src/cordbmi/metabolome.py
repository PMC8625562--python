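"""Metabolite panel QC and transformation.

The preparation pipeline, in fixed order:

1. :func:`cv_filter` — drop metabolites whose coefficient of variation
   (100 * sd / mean over observed raw intensities) exceeds a threshold
   (default 20%, strict inequality: a CV of exactly 20% is retained).
2. :func:`impute_nondetects` — replace non-detects by half of the minimum
   observed intensity of that metabolite.
3. :func:`inverse_normal_transform` — rank-based inverse normal transform
   per metabolite, Phi^{-1}((r - c) / (n - 2c + 1)) with Blom offset
   c = 3/8 and average ranks for ties.

Intensities are held as a children x metabolites DataFrame with NaN marking
non-detects; a companion annotation frame carries metabolite type (TAG, DAG,
CE, ...) and platform (C8-pos / HILIC-pos); a QC frame records per-metabolite
CV, non-detect count and retention status.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

STATUS_RETAINED = "retained"
STATUS_EXCLUDED_CV = "excluded_cv"
STATUS_TOO_FEW = "excluded_too_few_observed"

BLOM_OFFSET = 0.375


@dataclass
class MetabolitePanel:
    """Children x metabolites intensity matrix with QC state."""

    intensities: pd.DataFrame
    annotations: pd.DataFrame = None  # metabolite_id, type, platform
    qc: pd.DataFrame = None
    transform: str = "raw"  # raw | imputed | inverse_normal

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(
                {
                    "metabolite_id": self.intensities.columns,
                    "type": "other",
                    "platform": "C8-pos",
                }
            )
        self.annotations = self.annotations.set_index(
            self.annotations["metabolite_id"].values
        )
        if self.qc is None:
            self.qc = pd.DataFrame(
                {
                    "cv": np.nan,
                    "n_nondetect": self.intensities.isna().sum().to_numpy(),
                    "status": STATUS_RETAINED,
                },
                index=self.intensities.columns,
            )

    @property
    def child_ids(self):
        return self.intensities.index

    @property
    def retained(self) -> pd.Index:
        return self.qc.index[self.qc["status"] == STATUS_RETAINED]

    def retained_matrix(self) -> pd.DataFrame:
        return self.intensities[self.retained]


def _column_cv(col: pd.Series, ddof: int = 1) -> float:
    obs = col.dropna().to_numpy(float)
    if len(obs) < 2:
        return np.nan
    mean = obs.mean()
    if mean == 0:
        return np.inf
    return 100.0 * obs.std(ddof=ddof) / mean


def cv_filter(panel: MetabolitePanel, threshold: float = 20.0, ddof: int = 1) -> MetabolitePanel:
    """Mark metabolites with CV strictly above ``threshold`` percent excluded.

    CV is computed on raw observed (non-missing) intensities with sample
    (``ddof=1``) standard deviation.  Metabolites with fewer than two
    observed values get a distinct exclusion status.
    """
    qc = panel.qc.copy()
    for m in panel.intensities.columns:
        cv = _column_cv(panel.intensities[m], ddof=ddof)
        qc.loc[m, "cv"] = cv
        if np.isnan(cv):
            qc.loc[m, "status"] = STATUS_TOO_FEW
        elif cv > threshold:
            qc.loc[m, "status"] = STATUS_EXCLUDED_CV
    return replace(panel, qc=qc)


def impute_nondetects(panel: MetabolitePanel) -> MetabolitePanel:
    """Replace each non-detect by half the metabolite's minimum observed value."""
    intens = panel.intensities.copy()
    for m in panel.retained:
        col = intens[m]
        if col.isna().all():
            raise ValueError(f"metabolite {m!r} has no observed values to impute from")
        if col.isna().any():
            intens[m] = col.fillna(0.5 * col.min())
    return replace(panel, intensities=intens, transform="imputed")


def inverse_normal_scores(values: np.ndarray, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse normal scores of a complete 1-d array."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    r = rankdata(values, method="average")
    return norm.ppf((r - offset) / (n - 2.0 * offset + 1.0))


def inverse_normal_transform(panel: MetabolitePanel, offset: float = BLOM_OFFSET) -> MetabolitePanel:
    """Apply the rank-based inverse normal transform to each retained metabolite."""
    intens = panel.intensities.copy()
    cols = panel.retained
    if intens[cols].isna().any().any():
        raise ValueError("non-detects must be imputed before transformation")
    for m in cols:
        intens[m] = inverse_normal_scores(intens[m].to_numpy(), offset=offset)
    return replace(panel, intensities=intens, transform="inverse_normal")


def prepare_panel(
    panel: MetabolitePanel, cv_threshold: float = 20.0, offset: float = BLOM_OFFSET
) -> MetabolitePanel:
    """Full QC pipeline: CV filter, half-minimum imputation, inverse normal."""
    return inverse_normal_transform(
        impute_nondetects(cv_filter(panel, threshold=cv_threshold)), offset=offset
    )


def load_panel(intensity_path, annotation_path=None, nondetect_sentinel=None) -> MetabolitePanel:
    """Read an intensity matrix (first column child_id) and optional annotations.

    Non-detects are empty cells; ``nondetect_sentinel`` additionally maps a
    literal value (e.g. 0) to non-detect.
    """
    intens = pd.read_csv(intensity_path, sep=None, engine="python").set_index("child_id")
    intens = intens.astype(float)
    if nondetect_sentinel is not None:
        intens = intens.replace(nondetect_sentinel, np.nan)
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep=None, engine="python")
    return MetabolitePanel(intensities=intens, annotations=ann)
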