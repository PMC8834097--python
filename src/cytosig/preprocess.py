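"""Column z-scoring, missing-value policies, and PCA/Mahalanobis outlier removal.

Concentration columns are standardized to mean 0 / SD 1 (sample SD, divisor
n−1) before any multivariate model.  Outliers are screened iteratively: a
PCA of the z-scored matrix, the squared Mahalanobis distance of every sample
in the leading principal-component scores, and removal of the single worst
sample beyond the chi-square quantile of a confidence ellipse, refitting
until no sample exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import CytokinePanel, PanelError

__all__ = ["ZScaledMatrix", "OutlierParams", "zscore", "impute_missing", "remove_outliers"]

IMPUTE_POLICIES = ("half_min", "column_min", "drop_sample")


@dataclass
class ZScaledMatrix:
    """A z-scored samples × analytes matrix with its scaling parameters.

    ``column_means``/``column_sds`` (pg/mL) allow applying the identical
    transform to new data.
    """

    z: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    analyte_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Apply the stored training scaling to a new raw matrix."""
        return (np.asarray(values, dtype=float) - self.column_means) / self.column_sds


@dataclass
class OutlierParams:
    """Confidence-ellipse parameters for the Mahalanobis outlier screen.

    ``confidence`` is the ellipse mass (default 0.995 → a 99.5% ellipse);
    ``n_components`` the number of leading PCs defining the ellipse (2, an
    ellipse being two-dimensional, by default).
    """

    confidence: float = 0.995
    n_components: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")


def impute_missing(panel: CytokinePanel, policy: str = "half_min") -> CytokinePanel:
    """Resolve missing cells before scaling.

    ``half_min`` replaces a missing cell with half the column's minimum
    observed value (the usual below-detection-limit convention for
    multiplexed immunoassays), ``column_min`` with the minimum itself, and
    ``drop_sample`` removes any sample with a missing cell.
    """
    if policy not in IMPUTE_POLICIES:
        raise ValueError(f"unknown imputation policy {policy!r}; choose from {IMPUTE_POLICIES}")
    conc = panel.concentrations
    if not conc.isna().any().any():
        return panel.copy()
    all_missing = conc.columns[conc.isna().all(axis=0)].tolist()
    if all_missing:
        raise PanelError(f"analytes with no observed values: {all_missing}")
    if policy == "drop_sample":
        keep = conc.index[~conc.isna().any(axis=1)]
        return CytokinePanel(conc.loc[keep], panel.metadata.loc[keep])
    mins = conc.min(axis=0, skipna=True)
    fill = mins / 2.0 if policy == "half_min" else mins
    return CytokinePanel(conc.fillna(fill), panel.metadata.copy())


def zscore(panel: CytokinePanel, policy: str = "half_min") -> ZScaledMatrix:
    """Standardize each analyte column to mean 0, sample SD 1.

    Missing cells are imputed (``policy``) first.  Constant columns cannot
    be scaled and raise :class:`PanelError` listing the analytes.
    """
    if panel.n_samples < 2:
        raise PanelError("z-scoring needs at least 2 samples")
    filled = impute_missing(panel, policy)
    x = filled.values
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    constant = np.asarray(filled.analyte_names)[sds == 0.0]
    if constant.size:
        raise PanelError(f"constant analyte columns cannot be z-scored: {constant.tolist()}")
    return ZScaledMatrix((x - means) / sds, means, sds,
                         analyte_names=filled.analyte_names,
                         sample_ids=filled.sample_ids)


def _pc_mahalanobis_sq(z: np.ndarray, n_components: int) -> np.ndarray:
    """Squared Mahalanobis distance of each row in the leading PC scores."""
    n = z.shape[0]
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    eigvals = s[:k] ** 2 / (n - 1)
    eigvals = np.where(eigvals > 0, eigvals, np.inf)
    return (scores**2 / eigvals).sum(axis=1)


def remove_outliers(panel: CytokinePanel, params: OutlierParams | None = None,
                    policy: str = "half_min") -> tuple[CytokinePanel, list[str]]:
    """Iteratively remove samples outside the PCA confidence ellipse.

    Each round z-scores the surviving panel, computes PC-space squared
    Mahalanobis distances, and removes the single worst sample whose
    distance exceeds the chi-square quantile at ``params.confidence`` with
    df = ``params.n_components`` (ties broken by smaller row index), then
    refits.  Stops when no sample exceeds the cutoff.

    Returns the surviving panel and the removed sample ids in removal order.
    """
    params = params or OutlierParams()
    current = panel.copy()
    if current.n_samples <= params.n_components + 2:
        raise PanelError(
            f"need more than {params.n_components + 2} samples for the outlier screen"
        )
    cutoff = stats.chi2.ppf(params.confidence, df=params.n_components)
    removed: list[str] = []
    while True:
        zm = zscore(current, policy)
        d2 = _pc_mahalanobis_sq(zm.z, params.n_components)
        worst = int(np.argmax(d2))  # argmax takes the first (smaller index) on ties
        if d2[worst] <= cutoff:
            break
        sid = current.sample_ids[worst]
        current = current.drop_samples([sid])
        removed.append(sid)
        if current.n_samples <= params.n_components + 2:
            raise PanelError(
                "outlier removal reduced the cohort below "
                f"{params.n_components + 3} samples (degenerate cohort); removed so far: {removed}"
            )
    return current, removed
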