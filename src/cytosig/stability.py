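"""Leave-K-out loading-stability profiling (LKOCV).

The LV1 loading profile of a PLS model fitted to a small cohort can be
driven by a handful of samples.  To quantify this, K samples are removed
uniformly at random (without replacement within a draw), the full z-score →
fit → rotate pipeline is re-run, the replicate's LV1 weights are sign-aligned
to the full-model reference, and the procedure repeats (100 draws by
default).  The per-analyte mean ± SD across replicates gives the error bars
on the loading bar charts; the coefficient of variation SD/|mean| is the
stability score used for signature selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .panel import CytokinePanel, PanelError
from .pls import fit_panel

__all__ = ["StabilityProfile", "lkocv_profile"]

_MAX_REDRAWS = 1000


@dataclass
class StabilityProfile:
    """Per-analyte LV1 loading statistics across leave-K-out replicates."""

    analyte_names: list[str]
    mean_loading: np.ndarray
    sd_loading: np.ndarray
    cv: np.ndarray                   # SD / |mean|, ∞ where mean == 0
    K: int
    n_iterations: int
    reference_loadings: np.ndarray   # full-model LV1 weights (case-positive)
    n_redraws: int = 0
    seed: Union[int, None] = None
    replicate_loadings: Union[np.ndarray, None] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "analyte": self.analyte_names,
            "mean": self.mean_loading,
            "sd": self.sd_loading,
            "cv": self.cv,
            "reference": self.reference_loadings,
        })

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def read(path: Union[str, Path], K: int = -1, n_iterations: int = -1) -> "StabilityProfile":
        df = pd.read_csv(path, sep="\t")
        return StabilityProfile(
            analyte_names=df["analyte"].astype(str).tolist(),
            mean_loading=df["mean"].to_numpy(float),
            sd_loading=df["sd"].to_numpy(float),
            cv=df["cv"].to_numpy(float),
            K=K, n_iterations=n_iterations,
            reference_loadings=df["reference"].to_numpy(float),
        )


def _valid_subset(labels: np.ndarray, keep: np.ndarray, discriminant: bool) -> bool:
    if not discriminant:
        return True
    kept = labels[keep]
    return all((kept == g).sum() >= 2 for g in np.unique(labels))


def lkocv_profile(panel: CytokinePanel, target: str = "group",
                  case_label: Union[str, None] = None, K: int = 5,
                  n_iterations: int = 100, seed: Union[int, None] = None,
                  policy: str = "half_min",
                  keep_replicates: bool = False) -> StabilityProfile:
    """Profile LV1 loading stability under leave-K-out refitting.

    Each of ``n_iterations`` replicates drops a uniformly random K-subset of
    samples (subsets are drawn independently across replicates), re-runs the
    full fit, and sign-aligns its LV1 weights to the full-model reference
    (flipped when the dot product is negative).  For a discriminant target a
    draw that would leave any group with fewer than 2 samples is redrawn;
    the count of redraws is recorded on the profile.  Fully reproducible
    from ``seed``.
    """
    n = panel.n_samples
    if K < 0:
        raise ValueError("K must be ≥ 0")
    if K >= n - 2:
        raise ValueError(f"K={K} too large for n={n} (need K < n − 2)")
    reference = fit_panel(panel, target=target, case_label=case_label, policy=policy)
    ref_w1 = reference.lv1_loadings
    labels = panel.groups() if target == "group" else np.array([])
    discriminant = target == "group"

    rng = np.random.default_rng(seed)
    sample_ids = np.asarray(panel.sample_ids)
    p = panel.n_analytes
    reps = np.empty((n_iterations, p))
    n_redraws = 0
    for it in range(n_iterations):
        if K == 0:
            keep = np.arange(n)
        else:
            for _ in range(_MAX_REDRAWS):
                drop = rng.choice(n, size=K, replace=False)
                keep = np.setdiff1d(np.arange(n), drop)
                if _valid_subset(labels, keep, discriminant):
                    break
                n_redraws += 1
            else:
                raise PanelError(
                    f"could not draw a leave-{K}-out subset keeping ≥2 samples per group"
                )
        sub = panel.subset_samples(sample_ids[keep].tolist())
        model = fit_panel(sub, target=target, case_label=case_label, policy=policy)
        w1 = model.lv1_loadings
        if float(w1 @ ref_w1) < 0:
            w1 = -w1
        reps[it] = w1

    if K == 0:  # all replicates are the full model: SD is exactly zero
        mean, sd = reps[0].copy(), np.zeros(p)
    else:
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if n_iterations > 1 else np.zeros(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0.0, np.inf, sd / np.abs(mean))
    return StabilityProfile(
        analyte_names=panel.analyte_names,
        mean_loading=mean, sd_loading=sd, cv=cv,
        K=K, n_iterations=n_iterations,
        reference_loadings=ref_w1, n_redraws=n_redraws, seed=seed,
        replicate_loadings=reps if keep_replicates else None,
    )
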