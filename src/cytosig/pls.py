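"""NIPALS partial least squares regression with orthogonal LV rotation.

Two flavors are used throughout: discriminant PLSR (D-PLSR), regressing the
z-scored analyte matrix on a two-class ±1 group encoding, and continuous
PLSR against a clinical score.  Both fit exactly two latent variables
(LV1/LV2).  After fitting, an orthogonal rotation of the score/weight plane
aligns the group separation (or the covariance with the continuous target)
with LV1 and orients the case group (or better score) positive.

For a single-response y the NIPALS sequence is deterministic:

    w = Xᵀy / ‖Xᵀy‖,  t = X w,  p = Xᵀt / tᵀt,  q = yᵀt / tᵀt,
    X ← X − t pᵀ,     y ← y − t q

per component.  The weight vectors of successive components are orthonormal,
so an orthogonal rotation R applied to both scores and weights leaves the
reconstruction T Wᵀ unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .panel import CytokinePanel, PanelError
from .preprocess import ZScaledMatrix, zscore

__all__ = ["PLSModel", "PLSError", "encode_groups", "fit_pls", "rotate_to_lv1",
           "project", "fit_panel", "resolve_target"]


class PLSError(ValueError):
    """Raised for degenerate PLS inputs (no predictive direction, etc.)."""


@dataclass
class PLSModel:
    """A fitted 2-component PLS model.

    Raw NIPALS quantities (``weights``, ``x_loadings``, ``scores_raw``,
    ``x_rotations``) are stored unrotated; ``rotation`` is the orthogonal
    2×2 matrix applied on top.  The user-facing ``scores`` and
    ``lv_weights`` properties are post-rotation.
    """

    analyte_names: list[str]
    n_components: int
    weights: np.ndarray        # p × c, orthonormal columns (raw NIPALS w)
    x_loadings: np.ndarray     # p × c
    y_loadings: np.ndarray     # c
    x_rotations: np.ndarray    # p × c, W (PᵀW)⁻¹; X_z @ x_rotations = scores_raw
    scores_raw: np.ndarray     # n × c
    x_mean: np.ndarray         # training column means (pg/mL)
    x_sd: np.ndarray           # training column SDs (pg/mL)
    y_mean: float
    y_encoding: Union[dict, str]   # group_label → ±1, or "continuous"
    case_label: Union[str, None] = None
    sample_ids: list[str] = field(default_factory=list)
    rotation: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rotation is None:
            self.rotation = np.eye(self.n_components)
        self.rotation = np.asarray(self.rotation, dtype=float)

    @property
    def scores(self) -> np.ndarray:
        """Per-sample LV scores after rotation (n × c)."""
        return self.scores_raw @ self.rotation

    @property
    def lv_weights(self) -> np.ndarray:
        """Per-analyte LV weight profile after rotation (p × c).

        Column 0 is the LV1 loading profile plotted as bar charts."""
        return self.weights @ self.rotation

    @property
    def projection_matrix(self) -> np.ndarray:
        """Matrix mapping a z-scored data matrix to rotated scores."""
        return self.x_rotations @ self.rotation

    @property
    def lv1_loadings(self) -> np.ndarray:
        return self.lv_weights[:, 0]


def encode_groups(labels: Sequence[str], case_label: str) -> np.ndarray:
    """Encode a two-class grouping as ±1 (case → +1, other → −1)."""
    labels = [str(l) for l in labels]
    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise PLSError(f"discriminant encoding needs exactly 2 distinct labels, got {distinct}")
    if case_label not in distinct:
        raise PLSError(f"case label {case_label!r} not among groups {distinct}")
    return np.where(np.asarray(labels) == case_label, 1.0, -1.0)


def fit_pls(z: ZScaledMatrix, y: np.ndarray, n_components: int = 2,
            y_encoding: Union[dict, str] = "continuous",
            case_label: Union[str, None] = None) -> PLSModel:
    """Fit a single-response PLS by NIPALS on a z-scored matrix.

    ``y`` is centered internally.  Deterministic: no random initialization
    is needed for a single-column response.
    """
    X = np.array(z.z, dtype=float, copy=True)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise PLSError("need at least 3 samples")
    if y.shape != (n,):
        raise PLSError(f"y must have length {n}, got shape {y.shape}")
    if n_components > min(n - 1, p):
        raise PLSError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    for k in range(n_components):
        cov = X.T @ yc
        norm = np.linalg.norm(cov)
        if norm < 1e-12:
            raise PLSError(f"no predictive direction: Xᵀy vanished at component {k + 1}")
        w = cov / norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise PLSError(f"degenerate score vector at component {k + 1}")
        pk = X.T @ t / tt
        qk = float(yc @ t) / tt
        X -= np.outer(t, pk)
        yc = yc - t * qk
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t

    x_rot = W @ np.linalg.inv(P.T @ W)
    return PLSModel(
        analyte_names=list(z.analyte_names),
        n_components=n_components,
        weights=W, x_loadings=P, y_loadings=q, x_rotations=x_rot, scores_raw=T,
        x_mean=np.asarray(z.column_means, dtype=float),
        x_sd=np.asarray(z.column_sds, dtype=float),
        y_mean=y_mean, y_encoding=y_encoding, case_label=case_label,
        sample_ids=list(z.sample_ids),
    )


def _rotation_from_direction(d: np.ndarray) -> np.ndarray:
    """Orthogonal 2×2 rotation whose first axis is the direction of ``d``."""
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise PLSError("degenerate rotation: separation direction has zero length")
    u = d / norm
    # columns: LV1 axis = u, LV2 axis = its perpendicular (det = +1)
    return np.array([[u[0], -u[1]], [u[1], u[0]]])


def rotate_to_lv1(model: PLSModel, groups: Union[Sequence[str], None] = None,
                  target: Union[np.ndarray, None] = None) -> PLSModel:
    """Rotate the LV plane so all group separation (or target covariance)
    falls on LV1, case/better-score positive.

    Discriminant mode (``groups`` given, with ``model.case_label``): the
    optimal LV1 axis maximizing the squared difference of group mean scores
    is the direction of the 2-D mean-difference vector; the rotation is
    computed in closed form.  Regression mode (``target`` given): the axis
    maximizing squared covariance with the target is the direction of the
    score–target covariance vector.  The reconstruction T Wᵀ is unchanged.
    """
    if model.n_components != 2:
        raise PLSError("rotation is defined for 2-component models")
    T = model.scores_raw
    if groups is not None:
        if model.case_label is None:
            raise PLSError("discriminant rotation needs model.case_label")
        labels = np.asarray([str(g) for g in groups])
        case = labels == model.case_label
        if case.sum() == 0 or (~case).sum() == 0:
            raise PLSError("both groups must be present for rotation")
        d = T[case].mean(axis=0) - T[~case].mean(axis=0)
    elif target is not None:
        y = np.asarray(target, dtype=float)
        yc = y - y.mean()
        d = T.T @ yc  # ∝ covariance of each raw LV with the target
    else:
        raise PLSError("provide groups (discriminant) or target (regression)")
    R = _rotation_from_direction(d)
    rotated = PLSModel(
        analyte_names=model.analyte_names, n_components=model.n_components,
        weights=model.weights, x_loadings=model.x_loadings, y_loadings=model.y_loadings,
        x_rotations=model.x_rotations, scores_raw=model.scores_raw,
        x_mean=model.x_mean, x_sd=model.x_sd, y_mean=model.y_mean,
        y_encoding=model.y_encoding, case_label=model.case_label,
        sample_ids=model.sample_ids, rotation=R,
    )
    return rotated


def project(model: PLSModel, panel: CytokinePanel, scaling: str = "self",
            policy: str = "half_min") -> np.ndarray:
    """Score new samples on a fitted model's latent variables.

    ``scaling="self"`` (default) z-scores the target panel internally with
    its own means/SDs — each dataset is standardized within itself before
    modeling — while ``scaling="training"`` reuses the model's stored
    training scaling.  Returns an m × n_components score matrix.
    """
    missing = [a for a in model.analyte_names if a not in panel.concentrations.columns]
    if missing:
        raise PanelError(f"panel lacks model analytes: {missing}")
    sub = panel.subset_analytes(model.analyte_names)
    if scaling == "self":
        z = zscore(sub, policy).z
    elif scaling == "training":
        from .preprocess import impute_missing
        z = (impute_missing(sub, policy).values - model.x_mean) / model.x_sd
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return z @ model.projection_matrix


def resolve_target(panel: CytokinePanel, target: str,
                   case_label: Union[str, None] = None) -> tuple[np.ndarray, Union[dict, str]]:
    """Build the regression response for a panel.

    ``target="group"`` gives the discriminant ±1 encoding of
    ``metadata["group_label"]`` against ``case_label``; any other string
    names a numeric metadata column (clinical score, age, ...).
    """
    if target == "group":
        if case_label is None:
            raise PLSError("discriminant target needs case_label")
        labels = panel.groups()
        y = encode_groups(labels, case_label)
        other = sorted(set(str(l) for l in labels) - {case_label})[0]
        return y, {case_label: 1.0, other: -1.0}
    if target not in panel.metadata.columns:
        raise PanelError(f"metadata column not found: {target!r}")
    y = panel.metadata[target].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise PanelError(f"target column {target!r} has missing values")
    return y, "continuous"


def fit_panel(panel: CytokinePanel, target: str = "group",
              case_label: Union[str, None] = None, n_components: int = 2,
              policy: str = "half_min") -> PLSModel:
    """Convenience pipeline: z-score → NIPALS fit → rotate LV1, orient positive.

    The component count is clamped to min(n − 1, p), so a single-analyte
    panel yields a 1-component model (orientation applied, no rotation).
    """
    y, enc = resolve_target(panel, target, case_label)
    z = zscore(panel, policy)
    ncomp = min(n_components, panel.n_analytes, panel.n_samples - 1)
    model = fit_pls(z, y, n_components=ncomp, y_encoding=enc,
                    case_label=case_label if target == "group" else None)
    if ncomp == 1:
        # orient LV1 case-positive (or better-score-positive) by a sign flip
        t1 = model.scores_raw[:, 0]
        yc = y - y.mean()
        sign = 1.0 if float(t1 @ yc) >= 0 else -1.0
        model.rotation = np.array([[sign]])
        return model
    if target == "group":
        return rotate_to_lv1(model, groups=panel.groups())
    return rotate_to_lv1(model, target=y)
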