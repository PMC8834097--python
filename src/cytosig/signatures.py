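"""Cross-dataset coincident-signature selection and transfer.

An analyte belongs to the coincident signature of two datasets when its
LKOCV mean LV1 loading is large (|mean| ≥ 0.2 by default), stable
(CV < 1 in both), and points the same way (case-up in both or case-down in
both).  The reduced signature can then be refit on either dataset, and a
model trained on one dataset can be projected onto the other; separation of
cases from controls on the projected LV1 is summarized as an AUC plus a
rank-sum p value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import AnalyteMap, CytokinePanel, PanelError
from .pls import PLSModel, fit_panel, project
from .stability import StabilityProfile
from .stats import wilcoxon_rank_sum

__all__ = ["SignatureCriteria", "SignatureSet", "TransferResult",
           "select_coincident", "reduced_fit", "transfer_signature", "lv1_auc"]


@dataclass
class SignatureCriteria:
    """Thresholds for coincident-analyte selection."""

    mean_threshold: float = 0.2
    cv_threshold: float = 1.0
    require_direction_match: bool = True

    def __post_init__(self) -> None:
        if self.mean_threshold <= 0:
            raise ValueError("mean_threshold must be > 0")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")


@dataclass
class SignatureSet:
    """Analytes passing coincident selection, with case direction."""

    analytes: list[str]
    directions: dict[str, str] = field(default_factory=dict)  # analyte → case-up | case-down
    sources: tuple[str, str] = ("A", "B")

    def __len__(self) -> int:
        return len(self.analytes)


@dataclass
class TransferResult:
    """Projection of one dataset's signature model onto another dataset."""

    scores: pd.DataFrame       # sample, LV1, LV2, group
    auc: float                 # case-vs-control separation on projected LV1
    p_value: float             # two-sided rank-sum p of the same comparison
    case_label: str


def select_coincident(profile_a: StabilityProfile, profile_b: StabilityProfile,
                      criteria: SignatureCriteria | None = None,
                      sources: tuple[str, str] = ("A", "B")) -> SignatureSet:
    """Select analytes stable and concordant across two stability profiles.

    Both profiles must be oriented case-positive.  An analyte is selected
    iff |mean LV1 loading| ≥ ``mean_threshold`` in both profiles, CV <
    ``cv_threshold`` in both, and (by default) the loading signs agree.
    Profiles are intersected on analyte name; disjoint profiles are an
    error, an empty selection only a warning.
    """
    criteria = criteria or SignatureCriteria()
    idx_b = {a: i for i, a in enumerate(profile_b.analyte_names)}
    shared = [a for a in profile_a.analyte_names if a in idx_b]
    if not shared:
        raise PanelError("stability profiles share no analytes")
    chosen, directions = [], {}
    for a in shared:
        ia, ib = profile_a.analyte_names.index(a), idx_b[a]
        ma, mb = profile_a.mean_loading[ia], profile_b.mean_loading[ib]
        ca, cb = profile_a.cv[ia], profile_b.cv[ib]
        if abs(ma) < criteria.mean_threshold or abs(mb) < criteria.mean_threshold:
            continue
        if not (ca < criteria.cv_threshold and cb < criteria.cv_threshold):
            continue
        if criteria.require_direction_match and np.sign(ma) != np.sign(mb):
            continue
        chosen.append(a)
        directions[a] = "case-up" if ma > 0 else "case-down"
    if not chosen:
        warnings.warn("no analyte passed coincident selection", stacklevel=2)
    return SignatureSet(chosen, directions, sources)


def reduced_fit(panel: CytokinePanel, signature: SignatureSet, target: str = "group",
                case_label: Union[str, None] = None, policy: str = "half_min") -> PLSModel:
    """Refit the full PLS pipeline on the signature-restricted panel."""
    if not signature.analytes:
        raise PanelError("signature set is empty")
    sub = panel.subset_analytes(signature.analytes)
    return fit_panel(sub, target=target, case_label=case_label, policy=policy)


def lv1_auc(lv1: np.ndarray, labels: np.ndarray, case_label: str) -> float:
    """AUC of case vs control separation along LV1 scores.

    Equals the Mann–Whitney U of the case scores divided by n_case·n_ctrl
    (ties counted half).
    """
    labels = np.asarray([str(l) for l in labels])
    case = np.asarray(lv1, dtype=float)[labels == case_label]
    ctrl = np.asarray(lv1, dtype=float)[labels != case_label]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both case and control samples are required for AUC")
    ranks = sps.rankdata(np.concatenate([case, ctrl]))
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * ctrl.size))


def transfer_signature(model_a: PLSModel, panel_b: CytokinePanel,
                       amap: AnalyteMap | None = None,
                       case_label: Union[str, None] = None,
                       policy: str = "half_min") -> TransferResult:
    """Project a model fitted on dataset A onto dataset B and score separation.

    ``amap`` translates B's analyte names to A's (identity if omitted);
    panel B is z-scored internally before projection.  ``case_label`` names
    B's case group (defaults to the model's own case label).  Raises
    :class:`PanelError` naming any model analyte the map/panel does not
    cover.
    """
    if amap is not None and len(amap) > 0:
        lut_b = {str(c).strip().casefold(): c for c in panel_b.analyte_names}
        rename = {}
        for a_name, b_name in amap.pairs:
            key = str(b_name).strip().casefold()
            if key in lut_b:
                rename[lut_b[key]] = a_name
        panel_b = CytokinePanel(panel_b.concentrations.rename(columns=rename),
                                panel_b.metadata.copy())
    missing = [a for a in model_a.analyte_names if a not in panel_b.concentrations.columns]
    if missing:
        raise PanelError(f"transfer coverage gap, analytes not available: {missing}")
    scores = project(model_a, panel_b, scaling="self", policy=policy)
    case_label = case_label if case_label is not None else model_a.case_label
    if case_label is None:
        raise ValueError("case_label required to score separation")
    labels = panel_b.groups()
    auc = lv1_auc(scores[:, 0], labels, case_label)
    case_mask = np.asarray([str(l) for l in labels]) == case_label
    res = wilcoxon_rank_sum(scores[case_mask, 0], scores[~case_mask, 0], mode="normal")
    frame = pd.DataFrame({
        "sample": panel_b.sample_ids,
        "LV1": scores[:, 0],
        "LV2": scores[:, 1],
        "group": [str(l) for l in labels],
    })
    return TransferResult(frame, auc, res.p_raw, case_label)
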