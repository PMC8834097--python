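"""End-to-end study replica on synthetic panels.

Sequence: simulate a human-plasma-like cohort and a mouse-brain-like cohort
sharing a planted signature → impute / outlier-screen → discriminant PLS on
each → LKOCV stability profiles → univariate screens → coincident-signature
selection on the shared analytes → reduced refit → cross-dataset transfer
with an AUC.  Every stage seed derives from the single run seed, so a rerun
with the same config is bit-identical; each stage output file's sha256 is
recorded in the run summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

from . import panel_io
from .panel import CytokinePanel
from .pls import fit_panel
from .preprocess import OutlierParams, impute_missing, remove_outliers
from .signatures import SignatureCriteria, reduced_fit, select_coincident, transfer_signature
from .stability import lkocv_profile
from .stats import univariate_screen
from .synthetic import (attach_clinical_scores, gen_clinical_scores, gen_paired_datasets,
                        human_plasma_config, mouse_brain_config, shared_names)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one end-to-end run (all stage seeds derive from ``seed``)."""

    seed: int = 0
    shared_signature_size: int = 7
    effect_size: float = 1.5
    k_human: int = 3
    k_mouse: int = 1
    n_iterations: int = 100
    mean_threshold: float = 0.2
    cv_threshold: float = 1.0
    outlier_confidence: float = 0.995
    outlier_components: int = 2
    screen_mouse_outliers: bool = True
    impute_policy: str = "half_min"
    motor_score: str = "BAMF_gross_motor"

    @staticmethod
    def from_yaml(path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return RunConfig(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(config: RunConfig, out_dir: Union[str, Path]) -> dict:
    """Run the full study replica; returns (and writes) the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim_seed, lk_h, lk_m, lk_hs, lk_ms, lk_score = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=6))
    written: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        written[name] = _sha256(path)

    # -- stage 1: simulate -------------------------------------------------
    shared_sig = shared_names()[: config.shared_signature_size]
    cfg_h = human_plasma_config(effect_size=config.effect_size)
    cfg_m = mouse_brain_config(effect_size=config.effect_size)
    (human, truth_h), (mouse, truth_m) = gen_paired_datasets(
        cfg_h, cfg_m, shared_sig, mode="shared", seed=sim_seed)
    scores = gen_clinical_scores(truth_h, cfg_h, seed=sim_seed + 1)
    human = attach_clinical_scores(human, scores)
    emit("human_panel.tsv", lambda p: panel_io.write_panel(
        human, p, out / "human_meta.tsv") or None)
    written["human_meta.tsv"] = _sha256(out / "human_meta.tsv")
    emit("mouse_panel.tsv", lambda p: panel_io.write_panel(
        mouse, p, out / "mouse_meta.tsv") or None)
    written["mouse_meta.tsv"] = _sha256(out / "mouse_meta.tsv")

    # -- stage 2: preprocess ----------------------------------------------
    human = impute_missing(human, config.impute_policy)
    mouse = impute_missing(mouse, config.impute_policy)
    removed: list[str] = []
    if config.screen_mouse_outliers:
        mouse, removed = remove_outliers(
            mouse, OutlierParams(config.outlier_confidence, config.outlier_components),
            policy=config.impute_policy)

    # -- stage 3: discriminant fits + stability ---------------------------
    case_h, case_m = cfg_h.case_label, cfg_m.case_label
    model_h = fit_panel(human, "group", case_label=case_h, policy=config.impute_policy)
    model_m = fit_panel(mouse, "group", case_label=case_m, policy=config.impute_policy)
    prof_h = lkocv_profile(human, "group", case_label=case_h, K=config.k_human,
                           n_iterations=config.n_iterations, seed=lk_h,
                           policy=config.impute_policy)
    prof_m = lkocv_profile(mouse, "group", case_label=case_m, K=config.k_mouse,
                           n_iterations=config.n_iterations, seed=lk_m,
                           policy=config.impute_policy)
    emit("human_profile.tsv", prof_h.write)
    emit("mouse_profile.tsv", prof_m.write)

    # continuous PLSR of case samples against a motor score
    cases = human.subset_samples(
        [s for s, g in zip(human.sample_ids, human.groups()) if g == case_h])
    model_score = fit_panel(cases, config.motor_score, policy=config.impute_policy)
    prof_score = lkocv_profile(cases, config.motor_score, K=config.k_human,
                               n_iterations=config.n_iterations, seed=lk_score,
                               policy=config.impute_policy)
    emit("motor_score_profile.tsv", prof_score.write)

    # -- stage 4: univariate screens --------------------------------------
    stats_h = univariate_screen(human, grouping="group3")
    stats_m = univariate_screen(mouse, grouping="group_label")
    emit("human_stats.tsv", lambda p: stats_h.to_csv(p, sep="\t", index=False))
    emit("mouse_stats.tsv", lambda p: stats_m.to_csv(p, sep="\t", index=False))

    # -- stage 5: shared-analyte restriction + coincident selection -------
    shared_analytes = [a for a in human.analyte_names if a in set(mouse.analyte_names)]
    human_s = human.subset_analytes(shared_analytes)
    mouse_s = mouse.subset_analytes(shared_analytes)
    prof_hs = lkocv_profile(human_s, "group", case_label=case_h, K=config.k_human,
                            n_iterations=config.n_iterations, seed=lk_hs,
                            policy=config.impute_policy)
    prof_ms = lkocv_profile(mouse_s, "group", case_label=case_m, K=config.k_mouse,
                            n_iterations=config.n_iterations, seed=lk_ms,
                            policy=config.impute_policy)
    criteria = SignatureCriteria(config.mean_threshold, config.cv_threshold)
    signature = select_coincident(prof_hs, prof_ms, criteria,
                                  sources=("human_plasma", "mouse_brain"))
    emit("signature.json", lambda p: p.write_text(json.dumps(
        {"analytes": signature.analytes, "directions": signature.directions,
         "sources": list(signature.sources)}, indent=1), encoding="utf-8"))

    # -- stage 6: reduced refit + transfer --------------------------------
    transfer = None
    if signature.analytes:
        model_red = reduced_fit(human_s, signature, "group", case_label=case_h,
                                policy=config.impute_policy)
        emit("reduced_model.json", lambda p: panel_io.serialize_model(model_red, p) and None)
        result = transfer_signature(model_red, mouse_s, case_label=case_m,
                                    policy=config.impute_policy)
        emit("transfer_scores.tsv", lambda p: result.scores.to_csv(p, sep="\t", index=False))
        transfer = {"auc": result.auc, "p_value": result.p_value,
                    "case_label": result.case_label}

    def top(model_or_prof, k=10):
        if hasattr(model_or_prof, "lv1_loadings"):
            names, w = model_or_prof.analyte_names, model_or_prof.lv1_loadings
        else:
            names, w = model_or_prof.analyte_names, model_or_prof.mean_loading
        order = np.argsort(-np.abs(w))[:k]
        return [{"analyte": names[i], "loading": float(w[i])} for i in order]

    summary = _jsonable({
        "config": asdict(config),
        "cohorts": {
            "human": {"n": human.n_samples, "p": human.n_analytes,
                      "planted": truth_h.planted_analytes},
            "mouse": {"n": mouse.n_samples, "p": mouse.n_analytes,
                      "planted": truth_m.planted_analytes,
                      "outliers_removed": removed},
        },
        "lv1_top_loadings": {"human": top(model_h), "mouse": top(model_m),
                             "motor_score": top(model_score)},
        "stability": {
            "human": {"K": prof_h.K, "median_cv": float(np.median(prof_h.cv))},
            "mouse": {"K": prof_m.K, "median_cv": float(np.median(prof_m.cv))},
        },
        "univariate": {
            "human_significant": int((stats_h["p_adjusted"] < 0.05).sum()),
            "mouse_significant": int((stats_m["p_adjusted"] < 0.05).sum()),
        },
        "signature": {"analytes": signature.analytes, "directions": signature.directions,
                      "n_shared_analytes": len(shared_analytes)},
        "transfer": transfer,
        "stage_hashes": dict(sorted(written.items())),
    })
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True),
                                      encoding="utf-8")
    return summary
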