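"""Synthetic cytokine cohorts with planted case effects and ground truth.

The generator emulates the statistical structure of multiplexed
cytokine/chemokine panels in a case-control cohort:

* log-normal concentrations — analyte *a* has baseline log10 level
  μ_a ~ U(0.5, 2.5) (log10 pg/mL) and within-cohort log10 SD
  σ_a ~ U(0.1, 0.3) (a 26–100% geometric CV, typical of plasma panels);
* a single latent inflammation/severity factor f per sample (standard
  normal, shifted upward in cases), loading on each analyte with
  λ_a ~ U(0.2, 0.7), which makes analytes positively co-regulated;
* planted case effects — a chosen subset of analytes is shifted upward by
  δ log10 units in cases (default 1.5, a ~30-fold elevation);
* mild cases — a case subgroup whose severity shift and planted effects are
  attenuated (factor 0.25 by default), so they cluster with controls;
* ordinal clinical scores monotonically tied to the latent severity.

Each generated panel comes with a :class:`SyntheticTruth` recording the
planted analytes, their directions, the per-sample severity, and the
configuration, enabling recovery tests of the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .panel import CytokinePanel

__all__ = ["SyntheticConfig", "SyntheticTruth", "gen_cohort", "gen_clinical_scores",
           "gen_paired_datasets", "attach_clinical_scores",
           "human_plasma_config", "mouse_plasma_config", "mouse_brain_config",
           "shared_names"]

#: number of analytes shared between the human-like and mouse-like panels
N_SHARED = 26

BAMF_COLUMNS = ("BAMF_gross_motor", "BAMF_fine_motor", "BAMF_upper_extremity",
                "BAMF_deglutition", "BAMF_articulation")
ASHWORTH_LEVELS = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)
_ASHWORTH_EDGES = (-0.5, 0.0, 0.5, 1.0, 1.75)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults follow the human plasma study design."""

    n_control: int = 18
    n_case: int = 18
    n_mild: int = 3                       # subset of cases with attenuated disease
    n_analytes: int = 41
    analyte_names: Union[list[str], None] = None
    planted_analytes: Union[list[str], None] = None
    n_planted: int = 8
    effect_size: float = 1.5              # δ, log10 units added in cases
    planted_directions: Union[list[int], None] = None  # ±1 per planted analyte
    case_shift: float = 1.0               # latent severity shift for typical cases
    mild_attenuation: float = 0.25
    mu_range: tuple[float, float] = (0.5, 2.5)      # baseline log10 pg/mL
    sigma_range: tuple[float, float] = (0.1, 0.3)   # within-cohort log10 SD
    lambda_range: tuple[float, float] = (0.2, 0.7)  # latent-factor loadings
    score_noise: float = 1.0
    control_label: str = "CTRL"
    case_label: str = "MLIV"
    species: str = "human"
    compartment: str = "plasma"
    age_value: Union[float, None] = None  # fixed age; None → uniform 2–30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_case < 3:
            raise ValueError("need at least 3 samples per group")
        if not 0 <= self.n_mild <= self.n_case:
            raise ValueError("n_mild must lie within the case group")
        if not 0.0 <= self.mild_attenuation <= 1.0:
            raise ValueError("mild_attenuation must be in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")

    def names(self) -> list[str]:
        if self.analyte_names is not None:
            if len(self.analyte_names) != self.n_analytes:
                raise ValueError("analyte_names length must equal n_analytes")
            return list(self.analyte_names)
        return [f"CYT-{i + 1:03d}" for i in range(self.n_analytes)]


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated panel."""

    planted_analytes: list[str]
    directions: dict[str, int]           # analyte → ±1 (case-up / case-down)
    severity: pd.Series                  # latent factor f per sample id
    config: SyntheticConfig = field(repr=False)


def shared_names(n: int = N_SHARED) -> list[str]:
    """Analyte names common to the human-like and mouse-like presets."""
    return [f"CYT-{i + 1:03d}" for i in range(n)]


def human_plasma_config(**kw) -> SyntheticConfig:
    """41-analyte human plasma panel: 18 controls, 18 cases (3 mild)."""
    names = shared_names() + [f"HUM-{i:03d}" for i in range(N_SHARED + 1, 42)]
    return SyntheticConfig(analyte_names=names, **kw)


def mouse_plasma_config(**kw) -> SyntheticConfig:
    """32-analyte mouse plasma panel (one age/sex stratum: 4 WT, 6 KO)."""
    names = shared_names() + [f"MUS-{i:03d}" for i in range(N_SHARED + 1, 33)]
    kw.setdefault("n_control", 4)
    kw.setdefault("n_case", 6)
    kw.setdefault("n_mild", 0)
    kw.setdefault("n_analytes", 32)
    kw.setdefault("control_label", "WT")
    kw.setdefault("case_label", "KO")
    kw.setdefault("species", "mouse")
    kw.setdefault("compartment", "plasma")
    kw.setdefault("age_value", 1.0)
    return SyntheticConfig(analyte_names=names, **kw)


def mouse_brain_config(**kw) -> SyntheticConfig:
    """32-analyte mouse brain panel: 5 WT vs 5 KO at 2 months."""
    kw.setdefault("n_control", 5)
    kw.setdefault("n_case", 5)
    kw.setdefault("compartment", "brain")
    kw.setdefault("age_value", 2.0)
    cfg = mouse_plasma_config(**kw)
    return cfg


def gen_cohort(config: SyntheticConfig,
               seed: Union[int, None] = None) -> tuple[CytokinePanel, SyntheticTruth]:
    """Generate one case-control cohort; reproducible from the seed.

    Per sample i and analyte a:

        log10 c[i, a] = μ_a + σ_a (λ_a f_i + √(1 − λ_a²) ε_ia)
                        + δ_a · 1[case] · (attenuation if mild)

    with f_i ~ N(0, 1) plus a group severity shift, ε iid standard normal,
    and δ_a = ±effect_size log10 units on planted analytes (0 elsewhere).
    Concentrations are 10^log10 (pg/mL), hence strictly positive.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = config.names()
    p = len(names)
    if config.n_planted > p:
        raise ValueError("more planted analytes than analytes")
    if config.planted_analytes is not None:
        missing = [a for a in config.planted_analytes if a not in names]
        if missing:
            raise ValueError(f"planted analytes not in panel: {missing}")
        planted = list(config.planted_analytes)
    else:
        planted = sorted(rng.choice(names, size=config.n_planted, replace=False).tolist())
    if config.planted_directions is not None:
        if len(config.planted_directions) != len(planted):
            raise ValueError("planted_directions length mismatch")
        directions = {a: int(d) for a, d in zip(planted, config.planted_directions)}
    else:
        directions = {a: 1 for a in planted}

    mu = rng.uniform(*config.mu_range, size=p)
    sigma = rng.uniform(*config.sigma_range, size=p)
    lam = rng.uniform(*config.lambda_range, size=p)

    n_ctrl, n_case, n_mild = config.n_control, config.n_case, config.n_mild
    n = n_ctrl + n_case
    is_case = np.concatenate([np.zeros(n_ctrl, bool), np.ones(n_case, bool)])
    is_mild = np.zeros(n, bool)
    if n_mild:
        is_mild[n - n_mild:] = True  # last n_mild cases are mild
    atten = np.where(is_mild, config.mild_attenuation, 1.0)

    shift = np.where(is_case, config.case_shift * atten, 0.0)
    f = rng.standard_normal(n) + shift
    eps = rng.standard_normal((n, p))
    delta = np.zeros(p)
    for a, d in directions.items():
        delta[names.index(a)] = d * config.effect_size
    log10c = (mu + sigma * (lam * f[:, None] + np.sqrt(1.0 - lam**2) * eps)
              + delta * (is_case * atten)[:, None])
    conc = np.power(10.0, log10c)

    ctrl_ids = [f"{config.control_label}-{i + 1:02d}" for i in range(n_ctrl)]
    case_ids = [f"{config.case_label}-{i + 1:02d}" for i in range(n_case)]
    ids = ctrl_ids + case_ids
    presentation = np.where(~is_case, "control", np.where(is_mild, "mild", "typical"))
    group3 = np.where(~is_case, config.control_label,
                      np.where(is_mild, f"{config.case_label}-mild",
                               f"{config.case_label}-typical"))
    sex = np.array(["F", "M"] * (n // 2 + 1))[:n]
    if config.age_value is not None:
        age = np.full(n, float(config.age_value))
    else:
        age = np.round(rng.uniform(2.0, 30.0, size=n), 1)
    meta = pd.DataFrame({
        "group_label": np.where(is_case, config.case_label, config.control_label),
        "presentation": presentation,
        "group3": group3,
        "species": config.species,
        "compartment": config.compartment,
        "sex": sex,
        "age": age,
    }, index=pd.Index(ids, name="sample"))
    panel = CytokinePanel(pd.DataFrame(conc, index=meta.index, columns=names), meta)
    truth = SyntheticTruth(planted, directions, pd.Series(f, index=meta.index, name="severity"),
                           config)
    return panel, truth


def gen_clinical_scores(truth: SyntheticTruth, config: Union[SyntheticConfig, None] = None,
                        seed: Union[int, None] = None) -> pd.DataFrame:
    """Ordinal clinical scores monotonically linked to the latent severity.

    Five 0–10 motor-function scores (higher = better function) follow
    ``round(clamp(10 − (2.5 f + score_noise η), 0, 10))``; a muscle-tone
    grade on the ordered scale {0, 1, 1.5, 2, 3, 4} (1.5 encoding grade
    "1+") is a monotone bucketing of f.  Mild cases carry an attenuated f
    by construction of the truth.
    """
    config = config or truth.config
    rng = np.random.default_rng((config.seed + 1) if seed is None else seed)
    f = truth.severity.to_numpy(dtype=float)
    n = f.size
    out = {}
    for col in BAMF_COLUMNS:
        eta = rng.standard_normal(n)
        raw = 10.0 - (2.5 * f + config.score_noise * eta)
        out[col] = np.round(np.clip(raw, 0.0, 10.0)).astype(int)
    idx = np.searchsorted(_ASHWORTH_EDGES, f, side="right")
    out["ashworth_elbow"] = np.asarray(ASHWORTH_LEVELS)[idx]
    return pd.DataFrame(out, index=truth.severity.index)


def attach_clinical_scores(panel: CytokinePanel, scores: pd.DataFrame) -> CytokinePanel:
    """Return a panel whose metadata includes the clinical score columns."""
    meta = panel.metadata.join(scores)
    return CytokinePanel(panel.concentrations.copy(), meta)


def gen_paired_datasets(config_a: SyntheticConfig, config_b: SyntheticConfig,
                        shared_signature: Sequence[str], mode: str = "shared",
                        seed: Union[int, None] = None):
    """Generate two cohorts whose planted effects share (or avoid) a signature.

    ``mode="shared"``: both cohorts plant ``shared_signature`` (same
    directions, case-up) plus independent extra analytes outside it, with
    extras kept private to each panel where possible so only the intended
    overlap is shared.  ``mode="disjoint"``: the two planted sets are
    disjoint, and the latent severity factor carries no group shift in
    either cohort (otherwise the co-regulation structure alone would
    transfer) — the null configuration for transfer tests.  An empty shared
    signature is equivalent to disjoint mode.
    """
    if mode not in ("shared", "disjoint"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = list(shared_signature)
    if not shared:
        mode = "disjoint"
    names_a, names_b = config_a.names(), config_b.names()
    for a in shared:
        if a not in names_a or a not in names_b:
            raise ValueError(f"shared signature analyte {a!r} missing from a panel")
    rng = np.random.default_rng(seed if seed is not None else config_a.seed)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    common = set(names_a) & set(names_b)

    def pick(names, n_pick, forbidden, prefer_private):
        pool = [x for x in names if x not in forbidden]
        private = [x for x in pool if x not in common]
        in_common = [x for x in pool if x in common]
        ordered = private + in_common if prefer_private else in_common + private
        if n_pick > len(ordered):
            raise ValueError("not enough analytes to plant")
        return ordered[:n_pick]

    if mode == "shared":
        extra_a = pick(names_a, max(config_a.n_planted - len(shared), 0),
                       set(shared), prefer_private=True)
        extra_b = pick(names_b, max(config_b.n_planted - len(shared), 0),
                       set(shared) | set(extra_a), prefer_private=True)
        planted_a, planted_b = shared + extra_a, shared + extra_b
        cfg_a = replace(config_a, planted_analytes=planted_a, planted_directions=None)
        cfg_b = replace(config_b, planted_analytes=planted_b, planted_directions=None)
    else:
        planted_a = pick(names_a, config_a.n_planted, set(), prefer_private=False)
        planted_b = pick(names_b, config_b.n_planted, set(planted_a), prefer_private=False)
        cfg_a = replace(config_a, planted_analytes=planted_a, planted_directions=None,
                        case_shift=0.0)
        cfg_b = replace(config_b, planted_analytes=planted_b, planted_directions=None,
                        case_shift=0.0)
    pair_a = gen_cohort(cfg_a, seed=seed_a)
    pair_b = gen_cohort(cfg_b, seed=seed_b)
    return pair_a, pair_b
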