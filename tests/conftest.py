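import numpy as np
import pandas as pd
import pytest

from cytosig import CytokinePanel, gen_cohort, human_plasma_config


def make_panel(values, groups, analytes=None, ids=None, **extra_meta):
    """Build a validated panel from a raw array and group labels."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"S{i + 1:02d}" for i in range(n)]
    analytes = analytes or [f"A{j + 1:02d}" for j in range(p)]
    meta = {"group_label": list(groups), "species": "human",
            "compartment": "plasma", "sex": ["F", "M"] * (n // 2 + 1),
            "age": [10.0] * n}
    meta["sex"] = meta["sex"][:n]
    meta.update(extra_meta)
    return CytokinePanel(
        pd.DataFrame(values, index=pd.Index(ids, name="sample"), columns=analytes),
        pd.DataFrame(meta, index=pd.Index(ids, name="sample")),
    )


def normal_panel(rng, n, p, groups=None, loc=100.0):
    """Panel whose z-scores are standard normal (no log-normal skew)."""
    groups = groups if groups is not None else ["X"] * n
    return make_panel(loc + rng.standard_normal((n, p)), groups)


@pytest.fixture(scope="session")
def human_cohort():
    """A default human-plasma-like cohort with ground truth (fixed seed)."""
    return gen_cohort(human_plasma_config(seed=11))


@pytest.fixture(scope="session")
def human_panel(human_cohort):
    return human_cohort[0]
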