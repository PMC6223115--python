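import numpy as np
import pandas as pd
import pytest

from spinedyn import KO_SPEC, WT_SPEC
from spinedyn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def wt_spec():
    return WT_SPEC


@pytest.fixture(scope="session")
def ko_spec():
    return KO_SPEC


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-group cohort, shared across tests that only read it."""
    cfg = CohortConfig(
        seed=11,
        n_spines={"WT": 300, "KO": 300},
        n_dendrites={"WT": 6, "KO": 6},
        n_animals={"WT": 3, "KO": 3},
        n_sessions=5,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_table():
    """Hand-written three-spine table with one elimination."""
    rows = [
        # spine a: three ordinary sessions
        ("m1", "d1", "a", "WT", 1, 0.10, False),
        ("m1", "d1", "a", "WT", 2, 0.12, False),
        ("m1", "d1", "a", "WT", 3, 0.11, False),
        # spine b: eliminated at session 2
        ("m1", "d1", "b", "WT", 1, 0.05, False),
        ("m1", "d1", "b", "WT", 2, 0.00, True),
        # spine c: gap between sessions (1 then 3)
        ("m1", "d2", "c", "WT", 1, 0.20, False),
        ("m1", "d2", "c", "WT", 3, 0.25, False),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "dendrite_id", "spine_id", "group",
            "session", "volume_um3", "eliminated",
        ],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
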