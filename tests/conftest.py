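import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nbtrial import SimulationConfig, TrialDataset, simulate_trial

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_dataset(rows, arm_labels=("control", "intervention")) -> TrialDataset:
    """Build a TrialDataset from (id, group, sex, age, university, hed, g_week|None) tuples."""
    recs = []
    for rid, group, sex, age, uni, hed, g in rows:
        recs.append(
            {
                "id": rid,
                "group": group,
                "sex": sex,
                "age": age,
                "university": uni,
                "hed": hed,
                "followed_up": g is not None,
                "g_week": g,
            }
        )
    df = pd.DataFrame(recs)
    df["g_week"] = pd.array([r["g_week"] for r in recs], dtype="Int64")
    return TrialDataset(df, arm_labels=arm_labels)


@pytest.fixture
def tiny_dataset() -> TrialDataset:
    """8 completers spanning both arms, both sexes and two sites."""
    return make_dataset(
        [
            ("a1", "control", "female", 21, "U1", 1.0, 90),
            ("a2", "control", "male", 24, "U2", 2.0, 140),
            ("a3", "control", "female", 28, "U1", 0.5, 60),
            ("a4", "control", "male", 22, "U2", 1.5, 200),
            ("b1", "intervention", "female", 23, "U1", 1.0, 80),
            ("b2", "intervention", "male", 26, "U2", 2.5, 130),
            ("b3", "intervention", "female", 30, "U1", 0.5, 50),
            ("b4", "intervention", "male", 20, "U2", 1.0, 110),
        ]
    )


@pytest.fixture(scope="session")
def small_trial() -> TrialDataset:
    """A small simulated trial with attrition, no contamination."""
    cfg = SimulationConfig(
        n_per_arm=(160, 170),
        attrition=(0.8, 0.6),
        seed=42,
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def toy_design():
    """Intercept + GROUP design with 8 rows, for brute-force oracles."""
    from nbtrial.data import DesignMatrix

    X = np.column_stack([np.ones(8), np.array([0, 0, 0, 0, 1, 1, 1, 1.0])])
    y = np.array([12, 7, 25, 16, 9, 5, 14, 11])
    return DesignMatrix(
        values=X,
        column_map=[("intercept", "-"), ("group", "intervention")],
        outcome=y,
        row_ids=list("abcdefgh"),
    )
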