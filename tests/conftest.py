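import numpy as np
import pandas as pd
import pytest

from flocklearn.datatypes import ChoiceEvent, GroupScan, Individual


@pytest.fixture
def small_roster() -> dict[str, Individual]:
    return {
        "a1": Individual("a1", "adult", "male", roost="R1",
                         tutored_option="red"),
        "a2": Individual("a2", "adult", "female", roost="R1"),
        "j1": Individual("j1", "juvenile", "unknown", roost="R2"),
        "u1": Individual("u1", "unknown", "unknown", roost=None),
    }


@pytest.fixture
def simple_scans() -> list[GroupScan]:
    # A,B together in 3 scans, A alone in 1, B alone in 2
    rows = [("s1", {"A", "B"}), ("s2", {"A", "B"}), ("s3", {"A", "B"}),
            ("s4", {"A"}), ("s5", {"B"}), ("s6", {"B"})]
    return [GroupScan(sid, float(i), "R1", frozenset(p))
            for i, (sid, p) in enumerate(rows)]


@pytest.fixture
def two_choice_events() -> list[ChoiceEvent]:
    return [
        ChoiceEvent("solo", 0.0, "R1", "red", 1),
        ChoiceEvent("solo", 120.0, "R1", "red", 1),
    ]


@pytest.fixture
def uniform_param_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"lambda": [2.0], "phi": [0.3], "gamma": [0.2], "f": [1.0],
         "beta": [0.0]},
        index=["solo"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
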