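import numpy as np
import pandas as pd
import pytest

from seromir import CohortTable, CtMatrix, SimulationConfig


@pytest.fixture
def tiny_ct() -> CtMatrix:
    """3 miRNAs × 2 samples, no flags; columns {20,30,40} and {21,31,41}."""
    ct = pd.DataFrame(
        {"s1": [20.0, 30.0, 40.0], "s2": [21.0, 31.0, 41.0]},
        index=["m1", "m2", "m3"],
    )
    flag = pd.DataFrame(False, index=ct.index, columns=ct.columns)
    return CtMatrix(ct, flag)


@pytest.fixture
def small_cohort() -> CohortTable:
    """One sample per group with plausible scores."""
    table = pd.DataFrame(
        {
            "group": ["ASD", "TS", "TS+ASD", "NC"],
            "IQ": [60.0, 95.0, 90.0, 80.0],
            "YGTSS": [0.0, 18.0, 22.0, 2.0],
            "ADOS_A": [7.0, 0.0, 6.0, 0.0],
            "ADOS_B": [8.0, 0.0, 9.0, 0.0],
            "ADOS_C": [3.0, 0.0, 3.0, 0.0],
            "ADOS_D": [4.0, 2.0, 4.0, 0.0],
        },
        index=pd.Index(["a1", "t1", "x1", "n1"], name="sample"),
    )
    return CohortTable(table)


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Small, flag-free profiling configuration for fast exact checks."""
    return SimulationConfig(
        seed=0,
        n_mirnas_per_panel=60,
        panels=("A",),
        flag_prob=0.0,
    )


def make_cohort(sizes: dict[str, int], rng: np.random.Generator | None = None) -> CohortTable:
    """Minimal cohort with the given group sizes and empty scores."""
    rows = []
    idx = []
    for group, n in sizes.items():
        for i in range(n):
            idx.append(f"{group.replace('+', '')}{i:02d}")
            rows.append({"group": group})
    table = pd.DataFrame(rows, index=pd.Index(idx, name="sample"))
    for col in ("IQ", "YGTSS", "ADOS_A", "ADOS_B", "ADOS_C", "ADOS_D"):
        table[col] = np.nan
    return CohortTable(table)
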