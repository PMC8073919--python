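import dataclasses

import numpy as np
import pandas as pd
import pytest

from bdrprs.phenotypes import CohortTable, PC_COLUMNS
from bdrprs.prs import PrsResult
from bdrprs.simulate import SimulationConfig, resolve_config
from bdrprs.weights import packaged_weight_table


@pytest.fixture(scope="session")
def table16():
    return packaged_weight_table()


@pytest.fixture(scope="session")
def continuous_config(table16):
    """Fully calibrated continuous-mode config (calibrations run once)."""
    return resolve_config(SimulationConfig(n=967, seed=0, weights=table16))


@pytest.fixture(scope="session")
def threshold12_config(table16):
    return resolve_config(
        SimulationConfig(n=967, seed=0, weights=table16, mode="threshold_logistic", threshold=12.0)
    )


@pytest.fixture(scope="session")
def threshold8_config(table16):
    return resolve_config(
        SimulationConfig(n=967, seed=0, weights=table16, mode="threshold_logistic", threshold=8.0)
    )


def reseeded(config: SimulationConfig, seed: int) -> SimulationConfig:
    """New config sharing the calibrated fields but with a fresh seed."""
    return dataclasses.replace(config, seed=seed)


def make_cohort(n: int, rng: np.random.Generator, bdr=None, responder=None,
                sex=None, bmi=None, age=None) -> CohortTable:
    """Small hand-rolled cohort for model unit tests (not the calibrated generator)."""
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "age_years": rng.uniform(6, 14, n) if age is None else age,
            "sex": rng.choice(["male", "female"], n) if sex is None else sex,
            "bmi_category": rng.choice(
                ["normal", "underweight", "overweight", "obese"], n
            )
            if bmi is None
            else bmi,
            "doctor_visits": rng.integers(0, 10, n),
        }
    )
    for c in PC_COLUMNS:
        df[c] = rng.standard_normal(n)
    if bdr is not None:
        df["bdr_percent"] = bdr
    if responder is not None:
        df["responder"] = responder
    return CohortTable(df)


def make_prs(z: np.ndarray) -> PrsResult:
    z = np.asarray(z, dtype=float)
    return PrsResult(
        sample_ids=[f"S{i}" for i in range(z.size)],
        raw_score=z.copy(),
        z_score=(z - z.mean()) / z.std(ddof=1),
        n_variants_used=16,
    )
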