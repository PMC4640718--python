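import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab import CtMatrix, ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def abc_expr() -> ExpressionMatrix:
    """Three genes, three samples: A and B proportional, C constant."""
    values = pd.DataFrame(
        {"s1": [1.0, 1.0, 2.0], "s2": [2.0, 2.0, 2.0], "s3": [4.0, 4.0, 2.0]},
        index=["A", "B", "C"],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def small_ct() -> CtMatrix:
    values = pd.DataFrame(
        {"s1": [20.0, 18.0, 10.0], "s2": [21.0, 18.0, 11.0], "s3": [22.0, 18.0, 12.0]},
        index=["A", "B", "C"],
    )
    groups = pd.Series({"s1": "control", "s2": "control", "s3": "heat"})
    return CtMatrix(values, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150)


def random_lognormal_expr(
    rng: np.random.Generator, n_genes: int = 6, n_samples: int = 8
) -> ExpressionMatrix:
    values = rng.lognormal(mean=3.0, sigma=0.7, size=(n_genes, n_samples))
    frame = pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(frame)
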