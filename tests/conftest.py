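import numpy as np
import pandas as pd
import pytest

from vinepop.table import ColumnSpec, CovariateTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def make_table(data: dict, kinds: dict | None = None, log_scale: set | None = None,
               weight_column: str | None = None) -> CovariateTable:
    """Build a CovariateTable from plain arrays with minimal ceremony."""
    kinds = kinds or {}
    log_scale = log_scale or set()
    df = pd.DataFrame(data)
    cols = []
    for name in data:
        if weight_column and name == weight_column:
            continue
        kind = kinds.get(name, "continuous" if pd.api.types.is_numeric_dtype(df[name]) else "categorical")
        cols.append(ColumnSpec(name=name, kind=kind, log_scale=name in log_scale))
    return CovariateTable(df=df, columns=cols, weight_column=weight_column)


@pytest.fixture
def gaussian_pair(rng):
    """Correlated bivariate normal sample (rho = 0.6), n = 2000."""
    cov = [[1.0, 0.6], [0.6, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=2000)
    return xy[:, 0], xy[:, 1]


@pytest.fixture
def small_fixture_table():
    """Complete synthetic population, 5 covariates, n = 1500."""
    from vinepop.fixtures import default_spec, generate

    spec = default_spec(
        n=1500, seed=7, complete=True, include_race=False,
        covariates=["age", "weight", "height", "scr"],
    )
    return generate(spec)
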