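import numpy as np
import pandas as pd
import pytest

from mipool.data_sim import (
    SimCondition,
    ampute_mar,
    build_default_specs,
    simulate_complete,
)
from mipool.imputation import impute_mice


@pytest.fixture(scope="session")
def default_specs():
    return build_default_specs()


@pytest.fixture(scope="session")
def complete_small():
    """One complete n=300 dataset, shared read-only across tests."""
    cond = SimCondition(n=300, rho=0.2, seed=91)
    return simulate_complete(cond, np.random.default_rng(91))


@pytest.fixture(scope="session")
def imputed_small(complete_small):
    """MAR-amputed and imputed (m=5) version of the small dataset."""
    md = ampute_mar(complete_small, rng=np.random.default_rng(92))
    return impute_mice(md, m=5, iterations=5, rng=np.random.default_rng(93))


@pytest.fixture()
def no_missing_stack(complete_small):
    """m=5 stack of identical copies (mask all false)."""
    from mipool.imputation import ImputedStack

    preds = complete_small.predictors
    return ImputedStack(
        datasets=[preds.copy() for _ in range(5)],
        outcome=complete_small.outcome,
        specs=complete_small.specs,
        m=5,
        iterations=0,
        include_outcome=True,
        mask=pd.DataFrame(False, index=preds.index, columns=preds.columns),
    )
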