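import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endotdm as e

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    params, _ = e.load_parameters()
    return params


@pytest.fixture(scope="session")
def table1():
    return e.table1_distributions()


@pytest.fixture(scope="session")
def life_table():
    return e.default_life_table()


@pytest.fixture(scope="session")
def engine(default_params, life_table):
    return e.TraceEngine(default_params, life_table)


@pytest.fixture(scope="session")
def base_case(default_params, life_table, engine):
    """Both base-case traces and the incremental summary, computed once."""
    no_tdm, tdm = e.build_strategies(default_params)
    trace_no = engine.trace(default_params, no_tdm)
    trace_tdm = engine.trace(default_params, tdm)
    inc = e.compare(e.summarize(trace_tdm), e.summarize(trace_no), wtp=20_000)
    return {"no_tdm": trace_no, "tdm": trace_tdm, "incremental": inc,
            "strategies": (no_tdm, tdm)}


@pytest.fixture(scope="session")
def flat_life_table():
    """Immortal table: qx = 0 at every age."""
    return e.LifeTable(ages=np.arange(0, 111), qx=np.zeros(111))
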