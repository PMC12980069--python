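import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from emocog.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort_small():
    """Small default-config cohort (dropout process active)."""
    return simulate_cohort(SimConfig(n_participants=24, seed=42))


@pytest.fixture(scope="session")
def cohort_clean():
    """Mid-sized planted-effect cohort with the dropout process disabled."""
    return simulate_cohort(SimConfig.recovery(n_participants=120, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def force_miss_run(trials: pd.DataFrame, pid: str, task: str, length: int) -> pd.DataFrame:
    """Overwrite one session's first `length` response-required main trials
    (and any interleaved no-go trials) with misses, to plant a dropout."""
    out = trials.copy()
    sel = (out["participant_id"] == pid) & (out["task"] == task) & (out["block"] > 0)
    idx = out.index[sel]
    required = out.loc[idx, "is_target"].to_numpy(bool)
    hit = np.flatnonzero(required)
    if len(hit) < length:
        raise AssertionError("session too short to plant a miss run")
    stop = idx[hit[length - 1]]
    span = idx[idx <= stop]
    req_span = out.loc[span, "is_target"].to_numpy(bool)
    out.loc[span, "responded"] = False
    out.loc[span, "rt_ms"] = np.nan
    out.loc[span, "timeout"] = req_span
    out.loc[span, "correct"] = ~req_span
    return out
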