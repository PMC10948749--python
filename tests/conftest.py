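import numpy as np
import pytest

import cgmetrics as cg
from cgmetrics import indices as gv
from cgmetrics import io as cio


@pytest.fixture(scope="session")
def default_cfg():
    return cg.default_config(123)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (20+20 subjects, 6 days) plus its windowed index tables."""
    cfg = cg.default_config(42)
    cfg.n_healthy = 20
    cfg.n_prediabetic = 20
    cfg.days = 6
    traces, panel, activity = cg.simulate_cohorts(cfg)
    windowed = [cio.analysis_window(tr, end_day=cfg.days) for tr in traces]
    daily = gv.cohort_daily_table(windowed)
    summary = gv.cohort_summary_table(windowed)
    return {
        "config": cfg,
        "traces": traces,
        "panel": panel,
        "activity": activity,
        "windowed": windowed,
        "daily": daily,
        "summary": summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
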