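"""Shared fixtures: long simulation runs reused across the suite.

The heavy runs (thousands of stochastic cycles) are session-scoped so the
period samples are computed once and shared between the distributional
tests.  Seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

import titrosc as T
from titrosc.cycle_analysis import PeriodSample, detect_periods


@pytest.fixture(scope="session")
def atc() -> T.TitrationParams:
    return T.make_atc(1.0, 1)


@pytest.fixture(scope="session")
def rtc() -> T.TitrationParams:
    return T.make_rtc(1.0, 1)


@pytest.fixture(scope="session")
def cme_periods_nb1(atc) -> PeriodSample:
    """>= 2000 detected cycles of the single-site ATC full CME."""
    traj = T.simulate_cme(atc, t_end=17_000.0, seed=1, max_switch=4_000_000)
    sample = detect_periods(traj)
    assert sample.n >= 2000, "simulation horizon did not yield 2000 cycles"
    return sample


@pytest.fixture(scope="session")
def pdmp_periods(atc) -> PeriodSample:
    """~10^3 detected cycles of the single-site ATC PDMP."""
    traj = T.simulate_pdmp(atc, t_end=8_200.0, seed=2, sample_dt=0.02)
    sample = detect_periods(traj)
    assert sample.n >= 1000
    return sample


@pytest.fixture(scope="session")
def cme_periods_nb3() -> PeriodSample:
    """10^3 cycles of the three-site ATC full CME."""
    traj = T.simulate_cme(T.make_atc(1.0, 3), t_end=9_000.0, seed=4,
                          max_switch=4_000_000)
    sample = detect_periods(traj)
    assert sample.n >= 1000
    return sample


@pytest.fixture(scope="session")
def linear_periods(atc) -> PeriodSample:
    """~2000 cycles of the linearized ATC PDMP."""
    traj = T.simulate_linear_pdmp(atc, t_end=16_000.0, seed=3)
    sample = detect_periods(traj)
    assert sample.n >= 1000
    return sample
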