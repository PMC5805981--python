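"""Stochastic-cycle period detection and coherence statistics.

A stochastic cycle is scored by a hysteresis protocol on an observable
concentration: an upward crossing of a high threshold qualifies as a cycle
mark only after the observable has first dipped below a low threshold, so
promoter-timescale jitter near either threshold cannot register as extra
cycles.  Periods are the gaps between successive marks; coherence is the
coefficient of variation CV = sd/mean (smaller CV = more coherent clock).

The module also carries the closed-form period law of the elementary
two-state promoter cycle with constant rates k+ and k-: the period is the
sum of two independent exponentials, i.e. hypoexponential, with mean
1/k+ + 1/k- and variance 1/k+^2 + 1/k-^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import TitrationParams
from .trajectory import Trajectory

__all__ = [
    "PeriodSample",
    "PeriodProtocol",
    "default_thresholds",
    "detect_periods",
    "period_filter",
    "TwoStateRates",
    "hypoexp_pdf",
    "hypoexp_cdf",
    "hypoexp_moments",
    "hypoexp_sample",
]


@dataclass
class PeriodSample:
    """Detected cycle periods plus summary statistics."""

    periods: np.ndarray
    n_discarded: int = 0
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        if np.any(self.periods <= 0):
            raise ValueError("periods must be positive")

    @property
    def n(self) -> int:
        return len(self.periods)

    @property
    def mean(self) -> float:
        return float(self.periods.mean()) if self.n else math.nan

    @property
    def variance(self) -> float:
        return float(self.periods.var(ddof=1)) if self.n > 1 else math.nan

    @property
    def cv(self) -> float:
        return math.sqrt(self.variance) / self.mean if self.n > 1 else math.nan

    def cv_bootstrap_se(self, n_boot: int = 1000, seed: int = 0) -> float:
        """Bootstrap standard error of the CV estimate."""
        if self.n < 2:
            return math.nan
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, self.n, size=(n_boot, self.n))
        res = self.periods[idx]
        cvs = res.std(axis=1, ddof=1) / res.mean(axis=1)
        return float(cvs.std(ddof=1))

    def summary(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "variance": self.variance,
            "cv": self.cv,
            "n_discarded": self.n_discarded,
            "protocol": self.protocol,
        }


@dataclass(frozen=True)
class PeriodProtocol:
    """Configuration of the cycle-detection protocol.

    mode 'hysteresis' marks upward crossings of ``hi`` armed by prior
    excursions below ``lo``; mode 'promoter' marks completions of the
    s = 0 -> >=1 -> 0 promoter round trip with an intervening titration
    (observable dip below ``lo``).  Thresholds default to fractions of the
    observed gene's saturating level beta_max/delta (hi at 50%, lo at 5%).
    """

    observable: str = "x"
    mode: str = "hysteresis"
    hi: float | None = None
    lo: float | None = None
    min_period: float = 0.0

    def resolved(self, params: TitrationParams | dict | None) -> "PeriodProtocol":
        if self.hi is not None and self.lo is not None:
            return self
        hi, lo = default_thresholds(params, self.observable)
        return replace(self, hi=self.hi if self.hi is not None else hi,
                       lo=self.lo if self.lo is not None else lo)


def default_thresholds(params, observable: str = "x") -> tuple[float, float]:
    """Hysteresis thresholds from the observed gene's largest production rate."""
    if params is None:
        raise ValueError("cannot derive default thresholds without parameters")
    if isinstance(params, TitrationParams):
        d = params.to_dict()
    else:
        d = dict(params)
    g = observable.upper()
    beta_max = max(d[f"beta_f_{g}"], d[f"beta_b_{g}"])
    delta = d[f"delta_{g}"]
    level = beta_max / delta
    return 0.5 * level, 0.05 * level


def detect_periods(
    traj: Trajectory, protocol: PeriodProtocol | None = None
) -> PeriodSample:
    """Detect cycle periods in a trajectory.

    Returns an empty, flagged sample when fewer than two marks are found
    (e.g. adiabatic-regime trajectories with no qualifying cycles).
    """
    protocol = (protocol or PeriodProtocol()).resolved(traj.meta.get("params"))
    v = traj.concentration(protocol.observable)
    t = traj.times
    if protocol.mode == "hysteresis":
        marks = _hysteresis_marks(t, v, protocol.hi, protocol.lo)
    elif protocol.mode == "promoter":
        marks = _promoter_marks(traj, v, protocol.lo)
    else:
        raise ValueError(f"unknown protocol mode {protocol.mode!r}")
    periods = np.diff(marks)
    sample = PeriodSample(
        periods=periods[periods > 0],
        protocol={"mode": protocol.mode, "observable": protocol.observable,
                  "hi": protocol.hi, "lo": protocol.lo,
                  "min_period": protocol.min_period,
                  "n_marks": len(marks)},
    )
    if protocol.min_period > 0:
        sample = period_filter(sample, protocol.min_period)
    return sample


def _hysteresis_marks(t, v, hi, lo) -> np.ndarray:
    marks = []
    armed = bool(v[0] < lo)
    for i in range(1, len(v)):
        if v[i] < lo:
            armed = True
        elif armed and v[i - 1] < hi <= v[i]:
            # linear interpolation of the crossing instant
            f = (hi - v[i - 1]) / (v[i] - v[i - 1])
            marks.append(t[i - 1] + f * (t[i] - t[i - 1]))
            armed = False
    return np.asarray(marks)


def _promoter_marks(traj: Trajectory, v, lo) -> np.ndarray:
    """Completions of the s: 0 -> >=1 -> 0 round trip with a titration dip."""
    params = traj.meta.get("params", {})
    col = "s_X" if params.get("nb_X", 0) > 0 else "s_Y"
    if traj.switches is not None and len(traj.switches):
        st = np.asarray(traj.switches.times)
        sv = np.asarray(getattr(traj.switches, col))
        # prepend the initial occupancy from the trajectory
        st = np.concatenate([[traj.times[0]], st])
        sv = np.concatenate([[traj.columns[col][0]], sv])
    else:
        st = traj.times
        sv = np.asarray(traj.columns[col])
    t = traj.times
    marks = []
    last = t[0]
    for i in range(1, len(sv)):
        if sv[i] == 0 and sv[i - 1] > 0:
            lo_dip = v[(t >= last) & (t <= st[i])].min(initial=np.inf) < lo
            if lo_dip:
                marks.append(float(st[i]))
                last = st[i]
    return np.asarray(marks)


def period_filter(sample: PeriodSample, min_period: float) -> PeriodSample:
    """Drop periods below ``min_period``, recording how many were removed."""
    keep = sample.periods >= min_period
    return PeriodSample(
        periods=sample.periods[keep],
        n_discarded=sample.n_discarded + int((~keep).sum()),
        protocol={**sample.protocol, "min_period": min_period},
    )


# ---------------------------------------------------------------------------
# two-state promoter period law


@dataclass(frozen=True)
class TwoStateRates:
    """Constant switching rates of the elementary two-state promoter cycle."""

    k_plus: float
    k_minus: float

    def __post_init__(self) -> None:
        if self.k_plus <= 0 or self.k_minus <= 0:
            raise ValueError("rates must be positive")


def hypoexp_pdf(tau, r: TwoStateRates):
    """Density of the two-state cycle period (sum of two exponentials).

    For distinct rates: k+ k-/(k- - k+) (e^{-k+ tau} - e^{-k- tau});
    for equal rates k the Erlang-2 limit k^2 tau e^{-k tau}.
    """
    tau = np.asarray(tau, dtype=float)
    kp, km = r.k_plus, r.k_minus
    out = np.zeros_like(tau)
    pos = tau >= 0
    if math.isclose(kp, km, rel_tol=1e-12):
        out[pos] = kp**2 * tau[pos] * np.exp(-kp * tau[pos])
    else:
        c = kp * km / (km - kp)
        out[pos] = c * (np.exp(-kp * tau[pos]) - np.exp(-km * tau[pos]))
    return out if out.ndim else float(out)


def hypoexp_cdf(tau, r: TwoStateRates):
    tau = np.asarray(tau, dtype=float)
    kp, km = r.k_plus, r.k_minus
    out = np.zeros_like(tau)
    pos = tau >= 0
    if math.isclose(kp, km, rel_tol=1e-12):
        out[pos] = 1.0 - (1.0 + kp * tau[pos]) * np.exp(-kp * tau[pos])
    else:
        out[pos] = 1.0 - (km * np.exp(-kp * tau[pos])
                          - kp * np.exp(-km * tau[pos])) / (km - kp)
    return out if out.ndim else float(out)


def hypoexp_moments(r: TwoStateRates) -> tuple[float, float]:
    """Mean 1/k+ + 1/k- and variance 1/k+^2 + 1/k-^2 of the cycle period."""
    return (1.0 / r.k_plus + 1.0 / r.k_minus,
            1.0 / r.k_plus**2 + 1.0 / r.k_minus**2)


def hypoexp_sample(r: TwoStateRates, seed: int = 0, n: int = 1000) -> np.ndarray:
    """Draw periods as sums of two independent exponentials."""
    rng = np.random.default_rng(seed)
    return (rng.exponential(1.0 / r.k_plus, size=n)
            + rng.exponential(1.0 / r.k_minus, size=n))
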