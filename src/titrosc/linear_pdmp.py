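"""Fast-titration linearization of the titration-circuit PDMP.

In the limit where the bimolecular titration reaction is much faster than
every other process, at most one of the two proteins is present at any
time: the state is either ``x > 0, y = 0`` (X_POS regime) or
``x = 0, y > 0`` (Y_POS regime).  Within a regime the surviving species
follows the *linear* ODE ``dw/dt = b - delta w`` whose net production
``b`` is the difference of the two genes' production rates (the minority
species is titrated away instantaneously).  Everything is then analytic:
the flow, the time for the majority species to be titrated to zero (the
deterministic regime switch), and the survival function of the next
promoter-binding event under the inhomogeneous hazard ``kappa x(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .model_core import HybridState, TitrationParams, production_rate
from .trajectory import SwitchRecord, Trajectory

Regime = Literal["X_POS", "Y_POS"]

__all__ = [
    "RegimeState",
    "LinearFlow",
    "net_production",
    "closed_flow",
    "flow_integral",
    "hitting_time_zero",
    "survival_binding",
    "sample_binding_time",
    "simulate_linear_pdmp",
]


@dataclass
class RegimeState:
    """Linearized-PDMP state: which species is positive, and how much of it."""

    regime: Regime = "X_POS"
    w: float = 0.0
    s_X: int = 0
    s_Y: int = 0

    def validate(self, p: TitrationParams) -> None:
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if not (0 <= self.s_X <= p.nb_X) or not (0 <= self.s_Y <= p.nb_Y):
            raise ValueError("promoter occupancy out of [0, nb]")

    @property
    def x(self) -> float:
        return self.w if self.regime == "X_POS" else 0.0

    @property
    def y(self) -> float:
        return self.w if self.regime == "Y_POS" else 0.0


@dataclass(frozen=True)
class LinearFlow:
    """The linear flow dw/dt = b - delta*w started from w(0) = x0."""

    b: float
    delta: float
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.x0 < 0:
            raise ValueError("x0 must be non-negative")


def net_production(s_X: int, s_Y: int, p: TitrationParams, regime: Regime) -> float:
    """Net production rate of the majority species in the fast-titration limit."""
    bx = production_rate(s_X, "X", p)
    by = production_rate(s_Y, "Y", p)
    return bx - by if regime == "X_POS" else by - bx


def closed_flow(f: LinearFlow, t: float) -> float:
    """Exact solution w(t) = b/delta + (x0 - b/delta) exp(-delta t)."""
    fp = f.b / f.delta
    return fp + (f.x0 - fp) * math.exp(-f.delta * t)


def _hit_time(f: LinearFlow) -> float:
    """First t >= 0 with w(t) = 0 (inf if the flow never reaches zero)."""
    if f.x0 == 0.0:
        return 0.0 if f.b <= 0 else math.inf
    if f.b >= 0:
        return math.inf
    return math.log1p(f.delta * f.x0 / (-f.b)) / f.delta


def hitting_time_zero(f: LinearFlow) -> float:
    """Deterministic titration time: when the majority species hits zero.

    For b < 0 the flow decays through zero at
    ``t* = ln(1 + delta x0 / (-b)) / delta``; for b >= 0 it never does
    (returns +inf), except for the degenerate x0 = 0, b = 0 flow pinned
    at zero (returns 0).
    """
    if f.b >= 0:
        return 0.0 if (f.x0 == 0.0 and f.b == 0.0) else math.inf
    return math.log1p(f.delta * f.x0 / (-f.b)) / f.delta


def flow_integral(f: LinearFlow, t: float) -> float:
    """Integral of the flow, clamped at the zero-hitting time.

    I(t) = (b/delta) t + (x0 - b/delta)(1 - exp(-delta t))/delta for
    t <= t*; past t* the species is exhausted, the hazard vanishes and
    the integral stays at I(t*).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    t = min(t, _hit_time(f))
    fp = f.b / f.delta
    return fp * t + (f.x0 - fp) * (-math.expm1(-f.delta * t)) / f.delta


def _integral_sup(f: LinearFlow) -> float:
    """sup_t I(t): finite iff the flow is eventually titrated or decays."""
    if f.b > 0:
        return math.inf
    if f.b == 0.0:
        return f.x0 / f.delta
    return flow_integral(f, _hit_time(f))


def survival_binding(t: float, f: LinearFlow, kappa: float) -> float:
    """Probability that no binding has occurred by time t.

    The binding hazard along the flow is ``kappa * x(t)``, so
    ``S(t) = exp(-kappa * I(t))`` with I the running integral of the flow
    (clamped once the species hits zero, where the hazard vanishes).
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return math.exp(-kappa * flow_integral(f, t))


def sample_binding_time(f: LinearFlow, kappa: float, u: float) -> float:
    """Invert the survival function: smallest t with S(t) = u.

    Returns +inf when ``S(inf) > u`` (the binding may never fire, which
    happens whenever the flow is titrated away or decays before enough
    hazard accumulates).
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly in (0, 1)")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    target = -math.log(u)  # solve kappa * I(t) = target
    if kappa == 0.0 or kappa * _integral_sup(f) <= target:
        return math.inf

    t_hi = _hit_time(f)
    if not math.isfinite(t_hi):
        # grow the bracket geometrically until the hazard integral suffices
        t_hi = 1.0 / f.delta
        while kappa * flow_integral(f, t_hi) < target:
            t_hi *= 2.0
    g = lambda t: kappa * flow_integral(f, t) - target
    if g(0.0) >= 0.0:
        return 0.0
    return float(brentq(g, 0.0, t_hi, xtol=1e-14, rtol=1e-14))


def _segment_flow(state: RegimeState, p: TitrationParams) -> LinearFlow:
    b = net_production(state.s_X, state.s_Y, p, state.regime)
    delta = p.delta_X if state.regime == "X_POS" else p.delta_Y
    return LinearFlow(b=b, delta=delta, x0=state.w)


def simulate_linear_pdmp(
    p: TitrationParams,
    init: RegimeState | None = None,
    t_end: float = 100.0,
    seed: int = 0,
    sample_dt: float = 0.01,
) -> Trajectory:
    """Sample path of the linearized PDMP.

    Each segment competes (i) exponential unbinding of each occupied
    promoter site chain, (ii) a binding event sampled by inverting the
    analytic survival function (only in the X_POS regime, since the
    binding hazard is kappa_Z * x and x = 0 throughout Y_POS), and
    (iii) the deterministic titration switch when the majority species
    hits zero.  Ties (probability zero) resolve deterministic switch >
    unbinding > binding.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    init = init or RegimeState()
    init.validate(p)
    rng = np.random.default_rng(seed)

    state = RegimeState(init.regime, init.w, init.s_X, init.s_Y)
    grid = np.arange(int(np.floor(t_end / sample_dt)) + 1) * sample_dt

    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    sxs: list[int] = []
    sys_: list[int] = []
    ev_t: list[float] = []
    ev_sx: list[int] = []
    ev_sy: list[int] = []
    ev_lab: list[str] = []

    def record(t: float, w: float) -> None:
        times.append(t)
        xs.append(w if state.regime == "X_POS" else 0.0)
        ys.append(w if state.regime == "Y_POS" else 0.0)
        sxs.append(state.s_X)
        sys_.append(state.s_Y)

    record(0.0, state.w)
    gi = 1
    t = 0.0
    n_events = 0

    while t < t_end:
        flow = _segment_flow(state, p)

        candidates: list[tuple[float, int, str]] = []  # (time, priority, label)
        if state.w == 0.0:
            t_det = 0.0 if flow.b < 0 else math.inf
        else:
            t_det = hitting_time_zero(flow)
        if math.isfinite(t_det):
            candidates.append((t_det, 0, "titration_switch"))
        for gene in ("X", "Y"):
            s = state.s_X if gene == "X" else state.s_Y
            theta = p.theta(gene)
            if s > 0 and theta > 0:
                candidates.append(
                    (rng.exponential(1.0 / theta), 1, f"unbind_{gene}"))
            kappa = p.kappa(gene)
            if s < p.nb(gene) and kappa > 0 and state.regime == "X_POS":
                tb = sample_binding_time(flow, kappa, rng.random())
                if math.isfinite(tb):
                    candidates.append((tb, 2, f"bind_{gene}"))

        if not candidates:
            # nothing can ever happen; flow to the horizon
            gi = _fill_grid(grid, gi, t, t_end, flow, record)
            record(t_end, closed_flow(flow, t_end - t))
            t = t_end
            break

        tau, _, label = min(candidates)
        t_next = t + tau
        seg_end = min(t_next, t_end)
        gi = _fill_grid(grid, gi, t, seg_end, flow, record)
        if t_next >= t_end:
            record(t_end, closed_flow(flow, t_end - t))
            t = t_end
            break

        w_new = closed_flow(flow, tau)
        t = t_next
        if label == "titration_switch":
            state.regime = "Y_POS" if state.regime == "X_POS" else "X_POS"
            state.w = 0.0
        else:
            kind, gene = label.split("_")
            ds = 1 if kind == "bind" else -1
            if gene == "X":
                state.s_X += ds
            else:
                state.s_Y += ds
            state.w = max(w_new, 0.0)
        record(t, state.w)
        ev_t.append(t)
        ev_sx.append(state.s_X)
        ev_sy.append(state.s_Y)
        ev_lab.append(label)
        n_events += 1

    meta = {
        "engine": "linear_pdmp",
        "params": p.to_dict(),
        "seed": int(seed),
        "t_end": float(t_end),
        "sample_dt": float(sample_dt),
        "n_events": n_events,
    }
    switches = SwitchRecord(
        times=np.array(ev_t), s_X=np.array(ev_sx, dtype=int),
        s_Y=np.array(ev_sy, dtype=int), labels=ev_lab,
    ) if ev_t else None
    return Trajectory(
        times=np.array(times),
        columns={
            "x": np.array(xs), "y": np.array(ys),
            "s_X": np.array(sxs), "s_Y": np.array(sys_),
        },
        meta=meta,
        switches=switches,
    )


def _fill_grid(grid, gi, t0, t1, flow, record) -> int:
    """Record closed-form samples at grid points inside (t0, t1]."""
    while gi < len(grid) and grid[gi] <= t1 + 1e-12:
        record(float(grid[gi]), max(closed_flow(flow, grid[gi] - t0), 0.0))
        gi += 1
    return gi


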