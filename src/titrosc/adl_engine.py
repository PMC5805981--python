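"""Alternative deterministic limit (ADL) of the linearized PDMP.

Instead of averaging over promoter states (the adiabatic limit), the ADL
replaces every random waiting time by its first moment and always fires
the channel with the smallest mean waiting time — the deterministic
analogue of Gillespie's first-reaction method.  The resulting dynamics are
fully deterministic and, for oscillatory parameters, settle into an
exactly periodic orbit with zero period variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .linear_pdmp import (
    LinearFlow,
    RegimeState,
    _segment_flow,
    closed_flow,
    flow_integral,
    hitting_time_zero,
    survival_binding,
)
from .model_core import TitrationParams
from .trajectory import SwitchRecord, Trajectory

__all__ = ["mean_waiting_times", "mean_binding_time", "simulate_adl", "AdlResult"]


def mean_binding_time(f: LinearFlow, kappa: float) -> float:
    """First moment of the binding time: E[T] = integral of S(t) dt.

    Diverges (returns +inf) whenever S(inf) > 0, i.e. whenever the flow is
    titrated away or decays before the hazard integral can grow without
    bound — the channel then never fires in the mean picture.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0.0 or f.b <= 0:
        # S(inf) = exp(-kappa * sup I) > 0 for b <= 0
        return math.inf
    val, _ = quad(lambda t: survival_binding(t, f, kappa), 0.0, math.inf, limit=200)
    return float(val)


def mean_waiting_times(state: RegimeState, p: TitrationParams) -> dict[str, float]:
    """Mean waiting time of every channel available at ``state``.

    Unbinding is exponential, mean 1/theta_Z; binding has mean equal to
    the integral of its survival function along the current flow; the
    deterministic titration switch has its exact hitting time.
    """
    state.validate(p)
    flow = _segment_flow(state, p)
    out: dict[str, float] = {}
    if state.w == 0.0:
        out["titration_switch"] = 0.0 if flow.b < 0 else math.inf
    else:
        out["titration_switch"] = hitting_time_zero(flow)
    for gene in ("X", "Y"):
        s = state.s_X if gene == "X" else state.s_Y
        theta = p.theta(gene)
        kappa = p.kappa(gene)
        if s > 0:
            out[f"unbind_{gene}"] = 1.0 / theta if theta > 0 else math.inf
        if s < p.nb(gene) and kappa > 0:
            if state.regime == "X_POS":
                out[f"bind_{gene}"] = mean_binding_time(flow, kappa)
            else:
                out[f"bind_{gene}"] = math.inf
    return out


@dataclass
class AdlResult:
    """ADL trajectory together with the detected deterministic period."""

    trajectory: Trajectory
    period: float
    cycle_states: list[tuple]  # discrete states visited around one cycle


_PRIORITY = {"titration_switch": 0, "unbind_X": 1, "unbind_Y": 1,
             "bind_X": 2, "bind_Y": 2}


def simulate_adl(
    p: TitrationParams,
    init: RegimeState | None = None,
    n_cycles: int = 3,
    max_events: int = 10_000,
    sample_dt: float = 0.01,
    w_quantum: float = 1e-9,
) -> AdlResult:
    """Deterministic first-reaction dynamics of the linearized circuit.

    Advances segment by segment, each time firing the channel with the
    minimal mean waiting time.  Periodicity is declared on the first
    revisit of a discrete state (regime, s_X, s_Y, quantized segment
    entry concentration); the simulation then runs ``n_cycles`` full
    cycles for the returned trajectory.
    """
    init = init or RegimeState()
    init.validate(p)
    state = RegimeState(init.regime, init.w, init.s_X, init.s_Y)

    t = 0.0
    seen: dict[tuple, float] = {}
    period = math.inf
    cycle_states: list[tuple] = []
    t_stop = math.inf
    segments: list[tuple[float, float, LinearFlow, RegimeState]] = []
    ev_t: list[float] = []
    ev_lab: list[str] = []
    ev_state: list[RegimeState] = []
    in_cycle = False

    for _ in range(max_events):
        key = (state.regime, state.s_X, state.s_Y,
               round(state.w / w_quantum))
        if key in seen and not in_cycle:
            period = t - seen[key]
            t_stop = t + (n_cycles - 1) * period
            in_cycle = True
        if not in_cycle:
            seen[key] = t
        if in_cycle:
            cycle_states.append((state.regime, state.s_X, state.s_Y))

        waits = mean_waiting_times(state, p)
        finite = {k: v for k, v in waits.items() if math.isfinite(v)}
        if not finite:
            raise RuntimeError(
                "all mean waiting times are infinite: absorbing state "
                f"{state} — parameters are non-oscillatory")
        label = min(finite, key=lambda k: (finite[k], _PRIORITY[k]))
        tau = finite[label]

        flow = _segment_flow(state, p)
        seg_end = t + tau
        segments.append((t, seg_end, flow, RegimeState(
            state.regime, state.w, state.s_X, state.s_Y)))

        t = seg_end
        w_new = max(closed_flow(flow, tau), 0.0)
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
            state.w = w_new
        ev_t.append(t)
        ev_lab.append(label)
        ev_state.append(RegimeState(state.regime, state.w, state.s_X, state.s_Y))
        if t >= t_stop:
            break
    else:
        if not in_cycle:
            raise RuntimeError(
                f"no periodic orbit found within {max_events} events")

    # de-duplicate the cycle state list down to one period
    if cycle_states:
        uniq: list[tuple] = []
        for cs in cycle_states:
            if cs in uniq:
                break
            uniq.append(cs)
        cycle_states = uniq

    traj = _segments_to_trajectory(segments, ev_t, ev_lab, ev_state,
                                   sample_dt, p)
    traj.meta.update({"engine": "adl", "params": p.to_dict(),
                      "period": period, "n_events": len(ev_t)})
    return AdlResult(trajectory=traj, period=period, cycle_states=cycle_states)


def _segments_to_trajectory(segments, ev_t, ev_lab, ev_state, sample_dt, p):
    t_end = segments[-1][1]
    grid = np.arange(int(np.floor(t_end / sample_dt)) + 1) * sample_dt
    times, xs, ys, sxs, sys_ = [], [], [], [], []
    gi = 0
    for (t0, t1, flow, st) in segments:
        while gi < len(grid) and grid[gi] <= t1 + 1e-12:
            tg = float(grid[gi])
            if tg + 1e-12 < t0:
                gi += 1
                continue
            w = max(closed_flow(flow, tg - t0), 0.0)
            times.append(tg)
            xs.append(w if st.regime == "X_POS" else 0.0)
            ys.append(w if st.regime == "Y_POS" else 0.0)
            sxs.append(st.s_X)
            sys_.append(st.s_Y)
            gi += 1
    switches = SwitchRecord(
        times=np.array(ev_t),
        s_X=np.array([s.s_X for s in ev_state], dtype=int),
        s_Y=np.array([s.s_Y for s in ev_state], dtype=int),
        labels=list(ev_lab),
    ) if ev_t else None
    return Trajectory(
        times=np.array(times),
        columns={"x": np.array(xs), "y": np.array(ys),
                 "s_X": np.array(sxs), "s_Y": np.array(sys_)},
        meta={},
        switches=switches,
    )
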