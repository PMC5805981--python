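"""Closed-form flows, survival laws, hitting times, and the linear simulator."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from titrosc.linear_pdmp import (
    LinearFlow,
    RegimeState,
    closed_flow,
    hitting_time_zero,
    net_production,
    sample_binding_time,
    simulate_linear_pdmp,
    survival_binding,
)


def _random_flows(n, seed, allow_negative_b=True):
    rng = np.random.default_rng(seed)
    lo = -6.0 if allow_negative_b else 0.1
    for _ in range(n):
        yield LinearFlow(
            b=float(rng.uniform(lo, 6.0)),
            delta=float(rng.uniform(0.2, 3.0)),
            x0=float(rng.uniform(0.0, 5.0)),
        ), rng


class TestClosedForms:
    def test_known_values(self):
        assert closed_flow(LinearFlow(2, 1, 0), 0.0) == 0.0
        assert closed_flow(LinearFlow(2, 1, 0), 1.0) == pytest.approx(
            2 * (1 - math.exp(-1)), abs=1e-12)
        assert hitting_time_zero(LinearFlow(-8, 1, 2)) == pytest.approx(
            math.log(1.25), abs=1e-12)
        assert hitting_time_zero(LinearFlow(2, 1, 1)) == math.inf
        assert hitting_time_zero(LinearFlow(-8, 1, 0)) == 0.0
        assert survival_binding(0.0, LinearFlow(2, 1, 0), 1.0) == 1.0
        assert survival_binding(5.0, LinearFlow(2, 1, 0), 0.0) == 1.0
        assert survival_binding(1.0, LinearFlow(2, 1, 0), 1.0) == \
            pytest.approx(math.exp(-(2 - 2 * (1 - math.exp(-1)))), abs=1e-12)

    def test_flow_agrees_with_ode_integration(self):
        for f, _ in _random_flows(100, seed=5):
            sol = solve_ivp(lambda t, w: [f.b - f.delta * w[0]], (0, 2.0),
                            [f.x0], rtol=1e-12, atol=1e-14)
            assert closed_flow(f, 2.0) == pytest.approx(
                float(sol.y[0, -1]), abs=1e-8)

    def test_hitting_time_agrees_with_root_finding(self):
        checked = 0
        for f, _ in _random_flows(100, seed=6):
            t_star = hitting_time_zero(f)
            if not math.isfinite(t_star) or t_star == 0.0:
                continue
            t_ref = brentq(lambda t: closed_flow(f, t), 1e-12, t_star * 10)
            assert t_star == pytest.approx(t_ref, abs=1e-8)
            checked += 1
        assert checked > 30

    def test_survival_agrees_with_quadrature(self):
        for f, rng in _random_flows(100, seed=7):
            t_cap = hitting_time_zero(f)
            t = float(rng.uniform(0, min(t_cap, 3.0))) if math.isfinite(
                t_cap) else float(rng.uniform(0, 3.0))
            kappa = float(rng.uniform(0.1, 2.0))
            integral, _ = quad(lambda u: closed_flow(f, u), 0.0, t,
                               epsabs=1e-12, epsrel=1e-12)
            assert survival_binding(t, f, kappa) == pytest.approx(
                math.exp(-kappa * integral), abs=1e-8)

    def test_survival_monotone_nonincreasing(self):
        f = LinearFlow(2, 1, 0.5)
        ts = np.linspace(0, 10, 200)
        s = [survival_binding(t, f, 1.3) for t in ts]
        assert np.all(np.diff(s) <= 1e-15)


class TestNetProduction:
    def test_atc_combinations(self, atc):
        assert net_production(0, 0, atc, "X_POS") == 2.0
        assert net_production(0, 1, atc, "X_POS") == -8.0
        assert net_production(0, 1, atc, "Y_POS") == 8.0

    def test_symmetric_rates_cancel(self):
        from titrosc.model_core import TitrationParams
        p = TitrationParams(beta_f_X=3, beta_b_X=3, beta_f_Y=3, beta_b_Y=3,
                            nb_Y=1)
        assert net_production(0, 0, p, "X_POS") == 0.0
        assert net_production(0, 0, p, "Y_POS") == 0.0


class TestBindingTimeSampler:
    def test_constant_hazard_median(self):
        # b = delta x0 pins the flow at x0: exponential with rate kappa x0
        f = LinearFlow(b=3.0, delta=1.5, x0=2.0)
        kappa = 0.7
        assert sample_binding_time(f, kappa, 0.5) == pytest.approx(
            math.log(2) / (kappa * 2.0), rel=1e-9)

    def test_limits(self):
        f = LinearFlow(2, 1, 0)
        assert sample_binding_time(f, 1.0, 1 - 1e-12) < 1e-5
        # titrated flow accumulates at most kappa*I(t*) hazard
        dead = LinearFlow(-4, 1, 0.5)
        assert sample_binding_time(dead, 0.1, 0.5) == math.inf

    def test_empirical_cdf_matches_survival(self):
        f = LinearFlow(2, 1, 0.8)
        kappa = 1.0
        rng = np.random.default_rng(17)
        samples = np.array([
            sample_binding_time(f, kappa, u) for u in rng.random(10_000)])
        cdf = lambda t: 1.0 - np.vectorize(
            lambda u: survival_binding(u, f, kappa))(t)
        assert stats.kstest(samples, cdf).pvalue > 1e-3

    def test_relative_variance_reduced_for_depleted_start(self):
        """Starting at x0 = 0 the system must wait for x to build up, which
        concentrates the binding time around its mean: the coefficient of
        variation is well below the memoryless value, whereas a high start
        behaves like a plain exponential (CV near 1)."""
        kappa = 1.0
        rng = np.random.default_rng(23)
        us = rng.random(2000)
        t_low = np.array([sample_binding_time(LinearFlow(2, 1, 0.0), kappa, u)
                          for u in us])
        t_high = np.array([sample_binding_time(LinearFlow(2, 1, 5.0), kappa, u)
                           for u in us])
        cv = lambda t: t.std() / t.mean()
        assert cv(t_low) < cv(t_high)
        assert cv(t_low) < 0.8


class TestLinearSimulator:
    def test_deterministic_switch_when_unbinding_disabled(self, atc):
        p = atc.with_overrides(theta_Y0=0.0)
        traj = simulate_linear_pdmp(
            p, init=RegimeState("X_POS", 2.0, 0, 1), t_end=1.0, seed=0)
        assert traj.switches.labels[0] == "titration_switch"
        assert traj.switches.times[0] == pytest.approx(math.log(1.25),
                                                       abs=1e-9)

    def test_regimes_are_mutually_exclusive(self, atc):
        traj = simulate_linear_pdmp(atc, t_end=300.0, seed=9)
        assert np.all((traj.columns["x"] == 0) | (traj.columns["y"] == 0))

    def test_full_cycle_dominates_state_sequence(self, atc):
        """The anticlockwise full cycle (s=0,Y_POS) -> (s=0,X_POS) ->
        (s=1,X_POS) -> (s=1,Y_POS) is the predominant route."""
        traj = simulate_linear_pdmp(atc, t_end=2000.0, seed=13)
        labels = traj.switches.labels
        n_bind = labels.count("bind_Y")
        n_unbind = labels.count("unbind_Y")
        n_switch = labels.count("titration_switch")
        # full cycles use two titration switches per bind; dissociation
        # from the x > 0 branch (the mini-cycle short cut) is the rare route
        assert n_switch > n_bind
        assert n_unbind > 0
        # most dissociations happen in the y > 0 regime (full cycle), i.e.
        # after a titration switch rather than directly after binding
        after_bind = sum(
            1 for i in range(1, len(labels))
            if labels[i] == "unbind_Y" and labels[i - 1] == "bind_Y")
        assert after_bind / max(n_unbind, 1) < 0.5

    def test_underestimates_cycle_length_relative_to_cme(
            self, linear_periods, cme_periods_nb1):
        """The instantaneous-titration approximation shortens cycles: the
        linearized model's periods sit below the full CME's."""
        assert linear_periods.mean < cme_periods_nb1.mean
        # both distributions are unimodal with modes in the same region
        lh, le = np.histogram(linear_periods.periods, bins=30,
                              range=(0, 25), density=True)
        ch, ce = np.histogram(cme_periods_nb1.periods, bins=30,
                              range=(0, 25), density=True)
        assert abs(le[np.argmax(lh)] - ce[np.argmax(ch)]) < 5.0
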