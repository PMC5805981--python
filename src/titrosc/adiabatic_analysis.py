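"""Fast-switching (adiabatic) limit of the titration circuits.

When promoter binding/unbinding is much faster than protein turnover the
promoter occupancy relaxes to its quasi-stationary distribution (QSD) at
the instantaneous TF concentration.  Averaging the two-valued promoter
output over the QSD yields an effective production rate, and the circuit
reduces to planar mass-action ODEs.  The Bendixson criterion then rules
out limit cycles whenever the Jacobian trace keeps one sign on the
positive quadrant — which it does for both idealized circuits, so any
sustained cycling at finite switching rates is genuinely non-adiabatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import Gene, TitrationParams

__all__ = [
    "PromoterQSD",
    "qsd",
    "beta_eff",
    "d_beta_eff_dx",
    "ode_rhs_adiabatic",
    "jacobian_trace",
    "no_limit_cycle_check",
    "converges_to_fixed_point",
]


@dataclass(frozen=True)
class PromoterQSD:
    """Quasi-stationary occupancy distribution over s = 0..nb."""

    probs: np.ndarray
    degenerate: bool = False  # theta = 0 with x > 0: all mass at s = nb

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("QSD entries must be non-negative and sum to 1")


def qsd(x: float, p: TitrationParams, gene: Gene) -> PromoterQSD:
    """QSD of the sequential binding chain at frozen TF concentration x.

    The chain has constant birth rate kappa*x and death rate theta, so
    detailed balance gives pi_s proportional to (kappa x / theta)^s.
    Independent of the adiabaticity factor lambda, which scales kappa and
    theta together.
    """
    if x < 0:
        raise ValueError("x must be non-negative")
    nb = p.nb(gene)
    kappa, theta = p.kappa(gene), p.theta(gene)
    if nb == 0:
        return PromoterQSD(probs=np.array([1.0]))
    if theta == 0.0:
        if kappa * x > 0:
            probs = np.zeros(nb + 1)
            probs[-1] = 1.0
            return PromoterQSD(probs=probs, degenerate=True)
        probs = np.zeros(nb + 1)
        probs[0] = 1.0
        return PromoterQSD(probs=probs)
    r = kappa * x / theta
    w = np.power(r, np.arange(nb + 1))
    return PromoterQSD(probs=w / w.sum())


def beta_eff(x: float, p: TitrationParams, gene: Gene) -> float:
    """Effective production rate: QSD-average of the two promoter outputs."""
    beta_f, beta_b = p.betas(gene)
    pi0 = float(qsd(x, p, gene).probs[0])
    return beta_f * pi0 + beta_b * (1.0 - pi0)


def d_beta_eff_dx(x: float, p: TitrationParams, gene: Gene) -> float:
    """Analytic derivative of the effective production rate w.r.t. x."""
    nb = p.nb(gene)
    kappa, theta = p.kappa(gene), p.theta(gene)
    if nb == 0 or theta == 0.0 or kappa == 0.0:
        return 0.0
    beta_f, beta_b = p.betas(gene)
    r = kappa * x / theta
    s = np.arange(nb + 1)
    S = np.power(r, s).sum()
    dS = (s[1:] * np.power(r, s[1:] - 1)).sum()
    dpi0_dr = -dS / S**2
    return (beta_b - beta_f) * (-dpi0_dr) * kappa / theta


def ode_rhs_adiabatic(x: float, y: float, p: TitrationParams) -> tuple[float, float]:
    """Mass-action ODEs of the adiabatically reduced circuit.

    dx/dt = beta_eff_X(x) - delta_X x - alpha x y
    dy/dt = beta_eff_Y(x) - delta_Y y - alpha x y

    For the ATC the X gene is constitutive so beta_eff_X is constant;
    for the RTC the Y gene is constitutive.  Both promoters are regulated
    by the concentration of X.
    """
    bx = beta_eff(x, p, "X")
    by = beta_eff(x, p, "Y")
    titr = p.alpha * x * y
    return bx - p.delta_X * x - titr, by - p.delta_Y * y - titr


def jacobian_trace(x: float, y: float, p: TitrationParams) -> float:
    """Trace of the Jacobian of the adiabatic ODEs at (x, y).

    tr J = d beta_eff_X/dx - delta_X - delta_Y - alpha (x + y).
    The regulated gene Y's rate enters only the dy/dt equation through x,
    an off-diagonal term, so it does not contribute to the trace.
    """
    return (d_beta_eff_dx(x, p, "X") - p.delta_X - p.delta_Y
            - p.alpha * (x + y))


def no_limit_cycle_check(
    p: TitrationParams,
    grid: int = 200,
    x_max: float | None = None,
    y_max: float | None = None,
) -> tuple[bool, float]:
    """Grid certificate for the Bendixson criterion.

    Returns (no_limit_cycle, worst_trace): True when the Jacobian trace is
    strictly negative at every grid point of [0, x_max] x [0, y_max], in
    which case the planar adiabatic system admits no limit cycle there.
    """
    beta_max = max(p.beta_f_X, p.beta_b_X, p.beta_f_Y, p.beta_b_Y)
    if x_max is None:
        x_max = 3.0 * beta_max / p.delta_X
    if y_max is None:
        y_max = 3.0 * beta_max / p.delta_Y
    worst = -math.inf
    for x in np.linspace(0.0, x_max, grid):
        # the trace is affine-decreasing in y, so only track the max over x rows
        tr = jacobian_trace(float(x), 0.0, p)
        worst = max(worst, tr)
        for y in np.linspace(0.0, y_max, grid):
            tr = jacobian_trace(float(x), float(y), p)
            if tr > worst:
                worst = tr
    return worst < 0.0, worst


def converges_to_fixed_point(
    p: TitrationParams,
    x0: float,
    y0: float,
    t_relax: float = 200.0,
    window: float = 20.0,
    tol: float = 1e-6,
) -> bool:
    """Integrate the adiabatic ODEs and test for convergence.

    Convergence means the trailing-window displacement of the state falls
    below ``tol`` — no sustained oscillation.
    """
    sol = solve_ivp(
        lambda t, z: ode_rhs_adiabatic(z[0], z[1], p),
        (0.0, t_relax + window), [x0, y0],
        t_eval=np.linspace(t_relax, t_relax + window, 50),
        rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    z = sol.y.T
    disp = np.linalg.norm(z - z[-1], axis=1).max()
    return bool(disp < tol)
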