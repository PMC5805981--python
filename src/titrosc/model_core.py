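"""Idealized activator- and repressor-titration circuits (ATC / RTC).

Both circuits couple two genes: gene X produces a transcription factor *X*
and gene Y produces an inhibitor *Y* that irreversibly titrates *X* into an
inactive complex (bimolecular rate ``alpha``).  In the ATC, X activates the
inhibitor gene by binding sequentially to ``nb_Y`` promoter sites; in the
RTC, X represses its own gene through ``nb_X`` sites.  Promoter association
and dissociation rates carry a common adiabaticity factor ``lam`` (lambda):
large ``lam`` is the fast-switching (adiabatic) regime, ``lam ~ 1`` the
non-adiabatic regime where discrete promoter states dominate the dynamics.

This module defines the parameter set, the discrete (copy-number) and hybrid
(concentration) state types, the chemical-master-equation reaction channels,
and the drift field / switching hazards of the piecewise deterministic
Markov process (PDMP) derived from the CME in the large-system-size limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Literal

import yaml

Gene = Literal["X", "Y"]

__all__ = [
    "TitrationParams",
    "DiscreteState",
    "HybridState",
    "ReactionChannel",
    "make_atc",
    "make_rtc",
    "from_preset",
    "production_rate",
    "cme_channels",
    "pdmp_drift",
    "switching_hazards",
]


@dataclass(frozen=True)
class TitrationParams:
    """Rate constants of an idealized titration circuit.

    Rates are mass-action constants in concentration units; the effective
    promoter rates are ``kappa_Z = kappa_Z0 * lam`` and
    ``theta_Z = theta_Z0 * lam`` so that the promoter quasi-stationary
    distribution is invariant under ``lam``.
    """

    Omega: float = 1000.0        # system size (molecules per unit concentration)
    lam: float = 1.0             # adiabaticity scaling of kappa_Z, theta_Z
    nb_X: int = 0                # sequential binding sites on gene X
    nb_Y: int = 1                # sequential binding sites on gene Y
    beta_f_X: float = 2.0        # production of X, promoter free
    beta_b_X: float = 2.0        # production of X, promoter bound
    beta_f_Y: float = 0.0        # production of Y, promoter free
    beta_b_Y: float = 10.0       # production of Y, promoter bound
    delta_X: float = 1.0         # degradation of X
    delta_Y: float = 1.0         # degradation of Y
    kappa_X0: float = 0.0        # base association rate on gene X
    kappa_Y0: float = 1.0        # base association rate on gene Y
    theta_X0: float = 0.0        # base dissociation rate on gene X
    theta_Y0: float = 0.5        # base dissociation rate on gene Y
    alpha: float = 10.0          # bimolecular titration rate X + Y -> complex
    name: str = "custom"

    def __post_init__(self) -> None:
        for f in (
            "Omega", "lam", "beta_f_X", "beta_b_X", "beta_f_Y", "beta_b_Y",
            "delta_X", "delta_Y", "kappa_X0", "kappa_Y0", "theta_X0",
            "theta_Y0", "alpha",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.Omega < 1:
            raise ValueError("Omega must be >= 1")
        if self.nb_X < 0 or self.nb_Y < 0:
            raise ValueError("binding-site counts must be non-negative")

    # effective promoter rates ------------------------------------------------
    @property
    def kappa_X(self) -> float:
        return self.kappa_X0 * self.lam

    @property
    def kappa_Y(self) -> float:
        return self.kappa_Y0 * self.lam

    @property
    def theta_X(self) -> float:
        return self.theta_X0 * self.lam

    @property
    def theta_Y(self) -> float:
        return self.theta_Y0 * self.lam

    def nb(self, gene: Gene) -> int:
        return self.nb_X if gene == "X" else self.nb_Y

    def kappa(self, gene: Gene) -> float:
        return self.kappa_X if gene == "X" else self.kappa_Y

    def theta(self, gene: Gene) -> float:
        return self.theta_X if gene == "X" else self.theta_Y

    def betas(self, gene: Gene) -> tuple[float, float]:
        if gene == "X":
            return self.beta_f_X, self.beta_b_X
        return self.beta_f_Y, self.beta_b_Y

    @property
    def regulated_gene(self) -> Gene | None:
        """The gene carrying binding sites (None if both are constitutive)."""
        if self.nb_X > 0:
            return "X"
        if self.nb_Y > 0:
            return "Y"
        return None

    # serialization -----------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TitrationParams":
        d = dict(d)
        if "lambda" in d:
            d["lam"] = d.pop("lambda")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TitrationParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, **kw) -> "TitrationParams":
        if "lambda" in kw:
            kw["lam"] = kw.pop("lambda")
        return replace(self, **kw)


def make_atc(lam: float, nb: int = 1) -> TitrationParams:
    """Activator-titration circuit at the standard parameter point.

    Gene X is constitutive (beta_X = 2); X activates gene Y
    (beta_f_Y = 0 -> beta_b_Y = 10) through ``nb`` sequential sites with
    kappa_Y = lam and theta_Y = 0.5 lam; alpha = 10, Omega = 10^3.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if nb < 1:
        raise ValueError("ATC preset requires at least one binding site on gene Y")
    return TitrationParams(
        Omega=1000.0, lam=float(lam), nb_X=0, nb_Y=int(nb),
        beta_f_X=2.0, beta_b_X=2.0, beta_f_Y=0.0, beta_b_Y=10.0,
        delta_X=1.0, delta_Y=1.0,
        kappa_X0=0.0, kappa_Y0=1.0, theta_X0=0.0, theta_Y0=0.5,
        alpha=10.0, name="ATC",
    )


def make_rtc(lam: float, nb: int = 1) -> TitrationParams:
    """Repressor-titration circuit: X represses its own gene.

    Gene Y is constitutive (beta_Y = 2); X binds ``nb`` sites on its own
    promoter (beta_f_X = 10 -> beta_b_X = 0) with kappa_X = 0.2 lam,
    theta_X = 0.4 lam.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if nb < 1:
        raise ValueError("RTC preset requires at least one binding site on gene X")
    return TitrationParams(
        Omega=1000.0, lam=float(lam), nb_X=int(nb), nb_Y=0,
        beta_f_X=10.0, beta_b_X=0.0, beta_f_Y=2.0, beta_b_Y=2.0,
        delta_X=1.0, delta_Y=1.0,
        kappa_X0=0.2, kappa_Y0=0.0, theta_X0=0.4, theta_Y0=0.0,
        alpha=10.0, name="RTC",
    )


_PRESETS = {"ATC": make_atc, "RTC": make_rtc}


def from_preset(name: str, lam: float = 1.0, nb: int = 1) -> TitrationParams:
    try:
        return _PRESETS[name.upper()](lam, nb)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")


@dataclass
class DiscreteState:
    """Copy-number state of the full CME: molecule counts + promoter occupancies."""

    N_X: int = 0
    N_Y: int = 0
    s_X: int = 0
    s_Y: int = 0

    def validate(self, p: TitrationParams) -> None:
        if self.N_X < 0 or self.N_Y < 0:
            raise ValueError("copy numbers must be non-negative")
        if not (0 <= self.s_X <= p.nb_X) or not (0 <= self.s_Y <= p.nb_Y):
            raise ValueError("promoter occupancy out of [0, nb]")


@dataclass
class HybridState:
    """PDMP state: real concentrations + discrete promoter occupancies."""

    x: float = 0.0
    y: float = 0.0
    s_X: int = 0
    s_Y: int = 0

    def validate(self, p: TitrationParams) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("concentrations must be non-negative")
        if not (0 <= self.s_X <= p.nb_X) or not (0 <= self.s_Y <= p.nb_Y):
            raise ValueError("promoter occupancy out of [0, nb]")


@dataclass(frozen=True)
class ReactionChannel:
    """One CME reaction: label, propensity at the queried state, state increment."""

    label: str
    rate: float
    effect: tuple[int, int, int, int]  # (dN_X, dN_Y, ds_X, ds_Y)


def production_rate(s: int, gene: Gene, p: TitrationParams) -> float:
    """Production rate of ``gene`` given its promoter occupancy ``s``.

    The promoter output is two-valued: beta_f when no activator/repressor is
    bound (s = 0) and beta_b as soon as any site is occupied (s >= 1).
    """
    nb = p.nb(gene)
    if not 0 <= s <= max(nb, 0):
        raise ValueError(f"occupancy s={s} out of range [0, {nb}] for gene {gene}")
    beta_f, beta_b = p.betas(gene)
    return beta_f if s == 0 else beta_b


def cme_channels(st: DiscreteState, p: TitrationParams) -> list[ReactionChannel]:
    """Reaction channels and propensities of the full CME at ``st``.

    Propensities follow mass-action system-size scaling by reaction order:
    zeroth order Omega*rate, first order rate*N, second order rate*N*N'/Omega.
    Promoter binding sequesters one free X molecule; unbinding returns it.
    Channels that would leave the state space are simply absent.
    """
    st.validate(p)
    O = p.Omega
    ch: list[ReactionChannel] = [
        ReactionChannel("prod_X", O * production_rate(st.s_X, "X", p), (1, 0, 0, 0)),
        ReactionChannel("prod_Y", O * production_rate(st.s_Y, "Y", p), (0, 1, 0, 0)),
        ReactionChannel("deg_X", p.delta_X * st.N_X, (-1, 0, 0, 0)),
        ReactionChannel("deg_Y", p.delta_Y * st.N_Y, (0, -1, 0, 0)),
        ReactionChannel("titration", p.alpha * st.N_X * st.N_Y / O, (-1, -1, 0, 0)),
    ]
    if st.s_X < p.nb_X:
        ch.append(ReactionChannel("bind_X", p.kappa_X * st.N_X / O, (-1, 0, 1, 0)))
    if st.s_X > 0:
        ch.append(ReactionChannel("unbind_X", p.theta_X, (1, 0, -1, 0)))
    if st.s_Y < p.nb_Y:
        ch.append(ReactionChannel("bind_Y", p.kappa_Y * st.N_X / O, (-1, 0, 0, 1)))
    if st.s_Y > 0:
        ch.append(ReactionChannel("unbind_Y", p.theta_Y, (1, 0, 0, -1)))
    return ch


def pdmp_drift(st: HybridState, p: TitrationParams) -> tuple[float, float]:
    """Deterministic flow of the PDMP at fixed promoter state.

    dx/dt = beta_X(s_X) - delta_X x - alpha x y
    dy/dt = beta_Y(s_Y) - delta_Y y - alpha x y

    Promoter-sequestration fluxes are O(1/Omega) in concentration and drop
    out of the lowest-order (thermodynamic-limit) flow.
    """
    bx = production_rate(st.s_X, "X", p)
    by = production_rate(st.s_Y, "Y", p)
    titr = p.alpha * st.x * st.y
    return bx - p.delta_X * st.x - titr, by - p.delta_Y * st.y - titr


def switching_hazards(
    st: HybridState, p: TitrationParams
) -> list[tuple[str, float, tuple[int, int]]]:
    """Promoter switching hazards at the hybrid state.

    Returns ``(label, rate, (ds_X, ds_Y))`` triples: sequential binding at
    kappa_Z * x while s_Z < nb_Z, sequential unbinding at theta_Z while
    s_Z > 0.
    """
    out: list[tuple[str, float, tuple[int, int]]] = []
    if st.s_X < p.nb_X:
        out.append(("bind_X", p.kappa_X * st.x, (1, 0)))
    if st.s_X > 0:
        out.append(("unbind_X", p.theta_X, (-1, 0)))
    if st.s_Y < p.nb_Y:
        out.append(("bind_Y", p.kappa_Y * st.x, (0, 1)))
    if st.s_Y > 0:
        out.append(("unbind_Y", p.theta_Y, (0, -1)))
    return out
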