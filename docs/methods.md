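# Methods

## Models

Two idealized two-gene circuits are built in. Gene X produces a
transcription factor *X*; gene Y produces an inhibitor *Y* that titrates
*X* irreversibly into an inactive complex at bimolecular rate α. In the
**activator-titration circuit (ATC)** X is constitutive (β_X = 2) and
activates gene Y (β_Y: 0 → 10 once any site is bound) through `nb_Y`
sequential binding sites with association rate κ_Y = λ and dissociation
rate θ_Y = 0.5 λ. In the **repressor-titration circuit (RTC)** Y is
constitutive (β_Y = 2) and X represses its own gene (β_X: 10 → 0) with
κ_X = 0.2 λ, θ_X = 0.4 λ. Degradation is first order (δ = 1), the system
size is Ω = 10³, and all times are dimensionless model units. The factor
λ multiplies exactly the promoter rates κ_Z and θ_Z, so the promoter's
quasi-stationary distribution is λ-invariant while the switching
*timescale* moves from non-adiabatic (λ = 1) to adiabatic (λ = 10³).

Promoter output is two-valued: β^f when no regulator is bound, β^b as
soon as one is. Binding is sequential for the idealized circuits, so the
site rates carry no combinatorial multiplicities (the KB model's
distributive binding does, see below).

## Simulation engines

**CME (exact).** The discrete-state master equation is sampled with the
Gillespie direct method. Propensities use standard mass-action
system-size scaling by reaction order (zeroth: Ωβ; first: rate·N;
second: rate·N·N′/Ω). Promoter binding sequesters one free X molecule
and unbinding returns it — mass conserving, and an O(1/Ω) effect on
concentrations. The inner loop is a numba kernel because the standard
parameter point generates ~10⁵ reaction events per stochastic cycle;
snapshots are stored on a uniform grid while promoter switch times are
kept exactly. A `freeze_proteins` mode holds the TF pool fixed, turning
the promoter into a constant-rate birth–death chain — the setting in
which the occupancy and period theory below is exact.

**PDMP (hybrid).** In the thermodynamic limit the CME becomes a
piecewise deterministic Markov process: concentrations follow
dx/dt = β_X(s_X) − δ_X x − αxy (and symmetrically for y) at fixed
promoter state, while s_Z jumps with hazards κ_Z x (binding, while
s_Z < nb_Z) and θ_Z (unbinding, while s_Z > 0). Promoter-sequestration
fluxes are O(1/Ω) in concentration and are dropped, consistent with the
lowest-order expansion. Event times are sampled exactly for
time-inhomogeneous hazards by integrated-hazard inversion: the ODE state
is augmented with dΛ/dt = Σ hazards and the event fires at the first
root of Λ(t) = −ln u, located on the integrator's dense output (LSODA,
rtol 1e−8, atol 1e−10; root tolerance ~1e−12). The firing channel is
chosen proportionally to the hazards *at the located event time*.
Integrator undershoot below zero concentration is clipped within
100·tol; larger negatives raise. The same loop drives the extended
models.

**Linearized PDMP.** In the fast-titration limit at most one species is
nonzero, giving two regimes (x > 0, y = 0 or x = 0, y > 0). The
surviving species obeys dw/dt = b − δw with b the *difference* of the
two genes' production rates, solved in closed form. The binding
survival function is S(t) = exp(−κ∫₀ᵗ x dt′) with the integral clamped
once the flow hits zero (the hazard vanishes there); binding times are
drawn by monotone bracketed root finding on S(t) = u (brentq,
xtol 1e−14). Regime switches occur deterministically when the majority
species is titrated to zero; simultaneous events (probability zero)
resolve in the order deterministic switch > unbinding > binding.

**ADL.** The alternative deterministic limit replaces each waiting time
by its first moment — exponential unbinding by 1/θ, binding by
∫₀^∞ S dt (adaptive quadrature; divergent integrals disable the
channel) — and always fires the minimal-mean channel, a deterministic
first-reaction scheme. Periodicity is declared on the first revisit of a
discrete state with the entry concentration quantized at 1e−9; if every
mean is infinite the state is absorbing and the run errors out as
non-oscillatory.

**Adiabatic theory.** At frozen x the sequential chain has QSD
π_s ∝ (κx/θ)^s (detailed balance; θ = 0 with x > 0 returns the
degenerate all-bound distribution explicitly). The effective rate
β^eff = β^f π₀ + β^b(1 − π₀) closes planar mass-action ODEs whose
Jacobian trace is dβ^eff_X/dx − δ_X − δ_Y − α(x + y). The Bendixson
check is a grid certificate (default 200×200 over [0, 3β_max/δ]²), not
a symbolic proof; the derivative of β^eff is analytic with a finite
difference cross-check in the tests.

## Cycle detection and coherence

The default protocol scores cycles by hysteresis on the observable x:
an upward crossing of x_hi counts only after a prior excursion below
x_lo, which rejects promoter-timescale jitter while capturing the
alternating high-amplitude phases. Thresholds default to 50% and 5% of
the *observed gene's* saturating level β_max/δ, where β_max is the
larger of that gene's two production rates (ATC: x_hi = 1, x_lo = 0.1;
RTC: x_hi = 5, x_lo = 0.5). Taking β_max over all genes instead would
put the ATC's high threshold at 5, above the reachable range of x
(which saturates at β_X/δ_X = 2), so no cycle could ever be scored;
normalizing by the observed gene is the choice that makes the protocol
well-posed for both circuits. An alternative promoter protocol (time
between completions of the s: 0 → ≥1 → 0 round trip with an intervening
titration dip) is available via configuration, as is a minimum-period
filter. Crossing times are interpolated linearly on the sampling grid.

Coherence is CV = sd/mean of the detected periods (unbiased variance),
with a bootstrap standard error available. The elementary two-state
promoter with constant rates k₊, k₋ has hypoexponential periods with
density k₊k₋/(k₋−k₊)(e^{−k₊τ} − e^{−k₋τ}) (Erlang-2 at equal rates),
mean 1/k₊ + 1/k₋ and variance 1/k₊² + 1/k₋².

## Extended models

The KB and VKBL architectures are implemented structurally; their rate
values are not printed here and must be supplied through the YAML
templates in `titrosc/templates/` (loading validates completeness). KB:
explicit mRNA, activator homodimerization, distributive binding of the
dimer with hazard multiplicities (G_max − G) and G, reversible
heterodimerization; bound dimers are sequestered from the free pool at
events (±1/V). Its reduced PDMP keeps stochastic unbinding but fires
binding deterministically at the first moment of its waiting-time
distribution, computed on the fly by integrating the survival function
along the flow until it falls below 1e−9 (a never-decaying survival
disables the channel). `rescale_mrna` multiplies both mRNA degradation
rates and both translation rates by ϖ, preserving the steady-state
protein synthesis flux while shortening the mRNA relaxation time to
1/(ϖδ_m). VKBL: the activator activates itself and the inhibitor
through two binary promoters; the complex C sequesters A and recycles R
when the complexed A degrades. An ADL variant of the VKBL model is not
provided — the deterministic-limit machinery is specific to the
linearized one-species flows.

## Problem sizes and numerical choices

Distributional tests use ≥2000 CME cycles (horizon 17 000 time units)
for the coherence measurement and 10³ cycles per engine for two-sample
comparisons; the two-state period law uses 10⁴ cycles; closed-form
oracles use 100 random parameter draws at 1e−8 agreement and 10⁴
inverse-transform samples for KS checks. Monte-Carlo assertions are set
at three standard errors of the relevant time-average or sample moment.
Stochastic tests fix their seeds.

## What the built-in conditions do and do not show

The built-in parameter point is the standard table of the idealized
circuits; passing tests show that the four engines agree with each
other and with the closed-form theory *at that point and in the stated
limits* (Ω = 10³, fast titration, frozen-TF promoters). They do not
validate the PDMP at small system size (the expansion is lowest order
in 1/Ω), finite-rate titration corrections inside the linearized model,
or any quantitative claim about the KB/VKBL models, whose published
rate constants are deliberately not shipped. The measured CV of the
idealized ATC depends mildly on the detection protocol; the hysteresis
defaults above are part of the reported number's definition.

## Known limitations

- Tau-leaping or other approximate CME accelerations are out of scope.
- Promoter copy number is 1; binding is sequential for the idealized
  circuits (non-sequential only in the KB model).
- The Bendixson certificate is a finite grid check with configurable
  bounds, not a proof over the whole quadrant.
- CME determinism is bit-exact for a fixed numba version; across numba
  versions the stream is reproducible but not guaranteed identical.
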