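# Methods

`hetpop` models an isogenic *E. coli* population in which every cell carries
the lac operon induction circuit, and asks how the population-average LacY
(lac permease) expression depends on the extracellular inducer (IPTG)
concentration when cell-to-cell heterogeneity is taken into account.  This
note records the models, the numerical choices, and the limits of what the
test suite demonstrates.

## Single-cell model hierarchy

**Full mass-action model.**  Five concentrations (LacY `Y`, the transport
intermediate `YIex`, intracellular IPTG `I`, free repressor `R`, free
operator `O0`) obey mass-action kinetics for operator–repressor binding
(association constant K_op = 16 nM⁻¹), IPTG–repressor sequestration
(K_I = 10⁻¹⁰ nM⁻²), passive membrane transport (rate k_t, both directions),
LacY-facilitated Michaelis–Menten uptake (half-saturation
K_p ≈ 4.55 × 10⁵ nM), transcription proportional to free operator, and
first-order degradation (λ_Y = λ_I = 0.0025 min⁻¹).  The intracellular IPTG
balance carries the efflux term −k_t[I]; transport is a reversible reaction
and without efflux the model contradicts its own reported steady states
(≈ 15.5 nM uninduced, ≈ 400 nM induced).  Because the single operator site
can release its bound repressor, free `R` may transiently exceed the
repressor pool R_T by at most one operator equivalent; the steady-state
helpers clip integrator overshoot to the invariant box.

**Reduced model.**  Treating both binding equilibria as fast collapses the
dynamics to (`Y`, `I`) with a Hill-type production term in [I]².  Reduced
and full steady states agree within 5 % across the induction range.

**Dimensionless one-variable model.**  With content x and time τ scales the
LacY dynamics become dx/dτ = R(x) = (πρ + x²)/(ρ + x²) − κx, with leakiness
π = 0.03, degradation κ = 0.05, and repression strength ρ, which decreases
with extracellular IPTG as ρ = (1 + K_op R_T)/(K_I Î²).

**Intrinsic noise (chemical Langevin closure).**  Slow operator fluctuations
(rate parameter K) and finite molecule numbers (reference count y*) enter
through closed-form drift A(x) and diffusion B(x) terms; K, y* → ∞ recovers
the deterministic rate exactly.  Paths use Euler–Maruyama in the Itô
interpretation (default step 10⁻³ τ) with reflection at x = 0, which keeps
contents non-negative without biasing the interior (B(0) = π/y* > 0 makes
negative excursions possible at any step size).  The closure is not meant
for very small molecule numbers (y* < 20), where large-deviation effects
dominate; the package does not implement rare-event corrections.

**Gillespie SSA.**  The elementary reactions are simulated exactly with the
direct method, converting concentrations to molecule counts via the cell
volume (1 nM ≈ 0.482 molecules).  The SSA's ensemble mean tracks the
reduced deterministic model through the slow induction transient and
reaches the uninduced steady level; it is the exact stochastic reference
for the single-cell description.

## Calibration and scales

Two constants are not tabulated and are fixed once:

* **R_T** from the leakiness relation π = 1/(1 + K_op R_T): R_T ≈ 2.02 nM,
  about one repressor molecule per cell, matching the operator content.
* **k_t** calibrated so that 28.8 μM extracellular IPTG maps to ρ = 0.09
  (the parameter pairing quoted for the stability analysis), giving
  k_t ≈ 0.782 min⁻¹ and λ_Y/(λ_Y + k_t) ≈ 3.2 × 10⁻³, inside the stated
  order-of-magnitude band.  All downstream IPTG axes inherit this choice.

The printed content/time scale definitions are not internally consistent;
the package adopts the pair that reproduces every published number:
ŷ = k_Y O_T/λ_Y = 416 nM converts population-level dimensionless content
(x of order one, ⟨Y⟩ = ŷ·⟨x⟩), while single-cell dimensionless trajectories
(fixed point near 1/κ) convert with ŷκ = 20.8 nM.  Time converts with
t̂ = κ/λ_Y = 20 min per τ, i.e. one dimensionless time unit is one
generation.

One consequence of the scale ambiguity cannot be papered over: under the
population-calibrated ρ↔IPTG mapping the one-variable model has no
uninduced fixed point at 15 μM (its own single-cell bistable window sits at
far larger ρ because it lacks the division-dilution term), so a
quantitative SSA-versus-Langevin trajectory overlay at both 15 and 45 μM
does not exist under any single content scale.  The tests therefore pin
each description to what it does reproduce: the dimensional ODE/SSA to the
15.5 nM uninduced level and the transient, and the dimensionless Langevin
to the 400 nM induced level and its exact deterministic limit.  A further
caution verified numerically: for small reference molecule numbers
(y* ≲ 20) the Langevin closure inflates transient means through the
E[x²] contribution to the positive feedback.

## Population models

**Homogeneous model.**  d⟨x⟩/dτ = R(⟨x⟩) − ⟨x⟩, the reaction rate minus
dilution by division at unit specific rate.  Its folds admit a closed form
(a quadratic in x after eliminating ρ), yielding the bistable interval
ρ ∈ [0.1022, 0.2415] ↔ IPTG ∈ [17.2, 26.9] μM at the default parameters.

**Deterministic cell population balance (DCPB).**  The number density
n(x, t) evolves under growth advection ∂(R n)/∂x, division at rate
Γ(x) = (x/⟨x⟩)^m, binary partitioning into fractions f and 1 − f, and
dilution.  Two standard regularizations are applied: the two-point
partitioning kernel is used in its normalized form
P(x, x′) = ½δ(x − f x′) + ½δ(x − (1 − f)x′) (the printed prefactors do not
integrate to one over daughter content), and the loss term is the
normalization-preserving dilution n·∫Γn dx; discretely the dilution
coefficient is taken from the number balance ∫(birth − Γn) dx, which makes
∫n dx exactly invariant under the semi-discrete flow up to boundary
outflow.

Discretization: node-centered finite volumes with first-order upwinding on
a grid graded toward x = 0 (nodes ∝ u³, default 500 nodes on [0, 4]);
trapezoidal quadrature coincides exactly with the cell-volume measure.  The
grading matters because the uninduced branch concentrates near x ≈ 0.03
while the induced branch sits near x ≈ 1.  Steady states are solved by
damped Newton (finite-difference Jacobian, line search, one equation
replaced by the normalization constraint), globalized when necessary by a
few implicit-Euler pseudo-time steps.  Branches in ρ are traced by pseudo
arc-length continuation in log ρ with the density scaled into the arc
metric; halving the grid spacing moves steady means by < 0.5 %, and the
m = 3 folds land within ~1 % of the published interval.

**Constant-number Monte Carlo (CNMC).**  Exactly N cells are simulated.
Between divisions every content follows the Langevin SDE; the waiting time
to the next division comes from the population hazard ΣΓ(x_i) accumulated
trapezoidally along the SDE path with an Exp(1) threshold and the crossing
times resolved inside the step by interpolation; the divider is drawn
proportionally to its rate at the (content-interpolated) division time;
daughters f·x and (1 − f)·x are assigned by a fair coin (the pair summing
to the mother content exactly in floating point), one replacing the
mother, the other a uniformly chosen *other* cell.  ⟨x⟩ in Γ is the
instantaneous population mean of the same copy.  The production loop is a
single compiled kernel (numba): one Euler–Maruyama proposal is drawn per
step window, divisions within the window modify only the divided slots
(daughters held to the window end — first-order consistent, the same order
as the Euler scheme), and the hazard is updated incrementally through the
running moments Σx and Σx^m, so a division costs O(N) for divider
selection only.  The step-level operations are also exposed individually
and a statistical cross-check ties the fused kernel to them.  One root
seed deterministically derives per-copy streams; runs are bitwise
reproducible.

## Equation-free coarse analysis

The macroscopic variable is the inverse CDF of content, expanded in four
orthogonal polynomials of p̃ = ½ − arcsin(1 − 2p)/π evaluated at
p_i = (i − ½)/N (the degree-1 normalizer 4.5953 equals
(¼ − 2/π²)^{-1/2}; degrees above three are generated by numerical
orthonormalization).  Restriction sorts a population and projects by least
squares against the point-set Gram matrix; lifting evaluates the truncated
ICDF, clips negatives (the clipped fraction is logged and should stay
below 1 %), and sorts.  Lift-then-restrict is the identity to 10⁻⁶ for
representable states, and a lifted population re-acquires its higher-order
coefficients within Δτ ≈ 0.1 (the healing time), so a coarse horizon of
T = 0.5 τ (configurable) is comfortably past the transient.

On the coarse map G_T the package provides Newton–Raphson with
forward-difference Jacobians (perturbation 10⁻² relative, common random
numbers on by default), eigenvalue stability (discrete-map criterion
|λ| < 1), and pseudo arc-length continuation with Keller null-space
tangents, noise-floor-adaptive corrector tolerances, a trust-region guard,
and a long-horizon (4T) residual validation that rejects slow "ghost"
states behind folds (fixed points are invariant under the horizon; ghost
drift grows linearly with it).  With a deterministic per-cell surrogate the
coarse Newton and continuation reproduce the homogeneous model's roots and
folds to better than 10⁻³, which isolates the coarse numerics from
simulator noise.

**Fold location at reduced ensemble sizes.**  Stochastic tolerances are
tied to the measured ensemble noise floor (two standard errors of the
averaged coefficients).  At the scale used for the bistability studies here
(N = 2000 cells, 10 copies, versus 10 000/50 in the published study) the
floor, amplified through the near-singular coarse Jacobian at a fold,
exceeds the branch curvature signal, and corrector-based fold rounding
becomes unreliable.  The bistability limits are therefore located by a
branch-survival method: a copy ensemble is relaxed onto the branch and
advanced directly at each probed ρ (the coarse mean is the readout; the
populations are *not* re-lifted between probes, because at small N the
four-mode ICDF truncation clips the content tail that drives escape and
biases the limits outward by about 1 μM — verified empirically).  Beyond
the fold the ensemble escapes to the coexisting attractor, detected either
by leaving the branch band or by a sustained drift of the mean over the
final reports (the slow ghost transit); the limit is bracketed by
bisection in log ρ to a width of 0.02 (≈ 0.3–0.7 μM).  This measures the
same turning point the continuation would (where the branch ceases to
exist) with noise entering only through the escape decision, not through
residual inversion.  Arc-length continuation over the coarse map remains
available and exact in the deterministic limit.  Stability of the
intermediate (separatrix) state at reduced scale is likewise measured
robustly: the dominant unstable multiplier from the geometric growth of
the coarse drift along an escape from the bisected separatrix, the
contracting subdominant directions from the local Jacobian.

## Problem sizes and what the tests show

The suite runs the population studies at reduced scale: fold windows at
N = 2000 cells and 10 copies, cross-model checks at N ≈ 2000, the coarse
stability trio at N = 1000, the noise-induced switching run at N = 400
(switching is a rare event whose waiting time grows roughly exponentially
with N; at N = 400 it occurs within a few hundred generations, checked for
occurrence only).  SSA/Langevin comparisons use a 2–3 hour (simulated)
induction window rather than full relaxation.  Synthetic fixture
populations (constant, lognormal, bimodal) exercise the restriction and
lifting machinery; they emulate content dispersion only, not real
single-cell measurement artifacts (measurement noise, size structure, cell
cycle correlations), so passing tests demonstrate internal consistency of
the model stack and agreement with the published bifurcation structure, not
agreement with experimental lac operon data.

## Known limitations

* First-order upwinding adds numerical diffusion; fold locations converge
  ~1 % accurate at the default grid rather than to machine precision.
* The Langevin closure is untrusted for y* < 20 (no rare-event machinery).
* The coarse description truncates the ICDF at four modes; strongly bimodal
  transients are represented only through their monotone envelope.
* Finite-N bistability limits are slightly scale-dependent; at N = 2000 the
  measured limits sit within about 1 μM of the large-ensemble values.
* The CNMC kernel and the op-level API use different RNG stream layouts;
  they agree statistically, not bitwise (each is individually
  reproducible).
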