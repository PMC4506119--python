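"""Equation-free coarse analysis of the stochastic population model.

The macroscopic variable is the inverse CDF (ICDF) of the intracellular
content, expanded in a few orthogonal polynomials of the transformed
quantile variable ptilde = 1/2 - arcsin(1 - 2p)/pi.  Restriction projects a
sorted microscopic population onto the basis; lifting evaluates the
truncated ICDF back into N cell contents.  Wrapping the CNMC simulator
between lift and restrict defines the coarse time-stepper G_T, on which
Newton-Raphson (coarse steady states), eigenvalue stability and pseudo
arc-length continuation are performed with forward-difference Jacobians and
common random numbers for variance reduction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from . import _kernels
from ._continuation import trace_branch
from .cnmc import DivisionModel, PopulationState, copy_seeds
from .dcpb import BranchDiagram, BranchPoint, NumberDensity
from .single_cell import DimensionlessParams, KineticConstants, rho_to_iex

__all__ = [
    "BasisSet",
    "CoarseState",
    "CoarseMapConfig",
    "MicroStepper",
    "CNMCStepper",
    "ODESurrogateStepper",
    "CoarseMap",
    "build_basis",
    "restrict",
    "restrict_single",
    "lift",
    "lift_values",
    "density_to_coarse",
    "coarse_timestep",
    "coarse_residual",
    "fd_jacobian",
    "coarse_newton",
    "coarse_stability",
    "arclength_continuation",
    "healing_test",
    "HealingReport",
]

logger = logging.getLogger("hetpop.equation_free")

# Printed orthonormal basis coefficients on ptilde, degrees 0..3
_PRINTED_BASIS = (
    (1.0,),
    (-2.2977, 4.5953),
    (3.9171, -19.3299, 19.3299),
    (-5.8023, 51.3112, -119.1200, 79.4133),
)


@dataclass(frozen=True)
class BasisSet:
    """Orthogonal ICDF basis evaluated on the quantile point set."""

    N: int
    q: int
    p: np.ndarray
    ptilde: np.ndarray
    phi: np.ndarray            # (q+1, N)
    gram: np.ndarray           # (q+1, q+1), (1/N) Phi Phi^T

    @property
    def n_modes(self) -> int:
        return self.q + 1


@dataclass(frozen=True)
class CoarseState:
    """ICDF expansion coefficients alpha_0..alpha_q."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 1:
            raise ValueError("alpha must be one-dimensional")
        object.__setattr__(self, "alpha", a)

    @property
    def mean_content(self) -> float:
        """Population mean content; equals alpha_0 for an orthonormal basis."""
        return float(self.alpha[0])


@dataclass(frozen=True)
class CoarseMapConfig:
    """Configuration of the coarse time-stepper and coarse Newton."""

    T: float = 0.5
    copies: int = 10
    N: int = 2000
    dt: float = 1e-3
    fd_eps: float = 1e-2
    newton_tol: float = 1e-4
    max_iters: int = 12
    common_random_numbers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("horizon T must be positive")
        if not self.fd_eps > 0:
            raise ValueError("fd_eps must be positive")
        if self.copies < 1:
            raise ValueError("copies must be at least 1")


def build_basis(N: int, q: int = 3, orthonormalize: bool = False) -> BasisSet:
    """Evaluate the ICDF basis functions on p_i = (i - 0.5)/N.

    Degrees up to 3 use the printed polynomial coefficients in ptilde.
    Higher degrees require ``orthonormalize=True``, which orthonormalizes
    the monomials 1, ptilde, ptilde^2, ... against the point-set inner
    product (1/N) sum_i.
    """
    if N < 10:
        raise ValueError("N must be at least 10")
    if q < 0:
        raise ValueError("q must be non-negative")
    if q > 3 and not orthonormalize:
        raise ValueError(
            "printed basis coefficients stop at degree 3; pass "
            "orthonormalize=True for higher degrees"
        )
    p = (np.arange(1, N + 1) - 0.5) / N
    pt = 0.5 - np.arcsin(1.0 - 2.0 * p) / math.pi
    if orthonormalize:
        phi = np.empty((q + 1, N))
        for j in range(q + 1):
            v = pt**j
            for k in range(j):
                v = v - (phi[k] @ v / N) * phi[k]
            phi[j] = v / math.sqrt(v @ v / N)
    else:
        phi = np.array([np.polynomial.polynomial.polyval(pt, c)
                        for c in _PRINTED_BASIS[: q + 1]])
    gram = phi @ phi.T / N
    return BasisSet(N=N, q=q, p=p, ptilde=pt, phi=phi, gram=gram)


def restrict_single(contents: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Project one population onto the basis (least squares on the Gram)."""
    xs = np.sort(np.asarray(contents, dtype=float))
    if xs.size != basis.N:
        raise ValueError("population size must match the basis point set")
    b = basis.phi @ xs / basis.N
    return np.linalg.solve(basis.gram, b)


def restrict(states, basis: BasisSet) -> CoarseState:
    """Restrict one or several microscopic states to a coarse state.

    ``states`` may be a :class:`PopulationState`, a content array, or a
    sequence of either; coefficients are averaged across copies.
    """
    if isinstance(states, (PopulationState, np.ndarray)):
        states = [states]
    if len(states) == 0:
        raise ValueError("empty ensemble")
    alphas = []
    for s in states:
        contents = s.contents if isinstance(s, PopulationState) else s
        alphas.append(restrict_single(contents, basis))
    return CoarseState(alpha=np.mean(alphas, axis=0))


def lift_values(alpha: np.ndarray | CoarseState, basis: BasisSet) -> tuple[np.ndarray, float]:
    """Evaluate the truncated ICDF; returns (contents, clipped fraction).

    Negative ICDF values are clipped at zero and the result is sorted to
    enforce a monotone ICDF.
    """
    a = alpha.alpha if isinstance(alpha, CoarseState) else np.asarray(alpha, float)
    if a.size != basis.n_modes:
        raise ValueError("alpha length must equal the number of basis modes")
    x = basis.phi.T @ a
    clipped = float(np.mean(x < 0))
    x = np.sort(np.clip(x, 0.0, None))
    return x, clipped


def lift(alpha, basis: BasisSet, tau: float = 0.0,
         rng: np.random.Generator | None = None) -> PopulationState:
    """Lift a coarse state to a microscopic population of N cells."""
    del rng  # deterministic lifting; signature kept for stochastic variants
    x, clipped = lift_values(alpha, basis)
    if clipped > 0.01:
        logger.warning("lift clipped %.1f%% of the ICDF at zero", 100 * clipped)
    return PopulationState(tau=tau, contents=x)


def density_to_coarse(density: NumberDensity, basis: BasisSet) -> CoarseState:
    """Coarse state of a number density: sample its ICDF on the point set."""
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (density.values[1:] + density.values[:-1])
        * np.diff(density.grid.nodes)
    )])
    cdf /= cdf[-1]
    # invert the CDF at the quantile points (monotone interpolation)
    xs = np.interp(basis.p, cdf, density.grid.nodes)
    return CoarseState(alpha=restrict_single(xs, basis))


# ---------------------------------------------------------------------------
# microscopic simulators


class MicroStepper(Protocol):
    """Anything that can advance N cell contents over a horizon."""

    def advance(self, x0: np.ndarray, T: float, seed: int) -> np.ndarray: ...

    def advance_report(
        self, x0: np.ndarray, report_times: np.ndarray, seed: int
    ) -> np.ndarray: ...


@dataclass(frozen=True)
class CNMCStepper:
    """Constant-number Monte Carlo micro-simulator (compiled kernel)."""

    params: DimensionlessParams
    model: DivisionModel
    dt: float = 1e-3

    def advance_report(self, x0, report_times, seed):
        snaps, _ = _kernels.cnmc_step_kernel(
            np.asarray(x0, float), 0.0, np.asarray(report_times, float),
            self.dt, self.params.pi, self.params.rho, self.params.kappa,
            self.params.inv_K, self.params.inv_ystar,
            float(self.model.m), float(self.model.f), int(seed),
        )
        return snaps

    def advance(self, x0, T, seed):
        return self.advance_report(x0, np.array([float(T)]), seed)[-1]


@dataclass(frozen=True)
class ODESurrogateStepper:
    """Deterministic per-cell surrogate: dx/dtau = R(x) - x.

    Every cell follows the homogeneous-model vector field independently
    (no division, no noise); the coarse dynamics then coincide with the
    homogeneous model, providing an analytic oracle for the coarse
    numerics.  The seed argument is ignored.
    """

    params: DimensionlessParams
    dt: float = 5e-3

    def _rhs(self, x):
        from .dcpb import homogeneous_rhs

        return homogeneous_rhs(x, self.params)

    def advance_report(self, x0, report_times, seed):
        del seed
        x = np.asarray(x0, float).copy()
        snaps = np.empty((len(report_times), x.size))
        tau = 0.0
        for i, t_next in enumerate(report_times):
            while tau < t_next - 1e-12:
                h = min(self.dt, t_next - tau)
                k1 = self._rhs(x)
                k2 = self._rhs(np.abs(x + 0.5 * h * k1))
                k3 = self._rhs(np.abs(x + 0.5 * h * k2))
                k4 = self._rhs(np.abs(x + h * k3))
                x = np.abs(x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))
                tau += h
            snaps[i] = x
        return snaps

    def advance(self, x0, T, seed=0):
        return self.advance_report(x0, np.array([float(T)]), seed)[-1]


# ---------------------------------------------------------------------------
# coarse time-stepper


class CoarseMap:
    """The coarse time-stepper G_T as a callable map on coefficients.

    With common random numbers the per-copy seeds are frozen at
    construction, making the realized map deterministic; otherwise every
    evaluation draws fresh seeds.
    """

    def __init__(self, stepper: MicroStepper, basis: BasisSet,
                 cfg: CoarseMapConfig):
        self.stepper = stepper
        self.basis = basis
        self.cfg = cfg
        self._seeds = copy_seeds(cfg.seed, cfg.copies)
        self._stream = np.random.SeedSequence(cfg.seed ^ 0x5EED)
        self.last_copy_alphas: np.ndarray | None = None

    def _current_seeds(self) -> np.ndarray:
        if self.cfg.common_random_numbers:
            return self._seeds
        return (self._stream.spawn(1)[0].generate_state(
            self.cfg.copies, dtype=np.uint32) >> 1).astype(np.int64)

    def map(self, alpha: np.ndarray) -> np.ndarray:
        """One application of G_T (average over copies)."""
        x0, _ = lift_values(alpha, self.basis)
        seeds = self._current_seeds()
        alphas = np.empty((self.cfg.copies, self.basis.n_modes))
        for c in range(self.cfg.copies):
            xT = self.stepper.advance(x0, self.cfg.T, int(seeds[c]))
            alphas[c] = restrict_single(xT, self.basis)
        self.last_copy_alphas = alphas
        return alphas.mean(axis=0)

    def residual(self, alpha: np.ndarray) -> np.ndarray:
        return np.asarray(alpha, float) - self.map(alpha)

    def noise_floor(self) -> float:
        """2 x standard error of the averaged coefficients (last map call)."""
        if self.last_copy_alphas is None or self.cfg.copies < 2:
            return 0.0
        se = self.last_copy_alphas.std(axis=0, ddof=1) / math.sqrt(self.cfg.copies)
        return float(2.0 * se.max())


def coarse_timestep(alpha, stepper: MicroStepper, basis: BasisSet,
                    cfg: CoarseMapConfig) -> CoarseState:
    """Lift -> simulate for horizon T (copies) -> restrict -> average."""
    cmap = CoarseMap(stepper, basis, cfg)
    a = alpha.alpha if isinstance(alpha, CoarseState) else np.asarray(alpha, float)
    return CoarseState(alpha=cmap.map(a))


def coarse_residual(alpha, stepper: MicroStepper, basis: BasisSet,
                    cfg: CoarseMapConfig) -> np.ndarray:
    """Fixed-point residual alpha - G_T(alpha)."""
    cmap = CoarseMap(stepper, basis, cfg)
    a = alpha.alpha if isinstance(alpha, CoarseState) else np.asarray(alpha, float)
    return cmap.residual(a)


def _fd_eps_vector(alpha: np.ndarray, fd_eps: float) -> np.ndarray:
    # floor the perturbation at a fifth of unit coefficient scale so the
    # columns of stochastic maps stay above the realized-map roughness
    scale = np.maximum(np.abs(alpha), max(0.1 * np.max(np.abs(alpha)), 0.2))
    return fd_eps * scale


def fd_jacobian(map_fn: Callable[[np.ndarray], np.ndarray], alpha: np.ndarray,
                fd_eps: float = 1e-2, base: np.ndarray | None = None) -> np.ndarray:
    """Forward-difference Jacobian of a coarse map, one column per mode."""
    alpha = np.asarray(alpha, dtype=float)
    if base is None:
        base = map_fn(alpha)
    eps = _fd_eps_vector(alpha, fd_eps)
    J = np.empty((base.size, alpha.size))
    for j in range(alpha.size):
        ap = alpha.copy()
        ap[j] += eps[j]
        J[:, j] = (map_fn(ap) - base) / eps[j]
    return J


def coarse_newton(
    alpha0,
    cmap: CoarseMap,
    *,
    tol: float | None = None,
    max_iters: int | None = None,
    chord: bool = True,
) -> tuple[CoarseState, list[float]]:
    """Newton-Raphson on the coarse fixed-point equations.

    Solves [I - dG_T/dalpha] dalpha = -(alpha - G_T(alpha)) with a
    forward-difference Jacobian.  Iterations stop once the residual drops
    below max(newton_tol, the measured 2-SE noise floor).  ``chord=True``
    reuses the Jacobian while the residual keeps contracting.
    """
    cfg = cmap.cfg
    tol = cfg.newton_tol if tol is None else tol
    max_iters = cfg.max_iters if max_iters is None else max_iters
    a = (alpha0.alpha if isinstance(alpha0, CoarseState)
         else np.asarray(alpha0, float)).copy()
    trace: list[float] = []
    J = None
    prev_res = np.inf
    best_a, best_res, floor = a.copy(), np.inf, 0.0
    for it in range(max_iters):
        G = cmap.map(a)
        R = a - G
        res = float(np.max(np.abs(R)))
        trace.append(res)
        floor = max(floor, cmap.noise_floor())
        if res < best_res:
            best_a, best_res = a.copy(), res
        if res < max(tol, 2.0 * floor):
            return CoarseState(alpha=a), trace
        if J is None or not chord or res > 0.7 * prev_res:
            JG = fd_jacobian(cmap.map, a, cfg.fd_eps, base=G)
            J = np.eye(a.size) - JG
        try:
            da = np.linalg.solve(J, -R)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular coarse Jacobian") from exc
        a = a + da
        prev_res = res
    # stochastic maps cannot be solved below their realized roughness;
    # accept the best iterate when it sits inside the noise band
    if best_res < max(tol, 3.0 * floor):
        logger.info("coarse Newton noise-limited at residual %.2e", best_res)
        return CoarseState(alpha=best_a), trace
    raise RuntimeError(
        f"coarse Newton did not converge in {max_iters} iterations "
        f"(trace {['%.2e' % r for r in trace]})"
    )


def coarse_stability(alpha_star, cmap: CoarseMap) -> tuple[np.ndarray, bool]:
    """Eigenvalues of dG_T/dalpha at a coarse steady state.

    The coarse map is a discrete-time system: the state is stable iff all
    eigenvalue moduli are below one.
    """
    a = (alpha_star.alpha if isinstance(alpha_star, CoarseState)
         else np.asarray(alpha_star, float))
    JG = fd_jacobian(cmap.map, a, cmap.cfg.fd_eps)
    eig = np.linalg.eigvals(JG)
    return eig, bool(np.all(np.abs(eig) < 1.0))


def arclength_continuation(
    alpha0,
    rho_start: float,
    rho_range: tuple[float, float],
    stepper_factory: Callable[[float], MicroStepper],
    basis: BasisSet,
    cfg: CoarseMapConfig,
    constants: KineticConstants,
    *,
    ds: float = 0.06,
    max_steps: int = 60,
    direction: int = -1,
    stop_after_folds: int | None = None,
    newton_tol: float | None = None,
) -> BranchDiagram:
    """Pseudo arc-length continuation of coarse steady states in rho.

    ``stepper_factory(rho)`` builds the microscopic simulator at a given
    rho; the same common-random-number seed set is reused across the whole
    trace so the realized branch is smooth.  Continuation runs internally
    in log rho; folds are refined by a quadratic fit and reported in rho
    and extracellular IPTG.
    """
    a0 = (alpha0.alpha if isinstance(alpha0, CoarseState)
          else np.asarray(alpha0, float)).copy()
    base_tol = cfg.newton_tol if newton_tol is None else newton_tol
    maps: dict[float, CoarseMap] = {}
    floor_track = [0.0]

    def get_map(theta: float) -> CoarseMap:
        if theta not in maps:
            maps[theta] = CoarseMap(stepper_factory(float(np.exp(theta))),
                                    basis, cfg)
        return maps[theta]

    def F(u, theta):
        cmap = get_map(theta)
        res = cmap.residual(u)
        # track the measured coefficient noise so the corrector tolerance
        # follows the ensemble noise floor along the branch
        floor_track[0] = max(0.8 * floor_track[0], cmap.noise_floor())
        return res

    def tol_fn() -> float:
        return max(base_tol, 2.0 * floor_track[0])

    # Long-horizon validation: coarse fixed points are invariant under the
    # horizon, while slow "ghost" states behind a fold accumulate drift
    # roughly linearly in T.  Re-checking each accepted point with 4T
    # rejects ghost-corridor points that pass the T-residual test.
    val_cfg = CoarseMapConfig(
        T=4.0 * cfg.T, copies=cfg.copies, N=cfg.N, dt=cfg.dt,
        fd_eps=cfg.fd_eps, newton_tol=cfg.newton_tol,
        max_iters=cfg.max_iters,
        common_random_numbers=cfg.common_random_numbers,
        seed=cfg.seed + 9901,
    )
    val_maps: dict[float, CoarseMap] = {}

    def validate(u, theta) -> bool:
        if cfg.copies < 2:
            return True  # deterministic micro-simulators need no screening
        if theta not in val_maps:
            val_maps[theta] = CoarseMap(
                stepper_factory(float(np.exp(theta))), basis, val_cfg)
        vmap = val_maps[theta]
        res = float(np.max(np.abs(vmap.residual(np.asarray(u, float)))))
        limit = 2.5 * max(vmap.noise_floor(), floor_track[0], base_tol)
        if res > limit:
            logger.info("rejected ghost point at rho=%.4f (4T residual "
                        "%.2e > %.2e)", float(np.exp(theta)), res, limit)
            return False
        return True

    points: list[BranchPoint] = []

    def on_point(u, theta):
        rho = float(np.exp(theta))
        points.append(
            BranchPoint(
                rho=rho,
                iex_uM=rho_to_iex(rho, constants) / 1e3,
                mean_x=float(u[0]),
                meanY_nM=constants.y_hat * float(u[0]),
                stability="unknown",
                arc=float(len(points)),
                solution=u.copy(),
            )
        )

    result = trace_branch(
        F,
        a0,
        float(np.log(rho_start)),
        direction=direction,
        ds=ds,
        ds_min=2e-3,
        ds_max=2.0 * ds,
        max_steps=max_steps,
        p_range=(float(np.log(rho_range[0])), float(np.log(rho_range[1]))),
        newton_tol=tol_fn,
        max_newton=min(cfg.max_iters, 8),
        # perturbations relative to the coefficient scale, floored above the
        # micro-event granularity of the CRN map
        eps_u=lambda u: np.maximum(cfg.fd_eps * np.abs(u), 2e-3),
        eps_p=0.5 * cfg.fd_eps,
        p_weight=1.0,
        stop_after_folds=stop_after_folds,
        chord=True,
        min_corrector_iter=1 if cfg.copies > 1 else 0,
        validate=validate,
        on_point=on_point,
    )
    for fold in result.folds:
        if fold.index < len(points):
            points[fold.index].fold_flag = True
    fold_rhos = [float(np.exp(f.p)) for f in result.folds]
    fold_iex = [rho_to_iex(r, constants) / 1e3 for r in fold_rhos]
    return BranchDiagram(points=points, fold_rhos=fold_rhos, fold_iex_uM=fold_iex)


# ---------------------------------------------------------------------------
# healing-time diagnostics


@dataclass
class HealingReport:
    """Relative coefficient errors of a lifted state against the original."""

    times: np.ndarray
    rel_err: np.ndarray        # (n_report, q+2)
    noise_band: np.ndarray     # (n_report, q+2)
    alpha_original: np.ndarray
    alpha_lifted: np.ndarray

    def healed_by(self, mode: int) -> float | None:
        """First report time at which |rel err| of `mode` is inside the band."""
        inside = np.abs(self.rel_err[:, mode]) <= self.noise_band[:, mode]
        idx = np.argmax(inside)
        return float(self.times[idx]) if inside.any() else None


def healing_test(
    state: PopulationState,
    stepper: MicroStepper,
    *,
    q: int = 3,
    horizon: float = 1.0,
    report_dt: float = 0.1,
    copies: int = 10,
    seed: int = 0,
) -> HealingReport:
    """Measure how fast a lifted population relaxes onto the slow manifold.

    The state is restricted with q+1 modes and lifted back; the original
    and lifted populations are then co-evolved and the first q+2
    coefficients (computed in a degree-(q+1) basis) are compared at each
    report time.  The noise band 2 sigma_alpha / |alpha_original| is
    estimated from independent replicates evolved from the original state.
    """
    N = state.N
    basis_q = build_basis(N, q)
    basis_hi = build_basis(N, q + 1, orthonormalize=True)
    lifted = lift(restrict(state, basis_q), basis_q, tau=state.tau)

    report_times = np.arange(report_dt, horizon + 0.5 * report_dt, report_dt)
    seeds = copy_seeds(seed, copies + 2)
    orig_snaps = stepper.advance_report(state.contents, report_times,
                                        int(seeds[0]))
    lift_snaps = stepper.advance_report(lifted.contents, report_times,
                                        int(seeds[1]))
    a_orig = np.array([restrict_single(s, basis_hi) for s in orig_snaps])
    a_lift = np.array([restrict_single(s, basis_hi) for s in lift_snaps])
    denom = np.where(np.abs(a_orig) > 1e-12, np.abs(a_orig), 1e-12)
    rel_err = (a_lift - a_orig) / denom

    reps = np.empty((copies, len(report_times), q + 2))
    for c in range(copies):
        snaps = stepper.advance_report(state.contents, report_times,
                                       int(seeds[2 + c]))
        reps[c] = [restrict_single(s, basis_hi) for s in snaps]
    sigma = reps.std(axis=0, ddof=1) if copies > 1 else np.zeros_like(a_orig)
    band = 2.0 * sigma / denom
    return HealingReport(times=report_times, rel_err=rel_err, noise_band=band,
                         alpha_original=a_orig, alpha_lifted=a_lift)
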