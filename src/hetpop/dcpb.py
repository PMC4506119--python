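"""Deterministic population models.

Two levels are implemented:

* the homogeneous model ``d<x>/dt = R(<x>) - <x>`` (all cells behave like
  the average cell; the -<x> term is dilution by division at unit rate),
  with a closed-form fold analysis of its bistable region;
* the deterministic cell population balance (DCPB) equation for the number
  density n(x, t): growth advection d(R n)/dx, division sink Gamma(x) n with
  Gamma(x) = (x/<x>)^m, a binary-partitioning birth integral with the
  normalized two-point kernel P(x, x') = 1/2 d(x - f x') + 1/2 d(x - (1-f) x'),
  and the normalization-preserving dilution term n * int Gamma n dx.

The steady DCPB problem is solved by damped Newton on a conservative
finite-volume (first-order upwind) discretization, and branches are traced
in rho by pseudo arc-length continuation (shared engine with the
equation-free layer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._continuation import (ContinuationError, ContinuationResult,
                            newton_solve, trace_branch)
from .cnmc import DivisionModel
from .single_cell import DimensionlessParams, KineticConstants, rho_to_iex

__all__ = [
    "Grid",
    "NumberDensity",
    "BranchPoint",
    "BranchDiagram",
    "homogeneous_rhs",
    "homogeneous_steady_states",
    "homogeneous_folds",
    "birth_term",
    "dcpb_residual",
    "dcpb_time_rhs",
    "dcpb_integrate",
    "dcpb_steady_solve",
    "dcpb_continuation",
    "gaussian_density",
]

logger = logging.getLogger("hetpop.dcpb")


@dataclass(frozen=True)
class Grid:
    """Content grid on [0, x_max]; nodes include both endpoints.

    Node spacing may be non-uniform.  Each node owns a finite-volume cell
    bounded by the midpoints between neighbouring nodes; trapezoidal
    quadrature on the nodes coincides exactly with the finite-volume cell
    sum, so all integrals and the conservative upwind advection share one
    discrete measure.
    """

    x_max: float
    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if not self.x_max > 0:
            raise ValueError("x_max must be positive")
        if nodes[0] != 0.0 or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must start at 0 and increase strictly")
        object.__setattr__(self, "nodes", nodes)

    @classmethod
    def uniform(cls, x_max: float = 4.0, n_nodes: int = 400) -> "Grid":
        return cls(x_max=x_max, nodes=np.linspace(0.0, x_max, n_nodes))

    @classmethod
    def stretched(cls, x_max: float = 4.0, n_nodes: int = 500,
                  power: float = 3.0) -> "Grid":
        """Grid clustered near x = 0 (nodes = x_max * u^power).

        The stationary densities of the uninduced branch sit at contents
        two orders of magnitude below the induced branch, so a graded grid
        resolves both with a few hundred nodes.
        """
        u = np.linspace(0.0, 1.0, n_nodes)
        return cls(x_max=x_max, nodes=x_max * u**power)

    @property
    def faces(self) -> np.ndarray:
        """Cell interfaces: domain ends plus midpoints between nodes."""
        mid = 0.5 * (self.nodes[:-1] + self.nodes[1:])
        return np.concatenate([[0.0], mid, [self.x_max]])

    @property
    def weights(self) -> np.ndarray:
        """Finite-volume cell widths (= trapezoidal quadrature weights)."""
        return np.diff(self.faces)

    def trapz(self, values: np.ndarray) -> float:
        return float(np.trapezoid(values, self.nodes))


@dataclass(frozen=True)
class NumberDensity:
    """Normalized cell number density on a grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.nodes.shape:
            raise ValueError("values must match the grid")
        if np.min(v) < -1e-8:
            raise ValueError("density values must be non-negative")
        v = np.clip(v, 0.0, None)
        total = self.grid.trapz(v)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {total:.8f})")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return self.grid.trapz(self.grid.nodes * self.values)


@dataclass
class BranchPoint:
    """One continuation solution along a bifurcation branch."""

    rho: float
    iex_uM: float
    mean_x: float
    meanY_nM: float
    stability: str            # "stable" | "unstable" | "unknown"
    arc: float
    fold_flag: bool = False
    solution: np.ndarray | None = None


@dataclass
class BranchDiagram:
    points: list[BranchPoint]
    fold_rhos: list[float]
    fold_iex_uM: list[float]


# ---------------------------------------------------------------------------
# homogeneous model


def homogeneous_rhs(x_h, params: DimensionlessParams):
    """Average-cell dynamics R(x) - x (reaction rate minus division dilution)."""
    from .single_cell import reaction_rate_reduced

    x = np.asarray(x_h, dtype=float)
    if np.any(x < 0):
        raise ValueError("content must be non-negative")
    out = reaction_rate_reduced(x, params) - x
    return float(out) if np.ndim(out) == 0 else out


def homogeneous_steady_states(params: DimensionlessParams) -> np.ndarray:
    """Real non-negative roots of R(x) - x = 0 (sorted ascending).

    The steady-state condition is the cubic
    -c x^3 + x^2 - c rho x + pi rho = 0 with c = 1 + kappa.
    """
    c = 1.0 + params.kappa
    roots = np.roots([-c, 1.0, -c * params.rho, params.pi * params.rho])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real[real >= 0])


def homogeneous_folds(pi: float = 0.03, kappa: float = 0.05) -> list[tuple[float, float]]:
    """Fold (turning) points of the homogeneous bistable region.

    Simultaneously solving the steady state and tangency conditions reduces
    to the quadratic 2 c^2 x^2 - c(3 pi + 1) x + 2 pi = 0 (c = 1 + kappa);
    each admissible root x maps to rho = x^2 (c x - 1)/(pi - c x).  Returns
    [(rho_small, x), (rho_large, x)] or an empty list when the parameters
    admit no bistability.
    """
    c = 1.0 + kappa
    disc = (c * (3 * pi + 1)) ** 2 - 16 * c * c * pi
    if disc <= 0:
        logger.info("no bistability for pi=%g, kappa=%g", pi, kappa)
        return []
    xs = np.roots([2 * c * c, -c * (3 * pi + 1), 2 * pi]).real
    folds = []
    for x in np.sort(xs):
        denom = pi - c * x
        if denom == 0:
            continue
        rho = x * x * (c * x - 1.0) / denom
        if rho > 0:
            folds.append((float(rho), float(x)))
    if len(folds) < 2:
        logger.info("no bistability for pi=%g, kappa=%g", pi, kappa)
        return []
    return sorted(folds)


# ---------------------------------------------------------------------------
# DCPB discretization


def _gamma(x: np.ndarray, mean_x: float, model: DivisionModel) -> np.ndarray:
    if not mean_x > 0:
        raise ValueError("mean content must be positive")
    return (x / mean_x) ** model.m


def birth_term(
    n: NumberDensity | np.ndarray,
    model: DivisionModel,
    mean_x: float,
    grid: Grid | None = None,
) -> np.ndarray:
    """Birth flux 2 int Gamma(x') P(x, x') n(x') dx' on the grid.

    With the normalized two-point kernel the integral collapses to
    2 * [ (1/2f) Gamma(x/f) n(x/f) + (1/2(1-f)) Gamma(x/(1-f)) n(x/(1-f)) ];
    densities beyond x_max are treated as zero.
    """
    if isinstance(n, NumberDensity):
        grid, values = n.grid, n.values
    else:
        if grid is None:
            raise ValueError("grid required when n is a bare array")
        values = np.asarray(n, dtype=float)
    x = grid.nodes
    out = np.zeros_like(values)
    for frac in (model.f, 1.0 - model.f):
        xs = x / frac
        n_s = np.interp(xs, x, values, left=0.0, right=0.0)
        n_s[xs > grid.x_max] = 0.0
        out += (0.5 / frac) * _gamma(np.maximum(xs, 0.0), mean_x, model) * n_s
    return 2.0 * out


def _advection(values: np.ndarray, grid: Grid, params: DimensionlessParams) -> np.ndarray:
    """Conservative first-order upwind discretization of d(R n)/dx."""
    from .single_cell import reaction_rate_reduced

    x = grid.nodes
    x_face = 0.5 * (x[:-1] + x[1:])
    r_face = reaction_rate_reduced(x_face, params)
    upw = np.where(r_face > 0, values[:-1], values[1:])
    flux = np.empty(x.size + 1)
    flux[1:-1] = r_face * upw
    flux[0] = 0.0  # no cells enter from below x = 0
    r_last = reaction_rate_reduced(x[-1], params)
    flux[-1] = r_last * values[-1] if r_last > 0 else 0.0
    return np.diff(flux) / grid.weights


def dcpb_residual(
    n: NumberDensity | np.ndarray,
    params: DimensionlessParams,
    model: DivisionModel,
    grid: Grid | None = None,
    *,
    boundary_tol: float = 1e-6,
) -> np.ndarray:
    """Steady-state residual of the population balance equation.

    residual = d(R n)/dx + Gamma n - birth + n * int Gamma n dx, with the
    population mean in Gamma computed self-consistently from n.
    """
    if isinstance(n, NumberDensity):
        grid, values = n.grid, n.values
    else:
        if grid is None:
            raise ValueError("grid required when n is a bare array")
        values = np.asarray(n, dtype=float)
    x = grid.nodes
    mass = grid.trapz(values)
    mean = grid.trapz(x * values) / mass if mass > 0 else 0.0
    if not mean > 0:
        raise ValueError("degenerate density: non-positive mean content")
    gam = _gamma(x, mean, model)
    if values[-1] > boundary_tol * max(np.max(values), 1e-300):
        warnings.warn(
            "density mass reaches the domain boundary; increase x_max "
            "or refine the grid",
            RuntimeWarning,
            stacklevel=2,
        )
    birth = birth_term(values, model, mean, grid)
    # dilution rate from the discrete number balance (continuum value
    # int Gamma n dx): keeps int n dx exactly invariant under the flow
    div_rate = grid.trapz(birth - gam * values)
    return (
        _advection(values, grid, params)
        + gam * values
        - birth
        + values * div_rate
    )


def dcpb_time_rhs(
    values: np.ndarray,
    params: DimensionlessParams,
    model: DivisionModel,
    grid: Grid,
) -> np.ndarray:
    """dn/dt for the dynamic population balance (= -residual)."""
    return -dcpb_residual(values, params, model, grid)


def dcpb_integrate(
    n0: NumberDensity,
    params: DimensionlessParams,
    model: DivisionModel,
    t_final: float,
    report_times: Sequence[float] | None = None,
):
    """Explicit time integration of the dynamic DCPB equation."""
    from scipy.integrate import solve_ivp

    grid = n0.grid
    t_eval = None if report_times is None else np.asarray(report_times, float)
    sol = solve_ivp(
        lambda t, v: dcpb_time_rhs(v, params, model, grid),
        (0.0, t_final),
        n0.values,
        method="RK45",
        rtol=1e-7,
        atol=1e-10,
        t_eval=t_eval,
    )
    return sol.t, sol.y.T  # (times, densities[t, node])


def gaussian_density(grid: Grid, center: float, width: float) -> NumberDensity:
    """Normalized Gaussian bump, a convenient initial guess."""
    v = np.exp(-0.5 * ((grid.nodes - center) / width) ** 2)
    return NumberDensity(grid=grid, values=v / grid.trapz(v))


def _reduced_system(values, params, model, grid):
    """Residual with the last node's equation replaced by normalization."""
    res = dcpb_residual(values, params, model, grid)
    res[-1] = grid.trapz(values) - 1.0
    return res


def dcpb_steady_solve(
    initial: NumberDensity | np.ndarray,
    params: DimensionlessParams,
    model: DivisionModel,
    grid: Grid | None = None,
    tol: float = 1e-9,
    max_iter: int = 40,
) -> NumberDensity:
    """Damped Newton solve of the steady population balance.

    One discrete equation is replaced by the normalization constraint
    int n dx = 1 (the dilution form makes the raw residuals linearly
    dependent at the solution).
    """
    if isinstance(initial, NumberDensity):
        grid, v0 = initial.grid, initial.values
    else:
        if grid is None:
            raise ValueError("grid required when initial is a bare array")
        v0 = np.asarray(initial, dtype=float)

    def system(u, _p):
        return _reduced_system(u, params, model, grid)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            v = newton_solve(system, v0, 0.0, tol=tol, max_iter=max_iter,
                             eps_u=1e-7)
        except ContinuationError:
            # globalize: a few implicit-Euler pseudo-time steps pull the
            # iterate towards the attracting manifold before full Newton
            v = v0.copy()
            for dt_pseudo in (0.2, 0.5, 1.0, 2.0):
                v = newton_solve(
                    lambda u, _p, vk=v, h=dt_pseudo: (u - vk) / h
                    + dcpb_residual(u, params, model, grid),
                    v,
                    0.0,
                    tol=1e-4,
                    max_iter=25,
                    eps_u=1e-7,
                )
                v = np.clip(v, 0.0, None)
                v /= grid.trapz(v)
            v = newton_solve(system, v, 0.0, tol=tol, max_iter=max_iter,
                             eps_u=1e-7)
    v = np.clip(v, 0.0, None)
    v /= grid.trapz(v)
    return NumberDensity(grid=grid, values=v)


def _dcpb_stability(values, params, model, grid) -> str:
    """Linear stability of a steady density under the dynamic DCPB flow."""
    n = values.size
    f0 = dcpb_time_rhs(values, params, model, grid)
    J = np.empty((n, n))
    for i in range(n):
        h = 1e-7 * max(abs(values[i]), 1.0)
        vp = values.copy()
        vp[i] += h
        J[:, i] = (dcpb_time_rhs(vp, params, model, grid) - f0) / h
    eig = np.linalg.eigvals(J)
    return "stable" if np.max(eig.real) < 1e-6 else "unstable"


def dcpb_continuation(
    rho_start: float,
    rho_range: tuple[float, float],
    model: DivisionModel,
    constants: KineticConstants,
    grid: Grid | None = None,
    *,
    pi: float = 0.03,
    kappa: float = 0.05,
    initial: NumberDensity | None = None,
    ds: float = 0.08,
    max_steps: int = 120,
    compute_stability: bool = True,
    newton_tol: float = 1e-8,
) -> BranchDiagram:
    """Pseudo arc-length continuation of steady densities in rho.

    Continues internally in log rho.  Returns the branch (one
    :class:`BranchPoint` per accepted solution, fold rows flagged) together
    with refined fold locations mapped to extracellular IPTG.
    """
    grid = grid or Grid.stretched()
    p0 = DimensionlessParams(pi=pi, rho=rho_start, kappa=kappa)
    if initial is None:
        roots = homogeneous_steady_states(p0)
        x0 = float(roots[0])
        initial = gaussian_density(grid, x0, max(0.25 * x0, 0.005))
    # converge the starting point robustly before tracing the branch
    initial = dcpb_steady_solve(initial, p0, model, grid, tol=newton_tol)
    # scale the unknown so the arc-length metric balances density and rho
    u_scale = float(np.max(initial.values))

    def F(u, theta):
        prm = DimensionlessParams(pi=pi, rho=float(np.exp(theta)), kappa=kappa)
        return _reduced_system(u * u_scale, prm, model, grid)

    theta0 = np.log(rho_start)
    theta_range = (np.log(rho_range[0]), np.log(rho_range[1]))
    points: list[BranchPoint] = []

    def on_point(u, theta):
        rho = float(np.exp(theta))
        v = np.clip(u * u_scale, 0.0, None)
        mass = grid.trapz(v)
        mean = grid.trapz(grid.nodes * v) / mass
        stab = "unknown"
        if compute_stability:
            stab = _dcpb_stability(u * u_scale,
                                   DimensionlessParams(pi=pi, rho=rho,
                                                       kappa=kappa),
                                   model, grid)
        points.append(
            BranchPoint(
                rho=rho,
                iex_uM=rho_to_iex(rho, constants) / 1e3,
                mean_x=mean,
                meanY_nM=constants.y_hat * mean,
                stability=stab,
                arc=float(len(points)),
                solution=v / mass,
            )
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = trace_branch(
            F,
            initial.values / u_scale,
            theta0,
            direction=-1,
            ds=ds,
            ds_min=1e-4,
            ds_max=2.5 * ds,
            max_steps=max_steps,
            p_range=theta_range,
            newton_tol=newton_tol,
            max_newton=25,
            p_weight=1.0,
            on_point=on_point,
        )
    for fold in result.folds:
        if fold.index < len(points):
            points[fold.index].fold_flag = True
    fold_rhos = [float(np.exp(f.p)) for f in result.folds]
    fold_iex = [rho_to_iex(r, constants) / 1e3 for r in fold_rhos]
    return BranchDiagram(points=points, fold_rhos=fold_rhos, fold_iex_uM=fold_iex)
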