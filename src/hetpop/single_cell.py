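"""Single-cell lac operon kinetics.

The lac operon circuit (operator/repressor binding, IPTG uptake, LacY
facilitated transport, first-order degradation) is described at three levels:

* the full five-variable mass-action ODE model in ``full_ode_rhs``;
* a reduced two-variable model (``reduced_ode_rhs``) obtained by treating
  operator-repressor and IPTG-repressor binding as equilibria;
* a one-variable dimensionless model for the LacY content ``x`` whose
  deterministic rate is ``reaction_rate_reduced`` and whose intrinsic-noise
  (chemical Langevin) closure is given by ``langevin_drift`` /
  ``langevin_diffusion``.

The bifurcation parameter is the extracellular IPTG concentration, mapped to
the dimensionless repression-strength parameter ``rho`` by ``iex_to_rho``.
A Gillespie SSA over the elementary reactions (``gillespie_simulate``)
provides an exact stochastic reference for the Langevin approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from . import _kernels

__all__ = [
    "AVOGADRO",
    "KineticConstants",
    "DimensionlessParams",
    "CellPath",
    "build_constants",
    "iex_to_rho",
    "rho_to_iex",
    "params_from_iex",
    "reaction_rate_reduced",
    "full_ode_rhs",
    "reduced_ode_rhs",
    "steady_state_reduced",
    "steady_state_full",
    "langevin_drift",
    "langevin_diffusion",
    "integrate_langevin",
    "langevin_ensemble",
    "gillespie_simulate",
    "ssa_initial_counts",
    "FULL_STATE_VARS",
    "SSA_STATE_VARS",
]

AVOGADRO = 6.02214076e23

#: ordering of the full deterministic model state vector (concentrations, nM)
FULL_STATE_VARS = ("Y", "YIex", "I", "R", "O0")

#: ordering of the SSA count vector (molecule numbers)
SSA_STATE_VARS = ("Y", "YIex", "I", "Rf", "I2R", "O1")

# Dimensional rate constants of the reaction network.  The transport rate k_t
# is not among them: it is calibrated (see build_constants).
_TABLE_DEFAULTS = {
    "V_cell": 8e-16,    # L, E. coli volume
    "O_T": 2.08,        # nM, operator content (one molecule)
    "k_Y": 0.5,         # min^-1, transcription rate
    "k_r2": 3e-7,       # nM^-2 min^-1, IPTG-repressor association
    "k_mr2": 3e3,       # min^-1, IPTG-repressor dissociation
    "k_r": 960.0,       # nM^-1 min^-1, operator-repressor association
    "k_mr": 60.0,       # min^-1, operator-repressor dissociation
    "k_p": 1.32,        # nM^-1 min^-1, LacY-IPTG association
    "k_mp": 6e5,        # min^-1, LacY-IPTG dissociation
    "k_ft": 6e4,        # min^-1, facilitated transport
    "lam_Y": 0.0025,    # min^-1, LacY degradation
    "lam_I": 0.0025,    # min^-1, IPTG degradation
}

# Calibration anchor for the passive transport rate k_t: at extracellular
# IPTG 28.8 uM the repression-strength parameter equals rho = 0.09.
_KT_ANCHOR_IEX = 28.8e3   # nM
_KT_ANCHOR_RHO = 0.09


class InvalidParameterError(ValueError):
    """A kinetic constant or dimensionless parameter is out of range."""


@dataclass(frozen=True)
class KineticConstants:
    """Dimensional rate constants plus derived and calibrated quantities.

    All first-order rates are min^-1, concentrations nM.  ``k_t`` is the
    calibrated passive-transport rate; ``R_T`` the total repressor content
    derived from the leakiness ``pi``; ``y_hat``/``t_hat`` the content and
    time scales used to map dimensionless population content and time back
    to nM and minutes.
    """

    V_cell: float
    O_T: float
    k_Y: float
    k_r2: float
    k_mr2: float
    k_r: float
    k_mr: float
    k_p: float
    k_mp: float
    k_ft: float
    lam_Y: float
    lam_I: float
    k_t: float
    R_T: float
    pi: float
    kappa: float
    K_op: float = field(init=False)
    K_I: float = field(init=False)
    K_p: float = field(init=False)
    y_hat: float = field(init=False)
    t_hat: float = field(init=False)

    def __post_init__(self) -> None:
        for name in (
            "V_cell", "O_T", "k_Y", "k_r2", "k_mr2", "k_r", "k_mr",
            "k_p", "k_mp", "k_ft", "lam_Y", "lam_I", "k_t", "R_T",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not 0 < self.pi < 1:
            raise InvalidParameterError("pi must lie in (0, 1)")
        if not self.kappa > 0:
            raise InvalidParameterError("kappa must be strictly positive")
        object.__setattr__(self, "K_op", self.k_r / self.k_mr)
        object.__setattr__(self, "K_I", self.k_r2 / self.k_mr2)
        object.__setattr__(self, "K_p", self.k_mp / self.k_p)
        object.__setattr__(self, "y_hat", self.k_Y * self.O_T / self.lam_Y)
        object.__setattr__(self, "t_hat", self.kappa / self.lam_Y)

    @property
    def molecules_per_nM(self) -> float:
        """Molecule count corresponding to a 1 nM concentration."""
        return 1e-9 * self.V_cell * AVOGADRO

    @property
    def content_scale_single_cell(self) -> float:
        """nM per unit of the one-variable dimensionless content x.

        The single-cell reduction fixes the induced fixed point near
        x = 1/kappa, so the conversion carries an extra factor kappa
        relative to the population-level scale ``y_hat``.
        """
        return self.y_hat * self.kappa


@dataclass(frozen=True)
class DimensionlessParams:
    """Parameters of the dimensionless single-cell model.

    ``pi`` is the promoter leakiness, ``rho`` the repression strength
    (decreasing in extracellular IPTG), ``kappa`` the degradation parameter,
    ``sigma`` the transport parameter (approximately ``kappa``).  ``K_fluct``
    (operator fluctuation rate) and ``y_star`` (reference molecule number)
    control the intrinsic-noise terms; both may be ``inf`` to disable them.
    """

    pi: float = 0.03
    rho: float = 0.09
    kappa: float = 0.05
    sigma: float | None = None
    K_fluct: float = math.inf
    y_star: float = math.inf

    def __post_init__(self) -> None:
        if not 0 < self.pi < 1:
            raise InvalidParameterError("pi must lie in (0, 1)")
        if not self.rho > 0:
            raise InvalidParameterError("rho must be strictly positive")
        if not self.kappa > 0:
            raise InvalidParameterError("kappa must be strictly positive")
        if self.sigma is None:
            object.__setattr__(self, "sigma", self.kappa)
        if not 0.99 <= self.sigma / self.kappa <= 1.01:
            raise InvalidParameterError("sigma must approximately equal kappa")
        if not self.K_fluct > 0:
            raise InvalidParameterError("K_fluct must be positive or inf")
        if not self.y_star > 0:
            raise InvalidParameterError("y_star must be positive or inf")

    @property
    def inv_K(self) -> float:
        return 0.0 if math.isinf(self.K_fluct) else 1.0 / self.K_fluct

    @property
    def inv_ystar(self) -> float:
        return 0.0 if math.isinf(self.y_star) else 1.0 / self.y_star


@dataclass(frozen=True)
class CellPath:
    """A single-cell trajectory: dimensionless times and contents."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("contents must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def build_constants(
    overrides: Mapping[str, float] | None = None,
    *,
    pi: float = 0.03,
    kappa: float = 0.05,
) -> KineticConstants:
    """Assemble the kinetic constants with derived and calibrated members.

    ``R_T`` is fixed by inverting the leakiness relation
    ``pi = 1/(1 + K_op R_T)``; ``k_t`` is calibrated so that extracellular
    IPTG 28.8 uM maps onto ``rho = 0.09`` (unless overridden explicitly).

    Parameters
    ----------
    overrides
        Optional replacements for any dimensional constant (including
        ``k_t`` or ``R_T`` to bypass calibration/derivation).
    pi, kappa
        Dimensionless leakiness and degradation parameters used for the
        derived quantities.
    """
    values = dict(_TABLE_DEFAULTS)
    overrides = dict(overrides or {})
    for key, val in overrides.items():
        if key not in values and key not in ("k_t", "R_T"):
            raise InvalidParameterError(f"unknown constant {key!r}")
        if not val > 0:
            raise InvalidParameterError(f"override {key!r} must be positive")
        if key in values:
            values[key] = float(val)
    if not 0 < pi < 1:
        raise InvalidParameterError("pi must lie in (0, 1)")

    K_op = values["k_r"] / values["k_mr"]
    K_I = values["k_r2"] / values["k_mr2"]
    K_p = values["k_mp"] / values["k_p"]
    R_T = overrides.get("R_T", (1.0 / pi - 1.0) / K_op)
    y_hat = values["k_Y"] * values["O_T"] / values["lam_Y"]

    if "k_t" in overrides:
        k_t = float(overrides["k_t"])
    else:
        # closed-form calibration: Ihat(iex; k_t) must hit the anchor rho
        Ihat_target = math.sqrt((1.0 + K_op * R_T) / (K_I * _KT_ANCHOR_RHO))
        a = values["k_ft"] * y_hat / (K_p + _KT_ANCHOR_IEX)
        k_t = (_KT_ANCHOR_IEX * a - Ihat_target * values["lam_Y"]) / (
            Ihat_target - _KT_ANCHOR_IEX
        )
    return KineticConstants(k_t=k_t, R_T=R_T, pi=pi, kappa=kappa, **values)


def _ihat(iex: float, constants: KineticConstants) -> float:
    """Intracellular IPTG scale corresponding to extracellular ``iex`` (nM)."""
    return (
        iex
        * (constants.k_ft * constants.y_hat / (constants.K_p + iex) + constants.k_t)
        / (constants.lam_Y + constants.k_t)
    )


def iex_to_rho(
    iex: float,
    constants: KineticConstants,
    pi: float | None = None,
    kappa: float | None = None,
) -> float:
    """Map extracellular IPTG (nM) to the repression-strength parameter rho.

    ``rho = (1 + K_op R_T) / (K_I Ihat^2)`` is strictly decreasing in
    ``iex``.  ``pi`` may be supplied to override the leakiness baked into
    ``constants``; ``kappa`` is accepted for signature symmetry but does not
    enter the mapping.
    """
    del kappa
    if not iex > 0:
        raise ValueError("iex must be strictly positive")
    one_plus = 1.0 / pi if pi is not None else 1.0 + constants.K_op * constants.R_T
    return one_plus / (constants.K_I * _ihat(iex, constants) ** 2)


def rho_to_iex(
    rho: float,
    constants: KineticConstants,
    pi: float | None = None,
    kappa: float | None = None,
    *,
    iex_bracket: tuple[float, float] = (1e-1, 1e8),
) -> float:
    """Numerical inverse of :func:`iex_to_rho` (returns nM)."""
    if not rho > 0:
        raise ValueError("rho must be strictly positive")
    lo, hi = iex_bracket
    f = lambda z: iex_to_rho(z, constants, pi, kappa) - rho
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(f"rho={rho} outside attainable range")
    return brentq(f, lo, hi, rtol=1e-12)


def params_from_iex(
    iex: float,
    constants: KineticConstants,
    *,
    K_fluct: float = math.inf,
    y_star: float = math.inf,
) -> DimensionlessParams:
    """Dimensionless parameter set for extracellular IPTG ``iex`` (nM)."""
    return DimensionlessParams(
        pi=constants.pi,
        rho=iex_to_rho(iex, constants),
        kappa=constants.kappa,
        K_fluct=K_fluct,
        y_star=y_star,
    )


def reaction_rate_reduced(x, params: DimensionlessParams):
    """Deterministic dimensionless reaction rate R(x).

    R(x) = (pi rho + x^2)/(rho + x^2) - kappa x, the one-variable reduction
    of the lac operon kinetics.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("content x must be non-negative")
    num = params.pi * params.rho + x * x
    den = params.rho + x * x
    out = num / den - params.kappa * x
    return float(out) if out.ndim == 0 else out


def langevin_drift(x, params: DimensionlessParams):
    """Langevin drift A(x): R(x) plus the slow-operator 1/K correction."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("content x must be non-negative")
    pi, rho, kap = params.pi, params.rho, params.kappa
    d = rho + x * x
    out = (pi * rho + x * x) / d - kap * x
    invK = params.inv_K
    if invK > 0:
        out = out - invK * 2.0 * rho * x * (pi - 1.0) * (
            ((pi - 2.0) + kap * x) * x * x + rho * (kap * x - pi)
        ) / d**4
    return float(out) if out.ndim == 0 else out


def langevin_diffusion(x, params: DimensionlessParams):
    """Langevin diffusion B(x) >= 0 (finite-molecule + operator terms)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("content x must be non-negative")
    pi, rho, kap = params.pi, params.rho, params.kappa
    d = rho + x * x
    out = params.inv_ystar * (rho * (pi + kap * x) + x * x * (1.0 + kap * x)) / d
    invK = params.inv_K
    if invK > 0:
        out = out + invK * rho * x * x * (pi - 1.0) ** 2 / d**3
    return float(out) if out.ndim == 0 else out


def full_ode_rhs(state, constants: KineticConstants, iex: float) -> np.ndarray:
    """Right-hand side of the five-variable mass-action model (nM/min).

    State ordering is :data:`FULL_STATE_VARS` = (Y, YIex, I, R, O0).
    Transport through the membrane is reversible, so the intracellular IPTG
    balance carries both the influx ``k_t [Iex]`` and the efflux
    ``-k_t [I]``.
    """
    Y, YI, I, R, O0 = np.asarray(state, dtype=float)
    if min(Y, YI, I, R, O0) < 0:
        raise ValueError("concentrations must be non-negative")
    c = constants
    if O0 > c.O_T * (1 + 1e-9) or R > c.R_T + c.O_T + 1e-9:
        raise ValueError(
            "O0 must not exceed O_T, nor R the total repressor pool"
        )
    bind_p = c.k_p * Y * iex
    unbind_p = (c.k_ft + c.k_mp) * YI
    dY = c.k_Y * O0 + unbind_p - bind_p - c.lam_Y * Y
    dYI = bind_p - unbind_p
    dI = (
        c.k_mr2 * (c.R_T - R)
        - c.k_r2 * I * I * R
        + c.k_t * iex
        - c.k_t * I
        + c.k_ft * YI
        - c.lam_I * I
    )
    dR = (
        c.k_mr * (c.O_T - O0)
        - c.k_r * O0 * R
        - c.k_r2 * I * I * R
        + c.k_mr2 * (c.R_T - R)
    )
    dO0 = -c.k_Y * O0 - c.k_r * O0 * R + c.k_mr * (c.O_T - O0)
    return np.array([dY, dYI, dI, dR, dO0])


def reduced_ode_rhs(state, constants: KineticConstants, iex: float) -> np.ndarray:
    """Right-hand side of the two-variable equilibrium-reduced model.

    State is (Y, I) in nM.  Operator-repressor binding (association constant
    K_op) and IPTG-repressor binding (K_I) are treated as equilibrated, which
    collapses the production term to a Hill-like function of [I]^2.
    """
    Y, I = np.asarray(state, dtype=float)
    if Y < 0 or I < 0:
        raise ValueError("concentrations must be non-negative")
    c = constants
    KI2 = c.K_I * I * I
    dY = c.k_Y * c.O_T * (1.0 + KI2) / (1.0 + KI2 + c.K_op * c.R_T) - c.lam_Y * Y
    dI = (
        c.k_ft * iex * Y / (c.K_p + iex)
        + c.k_t * (iex - I)
        - c.lam_I * I
    )
    return np.array([dY, dI])


def _integrate_to_steady(rhs, y0, t_final=4e4, rtol=1e-10, atol=1e-9):
    sol = solve_ivp(rhs, (0.0, t_final), y0, method="LSODA", rtol=rtol, atol=atol)
    return sol.y[:, -1]


def steady_state_reduced(
    constants: KineticConstants, iex: float, y0: Sequence[float] = (0.0, 0.0)
) -> np.ndarray:
    """Steady state (Y, I) of the reduced model by long integration."""
    return _integrate_to_steady(
        lambda t, s: reduced_ode_rhs(s, constants, iex), list(y0)
    )


def steady_state_full(
    constants: KineticConstants, iex: float, y0: Sequence[float] | None = None
) -> np.ndarray:
    """Steady state of the full model by long integration.

    The default initial state is fully repressed: no LacY, no intracellular
    IPTG, all repressor free, operator mostly occupied at equilibrium.
    """
    c = constants
    if y0 is None:
        O0_eq = c.k_mr * c.O_T / (c.k_mr + c.k_r * c.R_T)
        y0 = [0.0, 0.0, 0.0, c.R_T, O0_eq]
    hi = np.array([np.inf, np.inf, np.inf, c.R_T + c.O_T, c.O_T])

    def rhs(t, s):
        # solvers may overshoot the invariant box by round-off; clip
        return full_ode_rhs(np.clip(s, 0.0, hi), c, iex)

    return _integrate_to_steady(rhs, list(y0))


def integrate_langevin(
    x0: float,
    params: DimensionlessParams,
    duration: float,
    dt: float = 1e-3,
    seed: int | None = 0,
    report_dt: float | None = None,
) -> CellPath:
    """Euler-Maruyama (Ito) path of the single-cell Langevin SDE.

    The content is reflected at x = 0, keeping every reported value
    non-negative.  With ``K_fluct`` and ``y_star`` infinite the path is the
    deterministic Euler trajectory of the reduced rate.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    if x0 < 0:
        raise ValueError("x0 must be non-negative")
    if report_dt is None:
        report_dt = max(duration / 400.0, dt)
    report_times = np.arange(0.0, duration + 0.5 * report_dt, report_dt)
    report_times[0] = 0.0
    paths = _kernels.langevin_paths(
        np.array([float(x0)]),
        report_times,
        dt,
        params.pi,
        params.rho,
        params.kappa,
        params.inv_K,
        params.inv_ystar,
        0 if seed is None else int(seed),
    )
    return CellPath(times=report_times, values=paths[:, 0])


def langevin_ensemble(
    x0: float,
    params: DimensionlessParams,
    duration: float,
    n_paths: int,
    dt: float = 1e-3,
    seed: int = 0,
    report_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble of Langevin paths; returns (report_times, values[t, path])."""
    if report_times is None:
        report_times = np.linspace(0.0, duration, 101)
    report_times = np.asarray(report_times, dtype=float)
    x0s = np.full(n_paths, float(x0))
    values = _kernels.langevin_paths(
        x0s, report_times, dt, params.pi, params.rho, params.kappa,
        params.inv_K, params.inv_ystar, int(seed),
    )
    return report_times, values


def ssa_initial_counts(
    constants: KineticConstants,
    Y: float = 0.0,
    YIex: float = 0.0,
    I: float = 0.0,
) -> np.ndarray:
    """Initial SSA molecule counts from concentrations (nM).

    Counts are rounded to the nearest non-negative integer.  The single
    repressor molecule starts free and the operator starts unoccupied.
    """
    F = constants.molecules_per_nM
    n_R = max(int(round(constants.R_T * F)), 1)
    counts = np.array(
        [round(Y * F), round(YIex * F), round(I * F), n_R, 0, 0], dtype=np.int64
    )
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return counts


def gillespie_simulate(
    counts0: np.ndarray,
    constants: KineticConstants,
    iex: float,
    t_stop: float,
    seed: int = 0,
    report_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact SSA over the elementary lac operon reactions.

    ``counts0`` follows :data:`SSA_STATE_VARS` = (Y, YIex, I, Rf, I2R, O1);
    the free-operator count is ``O_tot - O1`` with ``O_tot`` the single
    operator copy.  Extracellular IPTG is an unlimited reservoir at fixed
    concentration ``iex`` (nM).  Returns (report_times, counts[t, var]) with
    the state sampled left-continuously at each report time.
    """
    counts0 = np.asarray(counts0, dtype=np.int64)
    if counts0.shape != (6,):
        raise ValueError("counts0 must have six entries (Y, YIex, I, Rf, I2R, O1)")
    if np.any(counts0 < 0):
        raise ValueError("counts must be non-negative")
    n_O = 1  # one operator molecule (O_T = 2.08 nM in a cell volume)
    if counts0[5] > n_O:
        raise ValueError("operator count exceeds total operator content")
    if report_times is None:
        report_times = np.linspace(0.0, t_stop, 101)
    report_times = np.asarray(report_times, dtype=float)
    c = constants
    snaps = _kernels.ssa_kernel(
        counts0,
        report_times,
        float(iex),
        c.molecules_per_nM,
        n_O,
        c.k_r, c.k_mr, c.k_r2, c.k_mr2, c.k_t, c.k_Y,
        c.k_p, c.k_mp, c.k_ft, c.lam_Y, c.lam_I,
        int(seed),
    )
    return report_times, snaps
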