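"""Constant-number Monte Carlo (CNMC) simulation of a heterogeneous population.

A population of exactly N cells is simulated.  Between divisions each cell's
dimensionless LacY content follows the single-cell Langevin SDE (intrinsic
heterogeneity); division events fire according to the population hazard
sum_i Gamma(x_i) with Gamma(x) = (x/<x>)^m, the divider is selected
proportionally to its own rate, its content is split into fractions f and
1-f (extrinsic heterogeneity), and a randomly chosen cell is replaced by the
second daughter so the population size stays constant.

``sample_division_time`` / ``select_divider`` / ``apply_division`` expose the
individual algorithm steps; ``run_cnmc`` / ``ensemble_run`` execute the fused
compiled loop for production runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _kernels
from .single_cell import DimensionlessParams

__all__ = [
    "PopulationState",
    "DivisionModel",
    "CNMCConfig",
    "EnsembleResult",
    "DegeneratePopulationError",
    "division_rate",
    "sample_division_time",
    "select_divider",
    "apply_division",
    "run_cnmc",
    "ensemble_run",
    "copy_seeds",
    "write_snapshots_csv",
]

logger = logging.getLogger("hetpop.cnmc")


class DegeneratePopulationError(RuntimeError):
    """The population carries no content or no division hazard."""


@dataclass(frozen=True)
class PopulationState:
    """Microscopic state: N non-negative contents at dimensionless time tau."""

    tau: float
    contents: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.contents, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("contents must be a non-empty 1-D array")
        if np.any(c < 0):
            raise ValueError("contents must be non-negative")
        object.__setattr__(self, "contents", c)

    @property
    def N(self) -> int:
        return self.contents.size

    @property
    def mean(self) -> float:
        return float(self.contents.mean())


@dataclass(frozen=True)
class DivisionModel:
    """Division sharpness exponent m and partition asymmetry f in (0, 0.5]."""

    m: float = 2.0
    f: float = 0.5

    def __post_init__(self) -> None:
        if not self.m >= 0:
            raise ValueError("m must be non-negative")
        if not 0 < self.f <= 0.5:
            raise ValueError("f must lie in (0, 0.5]")


@dataclass(frozen=True)
class CNMCConfig:
    """Run configuration for CNMC simulations."""

    N: int = 10_000
    dt: float = 1e-3
    t_stop: float = 10.0
    copies: int = 50
    seed: int = 0
    report_times: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.t_stop > 0:
            raise ValueError("t_stop must be positive")
        if self.copies < 1:
            raise ValueError("copies must be at least 1")

    def resolved_report_times(self) -> np.ndarray:
        if self.report_times is None:
            return np.array([self.t_stop])
        rt = np.asarray(self.report_times, dtype=float)
        if np.any(np.diff(rt) <= 0) or rt[-1] > self.t_stop + 1e-12:
            raise ValueError("report times must increase and not exceed t_stop")
        return rt


def division_rate(x, mean_x: float, model: DivisionModel):
    """Per-cell division hazard Gamma(x) = (x/<x>)^m."""
    if not mean_x > 0:
        raise DegeneratePopulationError("population average content must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("content must be non-negative")
    out = (x / mean_x) ** model.m
    return float(out) if out.ndim == 0 else out


def _advance_contents(
    x: np.ndarray,
    h: float,
    params: DimensionlessParams,
    rng: np.random.Generator,
    z: np.ndarray | None = None,
    noise_scale: float = 1.0,
) -> np.ndarray:
    """One Euler-Maruyama step with reflection for a content array."""
    from .single_cell import langevin_drift, langevin_diffusion

    if z is None:
        z = rng.standard_normal(x.size)
    b = langevin_diffusion(x, params)
    out = x + langevin_drift(x, params) * h + np.sqrt(np.asarray(b) * h) * noise_scale * z
    return np.abs(out)


def sample_division_time(
    state: PopulationState,
    params: DimensionlessParams,
    model: DivisionModel,
    dt: float,
    rng: np.random.Generator,
    *,
    propagate: bool = True,
    max_steps: int = 2_000_000,
) -> tuple[float, np.ndarray]:
    """Draw the waiting time T to the next division event.

    An Exp(1) threshold -ln(1-p1) is accumulated against the trapezoidal
    integral of the population hazard along the (Langevin-propagated)
    contents; the crossing step is resolved by linear interpolation.  With
    ``propagate=False`` the contents are frozen, making the waiting time
    exactly exponential with rate sum_i Gamma(x_i).

    Returns (T, contents at tau + T).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    x = state.contents.copy()
    target = -np.log(1.0 - rng.random())
    hazard = 0.0
    gsum = float(np.sum(division_rate(x, x.mean(), model)))
    t = 0.0
    for _ in range(max_steps):
        if propagate:
            z = rng.standard_normal(x.size)
            x_new = _advance_contents(x, dt, params, rng, z)
        else:
            z = None
            x_new = x
        mean_new = x_new.mean()
        if not mean_new > 0:
            raise DegeneratePopulationError("population content vanished")
        gsum_new = float(np.sum(division_rate(x_new, mean_new, model)))
        dH = 0.5 * (gsum + gsum_new) * dt
        if dH > 0 and hazard + dH >= target:
            theta = np.clip((target - hazard) / dH, 0.0, 1.0)
            if propagate:
                x = _advance_contents(x, theta * dt, params, rng, z,
                                      noise_scale=np.sqrt(theta))
            return t + theta * dt, x
        x = x_new
        gsum = gsum_new
        hazard += dH
        t += dt
    raise DegeneratePopulationError(
        f"no division within {max_steps} steps (total hazard {hazard:.3e}, "
        f"target {target:.3e}): hazard effectively zero"
    )


def select_divider(
    state: PopulationState,
    mean_x: float | None,
    model: DivisionModel,
    rng: np.random.Generator,
) -> int:
    """Categorical draw of the dividing cell, P(k) = Gamma(x_k)/sum Gamma."""
    if mean_x is None:
        mean_x = state.mean
    gam = division_rate(state.contents, mean_x, model)
    gam = np.atleast_1d(gam)
    total = gam.sum()
    if not total > 0:
        raise DegeneratePopulationError("all division rates vanish")
    u = rng.random() * total
    return int(np.searchsorted(np.cumsum(gam), u))


def apply_division(
    state: PopulationState,
    k: int,
    model: DivisionModel,
    rng: np.random.Generator,
) -> PopulationState:
    """Divide cell k: daughters f*x_k and (1-f)*x_k (fair-coin assignment).

    The mother's slot receives one daughter; a uniformly chosen *other*
    slot is replaced by the second daughter, keeping N constant.
    """
    x = state.contents.copy()
    xm = x[k]
    # exact mass partition in floating point: with f <= 1/2 the larger
    # daughter b = xm - fl(f xm) satisfies fl(xm - b) = xm - b (Sterbenz),
    # so the pair (xm - b, b) sums to the mother content exactly
    d_big = xm - model.f * xm
    d_small = xm - d_big
    if rng.random() < 0.5:
        d1, d2 = d_small, d_big
    else:
        d1, d2 = d_big, d_small
    x[k] = d1
    j = int(rng.integers(0, state.N - 1))
    if j >= k:
        j += 1
    x[j] = d2
    return PopulationState(tau=state.tau, contents=x)


def copy_seeds(root_seed: int, copies: int) -> np.ndarray:
    """Deterministic per-copy kernel seeds (< 2^31) from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return (ss.generate_state(copies, dtype=np.uint32) >> 1).astype(np.int64)


def _as_contents(initial, N: int | None = None) -> np.ndarray:
    if isinstance(initial, PopulationState):
        return initial.contents.copy()
    x = np.asarray(initial, dtype=float)
    if x.ndim == 0:
        if N is None:
            raise ValueError("scalar initial condition requires N")
        x = np.full(N, float(x))
    if np.any(x < 0):
        raise ValueError("initial contents must be non-negative")
    return x


def run_cnmc(
    config: CNMCConfig,
    params: DimensionlessParams,
    model: DivisionModel,
    initial,
    seed: int | None = None,
) -> list[PopulationState]:
    """Run one CNMC copy; snapshots at the configured report times.

    ``initial`` may be a :class:`PopulationState`, a content array, or a
    scalar (all cells at a common content).  Fully reproducible given the
    seed (``config.seed`` unless overridden).
    """
    x0 = _as_contents(initial, config.N)
    if x0.size != config.N:
        raise ValueError("initial contents must have length N")
    rt = config.resolved_report_times()
    kseed = int(copy_seeds(config.seed if seed is None else seed, 1)[0])
    tau0 = initial.tau if isinstance(initial, PopulationState) else 0.0
    snaps, n_div = _kernels.cnmc_step_kernel(
        x0, tau0, tau0 + rt, config.dt,
        params.pi, params.rho, params.kappa,
        params.inv_K, params.inv_ystar,
        float(model.m), float(model.f), kseed,
    )
    logger.debug("CNMC copy: %d divisions over %.3f tau", n_div, rt[-1])
    return [PopulationState(tau=tau0 + t, contents=snaps[i]) for i, t in enumerate(rt)]


@dataclass
class EnsembleResult:
    """Per-copy CNMC snapshots and across-copy summary statistics."""

    report_times: np.ndarray
    #: contents[copy][report_index] -> PopulationState
    copies: list[list[PopulationState]]
    seeds: np.ndarray
    #: mean content per (report time, copy)
    mean_content: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_content = np.array(
            [[snap.mean for snap in copy] for copy in self.copies]
        ).T

    @property
    def ensemble_mean(self) -> np.ndarray:
        return self.mean_content.mean(axis=1)

    @property
    def ensemble_sd(self) -> np.ndarray:
        return self.mean_content.std(axis=1, ddof=1) if len(self.copies) > 1 else (
            np.zeros(self.report_times.size)
        )

    def coefficient_summary(self, q: int = 3):
        """Across-copy mean/SD of ICDF basis coefficients at each report time."""
        from .equation_free import build_basis, restrict_single

        basis = build_basis(self.copies[0][0].N, q)
        n_rep = self.report_times.size
        alphas = np.array(
            [
                [restrict_single(copy[i].contents, basis) for i in range(n_rep)]
                for copy in self.copies
            ]
        )  # (copies, reports, q+1)
        return alphas.mean(axis=0), alphas.std(axis=0, ddof=1)


def ensemble_run(
    config: CNMCConfig,
    params: DimensionlessParams,
    model: DivisionModel,
    initial,
    copies: int | None = None,
) -> EnsembleResult:
    """Independent-seed CNMC replicates with across-copy statistics."""
    n_copies = config.copies if copies is None else copies
    if n_copies < 1:
        raise ValueError("copies must be at least 1")
    seeds = copy_seeds(config.seed, n_copies)
    rt = config.resolved_report_times()
    runs = []
    for c in range(n_copies):
        runs.append(run_cnmc(config, params, model, initial, seed=int(seeds[c])))
    logger.debug("ensemble: %d copies, seeds %s", n_copies, seeds.tolist())
    return EnsembleResult(report_times=rt, copies=runs, seeds=seeds)


def write_snapshots_csv(result: EnsembleResult, path: str | Path) -> Path:
    """Write one row per cell (copy, time, content) plus a JSON sidecar."""
    import pandas as pd

    path = Path(path)
    rows = []
    for c, copy in enumerate(result.copies):
        for snap in copy:
            rows.append(
                pd.DataFrame(
                    {"copy": c, "time": snap.tau, "content": snap.contents}
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"seeds": result.seeds.tolist(),
                    "report_times": result.report_times.tolist()}, indent=1)
    )
    return path
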