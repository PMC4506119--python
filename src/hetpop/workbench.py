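"""Run orchestration: configuration, scenarios, fixtures and result tables.

Scenario ids map the bifurcation studies of the population models (effect
of intrinsic noise, of operator fluctuations and molecule numbers, of
division sharpness and partitioning asymmetry, and the noise-induced
switching run) onto concrete pipelines.  A scale factor <= 1 shrinks the
population size and copy count jointly for reduced-cost runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cnmc import (CNMCConfig, DivisionModel, PopulationState, ensemble_run,
                   run_cnmc)
from .dcpb import (BranchDiagram, BranchPoint, Grid, dcpb_continuation,
                   dcpb_steady_solve, gaussian_density, homogeneous_folds,
                   homogeneous_steady_states)
from .equation_free import (CNMCStepper, CoarseMap, CoarseMapConfig,
                            arclength_continuation, build_basis,
                            coarse_newton, density_to_coarse, lift)
from .single_cell import (DimensionlessParams, KineticConstants,
                          build_constants, iex_to_rho, rho_to_iex)

__all__ = [
    "ConfigError",
    "WorkbenchConfig",
    "ScenarioSpec",
    "RunRecord",
    "load_config",
    "run_scenario",
    "make_fixture_population",
    "write_branch_table",
    "read_branch_table",
    "homogeneous_branch",
    "SCENARIOS",
]

logger = logging.getLogger("hetpop.workbench")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class WorkbenchConfig:
    """Validated run configuration with defaults filled in."""

    N: int = 10_000
    copies: int = 50
    m: float = 2.0
    f: float = 0.5
    pi: float = 0.03
    kappa: float = 0.05
    K_fluct: float = float("inf")
    y_star: float = float("inf")
    dt: float = 1e-3
    T: float = 0.5
    t_stop: float = 10.0
    seed: int = 0
    x_max: float = 4.0
    grid_nodes: int = 400

    def __post_init__(self) -> None:
        if not 0 < self.f <= 0.5:
            raise ConfigError("f must lie in (0, 0.5]")
        if self.m < 0:
            raise ConfigError("m must be non-negative")
        if not 0 < self.pi < 1:
            raise ConfigError("pi must lie in (0, 1)")
        for name in ("kappa", "dt", "T", "t_stop", "x_max"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.N < 2 or self.copies < 1 or self.grid_nodes < 10:
            raise ConfigError("N >= 2, copies >= 1, grid_nodes >= 10 required")

    def division_model(self) -> DivisionModel:
        return DivisionModel(m=self.m, f=self.f)

    def params(self, rho: float) -> DimensionlessParams:
        return DimensionlessParams(pi=self.pi, rho=rho, kappa=self.kappa,
                                   K_fluct=self.K_fluct, y_star=self.y_star)


def load_config(path: str | Path) -> WorkbenchConfig:
    """Load and schema-validate a YAML or JSON configuration file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration must be a mapping")
    known = {f.name for f in dataclasses.fields(WorkbenchConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    converted = {}
    for key, val in raw.items():
        if val in ("inf", ".inf"):
            val = float("inf")
        converted[key] = val
    try:
        cfg = WorkbenchConfig(**converted)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    logger.info(
        "config loaded: N=%d copies=%d m=%g f=%g; derived k_t=%.6f R_T=%.6f "
        "y_hat=%.1f t_hat=%.1f",
        cfg.N, cfg.copies, cfg.m, cfg.f,
        constants.k_t, constants.R_T, constants.y_hat, constants.t_hat,
    )
    return cfg


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, scalable study (e.g. ``fig6``) with parameter overrides."""

    scenario: str
    overrides: Mapping[str, Any] = field(default_factory=dict)
    scale: float = 1.0
    outdir: str | Path = "results"

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ConfigError("scale factor must lie in (0, 1]")
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"known: {sorted(SCENARIOS)}"
            )


@dataclass
class RunRecord:
    """Provenance of one scenario run (config, seeds, outputs)."""

    scenario: str
    config: dict
    seeds: list[int]
    versions: dict
    wall_clock_s: float
    manifest: list[str]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                   default=str))
        return path


def make_fixture_population(
    kind: str,
    N: int,
    parameters: Mapping[str, float] | None = None,
    seed: int = 0,
) -> PopulationState:
    """Reproducible synthetic populations for tests.

    Kinds: ``constant`` (all cells at ``c``), ``lognormal`` (``mean``,
    ``sigma`` of log-content), ``bimodal`` (mixture at ``x_low``/``x_high``
    with ``weight`` on the low mode and relative ``spread``).
    """
    if N < 10:
        raise ConfigError("N must be at least 10")
    p = dict(parameters or {})
    rng = np.random.default_rng(seed)
    if kind == "constant":
        c = float(p.pop("c", 0.5))
        if c < 0:
            raise ConfigError("constant content must be non-negative")
        contents = np.full(N, c)
    elif kind == "lognormal":
        mean = float(p.pop("mean", 0.5))
        sigma = float(p.pop("sigma", 0.3))
        if mean <= 0 or sigma <= 0:
            raise ConfigError("lognormal mean and sigma must be positive")
        contents = rng.lognormal(np.log(mean), sigma, N)
    elif kind == "bimodal":
        x_low = float(p.pop("x_low", 0.1))
        x_high = float(p.pop("x_high", 0.9))
        weight = float(p.pop("weight", 0.5))
        spread = float(p.pop("spread", 0.1))
        if not 0 < weight < 1:
            raise ConfigError("weight must lie in (0, 1)")
        n_low = int(round(weight * N))
        lows = x_low * np.abs(1.0 + spread * rng.standard_normal(n_low))
        highs = x_high * np.abs(1.0 + spread * rng.standard_normal(N - n_low))
        contents = np.concatenate([lows, highs])
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    if p:
        raise ConfigError(f"unknown fixture parameter(s): {sorted(p)}")
    return PopulationState(tau=0.0, contents=contents)


_BRANCH_COLUMNS = ["rho", "iex_uM", "mean_x", "meanY_nM", "stability",
                   "fold_flag", "arc"]


def write_branch_table(points: Sequence[BranchPoint], path: str | Path,
                       config: Mapping | None = None) -> Path:
    """Write a branch as CSV (fold rows flagged) with a JSON sidecar."""
    if len(points) == 0:
        raise ValueError("cannot write an empty branch table")
    path = Path(path)
    df = pd.DataFrame(
        [{c: getattr(pt, c) for c in _BRANCH_COLUMNS} for pt in points]
    )
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(dict(config or {}), indent=1, default=str))
    return path


def read_branch_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def homogeneous_branch(
    constants: KineticConstants,
    rho_range: tuple[float, float] = (0.03, 0.5),
    pi: float = 0.03,
    kappa: float = 0.05,
    n: int = 400,
) -> list[BranchPoint]:
    """Homogeneous-model branch parameterized along x (closed form).

    Every steady state satisfies rho = x^2 (c x - 1)/(pi - c x) with
    c = 1 + kappa, so sweeping x enumerates the whole S-curve; stability is
    the sign of d(R(x) - x)/dx.
    """
    from .dcpb import homogeneous_rhs

    c = 1.0 + kappa
    xs = np.linspace(pi / c * 1.0001, 1.0 / c * 0.9999, n)
    folds = homogeneous_folds(pi, kappa)
    fold_xs = [x for _, x in folds]
    points = []
    for x in xs:
        rho = x * x * (c * x - 1.0) / (pi - c * x)
        if not rho_range[0] <= rho <= rho_range[1]:
            continue
        prm = DimensionlessParams(pi=pi, rho=rho, kappa=kappa)
        h = 1e-7
        slope = (homogeneous_rhs(x + h, prm) - homogeneous_rhs(x - h, prm)) / (2 * h)
        near_fold = any(abs(x - fx) < (xs[1] - xs[0]) for fx in fold_xs)
        points.append(
            BranchPoint(
                rho=float(rho),
                iex_uM=rho_to_iex(rho, constants) / 1e3,
                mean_x=float(x),
                meanY_nM=constants.y_hat * float(x),
                stability="stable" if slope < 0 else "unstable",
                arc=float(len(points)),
                fold_flag=bool(near_fold),
            )
        )
    return points


# ---------------------------------------------------------------------------
# scenario pipelines


def _scaled(cfg: WorkbenchConfig, scale: float) -> tuple[int, int]:
    return max(int(round(cfg.N * scale)), 100), max(int(round(cfg.copies * scale)), 2)


def _coarse_branch(
    cfg: WorkbenchConfig,
    constants: KineticConstants,
    scale: float,
    rho_start: float,
    rho_range: tuple[float, float],
    K_fluct: float,
    y_star: float,
    m: float | None = None,
    direction: int = -1,
    max_steps: int = 40,
    relax_tau: float = 5.0,
) -> BranchDiagram:
    """Trace one coarse CNMC branch with the equation-free machinery."""
    N, copies = _scaled(cfg, scale)
    model = DivisionModel(m=cfg.m if m is None else m, f=cfg.f)
    basis = build_basis(N, 3)
    mapcfg = CoarseMapConfig(T=cfg.T, copies=copies, N=N, dt=cfg.dt,
                             seed=cfg.seed)

    def factory(rho: float) -> CNMCStepper:
        prm = DimensionlessParams(pi=cfg.pi, rho=rho, kappa=cfg.kappa,
                                  K_fluct=K_fluct, y_star=y_star)
        return CNMCStepper(params=prm, model=model, dt=cfg.dt)

    # relax to the attractor at rho_start, then Newton-polish
    prm0 = DimensionlessParams(pi=cfg.pi, rho=rho_start, kappa=cfg.kappa,
                               K_fluct=K_fluct, y_star=y_star)
    roots = homogeneous_steady_states(prm0)
    x0 = np.full(N, float(roots[0] if direction < 0 else roots[-1]))
    run_cfg = CNMCConfig(N=N, dt=cfg.dt, t_stop=relax_tau, copies=1,
                         seed=cfg.seed)
    snap = run_cnmc(run_cfg, prm0, model, x0)[-1]
    from .equation_free import restrict

    alpha0 = restrict(snap, basis)
    cmap = CoarseMap(factory(rho_start), basis, mapcfg)
    alpha0, _ = coarse_newton(alpha0, cmap)
    return arclength_continuation(
        alpha0, rho_start, rho_range, factory, basis, mapcfg, constants,
        direction=direction, max_steps=max_steps,
    )


def coarse_fold_window(
    rho_start: float,
    x_relax: float,
    direction: int,
    model: DivisionModel,
    constants: KineticConstants,
    *,
    K_fluct: float = float("inf"),
    y_star: float = float("inf"),
    N: int = 2000,
    copies: int = 10,
    seed: int = 0,
    T: float = 0.5,
    dt: float = 2e-3,
    ds: float = 0.04,
    max_steps: int = 14,
    relax_tau: float = 6.0,
    pi: float = 0.03,
    kappa: float = 0.05,
) -> BranchDiagram:
    """Locate one coarse fold of the CNMC bifurcation diagram.

    Starting inside the bistable region on the branch selected by the
    relaxation content ``x_relax``, the population is relaxed to its
    attractor, Newton-polished, and continued towards the fold
    (``direction=-1`` decreases rho).  The trace stops at the first fold,
    whose location is reported in rho and extracellular IPTG.
    """
    basis = build_basis(N, 3)
    mapcfg = CoarseMapConfig(T=T, copies=copies, N=N, dt=dt, seed=seed,
                             newton_tol=2e-4, max_iters=8)

    def factory(rho: float) -> CNMCStepper:
        prm = DimensionlessParams(pi=pi, rho=rho, kappa=kappa,
                                  K_fluct=K_fluct, y_star=y_star)
        return CNMCStepper(params=prm, model=model, dt=dt)

    prm0 = DimensionlessParams(pi=pi, rho=rho_start, kappa=kappa,
                               K_fluct=K_fluct, y_star=y_star)
    run_cfg = CNMCConfig(N=N, dt=dt, t_stop=relax_tau, copies=1, seed=seed)
    snap = run_cnmc(run_cfg, prm0, model, float(x_relax))[-1]
    from .equation_free import restrict

    alpha0, _ = coarse_newton(restrict(snap, basis),
                              CoarseMap(factory(rho_start), basis, mapcfg))
    return arclength_continuation(
        alpha0, rho_start, (0.02, 0.5), factory, basis, mapcfg, constants,
        ds=ds, max_steps=max_steps, direction=direction, stop_after_folds=1,
    )


def coarse_bistability_limit(
    rho_inside: float,
    x_relax: float,
    direction: int,
    model: DivisionModel,
    constants: KineticConstants,
    *,
    K_fluct: float = float("inf"),
    y_star: float = float("inf"),
    N: int = 2000,
    copies: int = 10,
    seed: int = 0,
    T: float = 0.5,
    dt: float = 1e-3,
    pi: float = 0.03,
    kappa: float = 0.05,
    step_theta: float = 0.04,
    tol_theta: float = 0.02,
    max_map_iters: int = 24,
    max_probes: int = 22,
) -> tuple[float, float]:
    """Locate a coarse bistability limit (fold) by branch-survival bisection.

    A copy ensemble of CNMC populations is relaxed on the branch selected
    by ``x_relax`` and advanced directly at each probed rho (the coarse
    mean content is the readout; re-lifting between probes is avoided
    because at small N the truncated ICDF clips the escape-driving content
    tail and biases the limits outward).  Inside the bistable region the
    ensemble settles on the branch; beyond its fold it escapes to the
    coexisting attractor, an unambiguous order-one signature.  The fold is
    bracketed by stepping rho in ``direction`` (in log rho, steps
    ``step_theta``) until the branch is lost and then refined by bisection
    to ``tol_theta``.

    Returns (rho_fold, iex_fold_uM).
    """
    from .cnmc import PopulationState, copy_seeds

    del T, max_map_iters  # probes advance the microscopic ensemble directly
    probe_tau = 12.0
    report = np.arange(1.0, probe_tau + 0.01, 1.0)
    # low branches (direction < 0) escape upward in content, upper branches
    # downward
    escape_sign = 1.0 if direction < 0 else -1.0

    def params(rho: float) -> DimensionlessParams:
        return DimensionlessParams(pi=pi, rho=rho, kappa=kappa,
                                   K_fluct=K_fluct, y_star=y_star)

    seeds = copy_seeds(seed, copies)
    warm_cfg = CNMCConfig(N=N, dt=dt, t_stop=6.0, copies=1, seed=seed)
    pops: list[np.ndarray] = []
    for s in seeds:
        snap = run_cnmc(warm_cfg, params(rho_inside), model,
                        float(x_relax), seed=int(s))[-1]
        pops.append(snap.contents)
    a0_ref = float(np.mean([p.mean() for p in pops]))
    drift_tol = 0.06 * a0_ref

    n_probes = [0]

    def probe(theta: float, start: list[np.ndarray]):
        """Relax the ensemble at rho = e^theta; classify survival vs escape.

        Escape shows either as the copy-averaged mean content leaving the
        branch band, or as a sustained drift towards the coexisting
        attractor over the final reports (the slow "ghost" transit past a
        fold).
        """
        rho = float(np.exp(theta))
        n_probes[0] += 1
        cfg_p = CNMCConfig(N=N, dt=dt, t_stop=probe_tau, copies=1, seed=seed,
                           report_times=tuple(report))
        traj = np.zeros(report.size)
        ends = []
        for ci, x0 in enumerate(start):
            s = int(np.random.SeedSequence(
                [seed, n_probes[0], ci]).generate_state(1)[0] >> 1)
            snaps = run_cnmc(cfg_p, params(rho), model,
                             PopulationState(tau=0.0, contents=x0), seed=s)
            traj += np.array([sn.mean for sn in snaps]) / copies
            ends.append(snaps[-1].contents)
        if traj[-1] > 2.2 * a0_ref or traj[-1] < 0.45 * a0_ref:
            return False, ends
        drift = traj[-1] - traj[-5]
        if escape_sign * drift > drift_tol:
            return False, ends
        return True, ends

    theta_in = float(np.log(rho_inside))
    ok, pops = probe(theta_in, pops)
    if not ok:
        raise RuntimeError(
            f"starting point rho={rho_inside} is not on the requested branch"
        )
    theta_out = None
    theta = theta_in
    while theta_out is None and n_probes[0] < max_probes:
        theta = theta + direction * step_theta
        ok, ends = probe(theta, pops)
        if ok:
            theta_in, pops = theta, ends
        else:
            theta_out = theta
    if theta_out is None:
        raise RuntimeError("no fold found within the probed rho range")
    while abs(theta_out - theta_in) > tol_theta and n_probes[0] < max_probes:
        mid = 0.5 * (theta_in + theta_out)
        ok, ends = probe(mid, pops)
        if ok:
            theta_in, pops = mid, ends
        else:
            theta_out = mid
    rho_fold = float(np.exp(0.5 * (theta_in + theta_out)))
    logger.info("bistability limit after %d probes: rho=%.4f", n_probes[0],
                rho_fold)
    return rho_fold, rho_to_iex(rho_fold, constants) / 1e3


def _scenario_intrinsic_noise(cfg: WorkbenchConfig, scale: float,
                              outdir: Path) -> list[str]:
    """Homogeneous vs DCPB vs CNMC (with and without intrinsic noise)."""
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    manifest = []
    hom = homogeneous_branch(constants, (0.04, 0.45), cfg.pi, cfg.kappa)
    manifest.append(str(write_branch_table(hom, outdir / "homogeneous.csv")))

    grid = Grid.stretched(cfg.x_max, cfg.grid_nodes)
    dc = dcpb_continuation(0.3, (0.05, 0.35), cfg.division_model(), constants,
                           grid, pi=cfg.pi, kappa=cfg.kappa,
                           compute_stability=False)
    manifest.append(str(write_branch_table(dc.points, outdir / "dcpb.csv",
                                           {"folds_iex_uM": dc.fold_iex_uM})))

    for tag, K, ys in (("cnmc_nonoise", float("inf"), float("inf")),
                       ("cnmc_noise", 500.0, 50.0)):
        # low branch swept downward in rho, upper branch upward
        low = _coarse_branch(cfg, constants, scale, 0.16, (0.05, 0.30),
                             K, ys, direction=-1, max_steps=30)
        up = _coarse_branch(cfg, constants, scale, 0.07, (0.04, 0.30),
                            K, ys, direction=1, max_steps=30)
        pts = low.points + up.points
        manifest.append(str(write_branch_table(
            pts, outdir / f"{tag}.csv",
            {"folds_iex_uM": low.fold_iex_uM + up.fold_iex_uM})))
    return manifest


def _scenario_noise_params(cfg, scale, outdir, settings, tag_fmt):
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    manifest = []
    for K, ys in settings:
        low = _coarse_branch(cfg, constants, scale, 0.16, (0.04, 0.30),
                             K, ys, direction=-1, max_steps=35)
        manifest.append(str(write_branch_table(
            low.points, outdir / (tag_fmt.format(K=K, ys=ys) + ".csv"),
            {"folds_iex_uM": low.fold_iex_uM})))
    return manifest


def _scenario_fig8a(cfg, scale, outdir):
    return _scenario_noise_params(
        cfg, scale, outdir,
        [(1000.0, 50.0), (500.0, 50.0), (250.0, 50.0)], "K{K:g}_y{ys:g}")


def _scenario_fig9(cfg, scale, outdir):
    return _scenario_noise_params(
        cfg, scale, outdir,
        [(1000.0, 500.0), (500.0, 50.0), (250.0, 25.0)], "K{K:g}_y{ys:g}")


def _scenario_division_sharpness(cfg, scale, outdir):
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    manifest = []
    for m in (1.0, 2.0, 3.0):
        br = _coarse_branch(cfg, constants, scale, 0.16, (0.04, 0.30),
                            500.0, 50.0, m=m, direction=-1, max_steps=35)
        manifest.append(str(write_branch_table(
            br.points, outdir / f"cnmc_m{m:g}.csv",
            {"folds_iex_uM": br.fold_iex_uM})))
    grid = Grid.stretched(cfg.x_max, cfg.grid_nodes)
    dc = dcpb_continuation(0.2, (0.04, 0.25), DivisionModel(m=3.0, f=cfg.f),
                           build_constants(pi=cfg.pi, kappa=cfg.kappa), grid,
                           pi=cfg.pi, kappa=cfg.kappa, compute_stability=False)
    manifest.append(str(write_branch_table(dc.points, outdir / "dcpb_m3.csv",
                                           {"folds_iex_uM": dc.fold_iex_uM})))
    return manifest


def _scenario_switching(cfg, scale, outdir):
    """Long single-copy run from an upper-branch coarse state at 30.8 uM."""
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    N, copies = _scaled(cfg, scale)
    rho = iex_to_rho(30.8e3, constants)
    model = DivisionModel(m=3.0, f=cfg.f)
    basis = build_basis(N, 3)
    grid = Grid.stretched(cfg.x_max, cfg.grid_nodes)
    prm = DimensionlessParams(pi=cfg.pi, rho=rho, kappa=cfg.kappa,
                              K_fluct=500.0, y_star=50.0)
    # upper-branch initial state from the DCPB steady density
    roots = homogeneous_steady_states(prm)
    dens = dcpb_steady_solve(gaussian_density(grid, float(roots[-1]), 0.05),
                             DimensionlessParams(pi=cfg.pi, rho=rho,
                                                 kappa=cfg.kappa),
                             model, grid)
    mapcfg = CoarseMapConfig(T=cfg.T, copies=copies, N=N, dt=cfg.dt,
                             seed=cfg.seed)
    cmap = CoarseMap(CNMCStepper(params=prm, model=model, dt=cfg.dt),
                     basis, mapcfg)
    alpha, _ = coarse_newton(density_to_coarse(dens, basis), cmap)
    start = lift(alpha, basis)
    run_cfg = CNMCConfig(
        N=N, dt=cfg.dt, t_stop=cfg.t_stop, copies=1, seed=cfg.seed,
        report_times=tuple(np.linspace(0.5, cfg.t_stop, 200)),
    )
    snaps = run_cnmc(run_cfg, prm, model, start)
    df = pd.DataFrame({
        "tau": [s.tau for s in snaps],
        "t_min": [s.tau * constants.t_hat for s in snaps],
        "meanY_nM": [constants.y_hat * s.mean for s in snaps],
    })
    path = outdir / "switching.csv"
    df.to_csv(path, index=False)
    return [str(path)]


def _scenario_slow_division(cfg, scale, outdir):
    constants = build_constants(pi=cfg.pi, kappa=cfg.kappa)
    manifest = []
    model = DivisionModel(m=1.0, f=0.3)
    grid = Grid.stretched(cfg.x_max, cfg.grid_nodes)
    dc = dcpb_continuation(0.35, (0.06, 0.45), model, constants, grid,
                           pi=cfg.pi, kappa=cfg.kappa, compute_stability=False)
    manifest.append(str(write_branch_table(dc.points, outdir / "dcpb.csv",
                                           {"folds_iex_uM": dc.fold_iex_uM})))
    for tag, K, ys in (("cnmc_nonoise", float("inf"), float("inf")),
                       ("cnmc_noise", 500.0, 50.0)):
        br = _coarse_branch(cfg, constants, scale, 0.35, (0.06, 0.45),
                            K, ys, m=1.0, direction=-1, max_steps=35)
        manifest.append(str(write_branch_table(
            br.points, outdir / f"{tag}.csv",
            {"folds_iex_uM": br.fold_iex_uM})))
    return manifest


SCENARIOS: dict[str, Callable] = {
    "fig6": _scenario_intrinsic_noise,
    "fig8a": _scenario_fig8a,
    "fig9": _scenario_fig9,
    "fig11": _scenario_division_sharpness,
    "fig12": _scenario_switching,
    "fig13": _scenario_slow_division,
}


def run_scenario(spec: ScenarioSpec,
                 base_config: WorkbenchConfig | None = None) -> RunRecord:
    """Execute a named scenario at the requested scale; write all tables."""
    cfg = base_config or WorkbenchConfig()
    if spec.overrides:
        cfg = dataclasses.replace(cfg, **dict(spec.overrides))
    if spec.scenario == "fig13":
        cfg = dataclasses.replace(cfg, f=0.3, m=1.0)
    outdir = Path(spec.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    try:
        manifest = SCENARIOS[spec.scenario](cfg, spec.scale, outdir)
    except Exception as exc:
        raise RuntimeError(f"scenario {spec.scenario!r} failed: {exc}") from exc
    record = RunRecord(
        scenario=spec.scenario,
        config=dataclasses.asdict(cfg) | {"scale": spec.scale},
        seeds=[cfg.seed],
        versions={"python": platform.python_version(),
                  "numpy": np.__version__},
        wall_clock_s=time.perf_counter() - t0,
        manifest=manifest,
    )
    record.write(outdir / f"{spec.scenario}_run.json")
    for m in manifest:
        if not Path(m).exists():
            raise RuntimeError(f"manifest entry missing on disk: {m}")
    return record
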