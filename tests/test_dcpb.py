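"""Population balance: homogeneous folds, discretization, steady solves."""

import numpy as np
import pytest

from hetpop.cnmc import CNMCConfig, DivisionModel, ensemble_run
from hetpop.dcpb import (
    Grid,
    NumberDensity,
    birth_term,
    dcpb_continuation,
    dcpb_integrate,
    dcpb_residual,
    dcpb_steady_solve,
    gaussian_density,
    homogeneous_folds,
    homogeneous_rhs,
    homogeneous_steady_states,
)
from hetpop.single_cell import DimensionlessParams


# frozen roots of the closed-form fold quadratic 1.1025 x^2 - 0.57225 x + 0.03
RHO_FOLDS = (0.10220120759600752, 0.24149493752870904)


class TestHomogeneous:
    def test_rhs_boundary_and_asymptotics(self):
        p = DimensionlessParams(rho=0.09)
        assert homogeneous_rhs(0.0, p) == pytest.approx(p.pi)
        # rho -> 0: production saturates at 1, stable root at 1/(1+kappa)
        p0 = DimensionlessParams(rho=1e-10)
        root = homogeneous_steady_states(p0)[-1]
        assert root == pytest.approx(1 / 1.05, rel=1e-4)

    def test_three_roots_in_bistable_region_match_dense_scan(self):
        p = DimensionlessParams(rho=0.15)
        roots = homogeneous_steady_states(p)
        assert len(roots) == 3
        # oracle: sign changes of the rhs on a dense grid
        xs = np.linspace(0.0, 1.2, 240_001)
        f = homogeneous_rhs(xs, p)
        crossings = xs[:-1][np.sign(f[:-1]) * np.sign(f[1:]) < 0]
        assert len(crossings) == 3
        np.testing.assert_allclose(roots, crossings, atol=1e-5)

    def test_folds_match_quadratic_oracle(self):
        folds = homogeneous_folds(0.03, 0.05)
        assert [r for r, _ in folds] == pytest.approx(list(RHO_FOLDS),
                                                      rel=1e-6)

    def test_folds_bracket_root_multiplicity_change(self):
        # brute-force scan: count roots on a rho grid; the multiplicity
        # changes exactly at the closed-form folds
        rhos = np.linspace(0.08, 0.27, 96)
        n_roots = [len(homogeneous_steady_states(
            DimensionlessParams(rho=r))) for r in rhos]
        switch = [0.5 * (rhos[i] + rhos[i + 1])
                  for i in range(len(rhos) - 1)
                  if n_roots[i] != n_roots[i + 1]]
        assert len(switch) == 2
        drho = rhos[1] - rhos[0]
        assert abs(switch[0] - RHO_FOLDS[0]) < drho
        assert abs(switch[1] - RHO_FOLDS[1]) < drho

    def test_no_bistability_for_weak_repression(self):
        assert homogeneous_folds(0.9, 0.05) == []


class TestBirthTerm:
    @pytest.fixture
    def smooth_density(self):
        grid = Grid.uniform(3.0, 600)
        return gaussian_density(grid, 0.8, 0.15)

    def test_number_balance_two_daughters_per_division(self, smooth_density):
        n = smooth_density
        model = DivisionModel(m=2, f=0.4)
        gam = (n.grid.nodes / n.mean) ** model.m
        births = n.grid.trapz(birth_term(n, model, n.mean))
        divisions = n.grid.trapz(gam * n.values)
        assert births == pytest.approx(2.0 * divisions, rel=1e-3)

    def test_symmetric_kernel_identity(self, smooth_density):
        # f = 1/2 collapses both kernel atoms: birth(x) = 4 Gamma(2x) n(2x)
        n = smooth_density
        model = DivisionModel(m=2, f=0.5)
        x = n.grid.nodes
        n2 = np.interp(2 * x, x, n.values, left=0.0, right=0.0)
        expected = 4.0 * (2 * x / n.mean) ** 2 * n2
        np.testing.assert_allclose(birth_term(n, model, n.mean), expected,
                                   atol=1e-10)

    def test_narrow_peak_maps_to_half_content(self):
        grid = Grid.uniform(3.0, 1200)
        n = gaussian_density(grid, 1.0, 0.02)
        b = birth_term(n, DivisionModel(m=2, f=0.5), n.mean)
        peak = grid.nodes[np.argmax(b)]
        assert peak == pytest.approx(0.5, abs=0.02)


class TestDynamicForm:
    def test_normalization_preserved_over_ten_tau(self):
        grid = Grid.uniform(3.0, 300)
        n0 = gaussian_density(grid, 0.55, 0.08)
        params = DimensionlessParams(rho=0.09)
        model = DivisionModel(m=2, f=0.5)
        _, dens = dcpb_integrate(n0, params, model, 10.0,
                                 report_times=[0.0, 5.0, 10.0])
        masses = [grid.trapz(d) for d in dens]
        assert max(abs(m - 1.0) for m in masses) < 1e-4

    def test_delta_density_recovers_homogeneous_rate(self):
        """A concentrated density obeys d<x>/dt = R(<x>) - <x> initially,
        and the discrete mean rate satisfies the exact first-moment law
        d<x>/dt = int R n dx - <x> int Gamma n dx as the density spreads."""
        from hetpop.dcpb import dcpb_time_rhs, _gamma
        from hetpop.single_cell import reaction_rate_reduced

        grid = Grid.uniform(2.0, 400)
        n0 = gaussian_density(grid, 0.6, 0.015)
        params = DimensionlessParams(rho=0.09)
        model = DivisionModel(m=2, f=0.5)
        rate0 = grid.trapz(grid.nodes * dcpb_time_rhs(n0.values, params,
                                                      model, grid))
        assert rate0 == pytest.approx(homogeneous_rhs(0.6, params), rel=0.01)
        # after the population has spread through divisions, the mean still
        # follows the (density-dependent) moment law exactly
        _, dens = dcpb_integrate(n0, params, model, 0.8, report_times=[0.8])
        v = dens[-1]
        x = grid.nodes
        mean = grid.trapz(x * v) / grid.trapz(v)
        gam = _gamma(x, mean, model)
        law = (grid.trapz(reaction_rate_reduced(x, params) * v)
               - mean * grid.trapz(gam * v))
        rate = grid.trapz(x * dcpb_time_rhs(v, params, model, grid))
        from hetpop.single_cell import reaction_rate_reduced as rr

        gross = grid.trapz(np.abs(rr(x, params)) * v) + mean * grid.trapz(
            gam * v)
        assert abs(rate - law) < 0.005 * gross


class TestSteadySolve:
    def test_converged_density_contract(self, symmetric_division):
        grid = Grid.stretched(4.0, 400)
        params = DimensionlessParams(rho=0.2)
        sol = dcpb_steady_solve(gaussian_density(grid, 0.034, 0.01), params,
                                symmetric_division, grid, tol=1e-8)
        assert grid.trapz(sol.values) == pytest.approx(1.0, abs=1e-6)
        res = dcpb_residual(sol, params, symmetric_division)
        assert np.max(np.abs(res)) < 1e-6

    def test_stationary_mean_matches_cnmc(self, symmetric_division):
        """Cross-model oracle: DCPB steady mean vs long CNMC runs."""
        params = DimensionlessParams(rho=0.2)  # monostable uninduced branch
        grid = Grid.stretched(4.0, 500)
        sol = dcpb_steady_solve(gaussian_density(grid, 0.034, 0.01), params,
                                symmetric_division, grid, tol=1e-8)
        cfg = CNMCConfig(N=2000, dt=1e-3, t_stop=14.0, copies=4, seed=31,
                         report_times=tuple(np.arange(8.0, 14.1, 1.0)))
        res = ensemble_run(cfg, params, symmetric_division, 0.034)
        copy_means = res.mean_content[-3:].mean(axis=0)
        se = copy_means.std(ddof=1) / np.sqrt(len(copy_means))
        assert abs(copy_means.mean() - sol.mean) < 3 * se

    def test_grid_refinement_changes_mean_below_half_percent(
            self, symmetric_division):
        params = DimensionlessParams(rho=0.2)
        means = []
        for n_nodes in (600, 1200):
            grid = Grid.stretched(4.0, n_nodes)
            sol = dcpb_steady_solve(gaussian_density(grid, 0.03, 0.008),
                                    params, symmetric_division, grid,
                                    tol=1e-8)
            means.append(sol.mean)
        assert abs(means[1] / means[0] - 1) < 0.005


class TestContinuation:
    def test_s_shaped_branch_with_two_folds(self, constants,
                                            symmetric_division):
        grid = Grid.stretched(4.0, 300)
        diag = dcpb_continuation(0.2, (0.05, 0.3), symmetric_division,
                                 constants, grid, compute_stability=True,
                                 newton_tol=1e-6)
        assert len(diag.fold_rhos) == 2
        lo, hi = sorted(diag.fold_rhos)
        # three coexisting solutions strictly inside the fold interval
        mid = 0.5 * (lo + hi)
        near = [p for p in diag.points if abs(p.rho - mid) < 0.1 * mid]
        means = sorted(p.mean_x for p in near)
        assert means[-1] > 3 * means[0]
        stabs = {p.stability for p in diag.points}
        assert stabs == {"stable", "unstable"}
        # the middle branch is the unstable one
        unstable = [p.mean_x for p in diag.points if p.stability == "unstable"]
        assert min(means) < np.median(unstable) < max(means)

    def test_folds_match_bruteforce_existence_scan(self, constants,
                                                   symmetric_division):
        """Low-branch fold against a steady-solve existence scan."""
        grid = Grid.stretched(4.0, 300)
        diag = dcpb_continuation(0.2, (0.05, 0.3), symmetric_division,
                                 constants, grid, compute_stability=False,
                                 newton_tol=1e-6)
        lo_fold = min(diag.fold_rhos)
        rhos = np.linspace(0.07, 0.11, 9)
        exists = []
        dens = dcpb_steady_solve(gaussian_density(grid, 0.03, 0.008),
                                 DimensionlessParams(rho=0.12),
                                 symmetric_division, grid, tol=1e-8)
        for r in rhos[::-1]:
            try:
                cand = dcpb_steady_solve(dens, DimensionlessParams(rho=r),
                                         symmetric_division, grid, tol=1e-8)
                on_low = cand.mean < 0.15
                exists.append(on_low)
                if on_low:
                    dens = cand
            except Exception:
                exists.append(False)
        last_low = rhos[::-1][np.where(exists)[0][-1]] if any(exists) else None
        # continuation fold within one scan step of the existence boundary
        assert last_low is not None
        assert abs(last_low - lo_fold) <= (rhos[1] - rhos[0]) + 1e-9


class TestNumberDensityValidation:
    def test_unnormalized_density_rejected(self):
        grid = Grid.uniform(2.0, 50)
        with pytest.raises(ValueError):
            NumberDensity(grid=grid, values=np.ones(50))
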