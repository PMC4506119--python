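# hetpop

Heterogeneous cell-population models of lac operon bistability.

`hetpop` models an isogenic *E. coli* population whose cells carry the lac
operon induction circuit, and computes how the population-average LacY
(lac permease) expression ⟨[Y]⟩ depends on the extracellular inducer (IPTG)
concentration when cell-to-cell heterogeneity is included.  It is aimed at
researchers in stochastic gene expression and population-balance modelling
who need the full bifurcation picture — stable and unstable branches, fold
(turning) points, hysteresis limits — for a stochastic population simulator
that has no closed-form equations.

The package implements, bottom to top:

* **Single-cell kinetics** — the mass-action lac operon network
  (operator–repressor binding, IPTG uptake, LacY-facilitated transport), its
  equilibrium reduction, the one-variable dimensionless rate
  R(x) = (πρ + x²)/(ρ + x²) − κx with repression strength
  ρ ∝ 1/[IPTG]², a chemical-Langevin closure for intrinsic noise with
  operator-fluctuation rate K and reference molecule number y\*, and an
  exact Gillespie SSA over the elementary reactions.
* **Constant-number Monte Carlo (CNMC)** — N cells evolving by the Langevin
  SDE between stochastic division events (hazard Γ(x) = (x/⟨x⟩)^m), with
  binary f/(1−f) partitioning and constant-N replacement; compiled with
  numba.
* **Deterministic cell population balance (DCPB)** — the number-density
  equation ∂n/∂t + ∂(R n)/∂x + Γn = 2∫Γ P n dx′ − n∫Γn dx, discretized
  conservatively and solved by damped Newton with pseudo arc-length
  continuation in ρ.
* **Equation-free coarse analysis** — restriction of populations to four
  inverse-CDF polynomial coefficients, lifting back to cell ensembles, the
  coarse time-stepper G_T, coarse Newton–Raphson, eigenvalue stability
  (|λ| vs the unit circle), arc-length continuation, healing-time
  diagnostics, and a branch-survival bisection that locates the stochastic
  bistability limits at small ensemble sizes.
* **Workbench** — YAML/JSON configuration, scenario runners for the
  bifurcation studies, synthetic fixture populations, CSV branch tables,
  and a `hetpop` command-line interface.

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.

## Worked example

```python
import numpy as np
from hetpop import (DivisionModel, Grid, build_constants, dcpb_continuation,
                    homogeneous_folds, rho_to_iex, steady_state_reduced)

constants = build_constants(pi=0.03, kappa=0.05)
print(f"calibrated transport rate k_t = {constants.k_t:.4f} 1/min")
print(f"repressor content R_T = {constants.R_T:.3f} nM")

for iex_uM in (15, 45):
    Y = steady_state_reduced(constants, iex_uM * 1e3)[0]
    print(f"single-cell steady LacY at {iex_uM} uM IPTG: {Y:.1f} nM")

folds = homogeneous_folds(pi=0.03, kappa=0.05)
iex = sorted(rho_to_iex(rho, constants) / 1e3 for rho, _ in folds)
print(f"homogeneous bistable IPTG interval: [{iex[0]:.1f}, {iex[1]:.1f}] uM")

diagram = dcpb_continuation(0.15, (0.04, 0.2), DivisionModel(m=3.0, f=0.5),
                            constants, Grid.stretched(4.0, 500),
                            compute_stability=False, newton_tol=1e-6)
lo, hi = sorted(diagram.fold_iex_uM)
print(f"population-balance (m=3) bistable interval: [{lo:.1f}, {hi:.1f}] uM")
```

prints

```
calibrated transport rate k_t = 0.7820 1/min
repressor content R_T = 2.021 nM
single-cell steady LacY at 15 uM IPTG: 16.0 nM
single-cell steady LacY at 45 uM IPTG: 399.5 nM
homogeneous bistable IPTG interval: [17.2, 26.9] uM
population-balance (m=3) bistable interval: [27.0, 37.4] uM
```

Reading the output: the transport rate k_t is calibrated once from the
anchor ρ(28.8 μM) = 0.09, and the total repressor pool R_T (≈ one molecule
per cell) follows from the 3 % promoter leakiness.  A single cell sits at
the uninduced level (≈ 16 nM LacY) at 15 μM IPTG and at the induced level
(≈ 400 nM) at 45 μM.  If every cell behaved like the average cell, both
states would coexist for IPTG between 17.2 and 26.9 μM; division and
partitioning heterogeneity with a sharp division rate (m = 3) shifts that
hysteresis window up to [27.0, 37.4] μM — heterogeneity makes the
population harder to induce.

The same analyses are available from the shell, e.g.

```bash
hetpop dcpb --rho-start 0.15 --rho-min 0.04 --rho-max 0.2 --out branch.csv
hetpop ef-newton --rho 0.09 --k 500 --y-star 50
hetpop scenario fig6 --scale 0.1 --out results/
```

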