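# prsvar

Quantitative analysis of cell-to-cell variability in single-cell
dual-reporter signaling data, built around the yeast pheromone response
system (PRS) but applicable to any system measured with one
pathway-inducible and one constitutive fluorescent reporter per cell.

Isogenic cells responding to the same ligand dose differ widely in their
output. `prsvar` separates that variability into its sources, calls
screen hits, clusters quantitative phenotypes, quantifies the shape of
single-cell trajectories, compares variability-versus-output curves
between strains, and provides resampling statistics for scored event
timings. A synthetic-data generator with known ground truth backs every
stage, so the whole pipeline is testable without any external data.

## The model and the statistics

Per-cell system output is modeled as the product of a pathway term and a
gene-expression term accumulated over the stimulation window ΔT:

    O_i = (L_i(αF) + λ_i) · (G_i + γ_i) · ΔT

where `L_i` is the cell's pathway capacity at pheromone dose αF (its
population mean follows a Hill curve of dose), `λ_i` is fast stochastic
fluctuation in pathway operation, `G_i` is the cell's general expression
capacity (read out by the constitutive reporter) and `γ_i` is fast
intrinsic expression noise. Variability is measured as the normalized
variance η²(X) = σ²(X)/⟨X⟩², and to small-noise order decomposes as

    η²(O) = η²(L) + η²(λ) + η²(G) + η²(γ) + 2ρ·η(L)·η(G)

Key estimators (module `prsvar.decomposition`):

- **O**, **G** — channel medians; transmitted signal **P = O/G**.
- **pathway variability** η²(P) + η²(γ) — the sample variance of the
  difference of the *mean*-normalized channels,
  σ²(r_i/⟨r⟩ − y_i/⟨y⟩): fluctuations shared through expression capacity
  cancel in the difference.
- **intrinsic noise** η²(γ) — the same difference variance computed from
  two reporters driven by identical promoters in the same cell.

Downstream stages:

- `prsvar.screen` — tail-quantile selection thresholds from reference
  replicates and hit-calling by five criteria codes (low/high output at
  the low dose, low/high pathway variability at the low dose, high
  pathway variability at the high dose).
- `prsvar.clustering` — the 10-measurement strain phenotype matrix
  (O, G, η²(O), η²(G), η²(P) at two doses), log₁₀ + row median-centering,
  Pearson-correlation distance, UPGMA, and cluster signatures.
- `prsvar.trajectories` — the progressive spread distribution (per
  timepoint, the width of the shortest interval containing half the
  cells' relative P values), its median the **MPS** with bootstrap CIs,
  and the **crookedness index** I_C = 1 − |net change|/total variation
  with threshold classification (default 0.3).
- `prsvar.curves` — piecewise-linear η²(P)-vs-P curves per strain, the
  **area between curves (ABC)** computed exactly by trapezoidal
  integration with crossing-point insertion, a cell-level resampling test
  for strain differences, and the rational fit η² = c₀ + c₁/P.
- `prsvar.events` — bootstrap mean/SD/CV ± SE, permutation tests against
  a reference group, and Fisher's exact test for category counts.
- `prsvar.simulate` — the ground-truth generator for snapshot
  populations, trajectories (with injectable "crooked" events) and whole
  screens with planted effects.

## Worked example

```python
import numpy as np
from prsvar import (SimulationParams, simulate_population,
                    decompose_population, mps, classify_crooked)
from prsvar.simulate import simulate_trajectories

params = SimulationParams(eta2_L=0.04, eta2_lambda=0.01, eta2_G=0.04,
                          eta2_gamma=0.005, rho=0.0,
                          lambda_mode="relative", seed=7)
cells = simulate_population(params, 10_000, dose_nM=20.0, twin_inducible=True)
d = decompose_population(cells)
print(f"P = O/G = {d.P:.2f}")
print(f"eta2(P) + eta2(gamma) = {d.eta2_P_plus_gamma:.4f}")
print(f"eta2(gamma)           = {d.eta2_gamma:.4f}")
print(f"eta2(P) corrected     = {d.eta2_P_corrected:.4f}")

times = np.arange(0.0, 301.0, 30.0)
tset, truth = simulate_trajectories(params.replace(seed=3), 100, times,
                                    crooked_frac=0.1, jump_magnitude=6.0)
res = mps(tset, n_boot=2000, seed=0)
_, summary = classify_crooked(tset, threshold=0.3)
print(f"MPS = {res.mps:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
print(f"crooked fraction = {summary['crooked_fraction']:.2f}")
```

prints

```
P = O/G = 7.14
eta2(P) + eta2(gamma) = 0.0554
eta2(gamma)           = 0.0050
eta2(P) corrected     = 0.0504
MPS = 0.262 (95% CI 0.190-0.306)
crooked fraction = 0.13
```

The population was generated with true pathway variability 0.05 and
intrinsic noise 0.005; the estimators recover both (0.0504 and 0.0050)
from 10,000 cells. The trajectory set had 13% of cells injected with a
transient pathway-rate excursion, and the crookedness classifier flags
exactly that fraction.

A command-line interface mirrors the library
(`prsvar simulate-cells | decompose | screen | cluster | trajectories |
compare | events | all`); see `prsvar --help`.

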