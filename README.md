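# turingmix

Reaction–diffusion pattern formation in an interacting (non-ideal)
two-species mixture. An activator `A` and an inhibitor `I` react through a
Hill–Langmuir production term with linear degradation, while their transport
is driven by gradients of exchange chemical potentials derived from a
Flory–Huggins free energy (interaction parameter `chi`, square-gradient
width `w`). The package provides:

- **`turingmix.core_model`** — thermodynamics (free energy, chemical
  potentials, Hessian), reaction kinetics, and the closed-form
  phase-separation thresholds `chi_plus = 1/phi0` (segregative spinodal) and
  `chi_minus` (associative binodal).
- **`turingmix.stability`** — linear stability analysis of the homogeneous
  state: dispersion relation, effective (cross-)diffusivity matrix, fastest
  growing mode, stability boundaries in `chi`, and the minimal
  pattern-supporting interaction `chi_star` by bisection.
- **`turingmix.simulator`** — conservative finite-difference integration on
  periodic 1D/2D grids: second-order stencils, staggered-grid fluxes with
  `D_i * phi_i` mobilities, explicit Euler with an automatic stable step.
  Compiled (numba) inner loops with a numpy reference path that tests hold
  to agreement.
- **`turingmix.metrics`** — pattern amplitude, spatial covariance, structure
  factor (radially averaged in 2D), dominant length scale, and power-law
  exponent fits.
- **`turingmix.experiments`** / **`turingmix.cli`** — parameter-plane scan
  drivers, 1D-vs-2D comparison, reduced-scale figure protocols, and the
  `turingmix` command-line interface.

All quantities are nondimensional: lengths in units of `w`, times in units
of `w**2 / D_A`, energies in units of `k_B T / nu`.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline checks (exact threshold value,
mass conservation, free-energy monotonicity, simulator-vs-LSA growth-rate
oracle, binodal cross-check, `k**-1/2` length scaling, regime signatures,
1D-vs-2D length transfer, threshold monotonicity). Simulation-heavy items
run at reduced desk scale; the full suite takes ~15–20 minutes on one CPU.

## Command line

```sh
# one simulation from a YAML/JSON config, final state to HDF5 (+ manifest)
turingmix simulate --config config.json --out run.h5

# pattern metrics of a stored state
turingmix metrics --in run.h5 --out metrics.csv

# stability boundaries (chi values where the LSA verdict flips)
turingmix stability --config config.json --axis h --axis-range 1 10 \
    --resolution 10 --out boundaries.csv

# two-axis parameter sweep (one seeded simulation + LSA verdict per cell)
turingmix scan --config config.json --axis1 chi:-12:8:9 --axis2 h:1:10:5 \
    --out scandir/

# reduced-scale reproduction of a published-figure protocol (1-5)
turingmix figures --which 3 --scale reduced --out figdir/
```

A config is a mapping with `params` (fields `phi0, chi, h, k, D_A, D_I, w`),
optional `grid` (`shape`, `dx`) and `sim` (`t_end`, `dt`, `seed`,
`noise_amplitude`, `snapshot_every`, `safety`, `early_stop`). Unknown keys
are rejected. Every command writes a JSON manifest next to its output;
rerunning with the same config and seed reproduces outputs bit-identically.

## Quick start (library)

```python
import numpy as np
from turingmix import (ModelParams, Grid, SimConfig, initial_condition,
                       simulate, dispersion_relation, pattern_metrics)

p = ModelParams(phi0=0.2, chi=1.0, h=5.0, k=0.1, D_I=10.0)
print(dispersion_relation(p).unstable)       # True: patterns expected

grid = Grid((512,), dx=1.0)
cfg = SimConfig(t_end=2000.0, seed=0)
res = simulate(initial_condition(p, grid, cfg), p, cfg)
print(pattern_metrics(res.state))            # amplitude, covariance, length
```
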