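# fibrilsorb

Phase-resolved analysis of water sorbed to a model cellulose nanofibril.

Water in contact with cellulose splits into two populations: bulk water,
and water sorbed to (or inside) the fibril, which diffuses several times
more slowly and exchanges with the bulk on a 10–100 ps timescale.  This
package implements the complete modelling workflow for quantifying that
behaviour from particle trajectories — for people studying nanocellulose
film swelling who want the trajectory-analysis machinery without
rerunning molecular dynamics:

* **fibril builder** — an idealized elementary fibril: a 6×6 grid of
  cellulose chains (52 glucose units each, 0.5190 nm rise, chains
  0.57 nm apart, alternating 43°/47° rotations), with surface-chain and
  dry-mass bookkeeping and GRO output;
* **sorbed/bulk classification** — a water oxygen is *sorbed* iff it
  lies inside the convex hull of the fibril's carbon point cloud,
  decided by Delaunay point location; plus k-nearest-neighbour
  water–cellulose distances and hull volume per frame;
* **phase-resolved diffusion** — every frame-to-frame step of every
  water is assigned a phase from its endpoint labels (WW bulk→bulk, CC
  sorbed→sorbed, WC/CW across the interface) and each phase's diffusion
  coefficient comes from the accumulated squared displacement:

  MSD_P = Σ (x_{t+Δt}−x_t)² + (y_{t+Δt}−y_t)² + (z_{t+Δt}−z_t)² = 6 D_P t_tot,P

  with t_tot,P = n_P Δt, Δt = 10 ps, plus a two-interval consistency
  check, an Arrhenius fit ln D = ln D₀ − E_A/(RT) and a linear D(T) fit;
* **residence and swelling statistics** — per-molecule total sorbed time
  and continuous residence runs, and the gravimetric swelling
  S = (W_t/W_O) × 100 % from the mean sorbed count and the fibril dry
  mass;
* **sorption isotherm models** — both published composite isotherms for
  nanocellulose films (Langmuir + Henry + clustering; Langmuir +
  Flory–Huggins + clustering, the implicit activity equation
  ln a = ln F + (1−F) + χ(1−F)² solved by bracketed root-finding), and
  the absolute-humidity arithmetic ρ = p/(R_v T) for conditioning
  states;
* **a trapping simulator** — two-regime Brownian dynamics (D_bulk,
  D_sorbed) in a periodic box with kinetic capture/escape at a convex
  trap region, providing trajectories with known ground truth so every
  stage above is testable end to end.

## Worked example

```python
import numpy as np
from fibrilsorb import build_fibril, surface_report
from fibrilsorb.simulate import default_recovery_config, simulate
from fibrilsorb.geometry import label_trajectory
from fibrilsorb.diffusion import partition_steps, estimate_D

rep = surface_report(build_fibril(), volume=354.0)
print(rep.n_surface_chains, round(rep.surface_fraction, 2), round(rep.density_given_volume, 1))
# 20 0.56 1.4        <- 20 of 36 chains on the surface; 1.4 g/cm^3

traj, truth = simulate(default_recovery_config(seed=1))   # 2,000 waters x 2,000 frames
steps = partition_steps(traj, label_trajectory(traj))
for phase in ("WW", "CC"):
    e = estimate_D(steps, phase)
    print(phase, round(e.D, 3))
# WW 3.686           <- bulk water, truth 3.7 x 1e-5 cm^2/s
# CC 0.598           <- sorbed water, truth 0.65 x 1e-5 cm^2/s (estimator
#                       reads slightly low inside a confining trap; see
#                       docs/methods.md)
```

The diffusion coefficients are reported in 10⁻⁵ cm²/s (1 nm²/ps = 10³ ×
10⁻⁵ cm²/s).  The bulk value is recovered to a fraction of a percent;
the sorbed value shows the documented confinement bias of the lag-1
estimator, still well inside the 10 % recovery band.

The same workflow is available as numbered drivers under `analysis/`
(build → simulate → classify → residence/swelling → diffusion →
isotherms), each writing its tables to `results/analysis/`, and as a CLI:

```
fibrilsorb run --seed 1 --out results/run     # full pipeline, YAML-configurable
fibrilsorb build-fibril --out fibril.gro
fibrilsorb validate my_config.yaml
```

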