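# Methods

## The system and what the package models

The object of study is a single cellulose elementary fibril in water.
The fibril is represented as a role-tagged point cloud: a 6×6 grid of 36
parallel chains, each 52 glucose units long (≈26.8 nm end to end at a
0.5190 nm rise per glucose — half the ~1.038 nm cellobiose repeat),
chains 0.57 nm apart and alternating between 43° and 47° rotations about
the chain axis.  The residue geometry is an idealized internal template
(six carbons on a puckered hexagonal ring, five oxygens at fixed
offsets, matching C6H10O5): every downstream analysis uses only carbon
and oxygen positions, so force-field-accurate coordinates would add
nothing.  Because the chain rotations are stated without an assignment
pattern, they are applied as a checkerboard; this is recorded so results
are deterministic.

Mass bookkeeping counts 162.14 g/mol per anhydroglucose plus one water
mass (18.02 g/mol) per chain for the condensation-polymer chain ends.
This gives a 36-chain dry mass of 5.05×10⁻¹⁹ g and, against the 354 nm³
reference fibril volume, a density of 1.4 g/cm³.  The ideal packing's
own convex hull is tighter (~260 nm³, 1.9 g/cm³): a freshly constructed
grid has none of the relaxation that swells a simulated fibril, which is
why density is reported against a supplied volume rather than the
builder's own hull.

## Sorbed/bulk classification

A water oxygen is *sorbed* iff it lies inside the convex hull of the
fibril carbon cloud, decided by point location in the Delaunay
triangulation of the carbons (scipy); points within 10⁻⁹ nm of a facet
count as inside.  This is a geometric, not an energetic, definition:
surface-adsorbed waters just outside the hull count as bulk.  An
optional distance-shell criterion (`shell_cutoff`, default off) exists
for sensitivity analysis only.  Geometry is non-periodic: the carbon
cloud must span at most half of every box edge, and the classification
refuses wider clouds.  A Monte-Carlo property test ties classification
and hull volume together: the sorbed fraction of uniform points times
the box volume reproduces the hull volume within sampling error.

## Phase-resolved diffusion

Each frame-to-frame displacement of each water (minimum-image unwrapped,
each component mapped into (−L/2, L/2]) is one step; the phase of a step
is the pair of endpoint labels: WW bulk→bulk, CC sorbed→sorbed, WC
bulk→sorbed, CW sorbed→bulk.  Phase conservation
n_WW+n_CC+n_WC+n_CW = (frames−1)×molecules holds exactly.  Per phase,

    MSD_P = Σ_steps |Δr|²  =  6 D_P t_tot,P ,   t_tot,P = n_P Δt ,

so D_P = MSD_P/(6 n_P Δt), converted as 1 nm²/ps = 10³ × 10⁻⁵ cm²/s.
Only lag-1 accumulation is used for reported values (a multi-lag MSD
curve is available as a diagnostic).  The quoted uncertainty is the
naive standard error of the per-step squared displacements propagated
through the estimator; steps are treated as independent, which
understates correlations near the trap boundary — it is a scale
indicator, not a rigorous confidence interval.  The two-interval check
re-applies the estimator to the first and second halves of each phase's
accumulated time (steps ordered by start time, ties by molecule) and
reports both values and their ratio.

Temperature dependence is summarized two ways: ordinary least squares of
D against T (°C), and an Arrhenius fit of ln D against 1/(RT_K) with
E_A = −slope, R = 8.314 J/(mol·K).  The Arrhenius form is the standard
ln D = ln D₀ − E_A/(RT); a sign test pins the convention.

## Residence times and swelling

Residence runs are maximal blocks of consecutive sorbed frames × Δt; a
single desorbed frame breaks a run (an optional `min_gap` bridges short
dropouts, default 0).  Totals obey the exchange identity Σ_molecules
total = Σ_frames count × Δt exactly.  Swelling uses the modelling
convention S = (W_t/W_O)×100 % with W_t the sorbed-water mass (count ×
18 g/mol / N_A) and W_O the fibril dry mass; the worked 1,000-water
example on the 36-chain fibril gives S = 5.9 % by direct arithmetic.
The experimental weighing form S = (W_t/W_O − 1)×100 % is a separate
entry point of the same formula object.  The sorbed-count series can be
smoothed with a centred moving average (window truncated at the
boundaries; n = 100 is the conventional display choice).

## Isotherm models and humidity states

Two published composite isotherms are implemented verbatim as printed,
selected by an explicit `variant` argument because their Langmuir and
clustering forms genuinely differ:

| term | park | hakalahti |
|---|---|---|
| Langmuir F_L | A_L B_L a/(1+B_L a), A_L=1, B_L=200 | A_L a/(1+B_L a), A_L=1.41, B_L=223 |
| mid-range | F_H = K_H a, K_H=13.7 | ln a = ln F + (1−F) + χ(1−F)², χ=0.67 |
| clustering F_C | K_C n aⁿ, K_C=18.2, n=11 | K_C aⁿ, n=10, K_C unstated → required argument |

Regime bounds follow the printed %RH columns (<10 / 10–60 / >60 for
park; <5 / 30–70 / >70 with the gaps tagged "unspecified" for
hakalahti).  Model outputs are treated as dimensionless uptake values;
the sources state no units.  The implicit Flory–Huggins equation has a
unique root in (0,1) for χ ≥ 0 and a < 1; it is found by bracketed
root-finding (Brent) on (10⁻¹², 1−10⁻¹²) with a tolerance far below the
10⁻¹⁰ contract, because the residual's slope grows like 1/F near small
roots; substituting the root back leaves a residual below 10⁻⁸ over
(a, χ) ∈ (0,1]×[0,2].

Absolute humidity is ρ = p/(R_v T_K), R_v = 461.5 J/(kg·K), with the
saturation pressure an input.  The two conditioning states (25 °C/80 %RH
at p_sat = 3.169 kPa; 39 °C/36 %RH at p_sat = 6.9969 kPa) both give
≈0.018 kg/m³, but from those printed factors the two values differ by
5.1 % (0.01842 vs 0.01749 kg/m³); tests assert the ~0.018 agreement at
that honest spread rather than a tighter one.

## The trapping simulator and its ground truth

Synthetic trajectories come from two-regime Brownian dynamics: per frame
interval Δt each particle takes a Gaussian step of per-axis variance
2DΔt with D = D_sorbed inside a static convex trap region and D = D_bulk
outside, wrapped into the periodic box.  Defaults mirror the 25 °C
reference state: D_bulk = 3.7×10⁻³ and D_sorbed = 0.65×10⁻³ nm²/ps
(i.e. 3.7 and 0.65 ×10⁻⁵ cm²/s), Δt = 10 ps.  Trapping is kinetic, not
energetic, so the ground truth is exact and tunable:

* a sorbed particle escapes with probability p_escape per step; a
  non-escaping step that would exit is folded back by billiard
  reflection at the first crossed facet; a successful escape always ends
  outside (the step is mirrored outward if needed), so the per-step exit
  probability is exactly p_escape;
* a bulk particle inside the capture shell (the region dilated by
  `capture_shell` = 0.3 nm along its facet normals) is captured with
  probability p_capture per step and pulled inside; uncaptured bulk
  particles never enter — boundary-crossing steps are folded back out.

With exact per-step transition probabilities, a well-mixed two-state
argument predicts the stationary sorbed fraction
f = r/(r+p_escape), r = p_capture·V_shell/(V_box−V_region).  The
prediction's ingredients are exact (and tested at binomial precision),
but the prediction itself ignores that escaped particles re-enter the
shell and are preferentially recaptured; measured occupancy runs ~20 %
above it, and the occupancy test carries a 30 % band documenting that
approximation.  Defaults p_escape = 0.2 (mean continuous residence
≈50 ps, consistent with picosecond-scale surface exchange) and
p_capture = 0.105 were chosen so the full-scale stationary prediction
gives ≈10³ sorbed waters of ~69,600 — the reference system's sorbed
population.

`emulate_paper_system(scale)` reproduces the reference geometry at
reduced scale: box proportional to (8.956, 9.198, 31.438) nm (volume
2590 nm³ and ~69,600 waters at scale 1), bulk density 803 kg/m³ at
every scale (18 g/mol bookkeeping), 10 ps frames, duration 4500 frames
scaled.  The fibril grid and chain length are capped so the carbon cloud
spans at most half of each box edge — the classification stage's
non-periodic-geometry contract; the reference fibril itself (26.9 of
31.4 nm axially) would violate it, so the emulated fibril is the scaled
stand-in, not a literal copy.

### Confinement bias and the choice of trap region

The lag-1 estimator measures chord displacements of *reflected* Brownian
motion.  Near a wall the folded chord is shorter than the free step, so
D̂ in a confining region reads low — a property of confined diffusion,
not an implementation error.  Its size grows with σ_s·S/V of the region
(σ_s = √(2 D_sorbed Δt) ≈ 0.11 nm).  For the full-size fibril
(~3.4 nm across) the effect is ~1–2 %; for the miniature hull that fits
a 2,000-water box (~1 nm across) it reaches ~10 %, and capture events
injecting particles at the wall concentrate the sorbed population there,
adding to it.  Quantitative recovery therefore uses the least-confining
trap the geometry contract allows — `trap="block"`, a centred block
spanning half of every box edge — where the bias is ≈−8 % for D_CC and
negligible for D_WW, inside the 10 % recovery band with stable
seed-to-seed behaviour.  The fibril-hull trap remains the default for
exercising the classification geometry; its sorbed-phase estimate is
asserted qualitatively (below truth, right order of magnitude) rather
than against the 10 % band.  WC/CW estimates on synthetic data are
dominated by the capture/escape relocation moves and are reported but
not interpreted.

## Problem sizes

Default test and acceptance scale: 2,000 waters × 2,000 frames (20 ns of
synthetic dynamics) for the quantitative recovery runs, ~2,000 waters ×
600 frames for the analysis drivers, 2,000 × 300 for the 20-seed
recovery sweep, and a few hundred particles for property tests — sizes
at which every statistical assertion has comfortable margin while the
whole suite runs in well under a minute on a laptop.  All randomness
flows from a single integer seed per run; repeated runs are
byte-identical.

## What the synthetic data does and does not show

The generator emulates the reference system's geometry, density,
recording interval, diffusion contrast and sorbed population, with exact
ground truth.  It does not model hydrogen bonding, water structuring at
the surface, fibril flexibility, or any energetics — so passing
recovery tests validates the *analysis machinery* (classification,
phase partitioning, estimators, residence statistics), not the physics
of cellulose–water interaction.  Real sorbed water need not follow
two-state kinetics with memoryless capture/escape, and real MD
diffusion coefficients carry finite-size and force-field effects the
synthetic truth has no analogue for.

## Known limitations

* The sorbed definition is the carbon-cloud convex hull: surface
  adsorption outside the hull is invisible to it.
* Lag-1 MSD only; subdiffusive or caged dynamics would need the
  multi-lag diagnostic and a different estimator.
* Uncertainties on D are naive SEs over steps.
* The GRO writer emits a single frame; multi-frame exchange uses the
  internal tabular CSV format (binary trajectory formats are out of
  scope for the tested surface).
* Isotherm parameters are taken as published constants; fitting them to
  uptake data is out of scope.
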