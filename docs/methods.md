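# Methods

## Dynamic time warping

`compute_dtw` solves the standard dynamic program
`D(i,j) = |a_i − b_j| + min(D(i−1,j−1), D(i−1,j), D(i,j−1))` and backtracks
one optimal path. Choices that matter:

- **Local cost** is the scalar absolute difference; **path cost** is the
  unnormalised sum along the path. No squaring, no path-length
  normalisation, no step weights. Distances therefore scale with series
  length and with the units of the data.
- **Step pattern** is the symmetric `{(1,0), (0,1), (1,1)}` set implied by
  the boundary/monotonicity/continuity constraints.
- **Tie-break** in backtracking prefers the diagonal predecessor, then the
  vertical one. Optimal paths are frequently non-unique (any plateau of
  equal costs); the tie-break makes the returned path, and everything
  downstream of it, deterministic.
- **Sakoe-Chiba band**: cells with `|i − j| > band` are inadmissible. For
  unequal lengths the same `|i − j| ≤ band` rule applies, which requires
  `band ≥ |T_a − T_b|`; the band is interpreted as a half-width (60 means
  ±60 minutes around the diagonal). Band-constrained distances are
  non-increasing in the band radius and reach the exact distance at
  `band = T − 1`.
- The inner DP is numba-compiled; a 1440×1440 pair runs in tens of
  milliseconds, which is what makes per-neuron DTW inside the training loop
  practical.
- `dtw_oracle` enumerates *every* admissible path (capped at length 8) and
  is the independent correctness reference for the DP in the test suite.
  An approximate/coarsened DTW is deliberately not provided: on series of
  this length the exact banded DP is already fast, and approximation would
  add an error source to the training rule.

## The three SOM variants

All variants share the online loop: per iteration one input day is drawn
(shuffled cycling, seeded), its BMU found, and every neuron with kernel
weight `h ≥ kernel_cutoff` updated. They differ in the metric and the
update:

| variant | BMU metric | update |
|---|---|---|
| `euclidean` | Euclidean | timestamp-aligned (`W + εh(x − W)`) |
| `dtw_match` | DTW | timestamp-aligned |
| `dtw_full` | DTW | DTW-aligned |

The DTW-aligned update computes, for each pair `(t, t̄)` on the warping path
between the neuron's weights and the input, the convex combination
`v = W_t + εh·(x_t̄ − W_t)` and places it at the pseudo-timestamp
`t̃ = t + εh·(t̄ − t)`. Moving the timestamp by the *same* fraction as the
value is the one rule that makes the two limits exact: `εh = 0` returns the
weights unchanged, `εh = 1` returns the input exactly (values and
timestamps both arrive at the input's point set, and the boundary pairs pin
`t̃ = 0` and `T−1`). Many-to-one alignments give duplicate `t̃`; their
values are averaged. The irregular `(t̃, v)` point set is then linearly
interpolated back onto the integer grid. Because every step is a convex
combination or an interpolation, trained weights can never leave the data
range — a property the suite checks.

Each updated neighbour computes its **own** DTW path to the input rather
than reusing the BMU's path: the neighbour's weights are what is being
aligned, and reusing the BMU's path would move the neighbour along an
alignment that may be wrong for it.

### Schedules and defaults

The training schedules are not dictated by the method; the defaults are:

- learning rate `ε`: exponential decay 0.5 → 0.01 over the run;
- kernel width `σ`: exponential decay `max(R,C)/2` → 0.2. The floor matters:
  a Gaussian lattice kernel with `σ = 0.5` still couples adjacent neurons at
  `h = exp(−2) ≈ 0.135`, which permanently biases each neuron toward its
  neighbours' clusters (a two-cluster 1×2 map settles ~0.07 away from the
  cluster levels). At `σ = 0.2` the nearest-neighbour weight is
  `exp(−12.5) ≈ 4·10⁻⁶`, so the final phase is effectively winner-only and
  neurons converge onto their own clusters;
- iterations: 3000 (convergence plateau on day-length panels; the emitted
  per-iteration BMU-distance trace lets users verify the plateau);
- `kernel_cutoff = 10⁻³` skips negligible updates (pure efficiency;
  per-step effect below the cutoff itself);
- kernel space: lattice distance by default. The kernel can instead use the
  DTW distance between weight vectors (`kernel_space="dtw_weightspace"`);
  this is provided as an option because it is a defensible reading of
  "the kernel uses DTW distance", but the lattice kernel is what gives the
  map its 2-D topology (season gradients across the grid, Moore-neighbour
  distance), so it is the default.

BMU ties break to the lowest row-major neuron index; `init="sample"` draws
distinct input days as initial weights (with replacement plus a warning when
the grid outnumbers the data), `init="random"` draws uniformly over the
data range.

## Preprocessing chain

Fixed order: median-smooth each sensor stream (kernel 3, nearest-value edge
padding, missing values skipped by the window and left missing) → average
duplicate co-located sensors minute-wise (missing only when all sensors are
missing) → gap rule → min-max scaling → daily windowing → outcome matching.

- **Gap rule**: missing runs shorter than 60 minutes with observed values on
  both sides are linearly interpolated; runs of 60 minutes or longer are
  left missing and reported. The boundary case (exactly 60) is assigned to
  truncation. Runs touching a stream boundary are never extrapolated.
- **Scaling**: pollutant groups are mapped onto [0, 1] using the global
  min/max of the whole (location, variable) group — across all sites and
  days — so between-day amplitude differences survive. Temperature stays in
  native units by default (`scale_temperature=True` to override);
  weight-space quantities for temperature maps are therefore in °C.
- **Windowing**: non-overlapping 1440-minute windows anchored at 20:00
  (aligning with evening symptom questionnaires) and ending 19:59 the next
  day; any window with a missing or absent minute is dropped, so every
  daily observation has exactly 1440 finite values. Season labels are
  meteorological (DJF/MAM/JJA/SON) by window-start month.
- **Outcome matching**: inner join on (site, window-start date); duplicate
  outcome rows per site-date are an error; unmatched days keep a missing
  label and remain available for clustering.

## Evaluation metrics

- **Quantization error**: `sqrt(mean_i ||x_i − W_BMU(i)||²)` with the
  full-series Euclidean norm, *always*, regardless of which metric trained
  the map — the variants are only comparable on a common scale. The phrase
  "RMS error of moving each input to its cluster centroid" also admits a
  per-timestamp RMSE; that reading is available as
  `per_timestamp=True` (it divides each squared norm by `T`). "Centroid"
  is the BMU's weight vector (standard SOM usage), not the member mean.
- **Moore-neighbour distance**: mean Euclidean weight distance from each
  neuron to its existing ≤8 lattice neighbours, averaged over neurons;
  lower = smoother topology.
- **Cluster entropy** (bits): both the occupancy-weighted within-neuron
  label entropy (0 for pure neurons, ≤ log₂(#labels)) and the joint
  (neuron, label) entropy (≤ log₂(#neurons·#labels)) are reported. Purity
  numbers in the literature are sometimes quoted on scales exceeding
  log₂(#labels), which only the joint form can reach, so neither form is
  privileged.
- **Outcome fractions**: per neuron, positives / outcome-known assigned
  days; a neuron with no outcome-known days reports an *empty* fraction,
  never 0 — absence of evidence is not a zero rate.
- **Grid-size tuning** returns the (neuron count, QE) curve; the annotated
  elbow is a max-curvature suggestion, not a decision.

## Synthetic generator

The generator emulates the structure the method targets, with known ground
truth per site-day-variable:

- **Temperature**: noon-peaked half-sinusoid (sunrise 06:00, 12 h of
  daylight) on the 20:00-anchored grid, baseline/amplitude per
  meteorological season (winter −2 ± 6 °C through summer 22 ± 14 °C);
  indoor = outdoor baseline +3 °C with 0.4× amplitude.
- **PM2.5**: 5 µg/m³ baseline plus a Poisson number (default rate 2/day) of
  Gaussian-shaped spikes (SD 20 min, amplitude Uniform(20, 60) µg/m³)
  centred near 07:30 and 18:30 with Gaussian clock jitter (SD 20 min) —
  cooking-like events whose timing moves day to day. Spike timing
  parameters are free configuration, not calibrated to any study.
- **Warp**: every day passes through a random monotone piecewise-linear
  time map (4 interior knots at equal spacing, displacements
  Uniform(−w, +w) minutes, endpoints pinned, strict monotonicity enforced
  by rejection). Maximum feature displacement is `w` (default 30 min).
- **Noise/missingness**: additive Gaussian noise; Poisson-count gaps per
  day, 70% shorter than an hour and 30% longer, exercising both branches of
  the gap rule.
- **Outcome**: Bernoulli with logit linear in standardized daily spike
  count and indoor-PM daily SD (coefficients in config), so
  exposure-outcome coupling strength is tunable.
- One seeded generator per call; identical configs are byte-identical.

What it does **not** emulate: indoor-outdoor infiltration physics, sensor
drift or calibration error, autocorrelated (non-white) noise, weekday/
weekend structure, or a continuum of day shapes — seasons switch discretely
at month boundaries, so seasonal clusters are unrealistically separable.
Tests passing on this generator show the algorithmic properties (alignment,
shape preservation, determinism), not field performance.

## What the comparisons do and do not show

On warped-prototype data the DTW-aligned rule demonstrably (test suite,
majority over 10 seeds) keeps the trained weights' variance closer to the
input variance and retains ≥ 0.8× of a prototype peak that timestamp
averaging flattens. Quantization error, however, structurally favours
timestamp training on clean synthetic prototype data: for any fixed
assignment of days to neurons the timestamp-wise mean minimizes the
Euclidean QE, and Euclidean training converges to approximately those
means, while the DTW rule preserves sharp shapes and pays the full
elementwise misalignment penalty for every warped member. Both variants
recover the correct partition on such data, so the Euclidean variant's QE
is at or below the DTW variant's across every synthetic setting we swept
(spike widths 4–16 samples × warps 4–16 samples, and smooth seasonal
curves). A QE advantage for the DTW rule requires data where elementwise
similarity actively mis-partitions days — a regime real sensor panels may
occupy but this generator's clean, balanced prototypes do not. The
corresponding acceptance test states the QE-ordering claim as-is and
currently fails; it is retained deliberately rather than weakened.

## Problem sizes

The test suite runs day-length (T = 1440) series wherever the claim is
about minute-level data (banded-approximation quality, preprocessing), and
T = 144 (10-minute resolution) with M = 200 days for the training-loop
comparisons — full-year minute-level training runs are minutes of compute
and belong in application code, not unit tests; the package's own demo
config trains on 365 minute-level days in ~20 s.
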