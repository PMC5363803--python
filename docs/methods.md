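# Methods

## Excitable-lattice model

Each cell of a rectangular island is a two-variable Aliev–Panfilov
oscillator with excitation `u` (voltage-like, dimensionless, resting near
0 and peaking near 1) and recovery `v`:

```
du_ij/dt = k u_ij (1 − u_ij)(u_ij − a) − u_ij v_ij + c_ij + Φ (u_{i−1,j} + u_{i+1,j} + u_{i,j−1} + u_{i,j+1} − 4 u_ij)
dv_ij/dt = ε(u_ij) (k u_ij − v_ij)
```

Defaults (`APParams`): `k = 10` (reaction rate), `a = 0.05` (excitation
threshold), `Φ = 400` (nearest-neighbour electrotonic coupling; the
strong-coupling regime where the action-potential wavelength far exceeds
the largest island), `ε = 1` for `u ≤ 0.05` and `0.1` above (fast recovery
relaxation at rest, slow during the plateau), leak `c_ij` drawn once per
simulation from `N(0.09, 0.22 × 0.09)`, and `t ∈ [0, 120]` model time
units.  Everything is dimensionless; mapping model time to seconds is an
explicit user calibration (`time_unit_s`) because the model itself fixes
no clock.

Choices where the continuous description leaves freedom:

- **ε at the switch point.** `ε(u)` is specified by strict inequalities on
  both sides of `u = 0.05`; we use `eps_low` for `u ≤ u_switch`.  The
  boundary has measure zero along any trajectory.
- **Boundaries.** "Non-absorbing" is implemented as no-flux (missing
  neighbours mirror the cell's own value), which conserves spatially
  uniform states; a `truncate` mode (missing neighbours contribute
  nothing, which leaks at edges) is available for comparison.
- **Leak truncation.** The Gaussian leak is clipped at zero; at 22% CV a
  negative draw has probability ~3×10⁻⁶ per cell and would be an
  unphysical sink.
- **Initial condition.** `u = v = 0`; the first 20% of the record is
  discarded before peak counting to skip the start-up transient.

## Integration

The lattice ODEs are integrated with an adaptive Bogacki–Shampine 2(3)
embedded pair (FSAL, scaled-RMS error norm with `rtol = 10⁻⁶`,
`atol = 10⁻⁹`, step factors clipped to [0.2, 5]), implemented as a
numba-jitted loop that advances a whole batch of replicate lattices at
once and emits cubic-Hermite dense output on a fixed grid (`dt_out =
0.02` by default).  At `Φ = 400` the scheme is stability-limited to steps
of order `1/(8Φ) ≈ 10⁻³`, so accuracy is effectively free there.  Two
independent oracles guard the integrator in the tests: scipy's RK23 (the
same pair) on identical trajectories, and a fixed-step RK4 at
`dt = 10⁻³`, which agrees with the adaptive solution to better than
`10⁻²` in `u` over the full time span on a 4×4 lattice.

## Beat-period read-out

The per-island intensity trace is `I(t) = ⟨u_ij(t)⟩`.  Peaks are local
maxima above 50% of the trace range, separated by at least a quarter of
the running median inter-peak interval, with parabolic sub-sample
refinement; the beat period is the interval between the last two peaks
(NaN, flagged not raised, if fewer than two exist).

## Size sweep and the fastest-cell null

The sweep simulates square islands of 1, 2, 4, 8, 12 and 16 cells per
side, 52 replicates each with `c_ij` resampled, and reports per-size mean
and standard deviation of the period.  The "no monotone trend" check
fits an OLS line to the six per-size means and asks whether the 95% t
confidence interval of the slope covers zero.

The extreme-value null draws `N = size²` i.i.d. intrinsic periods per
replicate — resampled from actual uncoupled single-cell simulations of
the same leak distribution — and takes the minimum: if the fastest
pacemaker set the island rate, the expected period would fall strictly
with island size.  The coupled model instead adopts (approximately) the
mean intrinsic rate, with variance shrinking like the number of cells.

## Conduction velocity and Φ calibration

A quiescent strip (`c = 0`) is stimulated by initializing `u = 1` in the
first columns; the half-max arrival time of each column-mean trace is
fitted against column index and the velocity is the inverse slope (cells
per model time unit; `cell_pitch_um = 62.5`, one pitch when 16 cells span
1 mm, converts to physical units given a time calibration).  Geometry
defaults scale with the diffusion length `ℓ = sqrt(Φ/k)`: ~2ℓ of
stimulus, measurement starting 3ℓ beyond it, ~10ℓ of fitted range —
with a fixed short strip the broad front at large Φ corrupts the √Φ
velocity scaling.  `calibrate_phi` bisects in log Φ until the simulated
velocity is within 5% of a target, relying on that monotone scaling.

## Synthetic movies

Pixel model: `background·exp(−t/τ_bleach)` everywhere (drift is dominated
by autofluorescence bleaching), plus `f0·(1 + ΔF/F_k(t))` on island `k`'s
pixels, plus static Gaussian aggregates, plus i.i.d. Gaussian noise.
Defaults: 500 Hz (voltage) / 100 Hz (calcium) frame rates, 20 s records,
background 200 counts with `τ = 100 s`, `f0 = 100` counts, noise SD 2
counts, per-island period jitter CV 0.05 with random phase — chosen once
as plausible for a cooled-CMOS wide-field recording of a bright reporter.
The pulse template is a product of sigmoidal upstroke and decay whose two
time constants are calibrated numerically so the measured width at half
maximum and 20–80% (voltage) or 30–70% (calcium) rise time match the
spec to ≲0.01%.  Aggregates *occlude* the reporter underneath
(`pixel = static + (1 − w)·signal`): additive-only blobs would leave every
pixel perfectly correlated with the island trace and no correlation-based
weighting could demote them.  Noise is additive Gaussian rather than
Poisson; on ΔF/F at these contrasts the distinction is second order.
Voltage and calcium are separate single-channel movies (sequential
acquisition), linked by shared island phases when needed.

What the generator does *not* emulate: optics (no PSF, no vignetting),
motion/contraction artifacts, correlated (1/f or line) camera noise,
within-island waveform gradients, and reporter-specific photophysics.
Pipeline recoveries on these movies therefore demonstrate correctness of
the algorithms under the stated nuisances, not robustness to every
artifact of real recordings.

## Movie analysis pipeline

One configuration drives all islands with no per-island intervention:

1. **Background.** Grayscale opening of the reference image with an
   elliptical element 1.2× the island width and 200 µm tall (for masking
   and QC), and subtraction of the mean trace over a cell-free annulus
   2–10 px around each island (for the time series) — the surround trace
   tracks the bleaching autofluorescence exactly.
2. **QC.** Islands are rejected when fluorescent-pixel coverage (absolute
   threshold, Otsu fallback) is below 0.8 or fewer than two beats are
   detected in any channel; reasons are logged.
3. **Baseline.** The beat period is estimated from the autocorrelation's
   first peak; minima of a lightly smoothed copy (moving average of 5% of
   the window) are located in half-overlapping windows 1.2× the period,
   and the baseline is the linear interpolation through those minimum
   points.  `ΔF/F = (F − b)/b` after a positivity check.  The smoothing
   before the minimum exists because the minimum of a noisy trace is
   biased low by ~2 noise SDs.
4. **Spike detection.** Schmitt trigger on the trace range: an event
   fires on a rising crossing of 50% having previously been below 20%;
   a trace with range below 0.05 ΔF/F yields no events.
5. **Beat parameters.** The trace is smoothed once with a symmetric
   3-frame moving average (crossing times unbiased).  Amplitude = peak
   minus the diastolic base (10th percentile of the pre-upstroke
   interval); APD30/50/70 run from the upstroke half-max crossing to
   70/50/30% of peak on the decay, linearly interpolated between frames;
   rise time is 20→80% (voltage) or 30→70% (calcium) of peak; upstroke
   rate is the mean of the three largest central differences.  The
   percentile base and trimmed maximum exist because a raw min/max on an
   8×8-pixel sub-island's noisy trace is biased by noise extremes — the
   subdivision control (below) exposed a 2–3% apparent size dependence
   from exactly that estimator bias.
6. **Pixel weighting.** Each pixel's trace is regressed on the unit-peak
   island pulse shape; the Pearson correlation clipped at zero is its
   weight (exponent 1), the regression slope over the pixel baseline is
   the pixel's own ΔF/F, and slope over the mean image is the sensitivity
   map.  Amplitude histograms exclude unresponsive pixels
   (ΔF/F < 0.2) from the mean.
7. **Aggregation.** Islands are reduced to their median over beats
   (robust to one malformed beat), then per-size mean, s.e.m. and the
   across-island period std are reported, with pairwise two-sided Welch
   t-tests between sizes (raw p-values, no multiplicity correction —
   consistent with reporting per-comparison tests).
8. **Subdivision control.** A large island's mask is tiled at each
   smaller island size and the complete pipeline reruns on every tile;
   on a spatially uniform synthetic 1 mm island no parameter shifts by
   more than ~1.6% (noiseless: identical to ~10⁻⁵), confirming the
   analysis carries no island-size bias of its own.

## Synthetic expression and axis projection

The generator plants, per gene, a baseline log₂ expression
(`N(≈5, 2)`, then anchored so a noiseless library totals 10⁶ TPM) and an
axis loading `λ_g ~ N(0, 1)`; a sample of a group at position `p` takes
`baseline + p·λ + N(0, 0.15)` in log₂ space, and columns are converted to
TPM and renormalized to 10⁶.  Because TPM is compositional — total output
is not encodable — a planted position must not be confounded with library
size: loadings are shifted so the position-0 and position-1 profiles have
equal total output, and each group's noiseless profile is centered to the
same library size before noise.  Without this closure-consistency the
renormalization injects a position-correlated per-sample constant that
contaminates the axis vector (on a 149-gene axis it inflated ‖d‖² by
~11% and attenuated a planted 58% separation to ~52%); with it, noiseless
recovery is exact.  Default group design: 4 CP and 4 Adult-CM reference
samples, 10 small-island and 11 confluent samples at positions 0.500 and
0.547 (a 4.7% separation), with an optional 149-gene subset whose
positions differ more strongly (0.30 vs 0.88, a 58% separation) while the
rest of the genome moves only the global 4.7%.

Analysis: genes with mean TPM ≥ 10 in at least one island group are
retained (the filter matters — unfiltered matrices include genes whose
log₂(TPM+1) values are compressed toward zero, attenuating any signal);
values are log₂(TPM+1); the axis is the per-gene difference of reference
group centroids (zero-fold-change genes dropped with a warning); each
sample's position is `((x − origin)·d)/(d·d)`, the unique linear statistic
sending the start centroid to 0 and the end centroid to 1, and invariant
to any per-gene offset shared across samples.  Group separations are
`100·(mean_B − mean_A)` with s.e.m. by independent-group propagation and
a two-sided Welch t-test (the test is a package choice; a specific test
is not dictated by the statistic itself).  Per-gene z-scoring across
samples is provided for visualization-style standardization; constant
genes are dropped with a warning.

## Problem sizes in the tests and acceptance script

The simulation criteria run at full scale (6 sizes × 52 replicates,
t ∈ [0, 120]; 16×16 synchrony; 4×4 solver oracle).  Movie-based checks
use compact recordings — single 100 µm islands at 5 µm/px, 8–10 s at
100–500 Hz, and a 1 mm island at 12.5 µm/px for the subdivision control —
which already exercise every pipeline stage; expression checks use the
full 6,328-gene, 29-sample default design.  All randomness is seeded;
identical seeds give bitwise-identical leak matrices, movies and
matrices.

## Known limitations

- The model time unit is uncalibrated by construction; conduction
  velocities in mm/s require a user-supplied seconds-per-unit factor.
- The fastest-cell null resamples simulated intrinsic periods; it does
  not model partial coupling between a pacemaker and a passive syncytium.
- The multi-region ("crab") pattern's bridge and gap dimensions are
  illustrative parameters, not published values.
- `subdivide_mask` tiles the island's bounding box; for non-square masks
  the outermost tiles may be partly empty.
- The expression generator works at TPM level only (no read counts, no
  differential-expression modelling); gene sets such as a 149-gene
  island-responsive list are inputs, not outputs, of this package.
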