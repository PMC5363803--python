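# islandcardio

Tools for studying how the geometry of micropatterned cardiomyocyte
islands shapes their electrophysiology and transcriptional maturity.
Human iPSC-derived cardiomyocytes grown on square fibronectin islands
(50 µm – 1 mm) form electrically coupled syncytia whose spontaneous
beating, optical voltage/calcium waveforms, and gene expression all vary
with island size.  This package implements the computational core of that
analysis for people working with wide-field optical electrophysiology and
bulk RNA-seq of patterned cultures:

- **`islandcardio.geometry`** — island layouts, raster masks, the
  perimeter-cell fraction `(n² − (n−2)²)/n²` of an `n × n` cell grid, and
  subdivision of large islands into synthetic small ones (analysis-bias
  control).
- **`islandcardio.apsim`** — heterogeneous Aliev–Panfilov lattices.  Each
  cell obeys

  ```
  du_ij/dt = k u_ij (1 − u_ij)(u_ij − a) − u_ij v_ij + c_ij + Φ·L[u]_ij
  dv_ij/dt = ε(u_ij) (k u_ij − v_ij)
  ```

  with `k = 10`, `a = 0.05`, a step recovery rate `ε` (1 below
  `u = 0.05`, 0.1 above), strong nearest-neighbour coupling `Φ ≈ 400`,
  and per-cell leak currents `c_ij ~ N(0.09, 22%)` that give each cell
  its own intrinsic pacemaker rate.  Beat periods are read from the
  lattice-mean trace `I(t) = ⟨u_ij(t)⟩`.  Includes the replicated
  island-size sweep, the "fastest cell" extreme-value null model,
  conduction-velocity measurement, and Φ calibration.
- **`islandcardio.synth`** — ground-truthed synthetic data: calibrated
  ΔF/F pulse templates, rendered fluorescence movies (photobleaching
  background, camera noise, signal-insensitive bright aggregates), and
  TPM matrices with groups planted at known positions along a
  differentiation axis.
- **`islandcardio.pipeline`** — movie → beat table: morphological-opening
  background, island QC, surround-trace subtraction, sliding-minimum
  photobleach correction, Schmitt-trigger spike detection, per-beat
  parameters (amplitude, APD30/50/70 at 30/50/70% of return to baseline,
  20–80% rise time, maximum upstroke rate), correlation-based pixel
  weighting with per-pixel sensitivity maps, and per-size aggregation.
- **`islandcardio.devaxis`** — transcriptome placement: TPM ≥ 10
  expressed-gene filtering, log₂(TPM+1), a cardiac-progenitor →
  adult-cardiomyocyte axis `d` from reference centroids, normalized
  projection `((x − origin)·d)/(d·d)` (CP ↦ 0, Adult ↦ 1), and group
  separations as a percentage of the axis with Welch tests.

## Worked example

`examples/` holds one short narrative script per capability.  For
instance, `python examples/02_simulation_size_sweep.py` prints (numbers
from an actual run):

```
Coupled-lattice sweep (8 replicates/size, t in model units):
   1x1  cells: period  14.95 +/- 1.42
   2x2  cells: period  14.36 +/- 1.26
   4x4  cells: period  14.06 +/- 0.20
   8x8  cells: period  14.20 +/- 0.36
Fastest-cell null (period = min of N intrinsic periods):
   1x1  cells: period  14.59 +/- 1.81
   8x8  cells: period  12.43 +/- 0.02
```

The coupled islands keep a size-independent mean period while the
island-to-island spread collapses — coupling averages the heterogeneous
pacemakers — whereas the fastest-cell null predicts ever-faster beating
with size.  `python examples/04_maturation_axis.py` ends with

```
Confluent cultures are 4.60% +/- 0.12% closer to Adult-CM than small
islands (Welch p = 1.5e-16; planted: 4.7%)
```

recovering a planted 4.7% shift along the maturation axis, and
`examples/03_waveform_pipeline.py` shows the movie pipeline recovering
amplitude/APD50/rise time to within a few percent under bleaching and
noise.

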