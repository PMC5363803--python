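"""Coupled-oscillator islands: why bigger islands do not beat faster.

Simulates heterogeneous Aliev-Panfilov lattices at a few island sizes
(scaled down from the full 52-replicate sweep for a quick demonstration)
and contrasts the result with the 'fastest cell' extreme-value null, in
which the quickest intrinsic pacemaker would set each island's rate.
"""

import numpy as np

from islandcardio import apsim

params = apsim.APParams()          # k=10, a=0.05, phi=400, c ~ N(0.09, 22%)
per_rep, summary = apsim.size_sweep(sizes=(1, 2, 4, 8), n_reps=8,
                                    params=params, seed=1)
print("Coupled-lattice sweep (8 replicates/size, t in model units):")
for _, row in summary.iterrows():
    print(f"  {int(row['size']):2d}x{int(row['size']):<2d} cells: "
          f"period {row['mean']:6.2f} +/- {row['std']:.2f}")
# The mean period barely moves with size, but the island-to-island spread
# collapses: coupling averages the heterogeneous pacemakers.

intrinsic = apsim.intrinsic_periods(200, params, seed=2)
print(f"\nIntrinsic single-cell periods: mean {np.nanmean(intrinsic):.2f}, "
      f"CV {np.nanstd(intrinsic) / np.nanmean(intrinsic):.2f}")

null = apsim.fastest_cell_null(sizes=(1, 2, 4, 8), n_reps=2000,
                               period_distribution=intrinsic, seed=3)
print("Fastest-cell null (period = min of N intrinsic periods):")
for _, row in null.iterrows():
    print(f"  {int(row['size']):2d}x{int(row['size']):<2d} cells: "
          f"period {row['mean']:6.2f} +/- {row['std']:.2f}")
# The null predicts a strictly falling period with island size -- the
# opposite of the coupled simulation (and of the experiment).

m = apsim.conduction_velocity(params=params)
print(f"\nConduction on a strip at phi=400: {m.velocity_cells_per_time:.1f} "
      f"cells/time unit (arrival-time fit R^2 = {m.r_squared:.4f})")
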