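"""Movie in, beat table out: the optical-electrophysiology pipeline.

Renders a synthetic voltage-imaging movie of one 100 um island (known
waveform, photobleaching background, camera noise), runs the full
analysis (surround-background subtraction, sliding-minimum baseline,
Schmitt-trigger spike detection, per-beat parameterization), and compares
the recovered parameters with the generator's ground truth.
"""

import numpy as np

import islandcardio as ic
from islandcardio import pipeline, synth

wf = synth.WaveformSpec(kind="voltage", period_s=1.1, amplitude=0.35,
                        apd50_s=0.30, rise_time_s=0.05, f0=100.0)
layout = ic.IslandLayout(shapes=[ic.Square(1, 100, (40, 40))],
                         pixel_size_um=5.0, field_um=(200, 200))
spec = ic.MovieSpec(layout=layout, waveform=wf, frame_rate_hz=500.0,
                    duration_s=8.0, background_level=200.0,
                    bleach_tau_s=100.0, noise_sd=2.0, seed=42)
movie, truth = ic.render_movie(spec)
print(f"Rendered movie: {movie.shape[0]} frames of "
      f"{movie.shape[1]}x{movie.shape[2]} px at 500 Hz")

beats, traces, _ = pipeline.analyze_movie(movie, truth.labels, "voltage",
                                          frame_rate_hz=500.0)
isl = truth.islands.iloc[0]
print(f"\nDetected {len(beats)} beats; recovered (true) parameters:")
for col, unit in (("amplitude", "dF/F"), ("apd50", "s"), ("rise_time", "s"),
                  ("max_upstroke_rate", "dF/F per s")):
    rec = beats[col].median()
    print(f"  {col:18s} {rec:8.4f} ({isl[col]:.4f}) {unit}")
# Median-over-beats recovery is within a few percent despite the bleaching
# background and shot-like noise.

# subtract the (bleaching) background trace, not a constant, before
# estimating per-pixel sensitivities
sur = pipeline.surround_mask(truth.labels, 1)
sur_trace = movie[:, sur].mean(axis=1, dtype=np.float64)
maps, _ = pipeline.pixel_weighting(movie - sur_trace[:, None, None].astype(np.float32),
                                   truth.labels == 1, traces[1].dff)
stats = pipeline.amplitude_statistics(maps.per_pixel_dff)
print(f"\nPer-pixel dF/F over {stats['n_pixels']} island pixels: "
      f"mean of responsive pixels = {stats['mean_responsive']:.3f} "
      f"({stats['n_responsive']} pixels >= 0.2)")
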