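"""Projecting sample groups onto a developmental maturation axis.

Generates a synthetic TPM matrix in which small-island and confluent
cultures sit at known positions between cardiac-progenitor (CP) and
adult-cardiomyocyte (Adult-CM) reference centroids, then recovers those
positions with the projection statistic: filter to expressed genes,
log-transform, draw the CP -> Adult-CM axis, and express the group
separation as a percentage of the full axis.
"""

import numpy as np

from islandcardio import devaxis, synth

tpm, truth = synth.synth_expression(seed=7)        # small at 0.500, confluent at 0.547
groups = truth["groups"]
print(f"TPM matrix: {tpm.shape[0]} genes x {tpm.shape[1]} samples "
      f"({dict(groups.value_counts())})")

detected = [devaxis.genes_detected(tpm[s]) for s in tpm.columns]
print(f"Genes detected at TPM > 10: {int(np.mean(detected))} +/- "
      f"{int(np.std(detected))} per sample")

keep = devaxis.filter_expressed(tpm, groups, groups=("small", "confluent"))
logm = devaxis.log_transform(tpm.loc[keep])
print(f"Expressed-gene filter (mean TPM >= 10 in either island group): "
      f"{len(keep)} genes retained")

axis = devaxis.define_axis(logm, groups.index[groups == "CP"],
                           groups.index[groups == "Adult-CM"])
pos = devaxis.project(logm, axis)
print("\nMean position along the CP -> Adult-CM axis (0 = CP, 1 = Adult):")
for g in ("CP", "small", "confluent", "Adult-CM"):
    print(f"  {g:10s} {pos[groups == g].mean():+.4f}")

delta, sem, p = devaxis.percent_closer(pos[groups == "small"],
                                       pos[groups == "confluent"])
print(f"\nConfluent cultures are {delta:.2f}% +/- {sem:.2f}% closer to "
      f"Adult-CM than small islands (Welch p = {p:.1e}; planted: 4.7%)")
# Geometry nudges the transcriptome only a few percent along the global
# maturation trajectory.
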