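"""Detect segregation distortion and correct the genetic map for selection.

Simulates a chromosome carrying two-locus gametic selection (retention 0.67
for the recurrent allele at one locus, 0.37 for the donor allele at the
other), flags the distorted markers with 2.33-sigma bands, estimates the
selection coefficients by the 16-genotype-class fit, and compares naive vs
corrected map length between the selected loci.
"""

import numpy as np

from heterochiasma import simulate as sim
from heterochiasma import distortion as dst
from heterochiasma.io import CODE_A, CODE_H

spec = sim.ChromosomeSpec(
    name="chr1", genetic_length=0.9, physical_length=18_000_000,
    marker_positions=tuple(np.linspace(1, 18_000_000, 9).astype(int)),
    centromere_span=(8_000_000, 10_000_000),
)
matrix = sim.simulate_population([spec], {"chr1": sim.GammaModel(1.0)}, 6000, seed=3)
sel = sim.SelectionModel(2_000_000, 16_000_000, s1=0.67, s2=0.37,
                         unfavored1=CODE_A, unfavored2=CODE_H)
kept = sim.apply_gametic_selection(matrix, sel, "chr1", seed=4)
print(f"{matrix.n_plants} gametes before selection, {kept.n_plants} after")

profile = dst.distortion_profile(kept)
flagged = profile.loc[profile["flagged"], ["marker", "freq_c"]]
print(f"flagged markers ({len(flagged)}):")
print(flagged.to_string(index=False))

l1, l2 = kept.marker_map.markers("chr1")[1], kept.marker_map.markers("chr1")[7]
print(f"marginal fitness at {l1}: {dst.estimate_single_locus_fitness(kept, l1):.3f}")
print(f"marginal fitness at {l2}: {dst.estimate_single_locus_fitness(kept, l2):.3f}")

s1, s2, _ = dst.fit_selection_coefficients(kept, l1, l2, grid_step=0.1)
print(f"jointly fitted selection coefficients: s1* = {s1:.2f}, s2* = {s2:.2f}")

corr = dst.corrected_map_length(kept, "chr1", l1, l2, s1, s2)
between = corr.iloc[1:7]
print(f"between-loci map: naive {between['cm_naive'].sum():.1f} cM, "
      f"corrected {between['cm_corrected'].sum():.1f} cM "
      f"(simulated truth 67.5 cM)")
# The joint fit recovers the generating coefficients where the marginal
# allele ratios are biased toward 1 by linkage between the selected loci.
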