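"""Relate the crossover landscape to genomic features.

Generates synthetic feature tracks with Arabidopsis-like centromere-to-
telomere gradients and 2 kb euchromatic-mark windows, infers heterochromatic
intervals (mean presence < 0.2), classifies hot/cold intervals against the
bp-weighted arm mean, and fits rate-feature regressions excluding the
heterochromatic intervals.
"""

import numpy as np

from heterochiasma import simulate as sim
from heterochiasma import mapping as mp
from heterochiasma import features as feat

spec = sim.ChromosomeSpec(
    name="chr1", genetic_length=1.0, physical_length=20_000_000,
    marker_positions=tuple(np.linspace(1, 20_000_000, 50).astype(int)),
    centromere_span=(9_000_000, 11_000_000),
)
matrix = sim.simulate_population([spec], {"chr1": sim.GammaModel(2.6)}, 1500, seed=8)
tracks, windows = sim.generate_feature_tracks(spec, seed=9)

intervals = mp.interval_table(matrix, "chr1")
het = feat.infer_heterochromatin(windows, intervals)
print(f"heterochromatic intervals: {het.sum()} of {len(intervals)}")
print(feat.heterochromatic_regions_bed(intervals, het).to_string(index=False))

classed = feat.classify_hot_cold(intervals, {"chr1": 10_000_000}, het)
print(f"hot intervals: {int(classed['hot'].sum())}, "
      f"cold intervals: {int(classed['cold'].sum())}")

for name in ("gc", "genes", "te", "cpg"):
    res = feat.associate_rate_feature(intervals["cm_per_mb"], tracks[name], exclude=het)
    print(f"rate ~ {name:<5} slope {res['slope']:+9.2f}  R2 {res['r2']:.3f}  p {res['p']:.3g}")
# With a flat simulated CO landscape the associations should be weak; real
# female maps inherit strong (indirect) GC/gene/TE correlations from the
# positional gradients of those features.
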