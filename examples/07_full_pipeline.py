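"""Run the full pipeline on a scaled-down study-shaped configuration.

simulate -> QC -> maps -> distortion -> interference -> features -> scaling,
with every stage seeded from one master seed.  The default configuration
mirrors the study design (5 chromosomes, ~1,500 plants, 380 markers, male
chromosome-1 selection); ``scale=0.2`` shrinks plants and markers for a
quick demonstration run.
"""

import json

from heterochiasma import pipeline as pl

cfg = pl.default_config(seed=123, scale=0.2)
cfg.correct_distortion = False  # the joint selection fit is the slow stage
report = pl.run_all(cfg, out_dir="scratch/pipeline_demo")

chr1 = report["chromosomes"]["chr1"]
print(f"plants: {report['n_plants_male']} male / {report['n_plants_female']} female")
print(f"chr1 male map: {chr1['male']['cM_switch_count']:.1f} cM, "
      f"nu = {chr1['male']['nu']:.2f}")
print(f"chr1 M/F ratio: {chr1['mf_ratio']:.2f}")
print(f"distortion-flagged markers (male): {report['distortion']['n_flagged_male']}")
print(f"M/F-significant intervals genome-wide: {report['n_mf_significant_intervals']}")
print(f"male scaling threshold: {report['scaling_male']['threshold']['L_thr_mb']:.1f} Mb")
print("full report written to scratch/pipeline_demo/report.json")
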