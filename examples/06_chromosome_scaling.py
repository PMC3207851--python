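"""Fit crossover number vs chromosome size and test the obligate-CO models.

Uses five Arabidopsis-sized chromosomes with male-like genetic lengths,
fits (i) the unconstrained line, (ii) the obligate-CO threshold model
L_G = 0.5 + a (L_Mb - L_thr), and (iii) the Li-Freudenberg special case
L_thr = 0, whose goodness-of-fit p-value tests that model.
"""

import numpy as np

from heterochiasma import scaling as sc

physical_mb = np.array([30.43, 19.70, 23.46, 18.59, 26.98])
# male-like genetic lengths (Morgans) generated on the threshold model
rng = np.random.default_rng(0)
variances = np.full(5, 4e-4)  # study-scale length-estimator variances
truth = 0.5 + 0.065 * (physical_mb - 13.9)
genetic = truth + rng.normal(0, np.sqrt(variances))

lin = sc.fit_linear(physical_mb, 2 * genetic)
print(f"linear fit (COs/bivalent vs Mb): slope {lin['slope']:.3f}, "
      f"intercept {lin['intercept']:.3f}, R2 {lin['r2']:.3f}")

thr = sc.fit_threshold_model(genetic, physical_mb, variances)
print(f"threshold model: a = {thr.slope:.4f} M/Mb, L_thr = {thr.threshold:.1f} Mb, "
      f"chi2 = {thr.chi2:.2f} (dof {thr.dof}), p = {thr.p_value:.3f}")

lif = sc.test_li_freudenberg(genetic, physical_mb, variances)
print(f"Li-Freudenberg (L_thr = 0): a = {lif.slope:.4f}, chi2 = {lif.chi2:.1f} "
      f"(dof {lif.dof}), p = {lif.p_value:.2e}")
# The threshold model fits (p well above 0.05) while the L_thr = 0 model is
# decisively rejected - every chromosome carries the obligatory CO and only
# the size excess above the threshold adds more.
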