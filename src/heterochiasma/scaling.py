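"""Chromosome-size scaling of crossover numbers.

Three fits of per-bivalent CO number (twice the genetic length in Morgans)
against chromosome physical size:

* unconstrained ordinary least squares (per-bivalent COs vs Mb or vs
  synaptonemal-complex length in um),
* the obligate-CO threshold model ``L_G = 0.5 + a (L_Mb - L_thr)``: every
  chromosome gets the obligatory CO (0.5 Morgan of gametic map), sizes above
  the threshold ``L_thr`` add COs linearly,
* the Li-Freudenberg special case ``L_thr = 0``.

Weighted fits use inverse-variance weights with the variance of each
chromosome's genetic length equal to the per-plant CO-count sample variance
divided by the number of plants; goodness of fit is the chi-squared survival
at ``dof = points - parameters``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ScalingFit", "fit_linear", "fit_threshold_model", "test_li_freudenberg"]


@dataclass(frozen=True)
class ScalingFit:
    slope: float  # a: Morgans per Mb (or per um)
    threshold: float  # L_thr in Mb (0 for the Li-Freudenberg case)
    chi2: float
    dof: int
    p_value: float

    @property
    def intercept(self) -> float:
        return 0.5 - self.slope * self.threshold


def fit_linear(sizes, co_counts) -> dict:
    """OLS of per-bivalent CO count on chromosome size; slope, intercept, R^2."""
    sizes = np.asarray(sizes, dtype=float)
    co_counts = np.asarray(co_counts, dtype=float)
    res = stats.linregress(sizes, co_counts)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
    }


def _weighted_ls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted straight-line fit; returns (slope, intercept, chi2)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    return slope, intercept, float((w * resid**2).sum())


def fit_threshold_model(genetic_lengths, physical_mb, variances) -> ScalingFit:
    """Fit ``L_G = 0.5 + a (L_Mb - L_thr)`` by weighted least squares.

    ``genetic_lengths`` in Morgans, ``physical_mb`` in Mb, ``variances`` the
    estimator variances of the genetic lengths (weights are their inverses).
    The model is linear in (slope, intercept); the threshold is recovered as
    ``L_thr = (0.5 - intercept) / a`` and satisfies ``L_G = 0.5`` Morgan at
    ``L_Mb = L_thr`` by construction.
    """
    y = np.asarray(genetic_lengths, dtype=float)
    x = np.asarray(physical_mb, dtype=float)
    w = 1.0 / np.asarray(variances, dtype=float)
    if len(y) < 2:
        raise ValueError("at least two chromosomes required")
    slope, intercept, chi2 = _weighted_ls(x, y, w)
    thr = (0.5 - intercept) / slope
    dof = len(y) - 2
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan
    return ScalingFit(float(slope), float(thr), chi2, dof, p)


def test_li_freudenberg(genetic_lengths, physical_mb, variances) -> ScalingFit:
    """Constrained fit with ``L_thr = 0``: ``L_G = 0.5 + a L_Mb``.

    One free parameter; the goodness-of-fit p-value at ``dof = points - 1``
    is the test of the model.
    """
    y = np.asarray(genetic_lengths, dtype=float) - 0.5
    x = np.asarray(physical_mb, dtype=float)
    w = 1.0 / np.asarray(variances, dtype=float)
    slope = float((w * x * y).sum() / (w * x * x).sum())
    resid = y - slope * x
    chi2 = float((w * resid**2).sum())
    dof = len(x) - 1
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan
    return ScalingFit(slope, 0.0, chi2, dof, p)
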