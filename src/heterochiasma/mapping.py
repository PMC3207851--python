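"""Genetic-map estimation from backcross genotypes.

Per-interval recombination fractions, two chromosome-length estimators
(interval sum with Haldane's map function, and per-plant crossover counting
across all markers), male/female ratio confidence intervals, physical
truncation analysis, and the male-vs-female length test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CODE_MISSING, GenotypeMatrix

__all__ = [
    "IntervalEstimate",
    "ChromosomeLength",
    "RatioEstimate",
    "interval_recomb_fraction",
    "interval_table",
    "haldane_distance",
    "chromosome_length_interval_sum",
    "chromosome_length_switch_count",
    "per_plant_co_counts",
    "mf_ratio_ci",
    "truncate_chromosome",
    "truncation_loss_table",
    "compare_lengths_ttest",
    "co_count_distribution",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """Recombination fraction of one adjacent-marker interval.

    ``r = N_r / N`` over plants with no missing data at either marker;
    ``se^2 = r (1 - r) / N``; the 95% CI is ``r +/- 1.96 se``.
    """

    chrom: object
    left: str
    right: str
    n_recombinant: int
    n_informative: int
    r: float
    se: float
    ci95: tuple
    span_bp: int

    @property
    def cm(self) -> float:
        return 100.0 * self.r

    @property
    def cm_per_mb(self) -> float:
        return self.cm / (self.span_bp / 1e6)


@dataclass(frozen=True)
class ChromosomeLength:
    """Chromosome genetic length in Morgans with its estimator variance."""

    chrom: object
    morgans: float
    variance: float
    n_plants: int
    method: str  # "interval-sum" | "switch-count"

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def ci95(self) -> tuple:
        h = 1.96 * self.se
        return (self.morgans - h, self.morgans + h)

    @property
    def relvar(self) -> float:
        return self.variance / self.morgans**2 if self.morgans > 0 else np.nan


@dataclass(frozen=True)
class RatioEstimate:
    """Male/female length ratio with a Gaussian-approximation CI.

    The relative variance of the ratio is the sum of the two relative
    variances (both lengths are well estimated).
    """

    f: float
    ci95: tuple


def _pair_counts(codes: np.ndarray, j: int, k: int) -> tuple[int, int]:
    a, b = codes[:, j], codes[:, k]
    ok = (a != CODE_MISSING) & (b != CODE_MISSING)
    n = int(ok.sum())
    nr = int((a[ok] != b[ok]).sum())
    return nr, n


def interval_recomb_fraction(matrix: GenotypeMatrix, chrom, left: str, right: str) -> IntervalEstimate:
    """Estimate r for the adjacent-marker interval (left, right).

    Plants missing at either marker are excluded from both the numerator and
    the denominator.  With no informative plants the estimate is undefined
    (NaN, flagged by the NaN CI).
    """
    names = matrix.marker_map.markers(chrom)
    j, k = names.index(left), names.index(right)
    if abs(j - k) != 1:
        raise ValueError(f"markers {left!r}, {right!r} are not adjacent on {chrom}")
    codes = matrix.codes(chrom)
    nr, n = _pair_counts(codes, j, k)
    pos = matrix.marker_map.positions(chrom)
    span = int(pos[k] - pos[j])
    if n == 0:
        return IntervalEstimate(chrom, left, right, 0, 0, np.nan, np.nan, (np.nan, np.nan), span)
    r = nr / n
    se = float(np.sqrt(r * (1 - r) / n))
    return IntervalEstimate(chrom, left, right, nr, n, r, se, (r - 1.96 * se, r + 1.96 * se), span)


def interval_table(matrix: GenotypeMatrix, chrom) -> pd.DataFrame:
    """All adjacent-marker interval estimates on one chromosome."""
    rows = []
    ivals = matrix.marker_map.intervals(chrom)
    codes = matrix.codes(chrom)
    pos = matrix.marker_map.positions(chrom)
    for j in range(len(pos) - 1):
        nr, n = _pair_counts(codes, j, j + 1)
        span = int(pos[j + 1] - pos[j])
        if n:
            r = nr / n
            se = np.sqrt(r * (1 - r) / n)
            lo, hi = r - 1.96 * se, r + 1.96 * se
            cm = 100.0 * r
        else:
            r = se = lo = hi = cm = np.nan
        rows.append(
            dict(
                chrom=chrom,
                left=ivals["left"].iloc[j],
                right=ivals["right"].iloc[j],
                left_bp=int(pos[j]),
                right_bp=int(pos[j + 1]),
                span_bp=span,
                n=n,
                n_recombinant=nr,
                r=r,
                se=se,
                ci_lo=lo,
                ci_hi=hi,
                cm=cm,
                cm_per_mb=cm / (span / 1e6) if n else np.nan,
            )
        )
    return pd.DataFrame(rows)


def haldane_distance(r) -> float:
    """Haldane's map function: d = -ln(1 - 2 r) / 2 Morgans, for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = -0.5 * np.log1p(-2.0 * r)
    return float(d) if d.ndim == 0 else d


def chromosome_length_interval_sum(matrix: GenotypeMatrix, chrom) -> ChromosomeLength:
    """Length estimator 1: sum of Haldane distances over adjacent intervals.

    The variance sums the per-interval delta-method variances
    ``(dd/dr)^2 se^2 = se^2 / (1 - 2r)^2``.
    """
    tab = interval_table(matrix, chrom)
    ok = tab["n"] > 0
    r = tab.loc[ok, "r"].to_numpy()
    se = tab.loc[ok, "se"].to_numpy()
    total = float(np.sum(haldane_distance(r)))
    var = float(np.sum((se / (1.0 - 2.0 * r)) ** 2))
    return ChromosomeLength(chrom, total, var, int(tab.loc[ok, "n"].max() if ok.any() else 0), "interval-sum")


def per_plant_co_counts(matrix: GenotypeMatrix, chrom, region_bp: tuple | None = None) -> np.ndarray:
    """Observable CO count per plant: A<->H switches along non-missing calls.

    Missing calls are transparent (the walk skips them); a double CO hidden
    inside a missing run is necessarily uncounted.  ``region_bp`` restricts to
    markers inside a (start, end) bp window.  Plants with fewer than two
    non-missing markers are dropped.
    """
    codes = matrix.codes(chrom)
    if region_bp is not None:
        pos = matrix.marker_map.positions(chrom)
        inside = (pos >= region_bp[0]) & (pos <= region_bp[1])
        codes = codes[:, inside]
    counts = []
    for row in codes:
        obs = row[row != CODE_MISSING]
        if obs.size < 2:
            continue
        counts.append(int((np.diff(obs) != 0).sum()))
    return np.asarray(counts, dtype=int)


def _counts_aligned(matrix: GenotypeMatrix, chrom) -> np.ndarray:
    """Per-plant switch counts aligned to plant order (0 when uninformative)."""
    codes = matrix.codes(chrom)
    out = np.zeros(codes.shape[0], dtype=int)
    for i, row in enumerate(codes):
        obs = row[row != CODE_MISSING]
        if obs.size >= 2:
            out[i] = int((np.diff(obs) != 0).sum())
    return out


def chromosome_length_switch_count(
    matrix: GenotypeMatrix, chrom, region_bp: tuple | None = None
) -> ChromosomeLength:
    """Length estimator 2: mean per-plant CO count (Morgans).

    Uses all markers at once, so it recovers events that adjacent-pair
    estimates miss when data are missing.  The estimator variance is the
    sample variance of the per-plant counts divided by the number of plants.
    """
    counts = per_plant_co_counts(matrix, chrom, region_bp)
    n = counts.size
    if n == 0:
        return ChromosomeLength(chrom, np.nan, np.nan, 0, "switch-count")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1) / n) if n > 1 else np.nan
    return ChromosomeLength(chrom, mean, var, n, "switch-count")


def mf_ratio_ci(male: ChromosomeLength, female: ChromosomeLength) -> RatioEstimate:
    """Ratio f = L_G(male) / L_G(female) with Gaussian 95% CI."""
    f = male.morgans / female.morgans
    rel = np.sqrt(male.relvar + female.relvar)
    h = 1.96 * f * rel
    return RatioEstimate(float(f), (float(f - h), float(f + h)))


def truncate_chromosome(matrix: GenotypeMatrix, chrom, end_fraction: float) -> GenotypeMatrix:
    """Drop markers in the terminal ``end_fraction`` of physical length per end.

    Genetic intervals overlapping the removed terminal regions disappear with
    their outer markers, so downstream estimates use only intervals wholly
    inside the central region.  Other chromosomes are untouched.
    """
    if not (0 <= end_fraction < 0.5):
        raise ValueError("end_fraction must lie in [0, 0.5)")
    if end_fraction == 0:
        return matrix
    pos = matrix.marker_map.positions(chrom)
    length = pos[-1] - pos[0]
    lo = pos[0] + end_fraction * length
    hi = pos[-1] - end_fraction * length
    keep_chrom = [m for m, p in zip(matrix.marker_map.markers(chrom), pos) if lo <= p <= hi]
    keep = [
        m
        for m in matrix.marker_map.marker_names
        if matrix.marker_map.chrom_of(m) != chrom or m in set(keep_chrom)
    ]
    return matrix.subset_markers(keep)


def truncation_loss_table(matrix: GenotypeMatrix, chrom, end_fraction: float) -> pd.DataFrame:
    """Observed vs expected CO loss after truncation, by per-plant CO class.

    Plants are classed by their full-chromosome CO count (1 CO, >= 2 COs);
    the observed loss is the fraction of each class's COs falling outside the
    retained central region, the expected loss is the genetic fraction of the
    map removed (class-independent under interference-free placement; with
    positive interference multi-CO plants lose more, because their COs sit
    disproportionately in the extremities).
    """
    full = _counts_aligned(matrix, chrom)
    truncated_matrix = truncate_chromosome(matrix, chrom, end_fraction)
    kept = _counts_aligned(truncated_matrix, chrom)
    total_full = chromosome_length_switch_count(matrix, chrom).morgans
    total_trunc = chromosome_length_switch_count(truncated_matrix, chrom).morgans
    expected_loss = 1.0 - total_trunc / total_full if total_full > 0 else np.nan
    rows = []
    for label, mask in (("1", full == 1), (">=2", full >= 2)):
        held = int(full[mask].sum())
        lost = held - int(kept[mask].sum())
        rows.append(
            dict(
                co_class=label,
                n_plants=int(mask.sum()),
                cos_full=held,
                cos_lost=lost,
                observed_loss=lost / held if held else np.nan,
                expected_loss=expected_loss,
            )
        )
    return pd.DataFrame(rows)


def compare_lengths_ttest(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    """Welch two-sample t-test on per-plant CO counts; returns the p-value."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.array_equal(a, b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def co_count_distribution(matrix: GenotypeMatrix, chrom, k_max: int = 3) -> pd.Series:
    """Counts of plants with 0, 1, ..., k_max-1 and >= k_max observable COs."""
    counts = per_plant_co_counts(matrix, chrom)
    labels = [str(k) for k in range(k_max)] + [f"{k_max}+"]
    vals = [int((counts == k).sum()) for k in range(k_max)] + [int((counts >= k_max).sum())]
    return pd.Series(vals, index=labels, name=f"{chrom}_co_classes")
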