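"""Segregation distortion: detection, selection coefficients, map correction.

In a backcross the two parental alleles should segregate 1:1 at every marker.
Gametic selection at one or two loci distorts the observed frequencies; with
two selected loci it also biases recombination-fraction estimates for the
intervals between them (single-locus selection provably does not).

The correction models selection as post-meiotic gamete filtering with
retention probabilities ``s1``, ``s2`` for the unfavored allele at each locus
(``s1 s2`` jointly, no epistasis).  For each marker interval (Mi, Mi+1)
between the selected loci L1, L2, ordering L1 < Mi < Mi+1 < L2 defines three
consecutive intervals whose recombination rates (r12, r23, r34) determine the
16 four-locus genotype frequencies under the Haldane (no-interference) model;
gametic selection re-weights and re-normalizes them.  Fitting the observed
16-class counts by weighted chi-squared recovers the bias-free middle rate
r23; summing the per-interval chi-squareds and minimizing over (s1, s2)
infers the selection coefficients themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import optimize

from .io import CODE_A, CODE_H, CODE_MISSING, GenotypeMatrix
from . import mapping

__all__ = [
    "SixteenClassFit",
    "distortion_profile",
    "estimate_single_locus_fitness",
    "predict_16_genotype_freqs",
    "predict_class_freqs",
    "observed_class_counts",
    "fit_interval_rates",
    "fit_selection_coefficients",
    "corrected_map_length",
]


@dataclass(frozen=True)
class SixteenClassFit:
    """Fitted recombination rates of the three intervals L1-Mi-Mi+1-L2."""

    rates: tuple  # one rate per consecutive interval (3 when loci distinct)
    chi2: float
    target_index: int  # which fitted rate is the (Mi, Mi+1) interval

    @property
    def r_target(self) -> float:
        return self.rates[self.target_index]


def distortion_profile(matrix: GenotypeMatrix, alpha_band: float = 2.33) -> pd.DataFrame:
    """Per-marker parental-allele frequencies with 99% no-distortion bands.

    ``n_c`` / ``n_l`` count the recurrent (A) and donor (H) alleles; under no
    distortion the A frequency is 0.5 with standard error
    ``s^2 = 1 / (4 (n_c + n_l))``.  A marker is flagged when its frequency
    falls outside ``0.5 +/- 2.33 s`` (two-sided 1% level).  Bands vary
    marker-to-marker with the number of valid calls.
    """
    rows = []
    for chrom in matrix.marker_map.chromosomes:
        codes = matrix.codes(chrom)
        names = matrix.marker_map.markers(chrom)
        pos = matrix.marker_map.positions(chrom)
        n_c = (codes == CODE_A).sum(axis=0)
        n_l = (codes == CODE_H).sum(axis=0)
        tot = n_c + n_l
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(tot > 0, n_c / tot, np.nan)
            half = alpha_band * np.sqrt(1.0 / (4.0 * tot))
        for j in range(len(names)):
            rows.append(
                dict(
                    chrom=chrom,
                    marker=names[j],
                    pos=int(pos[j]),
                    n_c=int(n_c[j]),
                    n_l=int(n_l[j]),
                    freq_c=freq[j],
                    half_width=half[j],
                    flagged=bool(tot[j] > 0 and abs(freq[j] - 0.5) > half[j]),
                )
            )
    return pd.DataFrame(rows)


def estimate_single_locus_fitness(matrix: GenotypeMatrix, marker: str) -> float:
    """Relative fitness s of the minor allele at one marker.

    Under single-locus gametic selection the surviving allele ratio is
    ``1 : s`` (favored : unfavored), so ``s`` is estimated as the minor/major
    allele-count ratio.
    """
    chrom = matrix.marker_map.chrom_of(marker)
    codes = matrix.codes(chrom)
    j = matrix.marker_map.markers(chrom).index(marker)
    col = codes[:, j]
    n_c = int((col == CODE_A).sum())
    n_l = int((col == CODE_H).sum())
    if max(n_c, n_l) == 0:
        raise ValueError(f"no calls at marker {marker!r}")
    return min(n_c, n_l) / max(n_c, n_l)


def _haplotypes(m: int) -> np.ndarray:
    return np.array(list(product((0, 1), repeat=m)), dtype=np.int8)


def predict_class_freqs(
    rates, s1: float, s2: float, unfavored1: int = CODE_A, unfavored2: int = CODE_H
) -> np.ndarray:
    """Post-selection genotype-class frequencies for an ordered locus chain.

    ``rates`` are the recombination fractions of the ``m - 1`` consecutive
    intervals between ``m`` ordered loci; selection acts at the first locus
    (retention ``s1`` for allele ``unfavored1``) and the last (``s2`` for
    ``unfavored2``).  Classes are indexed by the haplotype in binary order
    (allele at the first locus is the most significant bit; 0 = A, 1 = H).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any((rates < 0) | (rates >= 0.5)):
        raise ValueError("recombination rates must lie in [0, 0.5)")
    m = len(rates) + 1
    haps = _haplotypes(m)
    switch = haps[:, :-1] != haps[:, 1:]
    pre = 0.5 * np.prod(np.where(switch, rates, 1.0 - rates), axis=1)
    w = np.ones(len(haps))
    w[haps[:, 0] == (1 if unfavored1 == CODE_H else 0)] *= s1
    w[haps[:, -1] == (1 if unfavored2 == CODE_H else 0)] *= s2
    post = pre * w
    return post / post.sum()


def predict_16_genotype_freqs(
    r12: float, r23: float, r34: float, s1: float = 1.0, s2: float = 1.0,
    unfavored1: int = CODE_A, unfavored2: int = CODE_H,
) -> np.ndarray:
    """16-class frequencies for distinct loci L1 < Mi < Mi+1 < L2."""
    return predict_class_freqs((r12, r23, r34), s1, s2, unfavored1, unfavored2)


def observed_class_counts(matrix: GenotypeMatrix, chrom, loci_markers: list[str]) -> np.ndarray:
    """Counts of the 2^m genotype classes at the given ordered markers.

    Plants missing at any of the loci are excluded.
    """
    names = matrix.marker_map.markers(chrom)
    idx = [names.index(mk) for mk in loci_markers]
    sub = matrix.codes(chrom)[:, idx]
    ok = np.all(sub != CODE_MISSING, axis=1)
    sub = sub[ok]
    m = len(idx)
    weights = 2 ** np.arange(m - 1, -1, -1)
    cls = sub @ weights
    return np.bincount(cls, minlength=2**m).astype(float)


def _chi2(observed: np.ndarray, freqs: np.ndarray) -> float:
    n = observed.sum()
    exp = n * freqs
    mask = exp > 0
    if np.any(~mask & (observed > 0)):
        return np.inf
    d = observed[mask] - exp[mask]
    return float((d * d / exp[mask]).sum())


def _naive_rates(observed: np.ndarray, m: int) -> np.ndarray:
    haps = _haplotypes(m)
    rates = np.empty(m - 1)
    for k in range(m - 1):
        rec = haps[:, k] != haps[:, k + 1]
        rates[k] = observed[rec].sum() / observed.sum()
    return np.clip(rates, 1e-4, 0.499)


def fit_interval_rates(
    observed: np.ndarray, s1: float = 1.0, s2: float = 1.0,
    unfavored1: int = CODE_A, unfavored2: int = CODE_H,
    target_index: int | None = None,
) -> SixteenClassFit:
    """Fit the consecutive-interval rates to observed genotype-class counts.

    Minimizes the Pearson chi-squared between observed and predicted class
    counts at fixed (s1, s2).  ``observed`` has length ``2^m``; ``m - 1``
    rates are fitted (box-constrained L-BFGS-B from the naive pairwise
    estimates).  ``target_index`` marks which interval is the one being
    corrected (default: the middle one).
    """
    observed = np.asarray(observed, dtype=float)
    m = int(np.log2(len(observed)))
    if 2**m != len(observed):
        raise ValueError("observed counts length must be a power of 2")
    if observed.sum() <= 0:
        raise ValueError("no observations")
    x0 = _naive_rates(observed, m)

    def objective(rates):
        return _chi2(observed, predict_class_freqs(rates, s1, s2, unfavored1, unfavored2))

    res = optimize.minimize(
        objective, x0, method="L-BFGS-B",
        bounds=[(1e-6, 0.499999)] * (m - 1),
    )
    if target_index is None:
        target_index = (m - 1) // 2
    return SixteenClassFit(tuple(float(v) for v in res.x), float(res.fun), target_index)


def _interval_locus_chain(names: list[str], i: int, j1: int, j2: int) -> tuple[list, int]:
    """Ordered locus chain for interval (names[i], names[i+1]) between loci j1 < j2.

    When an interval endpoint coincides with a selected locus the chain
    collapses (fewer classes).  Returns (marker chain, target interval index).
    """
    chain = sorted({j1, i, i + 1, j2})
    target = chain.index(i)
    return [names[k] for k in chain], target


def fit_selection_coefficients(
    matrix: GenotypeMatrix,
    locus1: str,
    locus2: str,
    unfavored1: int = CODE_A,
    unfavored2: int = CODE_H,
    grid_step: float = 0.05,
    refine: bool = True,
) -> tuple[float, float, pd.DataFrame]:
    """Infer (s1*, s2*) and re-fit corrected rates between two selected loci.

    For each candidate (s1, s2) every marker interval between L1 and L2 is
    fitted by :func:`fit_interval_rates`; the summed chi-squared is minimized
    over a ``grid_step`` grid on (0, 1]^2, then refined locally.  Returns the
    fitted coefficients and a per-interval table of naive vs corrected rates
    at the optimum.
    """
    chrom = matrix.marker_map.chrom_of(locus1)
    if matrix.marker_map.chrom_of(locus2) != chrom:
        raise ValueError("selected loci must be on the same chromosome")
    names = matrix.marker_map.markers(chrom)
    j1, j2 = names.index(locus1), names.index(locus2)
    if j1 >= j2:
        raise ValueError("locus1 must precede locus2")
    spans = [(i, *_interval_locus_chain(names, i, j1, j2)) for i in range(j1, j2)]
    counts = [observed_class_counts(matrix, chrom, chain) for _, chain, _ in spans]

    def total_chi2(s):
        s1, s2 = s
        if not (0 < s1 <= 1 and 0 < s2 <= 1):
            return np.inf
        tot = 0.0
        for (_, _, target), obs in zip(spans, counts):
            tot += fit_interval_rates(obs, s1, s2, unfavored1, unfavored2, target).chi2
        return tot

    grid = np.arange(grid_step, 1.0 + 1e-9, grid_step)
    best, best_val = None, np.inf
    for s1 in grid:
        for s2 in grid:
            v = total_chi2((s1, s2))
            if v < best_val:
                best, best_val = (s1, s2), v
    if refine:
        res = optimize.minimize(
            total_chi2, np.asarray(best), method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4},
        )
        if res.fun <= best_val:
            best = tuple(np.clip(res.x, 1e-3, 1.0))
    s1_star, s2_star = float(best[0]), float(best[1])

    rows = []
    for (i, chain, target), obs in zip(spans, counts):
        fit = fit_interval_rates(obs, s1_star, s2_star, unfavored1, unfavored2, target)
        naive = mapping.interval_recomb_fraction(matrix, chrom, names[i], names[i + 1])
        rows.append(
            dict(
                chrom=chrom, left=names[i], right=names[i + 1],
                r_naive=naive.r, r_corrected=fit.r_target, chi2=fit.chi2,
            )
        )
    return s1_star, s2_star, pd.DataFrame(rows)


def corrected_map_length(
    matrix: GenotypeMatrix,
    chrom,
    locus1: str,
    locus2: str,
    s1: float,
    s2: float,
    unfavored1: int = CODE_A,
    unfavored2: int = CODE_H,
) -> pd.DataFrame:
    """Selection-corrected per-interval map for one chromosome.

    Intervals between (L1, L2) get corrected rates from the multi-class fit
    at (s1, s2); intervals outside keep their naive estimates (single-locus
    selection does not bias them).  Corrected genetic distances use Haldane's
    map function; the chromosome total is the column sum of ``cm_corrected``.
    """
    names = matrix.marker_map.markers(chrom)
    j1, j2 = names.index(locus1), names.index(locus2)
    rows = []
    for i in range(len(names) - 1):
        naive = mapping.interval_recomb_fraction(matrix, chrom, names[i], names[i + 1])
        if j1 <= i < j2 and not (s1 == 1.0 and s2 == 1.0):
            chain, target = _interval_locus_chain(names, i, j1, j2)
            obs = observed_class_counts(matrix, chrom, chain)
            fit = fit_interval_rates(obs, s1, s2, unfavored1, unfavored2, target)
            r_corr = fit.r_target
        else:
            r_corr = naive.r
        rows.append(
            dict(
                chrom=chrom,
                left=names[i],
                right=names[i + 1],
                r_naive=naive.r,
                r_corrected=r_corr,
                cm_naive=100.0 * mapping.haldane_distance(min(naive.r, 0.499999))
                if not np.isnan(naive.r) else np.nan,
                cm_corrected=100.0 * mapping.haldane_distance(min(r_corr, 0.499999))
                if not np.isnan(r_corr) else np.nan,
            )
        )
    return pd.DataFrame(rows)
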