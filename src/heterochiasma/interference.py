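"""Crossover interference: Poisson-null tests and gamma-model MLE.

Under no interference, gametic CO counts per chromosome are Poisson with mean
equal to the genetic length in Morgans.  Under the gamma model, inter-CO
distances on the bivalent are Gamma(nu, 2 nu) Morgans; a gamete retains each
bivalent CO with probability p = 1/2 (thinning), and the likelihood of the
observed gametic CO positions is computed under the stationary thinned
renewal process:

* gap density between retained COs
  ``g(x) = sum_{j>=1} p (1-p)^(j-1) GammaPDF(x; j nu, 2 nu)`` (mean 1 Morgan),
* stationary first-event density ``h(x) = S_g(x)`` (mean gap is 1),
* censored final segment ``S_g(L - x_k)``,
* zero-CO gametes contribute ``integral_L^inf S_g(t) dt``, evaluated in
  closed form via ``integral_L^inf S_{a,b}(t) dt = (a/b) S_{a+1,b}(L)
  - L S_{a,b}(L)``.

``nu = 1`` reduces everything to the homogeneous Poisson process; ``nu``
relates to the counting model's parameter by ``nu = m + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CODE_MISSING, GenotypeMatrix
from . import mapping

__all__ = [
    "CoCountDistribution",
    "InterferenceFit",
    "poisson_expectation",
    "poisson_gof_test",
    "infer_gamete_co_positions",
    "infer_gamete_co_brackets",
    "gamete_co_position_lists",
    "gamete_co_bracket_lists",
    "thinned_gamma_loglik",
    "censored_gamma_loglik",
    "pattern_gamma_loglik",
    "gamete_pattern_data",
    "PatternData",
    "fit_nu",
    "fit_nu_censored",
    "fit_nu_pattern",
    "fit_chromosome_nu",
    "predicted_count_distribution",
]

_THIN_P = 0.5
# geometric truncation of the thinning series: (1-p)^J < 1e-18
_J_MAX = 60


@dataclass(frozen=True)
class CoCountDistribution:
    """Observed CO-count classes vs the Poisson null of mean ``lam``."""

    lam: float
    observed: np.ndarray  # classes 0, 1, ..., k_max+
    expected: np.ndarray
    p_value: float


@dataclass(frozen=True)
class InterferenceFit:
    """Maximum-likelihood gamma interference fit.

    ``nu`` is the fitted shape, ``ci95`` the profile-likelihood interval
    (log-likelihood within 1.92 of the maximum), ``m_equivalent = nu - 1``
    the counting-model parameter.
    """

    nu: float
    ci95: tuple
    loglik: float
    n_gametes: int
    n_cos: int

    @property
    def m_equivalent(self) -> float:
        return self.nu - 1.0


def poisson_expectation(lam: float, n_plants: int = 1, k_max: int = 3) -> dict:
    """Poisson class probabilities/counts and P(>= 2 COs) at mean ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    probs = stats.poisson.pmf(np.arange(k_max), lam)
    probs = np.append(probs, 1.0 - probs.sum())
    p_ge2 = float(1.0 - np.exp(-lam) * (1.0 + lam))
    return {
        "probs": probs,
        "counts": probs * n_plants,
        "p_ge2": p_ge2,
    }


def poisson_gof_test(counts: np.ndarray, lam: float | None = None) -> tuple[float, float]:
    """Pearson chi-squared test of per-plant CO counts against Poisson.

    ``counts`` are raw per-plant CO counts.  ``lam`` defaults to the sample
    mean (one parameter estimated from the data, so df = classes - 2).
    Upper classes are pooled until every expected count is >= 5.  Returns
    ``(chi2, p_value)``.
    """
    counts = np.asarray(counts, dtype=int)
    n = counts.size
    if lam is None:
        lam = float(counts.mean())
    k_hi = int(counts.max()) + 1
    obs = np.bincount(counts, minlength=k_hi + 1).astype(float)
    exp = stats.poisson.pmf(np.arange(k_hi + 1), lam) * n
    exp[-1] = n - exp[:-1].sum()  # tail mass
    # pool from the top until all expected >= 5 (keep at least 2 classes)
    while len(exp) > 2 and exp[-1] < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    if np.array_equal(obs, exp):
        return 0.0, 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = max(len(exp) - 2, 1)
    return chi2, float(stats.chi2.sf(chi2, df))


def infer_gamete_co_positions(calls: np.ndarray, marker_gen: np.ndarray) -> np.ndarray:
    """CO positions (Morgans) of one gamete by midpoint imputation.

    Each A<->H switch between consecutive non-missing calls is placed at the
    midpoint of its bracketing marker pair (missing runs are transparent).
    """
    calls = np.asarray(calls)
    obs = np.flatnonzero(calls != CODE_MISSING)
    if obs.size < 2:
        return np.empty(0)
    vals = calls[obs]
    sw = np.flatnonzero(np.diff(vals) != 0)
    return 0.5 * (marker_gen[obs[sw]] + marker_gen[obs[sw + 1]])


def infer_gamete_co_brackets(calls: np.ndarray, marker_gen: np.ndarray) -> np.ndarray:
    """Bracketing genetic interval of each CO of one gamete, shape (k, 2).

    Like :func:`infer_gamete_co_positions` but retains the full bracketing
    flank pair instead of collapsing it to the midpoint, for the
    interval-censored likelihood.
    """
    calls = np.asarray(calls)
    obs = np.flatnonzero(calls != CODE_MISSING)
    if obs.size < 2:
        return np.empty((0, 2))
    vals = calls[obs]
    sw = np.flatnonzero(np.diff(vals) != 0)
    return np.stack([marker_gen[obs[sw]], marker_gen[obs[sw + 1]]], axis=1)


def _estimated_marker_gen(matrix: GenotypeMatrix, chrom) -> np.ndarray:
    """Marker genetic coordinates from the data: cumulative Haldane distances."""
    tab = mapping.interval_table(matrix, chrom)
    d = mapping.haldane_distance(np.nan_to_num(tab["r"].to_numpy()))
    return np.concatenate([[0.0], np.cumsum(d)])


def gamete_co_position_lists(matrix: GenotypeMatrix, chrom) -> tuple[list, float]:
    """Midpoint-imputed CO positions per plant plus the map length (Morgans)."""
    marker_gen = _estimated_marker_gen(matrix, chrom)
    codes = matrix.codes(chrom)
    lists = [infer_gamete_co_positions(row, marker_gen) for row in codes]
    return lists, float(marker_gen[-1])


def gamete_co_bracket_lists(matrix: GenotypeMatrix, chrom) -> tuple[list, float]:
    """Bracketing-interval lists per plant plus the map length (Morgans)."""
    marker_gen = _estimated_marker_gen(matrix, chrom)
    codes = matrix.codes(chrom)
    lists = [infer_gamete_co_brackets(row, marker_gen) for row in codes]
    return lists, float(marker_gen[-1])


def _shapes_weights(nu: float):
    j = np.arange(1, _J_MAX + 1)
    w = _THIN_P * (1.0 - _THIN_P) ** (j - 1)
    return j * nu, w


def _gap_pdf(x: np.ndarray, nu: float) -> np.ndarray:
    shapes, w = _shapes_weights(nu)
    scale = 1.0 / (2.0 * nu)
    flat = np.asarray(x, dtype=float).reshape(-1)
    out = stats.gamma.pdf(flat[:, None], shapes[None, :], scale=scale) @ w
    return out.reshape(np.shape(x))


def _gap_sf(x: np.ndarray, nu: float) -> np.ndarray:
    shapes, w = _shapes_weights(nu)
    scale = 1.0 / (2.0 * nu)
    flat = np.asarray(x, dtype=float).reshape(-1)
    out = stats.gamma.sf(flat[:, None], shapes[None, :], scale=scale) @ w
    return out.reshape(np.shape(x))


def _zero_event_prob(L: float, nu: float) -> float:
    """P(no retained CO on [0, L]) = integral_L^inf S_g(t) dt (mean gap 1)."""
    shapes, w = _shapes_weights(nu)
    scale = 1.0 / (2.0 * nu)
    means = shapes * scale
    tail = means * stats.gamma.sf(L, shapes + 1, scale=scale) - L * stats.gamma.sf(
        L, shapes, scale=scale
    )
    return float(np.clip(tail @ w, 1e-300, 1.0))


def thinned_gamma_loglik(co_position_lists, L: float, nu: float) -> float:
    """Log-likelihood of gametic CO positions under the thinned gamma model."""
    if not nu > 0:
        raise ValueError("nu must be positive")
    firsts, gaps, tails, n_zero = [], [], [], 0
    for pos in co_position_lists:
        pos = np.asarray(pos, dtype=float)
        if pos.size == 0:
            n_zero += 1
            continue
        if pos.min() < -1e-9 or pos.max() > L + 1e-9:
            raise ValueError("CO position outside [0, L]")
        firsts.append(pos[0])
        tails.append(L - pos[-1])
        if pos.size > 1:
            gaps.append(np.diff(pos))
    ll = 0.0
    if firsts:
        # stationary first-event density S_g(x)/mean_gap with mean gap 1,
        # and the censored last segment S_g(L - x_k)
        edges = np.concatenate([np.asarray(firsts), np.asarray(tails)])
        ll += float(np.log(np.clip(_gap_sf(edges, nu), 1e-300, None)).sum())
    if gaps:
        g = _gap_pdf(np.concatenate(gaps), nu)
        ll += float(np.log(np.clip(g, 1e-300, None)).sum())
    if n_zero:
        ll += n_zero * np.log(_zero_event_prob(L, nu))
    return ll


class _GapTables:
    """Grid-tabulated gap density/survival of the thinned renewal process.

    Built once per (nu, L) likelihood evaluation; lookups are linear
    interpolation on a 4096-point grid (error ~1e-8 at Morgan scale), with
    closed forms for the zero-event probability and the within-segment pair
    mass ``c(d) = integral_0^d (d - t) g(t) dt`` (the probability weight of an
    ordered CO pair falling inside a span of length ``d``).
    """

    def __init__(self, nu: float, L: float, n_grid: int = 4096):
        self.nu = nu
        self.L = L
        self.shapes, self.w = _shapes_weights(nu)
        self.scale = 1.0 / (2.0 * nu)
        self.means = self.shapes * self.scale
        self.xs = np.linspace(0.0, L, n_grid)
        xg = self.xs.copy()
        xg[0] = 0.5 * xg[1]  # shape < 1 diverges at 0; evaluate off the origin
        pdf = stats.gamma.pdf(xg[:, None], self.shapes[None, :], scale=self.scale)
        sf = stats.gamma.sf(self.xs[:, None], self.shapes[None, :], scale=self.scale)
        self.g = pdf @ self.w
        self.s = sf @ self.w
        tail = self.means * stats.gamma.sf(L, self.shapes + 1, scale=self.scale) - L * sf[-1]
        self.zero = float(np.clip(tail @ self.w, 1e-300, None))
        # pair-mass table c(x) = integral_0^x (x - t) g(t) dt
        t1 = (self.means * stats.gamma.cdf(self.xs[:, None], self.shapes[None, :] + 1, scale=self.scale)) @ self.w
        self.c = self.xs * ((1.0 - sf) @ self.w) - t1

    def g_at(self, x):
        return np.interp(x, self.xs, self.g)

    def s_at(self, x):
        return np.interp(x, self.xs, self.s)

    def pair_mass(self, d):
        return np.interp(np.asarray(d, dtype=float), self.xs, self.c)

    def triple_mass(self, d, n_grid: int = 48):
        """``T3(d) = integral_0^d g(u) c(d - u) du``: mass of an ordered CO
        triple within a span of length d (the single-CO mass is d)."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        uniq, inv = np.unique(d, return_inverse=True)
        out = np.empty(len(uniq))
        for i, dd in enumerate(uniq):
            if dd <= 0:
                out[i] = 0.0
                continue
            u = np.linspace(0.0, dd, n_grid)
            out[i] = np.trapezoid(self.g_at(u) * self.pair_mass(dd - u), u)
        return out[inv]


def censored_gamma_loglik(bracket_lists, L: float, nu: float, n_nodes: int = 5) -> float:
    """Interval-censored log-likelihood of gametic CO patterns.

    Each gamete contributes the probability of its observed switch pattern:
    one CO somewhere inside each bracketing marker interval, integrated over
    the unknown positions with the stationary thinned-renewal density

    ``integral h(x1) g(x2-x1) ... g(xk-x_{k-1}) S_g(L-xk) dx1..dxk``

    evaluated by chained Gauss-Legendre quadrature (``n_nodes`` per
    interval).  This removes the upward interference bias that midpoint
    imputation introduces on coarse marker grids (quantized gaps cannot fall
    below one marker spacing, which mimics interference).  Crossover pairs
    hidden inside a single marker interval remain invisible to either
    likelihood.
    """
    if not nu > 0:
        raise ValueError("nu must be positive")
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    by_k: dict[int, list] = {}
    n_zero = 0
    for br in bracket_lists:
        br = np.asarray(br, dtype=float)
        if br.size == 0:
            n_zero += 1
            continue
        if br.min() < -1e-9 or br.max() > L + 1e-9:
            raise ValueError("bracket outside [0, L]")
        by_k.setdefault(br.shape[0], []).append(br)
    ll = 0.0
    if n_zero:
        ll += n_zero * np.log(_zero_event_prob(L, nu))
    for k, group in by_k.items():
        br = np.stack(group)  # (G, k, 2)
        mid = 0.5 * (br[..., 0] + br[..., 1])
        half = np.maximum(0.5 * (br[..., 1] - br[..., 0]), 1e-12)
        x = mid[..., None] + half[..., None] * nodes  # (G, k, q)
        w = half[..., None] * weights
        a = _gap_sf(x[:, 0, :], nu) * w[:, 0, :]  # stationary start (mean gap 1)
        for j in range(1, k):
            d = x[:, j, :, None] - x[:, j - 1, None, :]  # (G, q, q) >= 0
            p = _gap_pdf(np.maximum(d, 0.0), nu)
            a = np.einsum("guv,gv->gu", p, a) * w[:, j, :]
        lik = (a * _gap_sf(L - x[:, k - 1, :], nu)).sum(axis=1)
        ll += float(np.log(np.clip(lik, 1e-300, None)).sum())
    return ll


@dataclass
class PatternData:
    """nu-independent summary of a chromosome's switch patterns.

    ``groups`` holds, per observed CO count k, the stacked bracketing
    intervals (G, k, 2) and the gamete ids; the ``free_*`` arrays describe
    switch-free observation segments (candidate hosts for crossover pairs
    hidden by parity), with their anchoring observed-CO midpoints.
    """

    groups: list
    has_co: np.ndarray
    free_mid: np.ndarray
    free_span: np.ndarray
    free_gid: np.ndarray
    free_case: np.ndarray  # 0 interior, 1 before first CO, 2 after last, 3 zero-CO gamete
    anchor_l: np.ndarray
    anchor_r: np.ndarray
    n_gametes: int
    n_cos: int
    L: float


def gamete_pattern_data(matrix: GenotypeMatrix, chrom) -> PatternData:
    """Extract switch brackets and switch-free segments for every gamete."""
    marker_gen = _estimated_marker_gen(matrix, chrom)
    codes = matrix.codes(chrom)
    by_k: dict[int, list] = {}
    gid_by_k: dict[int, list] = {}
    free_mid, free_span, free_gid, free_case, anc_l, anc_r = [], [], [], [], [], []
    has_co = np.zeros(codes.shape[0], dtype=bool)
    n_cos = 0
    for gi, row in enumerate(codes):
        obs = np.flatnonzero(row != CODE_MISSING)
        if obs.size < 2:
            continue
        vals = row[obs]
        left = marker_gen[obs[:-1]]
        right = marker_gen[obs[1:]]
        switch = vals[:-1] != vals[1:]
        k = int(switch.sum())
        n_cos += k
        if k:
            has_co[gi] = True
            br = np.stack([left[switch], right[switch]], axis=1)
            by_k.setdefault(k, []).append(br)
            gid_by_k.setdefault(k, []).append(gi)
        sm = 0.5 * (left[switch] + right[switch])  # switch midpoints (anchors)
        n_before = np.cumsum(switch) - switch  # switches before each segment
        for seg in np.flatnonzero(~switch):
            span = right[seg] - left[seg]
            if span <= 0:
                continue
            free_mid.append(0.5 * (left[seg] + right[seg]))
            free_span.append(span)
            free_gid.append(gi)
            j = n_before[seg]
            if k == 0:
                free_case.append(3)
                anc_l.append(0.0)
                anc_r.append(0.0)
            elif j == 0:
                free_case.append(1)
                anc_l.append(0.0)
                anc_r.append(sm[0])
            elif j == k:
                free_case.append(2)
                anc_l.append(sm[k - 1])
                anc_r.append(0.0)
            else:
                free_case.append(0)
                anc_l.append(sm[j - 1])
                anc_r.append(sm[j])
    groups = [
        (k, np.stack(brs), np.asarray(gid_by_k[k], dtype=int))
        for k, brs in by_k.items()
    ]
    return PatternData(
        groups=groups,
        has_co=has_co,
        free_mid=np.asarray(free_mid),
        free_span=np.asarray(free_span),
        free_gid=np.asarray(free_gid, dtype=int),
        free_case=np.asarray(free_case, dtype=int),
        anchor_l=np.asarray(anc_l),
        anchor_r=np.asarray(anc_r),
        n_gametes=codes.shape[0],
        n_cos=n_cos,
        L=float(marker_gen[-1]),
    )


def pattern_gamma_loglik(data: PatternData, nu: float, n_nodes: int = 5) -> float:
    """Log-likelihood of the observed switch patterns under the gamma model.

    The base term integrates each observed CO over its bracketing marker
    interval (Gauss-Legendre chain, as in :func:`censored_gamma_loglik`).
    On top, every switch-free observation segment may hide an invisible CO
    pair (even counts leave no switch); its first-order probability weight is
    ``c(d) R`` with ``c(d)`` the within-segment pair mass and ``R`` the local
    event-pair density ratio at the segment midpoint given the neighbouring
    observed COs.  Without this term, maximum likelihood overestimates
    interference on marker data, because the shortest inter-CO gaps are
    systematically censored.
    """
    if not nu > 0:
        raise ValueError("nu must be positive")
    t = _GapTables(nu, data.L)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    base_log = np.zeros(data.n_gametes)
    base_log[~data.has_co] = np.log(t.zero)
    for k, br, gid in data.groups:
        mid = 0.5 * (br[..., 0] + br[..., 1])
        half = np.maximum(0.5 * (br[..., 1] - br[..., 0]), 1e-12)
        x = mid[..., None] + half[..., None] * nodes  # (G, k, q)
        w = half[..., None] * weights
        a = t.s_at(x[:, 0, :]) * w[:, 0, :]  # stationary first-event density
        for j in range(1, k):
            d = np.maximum(x[:, j, :, None] - x[:, j - 1, None, :], 0.0)
            a = np.einsum("guv,gv->gu", t.g_at(d), a) * w[:, j, :]
        lik = (a * t.s_at(data.L - x[:, k - 1, :])).sum(axis=1)
        base_log[gid] = np.log(np.clip(lik, 1e-300, None))
    corr_log = 0.0
    if data.free_mid.size:
        # hidden CO pair in a switch-free segment (first order per segment,
        # product across segments)
        m, case = data.free_mid, data.free_case
        al, ar = data.anchor_l, data.anchor_r
        R = np.empty(len(m))
        i0, i1, i2, i3 = (case == 0), (case == 1), (case == 2), (case == 3)
        eps = 1e-300
        R[i0] = t.g_at(m[i0] - al[i0]) * t.g_at(ar[i0] - m[i0]) / np.maximum(
            t.g_at(ar[i0] - al[i0]), eps
        )
        R[i1] = t.s_at(m[i1]) * t.g_at(ar[i1] - m[i1]) / np.maximum(t.s_at(ar[i1]), eps)
        R[i2] = t.g_at(m[i2] - al[i2]) * t.s_at(data.L - m[i2]) / np.maximum(
            t.s_at(data.L - al[i2]), eps
        )
        R[i3] = t.s_at(m[i3]) * t.s_at(data.L - m[i3]) / t.zero
        contrib = np.clip(R, 0.0, 1e8) * t.pair_mass(data.free_span)
        corr_log += float(np.log1p(np.clip(contrib, 0.0, None)).sum())
    if data.groups:
        # a switch segment can hide a CO triple (one observed switch, two
        # invisible): relative weight T3(d) / d against the single-CO mass
        spans = np.concatenate(
            [(br[..., 1] - br[..., 0]).ravel() for _, br, _ in data.groups]
        )
        spans = spans[spans > 0]
        rel3 = t.triple_mass(spans) / spans
        corr_log += float(np.log1p(np.clip(rel3, 0.0, None)).sum())
    return float(base_log.sum() + corr_log)


def fit_nu_pattern(data: PatternData) -> InterferenceFit:
    """Gamma-shape MLE from the full switch-pattern likelihood."""
    if data.n_cos < 2:
        raise ValueError("fewer than 2 COs in the data set; fit refused")
    return _profile_fit(
        lambda nu: pattern_gamma_loglik(data, nu), data.n_gametes, data.n_cos
    )


_NU_LO, _NU_HI = 0.05, 50.0


def _profile_fit(loglik, n_gametes: int, n_cos: int) -> InterferenceFit:
    """Maximize a 1-D log-likelihood in nu and profile the 95% CI.

    The search is bounded on log(nu) over [0.05, 50]; the CI is the set
    ``{nu : loglik(nu) >= max - 1.92}`` (chi-squared_1 95% cutoff), clipped
    to the search bounds.
    """
    res = optimize.minimize_scalar(
        lambda t: -loglik(float(np.exp(t))),
        bounds=(np.log(_NU_LO), np.log(_NU_HI)),
        method="bounded",
        options={"xatol": 1e-5},
    )
    nu_hat = float(np.exp(res.x))
    ll_max = -float(res.fun)
    cut = ll_max - 1.92

    def deficit(nu):
        return loglik(nu) - cut

    lo = _NU_LO if deficit(_NU_LO) > 0 else float(
        optimize.brentq(deficit, _NU_LO, nu_hat, xtol=1e-5)
    )
    hi = _NU_HI if deficit(_NU_HI) > 0 else float(
        optimize.brentq(deficit, nu_hat, _NU_HI, xtol=1e-5)
    )
    return InterferenceFit(nu_hat, (lo, hi), ll_max, n_gametes, n_cos)


def fit_nu(co_position_lists, L: float) -> InterferenceFit:
    """Gamma-shape MLE from known (or midpoint-imputed) CO positions."""
    n_cos = int(sum(len(p) for p in co_position_lists))
    if n_cos < 2:
        raise ValueError("fewer than 2 COs in the data set; fit refused")
    return _profile_fit(
        lambda nu: thinned_gamma_loglik(co_position_lists, L, nu),
        len(co_position_lists), n_cos,
    )


def fit_nu_censored(bracket_lists, L: float) -> InterferenceFit:
    """Gamma-shape MLE from interval-censored CO patterns."""
    n_cos = int(sum(len(b) for b in bracket_lists))
    if n_cos < 2:
        raise ValueError("fewer than 2 COs in the data set; fit refused")
    return _profile_fit(
        lambda nu: censored_gamma_loglik(bracket_lists, L, nu),
        len(bracket_lists), n_cos,
    )


def fit_chromosome_nu(matrix: GenotypeMatrix, chrom, method: str = "pattern") -> InterferenceFit:
    """Fit nu for one chromosome straight from a genotype matrix.

    ``method="pattern"`` (default) uses the full switch-pattern likelihood:
    observed COs integrated over their bracketing marker intervals plus the
    hidden-pair term for switch-free segments — the calibrated choice on
    marker data.  ``"censored"`` drops the hidden-pair term; ``"midpoint"``
    additionally fixes each CO at its bracket midpoint (fast, slightly
    interference-inflating on coarse maps).
    """
    if method == "pattern":
        return fit_nu_pattern(gamete_pattern_data(matrix, chrom))
    if method == "censored":
        lists, L = gamete_co_bracket_lists(matrix, chrom)
        return fit_nu_censored(lists, L)
    if method == "midpoint":
        lists, L = gamete_co_position_lists(matrix, chrom)
        return fit_nu(lists, L)
    raise ValueError(f"unknown method {method!r}")


def predicted_count_distribution(L: float, nu: float, k_max: int = 6, n_grid: int = 4096) -> np.ndarray:
    """Gametic CO-count distribution P(N = k) predicted by the model.

    Computed by numeric convolution on a grid: the density of the k-th
    retained CO is ``h * g^((k-1)*)`` with stationary first-event density
    ``h = S_g`` and gap density ``g``; ``P(N = k)`` integrates it against the
    censoring survival ``S_g(L - x)``.  Returns probabilities for
    ``k = 0 .. k_max`` (the last entry absorbs the tail remainder).
    """
    x = np.linspace(0.0, L, n_grid)
    dx = x[1] - x[0]
    h = _gap_sf(x, nu)  # stationary first-event density (mean gap 1)
    g = _gap_pdf(x, nu)
    sg = _gap_sf(L - x, nu)
    probs = [_zero_event_prob(L, nu)]
    dens = h.copy()
    for _ in range(1, k_max):
        probs.append(float(np.trapezoid(dens * sg, dx=dx)))
        dens = np.convolve(dens, g)[:n_grid] * dx
    probs.append(max(1.0 - sum(probs), 0.0))
    return np.asarray(probs)


def chromosome_co_summary(matrix: GenotypeMatrix, chrom) -> pd.Series:
    """Poisson-null test and gamma fit for one chromosome, as a Series."""
    counts = mapping.per_plant_co_counts(matrix, chrom)
    lam = float(counts.mean())
    chi2, p = poisson_gof_test(counts)
    fit = fit_chromosome_nu(matrix, chrom)
    return pd.Series(
        {
            "chrom": chrom,
            "n_plants": counts.size,
            "mean_cos": lam,
            "poisson_chi2": chi2,
            "poisson_p": p,
            "nu": fit.nu,
            "nu_ci_lo": fit.ci95[0],
            "nu_ci_hi": fit.ci95[1],
            "loglik": fit.loglik,
        }
    )
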