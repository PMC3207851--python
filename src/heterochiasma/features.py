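"""Genomic-feature context of the crossover landscape.

Heterochromatin inference from euchromatic histone marks, bp-weighted arm
mean rates, hot/cold interval classification, male/female per-interval
comparison with Benjamini-Hochberg control, and linear rate-feature and
positional-gradient associations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "infer_heterochromatin",
    "heterochromatic_regions_bed",
    "arm_mean_rates",
    "classify_hot_cold",
    "compare_intervals_mf",
    "associate_rate_feature",
    "positional_gradient",
]

HET_THRESHOLD = 0.2  # mean euchromatic-mark presence below this => heterochromatic


def infer_heterochromatin(
    windows: pd.DataFrame, intervals: pd.DataFrame, threshold: float = HET_THRESHOLD
) -> np.ndarray:
    """Flag heterochromatic intervals from 2 kb euchromatic-mark windows.

    ``windows`` is BED-like (``chrom``, ``start``, ``end`` 0-based half-open,
    ``presence`` = mean presence of either euchromatic mark).  An interval is
    heterochromatic iff the mean presence over windows whose centers fall in
    it is strictly below ``threshold`` (a mean of exactly 0.2 is euchromatic).
    """
    flags = np.zeros(len(intervals), dtype=bool)
    for c, wsub in windows.groupby("chrom"):
        centers = 0.5 * (wsub["start"].to_numpy() + wsub["end"].to_numpy())
        pres = wsub["presence"].to_numpy()
        rows = intervals.index[intervals["chrom"] == c]
        for idx in rows:
            lo = intervals.at[idx, "left_bp"]
            hi = intervals.at[idx, "right_bp"]
            inside = (centers >= lo) & (centers < hi)
            if inside.any():
                flags[intervals.index.get_loc(idx)] = pres[inside].mean() < threshold
    return flags


def heterochromatic_regions_bed(intervals: pd.DataFrame, het_mask) -> pd.DataFrame:
    """Merge flagged intervals into contiguous BED regions (0-based half-open)."""
    het = intervals.loc[np.asarray(het_mask)]
    rows = []
    for c, sub in het.groupby("chrom"):
        sub = sub.sort_values("left_bp")
        cur_lo = cur_hi = None
        for _, row in sub.iterrows():
            lo, hi = int(row["left_bp"]) - 1, int(row["right_bp"]) - 1
            if cur_hi is not None and lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                if cur_hi is not None:
                    rows.append((c, cur_lo, cur_hi))
                cur_lo, cur_hi = lo, hi
        if cur_hi is not None:
            rows.append((c, cur_lo, cur_hi))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _arm_of(intervals: pd.DataFrame, centromere_mid: dict) -> np.ndarray:
    mids = 0.5 * (intervals["left_bp"] + intervals["right_bp"])
    cmid = intervals["chrom"].map(centromere_mid)
    return np.where(mids <= cmid, "L", "R")


def arm_mean_rates(
    intervals: pd.DataFrame, centromere_mid: dict, het_mask=None
) -> pd.DataFrame:
    """bp-weighted mean CO rate (cM/Mb) per chromosome arm.

    Heterochromatic intervals are excluded from the mean; each interval's
    weight is its physical span in bp.
    """
    tab = intervals.copy()
    tab["arm"] = _arm_of(tab, centromere_mid)
    if het_mask is not None:
        tab = tab.loc[~np.asarray(het_mask)]
    tab = tab.dropna(subset=["cm_per_mb"])
    rows = []
    for (c, arm), sub in tab.groupby(["chrom", "arm"]):
        w = sub["span_bp"].to_numpy(dtype=float)
        rows.append(
            dict(
                chrom=c,
                arm=arm,
                mean_cm_per_mb=float(np.average(sub["cm_per_mb"], weights=w)),
                euchromatic_bp=int(w.sum()),
                n_intervals=len(sub),
            )
        )
    return pd.DataFrame(rows)


def classify_hot_cold(
    intervals: pd.DataFrame, centromere_mid: dict, het_mask=None
) -> pd.DataFrame:
    """Flag hot/cold intervals against their arm mean rate.

    An interval is hot iff the lower bound of its 95% rate CI exceeds the arm
    mean, cold iff the upper bound falls below it; heterochromatic intervals
    are excluded from the arm means (but still classified).
    """
    tab = intervals.copy()
    tab["arm"] = _arm_of(tab, centromere_mid)
    arms = arm_mean_rates(intervals, centromere_mid, het_mask)
    key = arms.set_index(["chrom", "arm"])["mean_cm_per_mb"]
    mean = [
        key.get((c, a), np.nan) for c, a in zip(tab["chrom"], tab["arm"])
    ]
    tab["arm_mean_cm_per_mb"] = mean
    scale = 100.0 / (tab["span_bp"] / 1e6)  # r -> cM/Mb
    lo = tab["ci_lo"].clip(lower=0) * scale
    hi = tab["ci_hi"] * scale
    tab["hot"] = lo > tab["arm_mean_cm_per_mb"]
    tab["cold"] = hi < tab["arm_mean_cm_per_mb"]
    return tab


def compare_intervals_mf(
    male: pd.DataFrame, female: pd.DataFrame, q: float = 0.05, method: str = "z"
) -> pd.DataFrame:
    """Per-interval male vs female recombination-fraction comparison.

    Both tables must cover the same intervals (shared markers).  ``method``
    ``"z"`` uses the normal-approximation two-proportion test
    ``z = (r_m - r_f) / sqrt(se_m^2 + se_f^2)``; ``"fisher"`` uses Fisher's
    exact test on the 2x2 recombinant table.  Benjamini-Hochberg control at
    level ``q`` is applied genome-wide across all tested intervals.
    """
    if not (male["left"].tolist() == female["left"].tolist()):
        raise ValueError("male and female tables must cover the same intervals")
    out = male[["chrom", "left", "right", "left_bp", "right_bp", "span_bp"]].copy()
    out["r_male"] = male["r"].to_numpy()
    out["r_female"] = female["r"].to_numpy()
    if method == "z":
        se2 = male["se"].to_numpy() ** 2 + female["se"].to_numpy() ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (out["r_male"] - out["r_female"]) / np.sqrt(se2)
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(out["r_male"] == out["r_female"], 1.0, p)
    elif method == "fisher":
        p = np.array(
            [
                stats.fisher_exact(
                    [
                        [m_nr, m_n - m_nr],
                        [f_nr, f_n - f_nr],
                    ]
                ).pvalue
                for m_nr, m_n, f_nr, f_n in zip(
                    male["n_recombinant"], male["n"],
                    female["n_recombinant"], female["n"],
                )
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    out["p"] = p
    ok = ~np.isnan(p)
    sig = np.zeros(len(p), dtype=bool)
    if ok.any():
        sig[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    out["significant"] = sig
    return out


def associate_rate_feature(rates, feature, exclude=None) -> dict:
    """Ordinary least squares of CO rate on a genomic feature.

    ``exclude`` (boolean mask, e.g. heterochromatic intervals) removes
    intervals before fitting.  Returns slope, intercept, R^2 and the p-value
    for the hypothesis of no association.
    """
    rates = np.asarray(rates, dtype=float)
    feature = np.asarray(feature, dtype=float)
    keep = ~(np.isnan(rates) | np.isnan(feature))
    if exclude is not None:
        keep &= ~np.asarray(exclude)
    res = stats.linregress(feature[keep], rates[keep])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(keep.sum()),
    }


def positional_gradient(values, midpoints_bp, centromere_mid_bp: float) -> dict:
    """Linear association of a feature with distance from the centromere.

    ``values`` are per-interval feature values on ONE arm; the predictor is
    the distance of each interval midpoint from the centromere.  Returns the
    Pearson correlation and its p-value.
    """
    values = np.asarray(values, dtype=float)
    dist = np.abs(np.asarray(midpoints_bp, dtype=float) - centromere_mid_bp)
    keep = ~np.isnan(values)
    r, p = stats.pearsonr(dist[keep], values[keep])
    return {"r": float(r), "p": float(p), "n": int(keep.sum())}
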