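"""Meiosis and backcross-population simulator.

Crossovers (COs) on the bivalent are placed by a stationary gamma renewal
process: inter-CO genetic distances are Gamma(shape ``nu``, rate ``2 nu``)
Morgans, so the mean spacing is 0.5 Morgan and the CO intensity on the
bivalent is 2 per Morgan.  ``nu = 1`` is a Poisson process (no interference);
``nu > 1`` gives positive interference (under-dispersed counts, regular
spacings).  A gamete inherits each bivalent CO independently with probability
1/2 ("thinning": each CO involves two of the four chromatids), so the gametic
CO intensity is 1 per Morgan and the expected gametic CO count equals the
genetic length in Morgans.

The stationary (equilibrium) start draws the first CO from the density
``S(x)/mu`` where ``S`` is the Gamma(nu, 2 nu) survival and ``mu = 0.5``
Morgan, which makes the expected CO count on any sub-segment of length ``l``
exactly ``2 l`` — genetic length in equals genetic length out, matching the
model the interference fitter assumes.

On top of the meiotic model the module layers the nuisance structure of a
real genotyping experiment: two-locus gametic selection (segregation
distortion), missing calls, genotyping errors, and centromere-to-telomere
gradients in genomic features.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import CODE_A, CODE_H, CODE_MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "GammaModel",
    "ChromosomeSpec",
    "SelectionModel",
    "simulate_bivalent_crossovers",
    "simulate_bivalent_many",
    "thin_to_gamete",
    "genotype_gamete",
    "simulate_population",
    "apply_gametic_selection",
    "inject_missing_and_errors",
    "generate_feature_tracks",
]


@dataclass(frozen=True)
class GammaModel:
    """Gamma renewal model of CO placement on the bivalent.

    ``bivalent_rate`` (2 COs per Morgan) and ``thinning_p`` (1/2) are fixed by
    the definition of genetic distance; only the interference strength ``nu``
    is free.
    """

    nu: float
    bivalent_rate: float = 2.0
    thinning_p: float = 0.5

    def __post_init__(self):
        if not self.nu > 0:
            raise ValueError(f"gamma shape nu must be positive, got {self.nu}")
        if self.thinning_p != 0.5:
            raise ValueError("thinning probability is fixed at 0.5")

    @property
    def gap_shape(self) -> float:
        return self.nu

    @property
    def gap_rate(self) -> float:
        # mean gap = nu / (2 nu) = 0.5 Morgan
        return 2.0 * self.nu


@dataclass(frozen=True)
class ChromosomeSpec:
    """Physical and genetic geometry of one chromosome.

    ``genetic_length`` is in Morgans, ``physical_length`` in bp;
    ``marker_positions`` are strictly increasing 1-based bp;
    ``centromere_span`` is a (start, end) bp interval.
    ``map_knots`` optionally defines a piecewise-linear genetic<->physical
    relationship as (bp, Morgan) pairs anchored at (1, 0) and
    (physical_length, genetic_length); by default the map is linear
    (uniform cM/Mb).
    """

    name: str
    genetic_length: float
    physical_length: int
    marker_positions: tuple
    centromere_span: tuple
    map_knots: tuple | None = None

    def __post_init__(self):
        if not self.genetic_length > 0:
            raise ValueError("genetic_length must be positive")
        pos = np.asarray(self.marker_positions)
        if len(pos) and (pos.min() < 1 or pos.max() > self.physical_length):
            raise ValueError("markers must lie within [1, physical_length]")
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("marker positions must be strictly increasing")

    def _knot_arrays(self):
        if self.map_knots is None:
            bp = np.array([1.0, float(self.physical_length)])
            gen = np.array([0.0, self.genetic_length])
        else:
            k = np.asarray(self.map_knots, dtype=float)
            bp = np.concatenate([[1.0], k[:, 0], [float(self.physical_length)]])
            gen = np.concatenate([[0.0], k[:, 1], [self.genetic_length]])
            if not (np.all(np.diff(bp) > 0) and np.all(np.diff(gen) > 0)):
                raise ValueError("map_knots must be strictly increasing in bp and Morgans")
        return bp, gen

    def genetic_of_bp(self, bp) -> np.ndarray:
        """Monotone genetic coordinate (Morgans) of physical positions."""
        kb, kg = self._knot_arrays()
        return np.interp(np.asarray(bp, dtype=float), kb, kg)

    def bp_of_genetic(self, gen) -> np.ndarray:
        kb, kg = self._knot_arrays()
        return np.interp(np.asarray(gen, dtype=float), kg, kb)

    def marker_genetic_positions(self) -> np.ndarray:
        return self.genetic_of_bp(np.asarray(self.marker_positions, dtype=float))


@dataclass(frozen=True)
class SelectionModel:
    """Gametic selection at two loci.

    A gamete carrying the unfavored allele at locus 1 (resp. 2) is kept with
    probability ``s1`` (resp. ``s2``); with both unfavored alleles it is kept
    with probability ``s1 * s2`` (no epistasis).  ``unfavored1``/``unfavored2``
    are genotype codes (``CODE_A`` = recurrent allele, ``CODE_H`` = donor).
    """

    locus1_bp: int
    locus2_bp: int
    s1: float
    s2: float
    unfavored1: int = CODE_A
    unfavored2: int = CODE_H

    def __post_init__(self):
        if not self.locus1_bp < self.locus2_bp:
            raise ValueError("locus1_bp must be < locus2_bp")
        for s in (self.s1, self.s2):
            if not (0 < s <= 1):
                raise ValueError(f"selection coefficient {s} outside (0, 1]")

    def haplotype_weight(self, allele1: int, allele2: int) -> float:
        w = 1.0
        if allele1 == self.unfavored1:
            w *= self.s1
        if allele2 == self.unfavored2:
            w *= self.s2
        return w


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@lru_cache(maxsize=32)
def _equilibrium_grid(nu: float, n_grid: int = 8192):
    """Inverse-CDF grid for the equilibrium first-event distribution.

    For a renewal process with Gamma(nu, 2 nu) gaps, the stationary first-event
    density is S(x)/mu with mu = 0.5; its CDF has the closed form
    ``F_e(x) = x S_nu(x)/mu + F_{nu+1}(x)`` (same rate).
    """
    scale = 1.0 / (2.0 * nu)
    x_max = max(
        stats.gamma.ppf(1 - 1e-12, nu, scale=scale),
        stats.gamma.ppf(1 - 1e-12, nu + 1, scale=scale),
    )
    x = np.linspace(0.0, x_max, n_grid)
    fe = x * stats.gamma.sf(x, nu, scale=scale) / 0.5 + stats.gamma.cdf(
        x, nu + 1, scale=scale
    )
    fe[-1] = 1.0
    return x, fe


def _sample_equilibrium_first(nu: float, n: int, rng) -> np.ndarray:
    x, fe = _equilibrium_grid(float(nu))
    return np.interp(rng.random(n), fe, x)


def simulate_bivalent_many(
    spec: ChromosomeSpec, model: GammaModel, n: int, seed
) -> list[np.ndarray]:
    """Simulate ``n`` bivalents; returns a list of sorted CO positions (Morgans)."""
    rng = _as_rng(seed)
    L = spec.genetic_length
    shape, rate = model.gap_shape, model.gap_rate
    firsts = _sample_equilibrium_first(shape, n, rng)
    out: list[np.ndarray] = [np.empty(0)] * n
    # block-draw gaps; extend the rare gametes that outrun the block
    block = max(8, int(np.ceil(2 * model.bivalent_rate * L + 20)))
    active = np.flatnonzero(firsts <= L)
    positions = [None] * n
    for i in active:
        positions[i] = [firsts[i]]
    while len(active):
        gaps = rng.gamma(shape, 1.0 / rate, size=(len(active), block))
        still = []
        for row, i in enumerate(active):
            pts = positions[i]
            cur = pts[-1]
            for g in gaps[row]:
                cur += g
                if cur > L:
                    break
                pts.append(cur)
            else:
                still.append(i)
        active = np.asarray(still, dtype=int)
    for i in range(n):
        if positions[i] is not None:
            out[i] = np.asarray(positions[i])
    return out


def simulate_bivalent_crossovers(spec: ChromosomeSpec, model: GammaModel, seed) -> np.ndarray:
    """One bivalent realization: ordered CO positions in Morgans on [0, L]."""
    return simulate_bivalent_many(spec, model, 1, seed)[0]


def thin_to_gamete(bivalent_positions, model: GammaModel, seed) -> np.ndarray:
    """Retain each bivalent CO independently with probability 1/2."""
    rng = _as_rng(seed)
    pos = np.asarray(bivalent_positions, dtype=float)
    if pos.size == 0:
        return pos
    keep = rng.random(pos.size) < model.thinning_p
    return pos[keep]


def genotype_gamete(
    gamete_positions, spec: ChromosomeSpec, start_allele: int = CODE_A
) -> np.ndarray:
    """Marker alleles of a gamete given its CO positions (Morgans).

    The allele flips exactly at each CO; marker ``i`` carries the allele of
    the segment containing it.  Marker genetic coordinates come from the
    spec's genetic<->physical map (linear by default).
    """
    pos = np.asarray(gamete_positions, dtype=float)
    if pos.size and (pos.min() < 0 or pos.max() > spec.genetic_length + 1e-12):
        raise ValueError("CO position outside the chromosome span")
    marker_gen = spec.marker_genetic_positions()
    crossings = np.searchsorted(np.sort(pos), marker_gen, side="right")
    flip = crossings % 2 == 1
    other = CODE_H if start_allele == CODE_A else CODE_A
    return np.where(flip, other, start_allele).astype(np.int8)


def simulate_population(
    specs: list[ChromosomeSpec],
    models: dict,
    n_plants: int,
    seed,
    selection: dict | None = None,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    plant_prefix: str = "plant",
) -> GenotypeMatrix:
    """Simulate a backcross population over several chromosomes.

    ``models`` maps chromosome name -> :class:`GammaModel`; ``selection``
    (optional) maps chromosome name -> :class:`SelectionModel`.  Chromosomes
    are simulated independently.  Selection filters gametes, so the returned
    population may be smaller than ``n_plants``; all randomness derives from
    the single ``seed``.
    """
    root = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else seed.entropy)
    blocks = []
    keep_mask = np.ones(n_plants, dtype=bool)
    for k, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence((root.entropy, k)))
        model = models[spec.name]
        bivalents = simulate_bivalent_many(spec, model, n_plants, rng)
        codes = np.empty((n_plants, len(spec.marker_positions)), dtype=np.int8)
        starts = rng.random(n_plants) < 0.5
        for i in range(n_plants):
            gam = thin_to_gamete(bivalents[i], model, rng)
            start = CODE_A if starts[i] else CODE_H
            codes[i] = genotype_gamete(gam, spec, start)
        if selection and spec.name in selection:
            sel = selection[spec.name]
            keep_mask &= _selection_keep_mask(codes, spec, sel, rng)
        blocks.append(codes)
    table = pd.DataFrame(
        {"chrom": np.concatenate([[s.name] * len(s.marker_positions) for s in specs]),
         "pos": np.concatenate([np.asarray(s.marker_positions) for s in specs]),
         "marker": np.concatenate(
             [[f"{s.name}_m{j:03d}" for j in range(len(s.marker_positions))] for s in specs]
         )}
    )
    marker_map = MarkerMap(table)
    calls = pd.DataFrame(
        np.hstack(blocks),
        index=[f"{plant_prefix}{i:05d}" for i in range(n_plants)],
        columns=marker_map.marker_names,
    )
    matrix = GenotypeMatrix(calls.loc[keep_mask], marker_map)
    if missing_rate or error_rate:
        noise_rng = np.random.default_rng(np.random.SeedSequence((root.entropy, 10_007)))
        matrix = inject_missing_and_errors(matrix, missing_rate, error_rate, noise_rng)
    return matrix


def _nearest_marker_index(spec: ChromosomeSpec, bp: int) -> int:
    pos = np.asarray(spec.marker_positions)
    return int(np.argmin(np.abs(pos - bp)))


def _selection_keep_mask(codes, spec, sel: SelectionModel, rng) -> np.ndarray:
    j1 = _nearest_marker_index(spec, sel.locus1_bp)
    j2 = _nearest_marker_index(spec, sel.locus2_bp)
    w = np.ones(codes.shape[0])
    w[codes[:, j1] == sel.unfavored1] *= sel.s1
    w[codes[:, j2] == sel.unfavored2] *= sel.s2
    return rng.random(codes.shape[0]) < w


def apply_gametic_selection(matrix: GenotypeMatrix, sel: SelectionModel, chrom, seed) -> GenotypeMatrix:
    """Filter a population by two-locus gametic selection.

    The haplotype class of each plant is read at the markers nearest the two
    selected loci (the loci must coincide with, or be tightly flanked by,
    markers); each gamete survives with its haplotype weight.  With
    ``s1 = s2 = 1`` the population is returned unchanged.
    """
    if sel.s1 == 1.0 and sel.s2 == 1.0:
        return matrix
    rng = _as_rng(seed)
    pos = matrix.marker_map.positions(chrom)
    codes = matrix.codes(chrom)
    j1 = int(np.argmin(np.abs(pos - sel.locus1_bp)))
    j2 = int(np.argmin(np.abs(pos - sel.locus2_bp)))
    w = np.ones(codes.shape[0])
    w[codes[:, j1] == sel.unfavored1] *= sel.s1
    w[codes[:, j2] == sel.unfavored2] *= sel.s2
    keep = rng.random(codes.shape[0]) < w
    return matrix.subset_plants(keep)


def inject_missing_and_errors(
    matrix: GenotypeMatrix, missing_rate: float, error_rate: float, seed
) -> GenotypeMatrix:
    """Flip calls (A<->H) at ``error_rate`` and blank them at ``missing_rate``."""
    for r in (missing_rate, error_rate):
        if not (0 <= r < 1):
            raise ValueError(f"rate {r} outside [0, 1)")
    if missing_rate == 0 and error_rate == 0:
        return matrix
    rng = _as_rng(seed)
    vals = matrix.calls.to_numpy().copy()
    if error_rate:
        flip = rng.random(vals.shape) < error_rate
        flip &= vals != CODE_MISSING
        vals[flip] = CODE_H + CODE_A - vals[flip]
    if missing_rate:
        vals[rng.random(vals.shape) < missing_rate] = CODE_MISSING
    calls = pd.DataFrame(vals, index=matrix.calls.index, columns=matrix.calls.columns)
    return GenotypeMatrix(calls, matrix.marker_map)


_DEFAULT_GRADIENTS = {
    # (value at centromere edge, value at telomere); CpG flat by default
    "gc": (0.33, 0.39),
    "genes": (0.25, 0.65),
    "te": (0.45, 0.05),
    "cpg": (0.035, 0.035),
}


def generate_feature_tracks(
    spec: ChromosomeSpec,
    seed,
    gradients: dict | None = None,
    noise_sd: float = 0.01,
    window_bp: int = 2000,
    euchromatin_presence: float = 0.8,
    heterochromatin_presence: float = 0.05,
    pericentromere_bp: int = 1_500_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize per-interval feature densities and 2 kb epigenetic windows.

    Emulates the positional structure of the Arabidopsis genome: GC and gene
    density rise, TE density falls from centromere to telomere on each arm;
    the CpG ratio has no positional trend; euchromatic-mark presence
    (H3K4me3/H3K27me3) is low inside and around the centromere.

    Returns ``(features, windows)``: per adjacent-marker-interval feature
    table and a BED-like window table (0-based half-open) of mean mark
    presence.
    """
    rng = _as_rng(seed)
    grads = dict(_DEFAULT_GRADIENTS)
    if gradients:
        grads.update(gradients)
    pos = np.asarray(spec.marker_positions, dtype=float)
    mid = 0.5 * (pos[:-1] + pos[1:])
    c_lo, c_hi = spec.centromere_span
    c_mid = 0.5 * (c_lo + c_hi)
    # relative distance from centromere along the owning arm, in [0, 1]
    left = mid <= c_mid
    rel = np.empty_like(mid)
    rel[left] = (c_mid - mid[left]) / max(c_mid - 1.0, 1.0)
    rel[~left] = (mid[~left] - c_mid) / max(spec.physical_length - c_mid, 1.0)
    feats = {"chrom": spec.name, "left_bp": pos[:-1].astype(int), "right_bp": pos[1:].astype(int)}
    for name, (at_cen, at_tel) in grads.items():
        base = at_cen + (at_tel - at_cen) * rel
        vals = base + rng.normal(0.0, noise_sd, size=len(mid))
        feats[name] = np.clip(vals, 0.0, 1.0)
    features = pd.DataFrame(feats)

    starts = np.arange(0, spec.physical_length, window_bp)
    ends = np.minimum(starts + window_bp, spec.physical_length)
    centers = 0.5 * (starts + ends)
    hetero = (centers >= c_lo - pericentromere_bp) & (centers <= c_hi + pericentromere_bp)
    level = np.where(hetero, heterochromatin_presence, euchromatin_presence)
    presence = np.clip(level + rng.normal(0.0, 0.05, size=len(starts)), 0.0, 1.0)
    windows = pd.DataFrame(
        {"chrom": spec.name, "start": starts, "end": ends, "presence": presence}
    )
    return features, windows
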