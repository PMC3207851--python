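"""Meiosis-simulator checks: stationarity, thinning, genotyping, selection."""

import numpy as np
import pytest
from scipy import stats

from heterochiasma import simulate as sim
from heterochiasma.io import CODE_A, CODE_H, CODE_MISSING
from conftest import make_matrix, make_spec


class TestBivalentProcess:
    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            sim.GammaModel(0.0)
        with pytest.raises(ValueError):
            make_spec(L=-1.0)

    def test_poisson_limit_counts(self):
        # nu = 1 makes the renewal process Poisson(2 per Morgan)
        spec = make_spec(L=1.0)
        counts = np.array(
            [len(p) for p in sim.simulate_bivalent_many(spec, sim.GammaModel(1.0), 20_000, 0)]
        )
        assert abs(counts.mean() - 2.0) < 3 * np.sqrt(2.0 / 20_000)
        k = np.arange(9)
        obs = np.array([(counts == v).sum() for v in k[:-1]] + [(counts >= 8).sum()])
        exp = np.append(stats.poisson.pmf(k[:-1], 2.0), stats.poisson.sf(7, 2.0)) * 20_000
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(k) - 1) > 1e-3

    def test_mean_count_matches_twice_genetic_length(self):
        # chromosome-1-male geometry: 2 * 1.4236 = 2.85 COs per bivalent
        spec = make_spec(L=1.4236, phys=30_430_000)
        counts = np.array(
            [len(p) for p in sim.simulate_bivalent_many(spec, sim.GammaModel(2.6), 100_000, 1)]
        )
        assert counts.mean() == pytest.approx(2.85, abs=0.03)

    def test_interference_shrinks_count_variance(self):
        spec = make_spec(L=1.0)
        v = {}
        for nu in (1.0, 5.0):
            counts = np.array(
                [len(p) for p in sim.simulate_bivalent_many(spec, sim.GammaModel(nu), 20_000, 2)]
            )
            v[nu] = counts.var()
        assert v[5.0] < v[1.0]

    def test_stationarity_on_subsegment(self):
        # expected CO count on any sub-segment of length l is 2 l, any nu
        spec = make_spec(L=2.0)
        for nu in (0.7, 4.0):
            pos = sim.simulate_bivalent_many(spec, sim.GammaModel(nu), 30_000, 3)
            inside = sum(int(((p >= 0.6) & (p < 1.1)).sum()) for p in pos)
            expect = 2 * 0.5 * 30_000
            assert abs(inside - expect) < 3 * np.sqrt(expect)


class TestThinning:
    def test_empty_is_identity(self):
        out = sim.thin_to_gamete([], sim.GammaModel(2.0), 0)
        assert len(out) == 0

    def test_gamete_mean_equals_genetic_length(self):
        spec = make_spec(L=1.0)
        model = sim.GammaModel(3.0)
        rng = np.random.default_rng(4)
        total = sum(
            len(sim.thin_to_gamete(p, model, rng))
            for p in sim.simulate_bivalent_many(spec, model, 20_000, rng)
        )
        assert abs(total / 20_000 - 1.0) < 3 * np.sqrt(1.0 / 20_000)

    def test_retention_is_binomial_half(self):
        model = sim.GammaModel(1.0)
        rng = np.random.default_rng(5)
        n = 8
        kept = np.array(
            [len(sim.thin_to_gamete(np.linspace(0, 1, n), model, rng)) for _ in range(20_000)]
        )
        obs = np.bincount(kept, minlength=n + 1)
        exp = stats.binom.pmf(np.arange(n + 1), n, 0.5) * 20_000
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, n) > 1e-3


class TestGenotyping:
    def test_no_cos_gives_constant_vector(self):
        spec = make_spec(n_markers=10)
        out = sim.genotype_gamete([], spec, CODE_H)
        assert (out == CODE_H).all()

    def test_single_co_switches_once_between_bracketing_markers(self):
        spec = make_spec(L=1.0, n_markers=6)
        gen = spec.marker_genetic_positions()
        co = 0.5 * (gen[2] + gen[3])
        out = sim.genotype_gamete([co], spec, CODE_A)
        assert list(out) == [CODE_A] * 3 + [CODE_H] * 3

    def test_double_co_in_one_interval_is_invisible(self):
        spec = make_spec(L=1.0, n_markers=6)
        gen = spec.marker_genetic_positions()
        lo, hi = gen[2] + 1e-4, gen[3] - 1e-4
        out = sim.genotype_gamete([lo, hi], spec, CODE_A)
        assert (out == CODE_A).all()

    def test_out_of_range_co_rejected(self):
        spec = make_spec(L=1.0)
        with pytest.raises(ValueError):
            sim.genotype_gamete([1.5], spec, CODE_A)

    def test_piecewise_map_moves_markers(self):
        # end-loaded map: most genetic length near the physical ends
        knots = ((10_000_000, 0.45),)
        spec = make_spec(L=0.5, phys=20_000_000, n_markers=5, knots=knots)
        gen = spec.marker_genetic_positions()
        assert gen[2] == pytest.approx(0.45, abs=0.01)  # mid-chromosome knot


class TestSelection:
    def test_neutral_selection_is_identity(self, small_population):
        matrix, spec = small_population
        sel = sim.SelectionModel(5_000_000, 15_000_000, 1.0, 1.0)
        out = sim.apply_gametic_selection(matrix, sel, "c1", 9)
        assert out.calls.equals(matrix.calls)

    def test_single_locus_allele_ratio(self):
        # fitness 1 : 0.37 leaves a 2.70 : 1 favored:unfavored ratio
        spec = make_spec(L=0.8, n_markers=10)
        matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(1.0)}, 60_000, seed=13)
        sel = sim.SelectionModel(1, 11_000_000, 1.0, 0.37, unfavored2=CODE_H)
        out = sim.apply_gametic_selection(matrix, sel, "c1", 14)
        codes = out.codes("c1")[:, 5]
        ratio = (codes == CODE_A).sum() / (codes == CODE_H).sum()
        assert ratio == pytest.approx(1 / 0.37, rel=0.05)

    def test_invalid_s_rejected(self):
        with pytest.raises(ValueError):
            sim.SelectionModel(1, 2, 0.0, 1.0)
        with pytest.raises(ValueError):
            sim.SelectionModel(5, 2, 0.5, 1.0)

    def test_single_locus_selection_leaves_r_unbiased(self):
        # the single-locus lemma: selection rescales recombinants and
        # non-recombinants equally, so r-hat stays unbiased
        from heterochiasma import mapping as mp

        spec = make_spec(L=0.6, n_markers=8)
        matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(1.0)}, 100_000, seed=15)
        sel = sim.SelectionModel(1, 8_500_000, 1.0, 0.3, unfavored2=CODE_H)
        kept = sim.apply_gametic_selection(matrix, sel, "c1", 16)
        full = mp.interval_table(matrix, "c1")
        selected = mp.interval_table(kept, "c1")
        for j in range(len(full)):
            r0, r1 = full["r"].iloc[j], selected["r"].iloc[j]
            se = np.sqrt(full["se"].iloc[j] ** 2 + selected["se"].iloc[j] ** 2)
            assert abs(r1 - r0) < 4 * se


class TestNoise:
    def test_zero_rates_identity(self, small_population):
        matrix, _ = small_population
        out = sim.inject_missing_and_errors(matrix, 0.0, 0.0, 0)
        assert out.calls.equals(matrix.calls)

    def test_missing_fraction_calibrated(self, clean_population):
        matrix, _ = clean_population
        out = sim.inject_missing_and_errors(matrix, 0.02, 0.0, 17)
        n = matrix.calls.size
        frac = (out.calls.to_numpy() == CODE_MISSING).sum() / n
        assert abs(frac - 0.02) < 3 * np.sqrt(0.02 * 0.98 / n)


class TestFeatureTracks:
    def test_gradients_and_centromeric_silence(self):
        spec = make_spec(L=1.0, phys=20_000_000, n_markers=40)
        feats, windows = sim.generate_feature_tracks(spec, seed=19)
        mid = 0.5 * (feats["left_bp"] + feats["right_bp"])
        cmid = 10_000_000
        for arm_mask in (mid < cmid - 1e6, mid > cmid + 1e6):
            dist = np.abs(mid[arm_mask] - cmid)
            assert stats.pearsonr(dist, feats.loc[arm_mask, "gc"])[0] > 0
            assert stats.pearsonr(dist, feats.loc[arm_mask, "genes"])[0] > 0
            assert stats.pearsonr(dist, feats.loc[arm_mask, "te"])[0] < 0
        centers = 0.5 * (windows["start"] + windows["end"])
        cen = (centers > spec.centromere_span[0]) & (centers < spec.centromere_span[1])
        assert windows.loc[cen, "presence"].mean() < 0.2

    def test_cpg_has_no_positional_trend(self):
        spec = make_spec(L=1.0, phys=20_000_000, n_markers=61)
        nonsig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            feats, _ = sim.generate_feature_tracks(spec, seed=seed)
            mid = 0.5 * (feats["left_bp"] + feats["right_bp"])
            p = stats.pearsonr(np.abs(mid - 1e7), feats["cpg"])[1]
            nonsig += p > 0.05
        assert nonsig >= 0.9 * n_seeds


class TestPopulation:
    def test_seed_reproducibility(self):
        spec = make_spec(n_markers=12)
        a = sim.simulate_population([spec], {"c1": sim.GammaModel(2.0)}, 50, seed=21)
        b = sim.simulate_population([spec], {"c1": sim.GammaModel(2.0)}, 50, seed=21)
        assert a.calls.equals(b.calls)

    def test_gamete_counts_poisson_at_nu_one(self, clean_population):
        from heterochiasma import mapping as mp

        matrix, spec = clean_population
        counts = mp.per_plant_co_counts(matrix, "c1")
        k = np.arange(5)
        obs = np.array([(counts == v).sum() for v in k[:-1]] + [(counts >= 4).sum()])
        lam = spec.genetic_length
        exp = np.append(stats.poisson.pmf(k[:-1], lam), stats.poisson.sf(3, lam)) * counts.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        assert stats.chi2.sf(chi2, len(k) - 1) > 1e-3
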