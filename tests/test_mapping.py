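"""Genetic-map estimation: recombination fractions, lengths, truncations."""

import numpy as np
import pytest
from scipy import stats

from heterochiasma import mapping as mp
from heterochiasma import simulate as sim
from heterochiasma.io import CODE_A, CODE_H, CODE_MISSING
from conftest import make_matrix, make_spec

A, H, M = CODE_A, CODE_H, CODE_MISSING


class TestIntervalEstimate:
    def test_ci_formula(self):
        # N_r = 10, N = 100: r = 0.1, half-width 1.96 sqrt(0.1*0.9/100)
        rows = [[A, H]] * 10 + [[A, A]] * 90
        est = mp.interval_recomb_fraction(make_matrix(rows), "c1", "c1_m000", "c1_m001")
        assert est.r == pytest.approx(0.1)
        assert est.ci95[1] - est.r == pytest.approx(0.0588, abs=1e-4)

    def test_zero_recombinants(self):
        est = mp.interval_recomb_fraction(make_matrix([[A, A]] * 50), "c1", "c1_m000", "c1_m001")
        assert est.r == 0.0
        assert est.ci95[0] == 0.0

    def test_missing_plant_excluded_from_both_counts(self):
        rows = [[A, H], [A, M], [A, A]]
        est = mp.interval_recomb_fraction(make_matrix(rows), "c1", "c1_m000", "c1_m001")
        assert est.n_informative == 2
        assert est.n_recombinant == 1

    def test_non_adjacent_rejected(self):
        with pytest.raises(ValueError, match="adjacent"):
            mp.interval_recomb_fraction(make_matrix([[A, A, A]]), "c1", "c1_m000", "c1_m002")


class TestHaldane:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.0906346, 0.1), (0.01, 0.0101014)],
    )
    def test_closed_form(self, r, expected):
        assert mp.haldane_distance(r) == pytest.approx(expected, abs=1e-6)

    def test_r_at_half_rejected(self):
        with pytest.raises(ValueError):
            mp.haldane_distance(0.5)


class TestChromosomeLengths:
    def test_interval_sum_single_interval(self):
        rows = [[A, H]] * 10 + [[A, A]] * 90
        L = mp.chromosome_length_interval_sum(make_matrix(rows), "c1")
        assert L.morgans == pytest.approx(0.111572, abs=1e-6)

    def test_no_recombinants_zero_length(self):
        L = mp.chromosome_length_interval_sum(make_matrix([[A, A, A]] * 20), "c1")
        assert L.morgans == 0.0

    def test_switch_count_skips_missing(self):
        counts = mp.per_plant_co_counts(make_matrix([[A, A, M, H, H]]), "c1")
        assert counts.tolist() == [1]

    def test_every_plant_one_switch(self):
        matrix = make_matrix([[A, A, H], [A, H, H], [H, A, A]])
        L = mp.chromosome_length_switch_count(matrix, "c1")
        assert L.morgans == 1.0
        assert L.variance == 0.0

    def test_estimators_agree_on_complete_data(self, clean_population):
        matrix, spec = clean_population
        l1 = mp.chromosome_length_interval_sum(matrix, "c1")
        l2 = mp.chromosome_length_switch_count(matrix, "c1")
        tab = mp.interval_table(matrix, "c1")
        r_max = tab["r"].max()
        assert abs(l1.morgans - l2.morgans) / l2.morgans < r_max

    def test_switch_count_detects_at_least_adjacent_recombinants(self):
        # with missing data, per-plant switch counting never sees fewer
        # events than the sum of adjacent-complete-pair recombinants
        spec = make_spec(L=0.8, n_markers=20)
        for seed in range(20):
            matrix = sim.simulate_population(
                [spec], {"c1": sim.GammaModel(2.0)}, 150, seed=seed, missing_rate=0.02
            )
            switches = mp.per_plant_co_counts(matrix, "c1").sum()
            adjacent = mp.interval_table(matrix, "c1")["n_recombinant"].sum()
            assert switches >= adjacent

    def test_interval_sum_recovers_truth(self):
        # simulated L = 0.8 M, nu = 3: estimate covers truth in most seeds
        spec = make_spec(L=0.8, n_markers=40)
        hits = 0
        for seed in range(30):
            matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(3.0)}, 2000, seed=100 + seed)
            est = mp.chromosome_length_interval_sum(matrix, "c1")
            hits += abs(est.morgans - 0.8) <= 1.96 * est.se
        assert hits >= 0.9 * 30 - 2


class TestRatio:
    def _length(self, mean, se, n=1000):
        return mp.ChromosomeLength("c", mean, se**2, n, "switch-count")

    def test_printed_cell_ratio(self):
        # per-meiocyte CO means 11.15 / 6.65
        est = mp.mf_ratio_ci(self._length(11.15, 0.05), self._length(6.65, 0.04))
        assert est.f == pytest.approx(1.6767, abs=1e-3)

    def test_identical_inputs_unit_ratio(self):
        est = mp.mf_ratio_ci(self._length(1.0, 0.1), self._length(1.0, 0.1))
        assert est.f == 1.0
        assert est.ci95[0] + est.ci95[1] == pytest.approx(2.0)

    def test_ci_from_relative_variances(self):
        est = mp.mf_ratio_ci(self._length(2.0, 0.1), self._length(1.0, 0.1))
        assert est.f == 2.0
        assert est.ci95[0] == pytest.approx(1.5617, abs=1e-3)
        assert est.ci95[1] == pytest.approx(2.4383, abs=1e-3)


class TestTruncation:
    def test_zero_fraction_identity(self, small_population):
        matrix, _ = small_population
        out = mp.truncate_chromosome(matrix, "c1", 0.0)
        assert out.calls.equals(matrix.calls)

    def test_uniform_map_keeps_central_fraction(self):
        spec = make_spec(L=1.0, n_markers=101)
        matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(1.0)}, 3000, seed=31)
        full = mp.chromosome_length_switch_count(matrix, "c1")
        central = mp.chromosome_length_switch_count(
            mp.truncate_chromosome(matrix, "c1", 0.15), "c1"
        )
        assert central.morgans / full.morgans == pytest.approx(0.70, abs=0.05)

    def test_end_loaded_map_ratio_drops_under_truncation(self):
        # male-like end-loaded maps lose proportionally more genetic length
        # than uniform female-like maps, shrinking the M/F ratio
        drops = 0
        n_seeds = 10
        for seed in range(n_seeds):
            knots = ((4_000_000, 0.55), (16_000_000, 0.75))  # ends carry 1.1 of 1.3 M
            spec_m = make_spec(L=1.3, n_markers=60, knots=knots)
            spec_f = make_spec(L=0.75, n_markers=60)
            mat_m = sim.simulate_population([spec_m], {"c1": sim.GammaModel(2.6)}, 700, seed=40 + seed)
            mat_f = sim.simulate_population([spec_f], {"c1": sim.GammaModel(2.7)}, 700, seed=80 + seed)
            full = (
                mp.chromosome_length_switch_count(mat_m, "c1").morgans
                / mp.chromosome_length_switch_count(mat_f, "c1").morgans
            )
            t_m = mp.chromosome_length_switch_count(mp.truncate_chromosome(mat_m, "c1", 0.15), "c1")
            t_f = mp.chromosome_length_switch_count(mp.truncate_chromosome(mat_f, "c1", 0.15), "c1")
            drops += (t_m.morgans / t_f.morgans) < full
        assert drops >= 8  # one-sided sign check

    def test_loss_table_zero_without_truncation(self, small_population):
        matrix, _ = small_population
        tab = mp.truncation_loss_table(matrix, "c1", 0.0)
        assert (tab["cos_lost"] == 0).all()

    def test_interference_penalizes_multi_co_plants(self):
        # under strong interference, >= 2-CO plants hold their COs nearer the
        # extremities, so truncation costs them more than expected
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            spec = make_spec(L=1.2, n_markers=60)
            matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(5.0)}, 1200, seed=200 + seed)
            tab = mp.truncation_loss_table(matrix, "c1", 0.15)
            multi = tab.loc[tab["co_class"] == ">=2"].iloc[0]
            wins += multi["observed_loss"] > multi["expected_loss"]
        assert wins >= 8

    def test_poisson_placement_loss_is_class_independent(self):
        spec = make_spec(L=1.2, n_markers=60)
        losses = []
        for seed in range(10):
            matrix = sim.simulate_population([spec], {"c1": sim.GammaModel(1.0)}, 1500, seed=300 + seed)
            tab = mp.truncation_loss_table(matrix, "c1", 0.15)
            multi = tab.loc[tab["co_class"] == ">=2"].iloc[0]
            losses.append(multi["observed_loss"] - multi["expected_loss"])
        # no systematic excess loss for the multi-CO class
        assert abs(np.mean(losses)) < 3 * np.std(losses) / np.sqrt(len(losses))


class TestLengthTest:
    def test_identical_samples_p_one(self):
        counts = np.array([1, 2, 0, 1])
        assert mp.compare_lengths_ttest(counts, counts) == 1.0

    def test_symmetry(self):
        a = np.random.default_rng(0).poisson(1.4, 500)
        b = np.random.default_rng(1).poisson(0.8, 500)
        assert mp.compare_lengths_ttest(a, b) == pytest.approx(mp.compare_lengths_ttest(b, a))

    def test_study_scale_difference_is_decisive(self):
        # 142 cM vs 81 cM maps at n = 1500 per sex
        spec_m = make_spec(L=1.42, n_markers=50)
        spec_f = make_spec(L=0.81, n_markers=50)
        mat_m = sim.simulate_population([spec_m], {"c1": sim.GammaModel(2.6)}, 1500, seed=51)
        mat_f = sim.simulate_population([spec_f], {"c1": sim.GammaModel(2.7)}, 1500, seed=52)
        p = mp.compare_lengths_ttest(
            mp.per_plant_co_counts(mat_m, "c1"), mp.per_plant_co_counts(mat_f, "c1")
        )
        assert p < 1e-8


class TestCoCountDistribution:
    def test_all_parental_in_class_zero(self):
        dist = mp.co_count_distribution(make_matrix([[A, A, A]] * 5), "c1")
        assert dist["0"] == 5
        assert dist.sum() == 5

    def test_matches_direct_enumeration(self):
        rows = [
            [A, A, A],  # 0
            [A, H, A],  # 2
            [A, H, H],  # 1
            [H, A, H],  # 2
            [A, M, H],  # 1
        ]
        dist = mp.co_count_distribution(make_matrix(rows), "c1")
        assert dist.tolist() == [1, 2, 2, 0]

    def test_classes_sum_to_informative_plants(self, small_population):
        matrix, _ = small_population
        dist = mp.co_count_distribution(matrix, "c1")
        assert dist.sum() == matrix.n_plants
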