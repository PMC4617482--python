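"""Output partitioning, conditional densities, MIRI and robustness."""

import numpy as np
import pytest
from scipy import stats

import condrobust as cr
from condrobust.core import (
    OutputSamples,
    Partition,
    conditional_densities,
    conditional_parameter_sets,
    estimate_density,
    evaluate_batch,
    kitano_robustness,
    miri,
    miri_table,
    partition_interval,
    partition_output,
    rank_parameters,
)
from condrobust.fixtures import gaussian_density_pair, make_identity_fixture
from condrobust.models import EvaluationFunction


def outputs_from(values, valid=None):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.size, bool) if valid is None else np.asarray(valid)
    return OutputSamples(values=values, fn_name="test", valid=valid)


class TestPartitionOutput:
    def test_order_statistics(self):
        out = outputs_from([5, 1, 9, 3, 7, 2, 10, 4, 8, 6])
        part = partition_output(out, 0.2)
        assert sorted(out.values[part.lower_indices]) == [1, 2]
        assert sorted(out.values[part.upper_indices]) == [9, 10]
        assert part.lower_threshold == 2 and part.upper_threshold == 9

    def test_all_equal_tie_break_disjoint(self):
        out = outputs_from([3.0] * 10)
        part = partition_output(out, 0.1)
        assert part.lower_indices.size == part.upper_indices.size == 1
        assert set(part.lower_indices) & set(part.upper_indices) == set()
        assert part.lower_indices[0] == 0  # ascending-index tie rule

    @pytest.mark.parametrize("n,alpha", [(10000, 0.1), (999, 0.1), (57, 0.25)])
    def test_tail_counts(self, n, alpha, rng):
        out = outputs_from(rng.uniform(size=n))
        part = partition_output(out, alpha)
        expected = int(round(alpha * n))
        assert part.lower_indices.size == expected
        assert part.upper_indices.size == expected
        assert set(part.lower_indices) & set(part.upper_indices) == set()

    def test_masked_rows_excluded(self, rng):
        values = rng.uniform(size=100)
        valid = np.ones(100, bool)
        valid[:20] = False
        part = partition_output(outputs_from(values, valid), 0.1)
        assert part.lower_indices.size == 8  # round(0.1 * 80)
        assert not set(part.lower_indices) & set(np.arange(20))

    def test_invalid_alpha_or_empty_tail(self):
        out = outputs_from(np.arange(10.0))
        with pytest.raises(ValueError):
            partition_output(out, 0.6)
        with pytest.raises(ValueError):
            partition_output(out, 0.01)


class TestPartitionInterval:
    def test_counting(self):
        out = outputs_from(np.arange(1.0, 11.0))
        idx, prob = partition_interval(out, 2.5, 4.5)
        assert sorted(out.values[idx]) == [3, 4]
        assert prob == pytest.approx(0.2)

    def test_full_range_probability_one(self):
        out = outputs_from(np.arange(1.0, 11.0))
        _, prob = partition_interval(out, 0.0, 11.0)
        assert prob == 1.0

    def test_standard_normal_central_mass(self, rng):
        out = outputs_from(rng.standard_normal(10000))
        _, prob = partition_interval(out, -1.0, 1.0)
        assert prob == pytest.approx(0.6827, abs=0.02)


class TestConditionalParameterSets:
    def test_identity_fixture_deciles(self):
        fixture = make_identity_fixture(3, 1)
        samples = cr.sample_l2hs(fixture.space, 2000, seed=0)
        out = outputs_from(fixture.evaluate_matrix(samples.matrix))
        part = partition_output(out, 0.1)
        p_upper, p_lower = conditional_parameter_sets(samples, part)
        # brute-force oracle: sort the driving column directly
        col = np.sort(samples.column("p1"))
        assert p_lower[:, 0].max() == pytest.approx(col[199], abs=1e-12)
        assert p_upper[:, 0].min() == pytest.approx(col[-200], abs=1e-12)
        assert p_upper.shape == p_lower.shape == (200, 3)

    def test_rows_are_disjoint_subsets(self, rng):
        fixture = make_identity_fixture(2, 2)
        samples = cr.sample_l2hs(fixture.space, 100, seed=1)
        out = outputs_from(fixture.evaluate_matrix(samples.matrix))
        part = partition_output(out, 0.2)
        assert not set(part.upper_indices) & set(part.lower_indices)

    def test_empty_partition_rejected(self):
        samples = cr.sample_l2hs(make_identity_fixture(2).space, 10, seed=0)
        empty = Partition(alpha=0.1, lower_indices=np.array([], int),
                          upper_indices=np.array([], int),
                          lower_threshold=0.0, upper_threshold=0.0)
        with pytest.raises(ValueError):
            conditional_parameter_sets(samples, empty)


class TestEstimateDensity:
    def test_normal_density_at_mode(self, rng):
        values = rng.standard_normal(10000)
        kde = estimate_density(values, (-6, 6))
        at_zero = kde.density[np.argmin(np.abs(kde.grid))]
        assert at_zero == pytest.approx(stats.norm.pdf(0), rel=0.05)

    def test_positive_and_normalized(self, rng):
        values = rng.uniform(2, 3, size=500)
        kde = estimate_density(values, (2, 3))
        assert np.all(kde.density >= 0)
        assert kde.integral() <= 1 + 1e-6

    def test_uniform_interior_flat(self, rng):
        values = rng.uniform(size=20000)
        kde = estimate_density(values, (0, 1))
        interior = (kde.grid > 0.2) & (kde.grid < 0.8)
        assert np.all(np.abs(kde.density[interior] - 1.0) < 0.1)

    def test_boundary_leakage_bounded(self, rng):
        # mass leaks past the box edges but stays above 0.95
        values = rng.uniform(size=5000)
        kde = estimate_density(values, (0, 1))
        assert 0.95 <= kde.integral() <= 1.0 + 1e-6

    def test_zero_variance_uses_bandwidth_floor(self):
        kde = estimate_density(np.full(100, 0.5), (0, 1))
        assert np.isfinite(kde.density).all()
        assert kde.bandwidth > 0
        assert kde.mode == pytest.approx(0.5, abs=1e-3)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            estimate_density(np.arange(5.0), (0, 10))


class TestMiri:
    def test_identical_densities_give_zero(self):
        f1, f2 = gaussian_density_pair(0.0, 0.0, 1.0)
        assert miri(f1, f2) == 0.0

    def test_shifted_normals_closed_form(self):
        f1, f2 = gaussian_density_pair(0.0, 3.0, 1.0)
        expected = 2 * (2 * stats.norm.cdf(1.5) - 1)
        assert miri(f1, f2) == pytest.approx(expected, abs=1e-3)

    def test_disjoint_supports_approach_two(self):
        f1, f2 = gaussian_density_pair(0.0, 40.0, 1.0, grid_size=16384)
        assert miri(f1, f2) >= 1.9

    def test_symmetry(self):
        f1, f2 = gaussian_density_pair(0.0, 2.0, 0.7)
        assert miri(f1, f2) == miri(f2, f1)

    def test_grid_mismatch_rejected(self):
        f1, _ = gaussian_density_pair(0.0, 1.0, 1.0)
        _, f2 = gaussian_density_pair(0.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            miri(f1, f2)


class TestRanking:
    def test_rank_parameters_descending(self):
        table = cr.MiriTable(parameters=("a", "b", "c"),
                             mu=np.array([0.1, 1.9, 0.5]), alpha=0.1)
        assert rank_parameters(table, 2) == ("b", "c")
        with pytest.raises(ValueError):
            rank_parameters(table, 4)

    def test_tie_break_declaration_order(self):
        table = cr.MiriTable(parameters=("a", "b", "c"),
                             mu=np.array([0.5, 0.5, 1.0]), alpha=0.1)
        assert table.ranking == ("c", "a", "b")


class TestKitanoRobustness:
    def test_constant_evaluation(self):
        assert kitano_robustness(outputs_from(np.full(100, 7.5))) == 7.5

    def test_uniform_fixture_mean(self):
        fixture = make_identity_fixture(2, 1)
        samples = cr.sample_l2hs(fixture.space, 4000, seed=3)
        out = outputs_from(fixture.evaluate_matrix(samples.matrix))
        assert kitano_robustness(out) == pytest.approx(0.5, abs=3 / np.sqrt(4000))

    def test_permutation_invariance(self, rng):
        values = rng.uniform(size=200)
        perm = rng.permutation(200)
        assert kitano_robustness(outputs_from(values)) == pytest.approx(
            kitano_robustness(outputs_from(values[perm])))


class TestEvaluateBatch:
    def test_identity_fixture_returns_first_column(self):
        fixture = make_identity_fixture(3, 1)
        samples = cr.sample_l2hs(fixture.space, 100, seed=0)
        fn = EvaluationFunction("area", "z")
        out = evaluate_batch(fixture, samples, fn)
        assert np.array_equal(out.values, samples.matrix[:, 0])
        assert out.n_effective == 100

    def test_worker_count_invariance(self, pulse_model, pulse_space):
        samples = cr.sample_l2hs(pulse_space, 24, seed=11)
        fn = EvaluationFunction("area", "Y")
        sim = cr.SimulationConfig(horizon=100, grid_size=201)
        serial = evaluate_batch(pulse_model, samples, fn, sim=sim, n_workers=1)
        parallel = evaluate_batch(pulse_model, samples, fn, sim=sim, n_workers=2)
        assert np.array_equal(serial.values, parallel.values)
        assert np.array_equal(serial.valid, parallel.valid)

    def test_multi_objective_shares_trajectories(self, pulse_model, pulse_space):
        samples = cr.sample_l2hs(pulse_space, 10, seed=4)
        fns = [EvaluationFunction("area", "Y"),
               EvaluationFunction("maximum", "Y")]
        sim = cr.SimulationConfig(horizon=100, grid_size=201)
        result = evaluate_batch(pulse_model, samples, fns, sim=sim)
        assert set(result) == {"area", "maximum"}
        single = evaluate_batch(pulse_model, samples, fns[1], sim=sim)
        assert np.array_equal(result["maximum"].values, single.values)

    def test_unknown_column_rejected(self, pulse_model):
        space = cr.build_parameter_space({"bogus": 1.0})
        samples = cr.sample_l2hs(space, 10, seed=0)
        with pytest.raises(ValueError):
            evaluate_batch(pulse_model, samples, EvaluationFunction("area", "Y"))


def test_miri_table_from_conditional_densities():
    fixture = make_identity_fixture(3, 2)
    samples = cr.sample_l2hs(fixture.space, 3000, seed=5)
    values = fixture.evaluate_matrix(samples.matrix)
    out = OutputSamples(values=values, fn_name="z",
                        valid=np.ones(values.size, bool))
    part = partition_output(out, 0.1)
    dens = conditional_densities(samples, part)
    table = miri_table(dens, 0.1)
    assert table.ranking[0] == "p2"
    assert np.all(table.mu >= 0) and np.all(table.mu <= 2)
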