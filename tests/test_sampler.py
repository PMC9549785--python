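import numpy as np
import pytest
from scipy import stats

from spotdecon import (
    CellTypeAnnotation,
    GeneCountMatrix,
    generate_dataset,
    sample_composition,
    sample_proportions,
    stratified_split,
    synthesize_profile,
    temperature_weights,
)
from spotdecon.sampler import CellTypeCountVector, _largest_remainder


class TestTemperatureWeights:
    def test_temp_zero_is_uniform(self):
        w = temperature_weights(0, 10, 10.0, 4, np.random.default_rng(0))
        np.testing.assert_allclose(w.p, [0.25] * 4, atol=1e-15)

    def test_temp_max_is_geometric_ladder(self):
        w = temperature_weights(10, 10, 10.0, 3, np.random.default_rng(1))
        np.testing.assert_allclose(
            sorted(w.p), [1 / 111, 10 / 111, 100 / 111], atol=1e-12
        )

    def test_half_temperature(self):
        w = temperature_weights(1, 2, 4.0, 2, np.random.default_rng(2))
        np.testing.assert_allclose(sorted(w.p), [1 / 3, 2 / 3], atol=1e-12)

    def test_max_min_ratio_is_base_power_k_minus_one(self):
        for K, base in [(3, 2.0), (5, 10.0), (11, 10.0)]:
            w = temperature_weights(7, 7, base, K, np.random.default_rng(3))
            assert w.p.max() / w.p.min() == pytest.approx(base ** (K - 1), rel=1e-9)

    def test_base_at_or_below_one_rejected(self):
        with pytest.raises(ValueError, match="base"):
            temperature_weights(5, 10, 1.0, 3, np.random.default_rng(0))

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        for temp in range(11):
            w = temperature_weights(temp, 10, 10.0, 7, rng)
            assert w.p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w.p > 0)


class TestSampleComposition:
    def test_sums_to_density(self):
        rng = np.random.default_rng(0)
        for density in (1, 5, 30):
            w = temperature_weights(5, 10, 10.0, 4, rng)
            comp = sample_composition(w, density, rng)
            assert comp.x.sum() == density
            assert comp.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_near_one_hot_weights_put_all_cells_in_one_type(self):
        eps = 1e-12
        from spotdecon.sampler import TemperatureWeights

        p = np.array([1 - 2 * eps, eps, eps])
        w = TemperatureWeights(p / p.sum(), temp=10, steps=10, base=10.0)
        comp = sample_composition(w, 10, np.random.default_rng(0))
        assert comp.x[0] == 10

    def test_density_one_is_single_draw(self):
        rng = np.random.default_rng(1)
        w = temperature_weights(0, 10, 10.0, 5, rng)
        comp = sample_composition(w, 1, rng)
        assert sorted(comp.x)[-1] == 1 and comp.x.sum() == 1

    def test_density_below_one_rejected(self):
        w = temperature_weights(0, 10, 10.0, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample_composition(w, 0, np.random.default_rng(0))

    def test_binomial_moment(self):
        # uniform p, K=2, density=10: mean count of type 1 is 5 +- 3 SE
        rng = np.random.default_rng(2)
        w = temperature_weights(0, 10, 10.0, 2, rng)
        n = 10_000
        draws = np.array([sample_composition(w, 10, rng).x[0] for _ in range(n)])
        se = np.sqrt(10 * 0.5 * 0.5 / n)
        assert abs(draws.mean() - 5.0) < 3 * se

    def test_frequencies_match_exact_multinomial_pmf(self):
        # K=3, density=2: six outcomes, exhaustive chi-square against the pmf
        rng = np.random.default_rng(3)
        p = np.array([0.5, 0.3, 0.2])
        from spotdecon.sampler import TemperatureWeights

        w = TemperatureWeights(p, temp=0, steps=1, base=10.0)
        n = 50_000
        outcomes = {}
        for _ in range(n):
            x = tuple(sample_composition(w, 2, rng).x)
            outcomes[x] = outcomes.get(x, 0) + 1
        support = [x for x in outcomes]
        observed = np.array([outcomes[x] for x in support])
        expected = np.array(
            [stats.multinomial.pmf(x, 2, p) for x in support]
        ) * n
        assert len(support) == 6  # all compositions of 2 into 3 parts seen
        _, pval = stats.chisquare(observed, expected)
        assert pval > 0.01


class TestSynthesizeProfile:
    def _split(self, rows, labels, genes=None):
        genes = genes or [f"g{j}" for j in range(len(rows[0]))]
        obs = [f"c{i}" for i in range(len(rows))]
        matrix = GeneCountMatrix(np.array(rows, dtype=float), obs, genes)
        ann = CellTypeAnnotation(dict(zip(obs, labels)), sorted(set(labels)))
        return matrix, ann

    def test_mean_then_normalize(self):
        # two identical type-A cells; the B cell is never drawn
        split = self._split([[2, 6], [2, 6], [9, 9]], ["A", "A", "B"])
        comp = CellTypeCountVector(np.array([2, 0]), 2)
        spot = synthesize_profile(comp, split, np.random.default_rng(0))
        np.testing.assert_allclose(spot.profile, [0.25, 0.75], atol=1e-12)
        np.testing.assert_allclose(spot.proportions, [1.0, 0.0], atol=1e-15)

    def test_two_types_average(self):
        split = self._split([[1, 0], [0, 1]], ["A", "B"])
        comp = CellTypeCountVector(np.array([1, 1]), 2)
        spot = synthesize_profile(comp, split, np.random.default_rng(0))
        np.testing.assert_allclose(spot.profile, [0.5, 0.5], atol=1e-12)
        np.testing.assert_allclose(spot.proportions, [0.5, 0.5], atol=1e-15)

    def test_missing_type_error_names_it(self):
        split = self._split([[1, 0], [0, 1]], ["A", "B"])
        matrix, ann = split
        only_a = matrix.subset_obs(["c0"])
        ann_a = CellTypeAnnotation({"c0": "A"}, ["A", "B"])
        comp = CellTypeCountVector(np.array([0, 1]), 1)
        with pytest.raises(ValueError, match="B"):
            synthesize_profile(comp, (only_a, ann_a), np.random.default_rng(0))

    def test_all_zero_cells_rejected(self):
        split = self._split([[0, 0], [1, 1]], ["A", "B"])
        comp = CellTypeCountVector(np.array([1, 0]), 1)
        with pytest.raises(ValueError, match="zero"):
            synthesize_profile(comp, split, np.random.default_rng(0))


class TestStratifiedSplit:
    def _reference(self, per_type=100, K=3):
        n = per_type * K
        rng = np.random.default_rng(0)
        obs = [f"c{i}" for i in range(n)]
        labels = sum(([f"T{k}"] * per_type for k in range(K)), [])
        matrix = GeneCountMatrix(
            rng.poisson(2.0, size=(n, 5)).astype(float), obs, [f"g{j}" for j in range(5)]
        )
        return matrix, CellTypeAnnotation(dict(zip(obs, labels)), [f"T{k}" for k in range(K)])

    def test_exact_division(self):
        matrix, ann = self._reference(100)
        splits = stratified_split(matrix, ann, (0.8, 0.1, 0.1), seed=0)
        for (m, a), expected in zip(splits, (80, 10, 10)):
            codes = a.labels_for(m.obs_ids)
            assert np.bincount(codes, minlength=3).tolist() == [expected] * 3

    def test_largest_remainder_with_forced_minimum(self):
        # 10 cells at (0.9, 0.05, 0.05): floor gives (9,0,0); the remainder
        # goes to one 0.05 split and the other is force-fed from the largest
        assert _largest_remainder(10, (0.9, 0.05, 0.05)) == [8, 1, 1]

    def test_small_type_all_splits_nonempty(self):
        matrix, ann = self._reference(10)
        splits = stratified_split(matrix, ann, (0.9, 0.05, 0.05), seed=0)
        for m, a in splits:
            assert m.n_obs > 0
            assert set(a.labels_for(m.obs_ids)) == {0, 1, 2}

    def test_disjoint_and_exhaustive(self):
        matrix, ann = self._reference(33)
        splits = stratified_split(matrix, ann, (0.8, 0.1, 0.1), seed=1)
        ids = [set(m.obs_ids) for m, _ in splits]
        assert ids[0] & ids[1] == ids[0] & ids[2] == ids[1] & ids[2] == set()
        assert ids[0] | ids[1] | ids[2] == set(matrix.obs_ids)

    def test_bad_fractions_rejected(self):
        matrix, ann = self._reference(10)
        with pytest.raises(ValueError, match="sum to 1"):
            stratified_split(matrix, ann, (0.5, 0.5, 0.5), seed=0)


class TestGenerateDataset:
    def test_spot_count_and_sums(self, separable_reference):
        _, matrix, annotation = separable_reference
        small = matrix.subset_obs(
            [o for o in matrix.obs_ids if o.endswith(("_0", "_1", "_2", "_3", "_4"))]
        )
        ann = CellTypeAnnotation(
            {o: annotation.mapping[o] for o in small.obs_ids}, annotation.label_order
        )
        ds = generate_dataset((small, ann), (10, 12), 5, seed=0)
        assert ds.n_spots == 5 * 3
        np.testing.assert_allclose(ds.profiles.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(ds.proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_bit_identical(self, separable_reference):
        _, matrix, annotation = separable_reference
        a = generate_dataset((matrix, annotation), (5, 6), 10, seed=123)
        b = generate_dataset((matrix, annotation), (5, 6), 10, seed=123)
        assert np.array_equal(a.profiles, b.profiles)
        assert np.array_equal(a.proportions, b.proportions)
        assert np.array_equal(a.temps, b.temps)

    def test_save_load_roundtrip(self, separable_reference, tmp_path):
        _, matrix, annotation = separable_reference
        ds = generate_dataset((matrix, annotation), (5, 5), 4, seed=9)
        ds.save(tmp_path / "ds")
        back = ds.load(tmp_path / "ds")
        np.testing.assert_allclose(back.profiles, ds.profiles, atol=1e-9)
        np.testing.assert_allclose(back.proportions, ds.proportions, atol=1e-9)
        assert back.label_order == ds.label_order


class TestProportionSampling:
    def test_extremes_reachable(self):
        # with temp drawn uniformly, every type hits proportion >= 0.9 somewhere
        props, _, _ = sample_proportions(5, (10, 14), 2000, seed=0)
        assert props.shape == (10_000, 5)
        assert np.all(props.max(axis=0) >= 0.9)

    def test_shuffle_removes_positional_bias(self):
        props, _, _ = sample_proportions(5, (10, 14), 2000, seed=1)
        means = props.mean(axis=0)
        # marginal means equal across types within Monte-Carlo error
        se = props.std(axis=0).max() / np.sqrt(props.shape[0])
        assert np.all(np.abs(means - 0.2) < 5 * se)
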