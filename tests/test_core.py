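import numpy as np
import pytest

from emsfilter import (
    Component,
    ConditionPair,
    CVScheme,
    EMSError,
    EffectScenario,
    EpochedDataset,
    ems_transform,
    filter_similarity,
    gen_effect_dataset,
    mean_difference,
    normalize_filter,
    project_topography,
    stationary_transform,
    whiten_filter,
    windowed_difference,
)

from conftest import brute_force_loo_ems


class TestNormalizeFilter:
    def test_three_four_five(self):
        w, flag = normalize_filter(np.array([3.0, 4.0]))
        np.testing.assert_allclose(w, [0.6, 0.8])
        assert not flag

    def test_zero_vector_degenerate(self):
        w, flag = normalize_filter(np.array([0.0, 0.0]))
        np.testing.assert_array_equal(w, [0.0, 0.0])
        assert flag

    def test_diagonal(self):
        w, _ = normalize_filter(np.array([1.0, -1.0]))
        np.testing.assert_allclose(w, [0.70711, -0.70711], atol=1e-5)
        assert abs(np.linalg.norm(w) - 1.0) < 1e-10

    def test_non_finite_raises(self):
        with pytest.raises(EMSError):
            normalize_filter(np.array([1.0, np.nan]))


class TestProjectTopography:
    def test_dot_product(self):
        assert project_topography([1.0, 2.0], [0.6, 0.8]) == pytest.approx(2.2)

    def test_orthogonal_zero(self):
        assert project_topography([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_basis_selection(self):
        assert project_topography([3.5, -1.0], [1.0, 0.0]) == 3.5

    def test_length_mismatch_raises(self):
        with pytest.raises(EMSError):
            project_topography([1.0], [1.0, 0.0])


class TestEmsTransform:
    def test_hand_enumeration_oracle(self, hand_dataset, pair):
        sm, fs = ems_transform(hand_dataset, mean_difference(pair))
        # fold leaving out trial 0: d = mean_A\{0} - mean_B = (0,2)-(-1,-1) = (1,3)
        np.testing.assert_allclose(
            fs.filters[:, 0, 0], np.array([1.0, 3.0]) / np.sqrt(10)
        )
        assert sm.values[0, 0] == pytest.approx(2 / np.sqrt(10))
        oracle_s, oracle_f = brute_force_loo_ems(
            hand_dataset.data, hand_dataset.labels
        )
        np.testing.assert_allclose(sm.values, oracle_s, atol=1e-12)
        np.testing.assert_allclose(fs.filters, oracle_f, atol=1e-12)

    def test_matches_brute_force_on_random_data(self, small_random_dataset, pair):
        sm, fs = ems_transform(small_random_dataset, mean_difference(pair))
        oracle_s, oracle_f = brute_force_loo_ems(
            small_random_dataset.data, small_random_dataset.labels
        )
        np.testing.assert_allclose(sm.values, oracle_s, atol=1e-10)
        np.testing.assert_allclose(fs.filters, oracle_f, atol=1e-10)

    def test_exact_null_fully_degenerate(self, pair):
        # class means exactly equal at every fold -> all surrogates 0 + mask
        data = np.ones((2, 3, 4))
        ds = EpochedDataset(
            data=data, times=np.arange(3) / 100.0, labels=np.array([0, 0, 1, 1])
        )
        sm, fs = ems_transform(ds, mean_difference(pair))
        assert fs.degenerate.all()
        assert sm.degenerate.all()
        np.testing.assert_array_equal(sm.values, 0.0)

    def test_scale_equivariance(self, small_random_dataset, pair):
        sm1, fs1 = ems_transform(small_random_dataset, mean_difference(pair))
        scaled = small_random_dataset.copy()
        scaled.data *= 3.0
        sm2, fs2 = ems_transform(scaled, mean_difference(pair))
        np.testing.assert_allclose(sm2.values, 3.0 * sm1.values, rtol=1e-10)
        np.testing.assert_allclose(fs2.filters, fs1.filters, atol=1e-12)

    def test_channel_permutation_invariance(self, small_random_dataset, pair):
        sm1, _ = ems_transform(small_random_dataset, mean_difference(pair))
        perm = np.random.default_rng(1).permutation(
            small_random_dataset.n_channels
        )
        permuted = small_random_dataset.copy()
        permuted.data = permuted.data[perm]
        permuted.channel_names = [permuted.channel_names[i] for i in perm]
        permuted.channel_groups = permuted.channel_groups[perm]
        sm2, _ = ems_transform(permuted, mean_difference(pair))
        np.testing.assert_allclose(sm2.values, sm1.values, atol=1e-10)

    def test_zero_channel_append_invariance(self, small_random_dataset, pair):
        sm1, _ = ems_transform(small_random_dataset, mean_difference(pair))
        aug = small_random_dataset.copy()
        aug.data = np.concatenate(
            [aug.data, np.zeros((1,) + aug.data.shape[1:])], axis=0
        )
        aug.channel_names = aug.channel_names + ["zero"]
        aug.channel_groups = np.concatenate([aug.channel_groups, [0]])
        sm2, _ = ems_transform(aug, mean_difference(pair))
        np.testing.assert_allclose(sm2.values, sm1.values, atol=1e-12)

    def test_no_leakage_bit_identical(self, small_random_dataset, pair):
        _, fs = ems_transform(small_random_dataset, mean_difference(pair))
        for fold_k in (0, 3, 7):
            corrupted = small_random_dataset.copy()
            corrupted.data[:, :, fs.folds[fold_k]] = 1e6
            _, fs2 = ems_transform(corrupted, mean_difference(pair))
            assert np.array_equal(
                fs.filters[:, :, fold_k], fs2.filters[:, :, fold_k]
            )

    def test_loopc_unequal_counts_error(self, pair):
        rng = np.random.default_rng(0)
        ds = EpochedDataset(
            data=rng.standard_normal((2, 3, 5)),
            times=np.arange(3) / 100.0,
            labels=np.array([0, 0, 0, 1, 1]),
        )
        with pytest.raises(EMSError, match="balance_trial_counts"):
            ems_transform(ds, mean_difference(pair), CVScheme("loopc", seed=0))

    def test_too_few_trials_per_class(self, pair):
        ds = EpochedDataset(
            data=np.random.default_rng(0).standard_normal((2, 3, 3)),
            times=np.arange(3) / 100.0,
            labels=np.array([0, 0, 1]),
        )
        with pytest.raises(EMSError, match="2 trials"):
            ems_transform(ds, mean_difference(pair))

    def test_mixed_units_refused(self, pair):
        rng = np.random.default_rng(0)
        ds = EpochedDataset(
            data=rng.standard_normal((4, 3, 6)),
            times=np.arange(3) / 100.0,
            labels=np.array([0, 1] * 3),
            channel_groups=np.array([0, 0, 1, 1]),
            units={0: "fT", 1: "fT/cm"},
        )
        with pytest.raises(EMSError, match="z-score"):
            ems_transform(ds, mean_difference(pair))

    def test_deterministic_given_seeded_scheme(self, pair):
        rng = np.random.default_rng(0)
        ds = EpochedDataset(
            data=rng.standard_normal((3, 4, 12)),
            times=np.arange(4) / 100.0,
            labels=np.array([0, 1] * 6),
        )
        scheme = CVScheme("kfold", k=4, seed=9)
        sm1, _ = ems_transform(ds, mean_difference(pair), scheme)
        sm2, _ = ems_transform(ds, mean_difference(pair), scheme)
        np.testing.assert_array_equal(sm1.values, sm2.values)


class TestCVScheme:
    @pytest.mark.parametrize(
        "scheme",
        [
            CVScheme("loo"),
            CVScheme("loopc", seed=0),
            CVScheme("kfold", k=4, seed=1),
            CVScheme("loso", subject_ids=np.repeat(np.arange(4), 3)),
        ],
    )
    def test_every_trial_in_exactly_one_fold(self, scheme):
        labels = np.array([0, 1] * 6)
        folds = scheme.folds(labels, ConditionPair(0, 1))
        all_trials = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_trials, np.arange(12))

    def test_loopc_one_per_condition(self):
        labels = np.array([0, 1] * 5)
        folds = CVScheme("loopc", seed=3).folds(labels, ConditionPair(0, 1))
        for fold in folds:
            assert sorted(labels[fold]) == [0, 1]

    def test_unknown_kind_raises(self):
        with pytest.raises(EMSError):
            CVScheme("bootstrap")


class TestStationaryTransform:
    def test_single_sample_reduces_to_ems(self, hand_dataset, pair):
        sm_e, _ = ems_transform(hand_dataset, mean_difference(pair))
        sm_s, fs_s = stationary_transform(
            hand_dataset, windowed_difference(pair, (0.0, 0.01))
        )
        np.testing.assert_allclose(sm_s.values, sm_e.values, atol=1e-12)
        assert fs_s.filters.shape[1] == 1

    def test_peak_inside_template_window_and_reappearance(self):
        # topography active in W = [0.1, 0.3) and again in W' = [0.6, 0.8);
        # the generator plants effects on condition-1 trials, so the
        # effect/control pair is (1, 0)
        effect_pair = ConditionPair(1, 0)
        topo = np.array([1.0, -1.0, 0.5, 0.0])
        scenario = EffectScenario(
            n_channels=4, n_samples=100, n_trials_per_class=15,
            tmin=0.0, noise_sd=0.3, seed=21,
            components=[
                Component(topography=topo, window=(0.1, 0.3), amplitude=2.0),
                Component(topography=topo, window=(0.6, 0.8), amplitude=2.0),
            ],
        )
        ds, _ = gen_effect_dataset(scenario)
        sm, _ = stationary_transform(ds, windowed_difference(effect_pair, (0.1, 0.3)))
        labels = sm.labels
        course = sm.values[labels == 1].mean(axis=0) - sm.values[labels == 0].mean(axis=0)
        t = ds.times
        in_w = (t >= 0.1) & (t < 0.3)
        in_w2 = (t >= 0.6) & (t < 0.8)
        outside = ~(in_w | in_w2)
        assert course[in_w].max() > 3 * np.abs(course[outside]).mean()
        # same template reappearing later -> deflection also at W'
        assert course[in_w2].max() > 3 * np.abs(course[outside]).mean()

    def test_per_timepoint_objective_rejected(self, hand_dataset, pair):
        with pytest.raises(EMSError, match="stationary"):
            stationary_transform(hand_dataset, mean_difference(pair))


class TestWhitenFilter:
    def test_identity_covariance_keeps_direction(self):
        d = np.array([1.0, 2.0, -1.0])
        out = whiten_filter(d, np.eye(3))
        np.testing.assert_allclose(out, d)

    def test_full_shrinkage_isotropic_limit(self):
        d = np.array([1.0, -1.0])
        sigma = np.array([[2.0, 0.7], [0.7, 2.0]])
        out = whiten_filter(d, sigma, shrinkage=1.0)
        np.testing.assert_allclose(out / np.linalg.norm(out),
                                   d / np.linalg.norm(d))

    def test_noisy_channel_downweighted(self):
        out = whiten_filter(np.array([1.0, 1.0]), np.diag([4.0, 1.0]))
        np.testing.assert_allclose(out, [0.25, 1.0])

    def test_asymmetric_covariance_raises(self):
        with pytest.raises(EMSError, match="symmetric"):
            whiten_filter(np.ones(2), np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestFilterSimilarity:
    def _fs_from_filters(self, filters):
        from emsfilter import SpatialFilterSet

        return SpatialFilterSet(
            filters=filters, folds=[np.array([k]) for k in range(filters.shape[2])],
            scheme="loo", normalized=True,
        )

    def test_identical_filters_all_ones(self):
        w = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        filters = np.tile(w[:, None, None], (1, 5, 3))
        sim = filter_similarity(self._fs_from_filters(filters))
        np.testing.assert_allclose(sim, 1.0, atol=1e-10)

    def test_sign_flip_gives_minus_one(self):
        w = np.array([1.0, -2.0, 0.5])
        filters = np.stack([w, -w], axis=1)[:, :, None]
        sim = filter_similarity(self._fs_from_filters(filters))
        assert sim[0, 1] == pytest.approx(-1.0)

    def test_two_regime_block_structure(self, pair):
        topo1 = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        topo2 = np.array([0.0, 0.0, 0.0, 0.0, 1.0, -1.0])
        scenario = EffectScenario(
            n_channels=6, n_samples=60, n_trials_per_class=20,
            tmin=0.0, noise_sd=0.2, seed=5,
            components=[
                Component(topography=topo1, window=(0.1, 0.25), amplitude=3.0),
                Component(topography=topo2, window=(0.35, 0.5), amplitude=3.0),
            ],
        )
        ds, _ = gen_effect_dataset(scenario)
        _, fs = ems_transform(ds, mean_difference(pair))
        sim = filter_similarity(fs)
        t = ds.times
        block1 = np.flatnonzero((t >= 0.12) & (t < 0.23))
        block2 = np.flatnonzero((t >= 0.37) & (t < 0.48))
        within1 = sim[np.ix_(block1, block1)].mean()
        within2 = sim[np.ix_(block2, block2)].mean()
        between = sim[np.ix_(block1, block2)].mean()
        assert within1 > between + 0.3
        assert within2 > between + 0.3
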