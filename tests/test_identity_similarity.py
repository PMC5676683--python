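"""Appearance similarity and the identity-likelihood matrix."""

import numpy as np
import pytest
from scipy import stats

from toxid.identity_similarity import (
    SimilarityConfig,
    build_id_matrix,
    build_sim_matrix,
    coexist,
    fragment_similarity,
    pair_correlations,
    pearson,
    shape_diff,
    similarity_amplitude,
    weighted_distribution,
)

from conftest import make_detection, make_hist_fragment


CFG = SimilarityConfig()


class TestPearson:
    def test_self_correlation(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_gives_zero(self):
        assert pearson([5, 5, 5], [1, 2, 3]) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])


class TestShapeDiff:
    def test_zero_at_identity(self):
        d = make_detection(hu=np.full(7, 0.3))
        assert shape_diff(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_single_component_hand_value(self):
        hu1 = np.full(7, 0.5)
        hu2 = hu1.copy()
        hu1[0], hu2[0] = 0.2, 0.25
        d1, d2 = make_detection(hu=hu1), make_detection(hu=hu2)
        assert shape_diff(d1, d2) == pytest.approx(1.0, abs=1e-9)  # |5 - 4|

    def test_symmetric(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d1 = make_detection(hu=rng.normal(0, 1, 7))
            d2 = make_detection(hu=rng.normal(0, 1, 7))
            assert shape_diff(d1, d2) == pytest.approx(shape_diff(d2, d1), rel=1e-12)

    def test_epsilon_guards_tiny_invariants(self):
        d1 = make_detection(hu=np.full(7, 1e-30))
        d2 = make_detection(hu=np.full(7, -1e-30))
        assert np.isfinite(shape_diff(d1, d2, hu_epsilon=1e-8))


class TestPairCorrelations:
    def test_identical_histograms_correlate_perfectly(self):
        h = np.arange(32)
        fR = make_hist_fragment(0, [h] * 3, start_frame=0)
        fC = make_hist_fragment(1, [h] * 4, start_frame=100)
        corr, n = pair_correlations(fR, fC, CFG)
        assert n == 12 and len(corr) == 12
        np.testing.assert_allclose(corr, 1.0)

    def test_shape_filter_can_exclude_everything(self):
        cfg = SimilarityConfig(shape_diff_limit=0.0)
        fR = make_hist_fragment(0, [np.arange(32)] * 3, hu=np.full(7, 0.2))
        fC = make_hist_fragment(1, [np.arange(32)] * 3, start_frame=50, hu=np.full(7, 0.4))
        corr, n = pair_correlations(fR, fC, cfg)
        assert len(corr) == 0 and n == 9

    def test_cross_product_count(self):
        rng = np.random.default_rng(0)
        fR = make_hist_fragment(0, rng.integers(0, 50, (3, 32)))
        fC = make_hist_fragment(1, rng.integers(0, 50, (4, 32)), start_frame=50)
        corr, n = pair_correlations(fR, fC, CFG)
        assert len(corr) == 12 and n == 12

    def test_matches_scalar_pearson(self):
        """The vectorised z-score path reproduces the scalar Pearson."""
        rng = np.random.default_rng(1)
        HR = rng.uniform(0, 100, (4, 32))
        HC = rng.uniform(0, 100, (5, 32))
        fR = make_hist_fragment(0, HR)
        fC = make_hist_fragment(1, HC, start_frame=50)
        corr, _ = pair_correlations(fR, fC, CFG)
        expected = [
            stats.pearsonr(hr, hc).statistic for hr in HR for hc in HC
        ]
        np.testing.assert_allclose(sorted(corr), sorted(expected), atol=1e-12)

    def test_subsampling_is_deterministic_and_symmetric(self):
        rng = np.random.default_rng(4)
        fR = make_hist_fragment(0, rng.integers(0, 60, (120, 32)))
        fC = make_hist_fragment(1, rng.integers(0, 60, (120, 32)), start_frame=500)
        cfg = SimilarityConfig(max_pairs=1000)
        c1, n1 = pair_correlations(fR, fC, cfg)
        c2, n2 = pair_correlations(fC, fR, cfg)
        assert n1 == n2 == 1000
        np.testing.assert_array_equal(c1, c2)


class TestWeightedDistribution:
    def test_all_ones_hand_value(self):
        got = weighted_distribution(np.ones(12), 12, SimilarityConfig())
        assert got == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_nonpositive_correlations_contribute_nothing(self):
        assert weighted_distribution(np.array([-1.0, -0.2, 0 - 1e-9]), 3, CFG) == 0.0

    def test_negatives_dilute_the_denominator(self):
        full = weighted_distribution(np.ones(10), 10, CFG)
        half = weighted_distribution(np.concatenate([np.ones(5), -np.ones(5)]), 10, CFG)
        assert half == pytest.approx(full / 2, abs=1e-12)

    def test_empty(self):
        assert weighted_distribution(np.empty(0), 0, CFG) == 0.0


class TestSimilarityAmplitude:
    def test_max_and_conventions(self):
        assert similarity_amplitude(np.array([0.2, 0.9, -0.5])) == pytest.approx(0.9)
        assert similarity_amplitude(np.empty(0)) == 0.0
        assert similarity_amplitude(np.array([0.7, 0.7])) == pytest.approx(0.7)


class TestFragmentSimilarity:
    def test_self_copy_reaches_all_ones_value(self):
        h = np.arange(32)
        fR = make_hist_fragment(0, [h] * 5)
        fC = make_hist_fragment(1, [h] * 5, start_frame=100)
        assert fragment_similarity(fR, fC, CFG) == pytest.approx(np.exp(-0.5), abs=1e-9)

    def test_anticorrelated_clamped_to_zero(self):
        up, down = np.arange(32), np.arange(32)[::-1]
        fR = make_hist_fragment(0, [up] * 3)
        fC = make_hist_fragment(1, [down] * 3, start_frame=100)
        assert fragment_similarity(fR, fC, CFG) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            fR = make_hist_fragment(0, rng.integers(0, 90, (6, 32)))
            fC = make_hist_fragment(1, rng.integers(0, 90, (4, 32)), start_frame=100)
            assert fragment_similarity(fR, fC, CFG) == pytest.approx(
                fragment_similarity(fC, fR, CFG), abs=1e-12
            )

    def test_noise_never_increases_similarity(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 100, (20, 32))
        fA = make_hist_fragment(0, base.astype(int))
        sims = []
        for noise in (0.0, 10.0, 25.0, 60.0, 150.0):
            pert = np.clip(
                base + np.random.default_rng(42).normal(0, noise, base.shape), 0, None
            )
            fB = make_hist_fragment(1, pert.astype(int), start_frame=500)
            sims.append(fragment_similarity(fA, fB, CFG))
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))


class TestCoexist:
    def test_interval_logic(self):
        f1 = make_hist_fragment(0, [np.arange(32)] * 100, start_frame=0)    # 0..99
        f2 = make_hist_fragment(1, [np.arange(32)] * 101, start_frame=50)   # 50..150
        f3 = make_hist_fragment(2, [np.arange(32)] * 51, start_frame=100)   # 100..150
        assert coexist(f1, f2)
        assert not coexist(f1, f3)  # adjacent intervals do not coexist
        assert coexist(f1, f1)


def _two_class_fragments(n_per_class=3, samples=6, seed=0):
    """Fragments drawn from two texture classes, pairwise non-coexisting."""
    rng = np.random.default_rng(seed)
    protos = [rng.uniform(0, 100, 32), rng.uniform(0, 100, 32)]
    frags, classes = [], []
    for k in range(2 * n_per_class):
        cls = k % 2
        hists = np.clip(protos[cls] + rng.normal(0, 3, (samples, 32)), 0, None)
        frags.append(make_hist_fragment(k, hists.astype(int), start_frame=1000 * k))
        classes.append(cls)
    return frags, classes


class TestIdMatrix:
    def test_identical_profiles_give_one(self):
        frags, classes = _two_class_fragments()
        idm = build_id_matrix(frags, CFG)
        same = [
            idm.values[i, j]
            for i in range(len(frags))
            for j in range(i + 1, len(frags))
            if classes[i] == classes[j]
        ]
        assert min(same) > 0.95

    def test_coexisting_pairs_zeroed_regardless_of_appearance(self):
        h = np.arange(32)
        f1 = make_hist_fragment(0, [h] * 5, start_frame=0)
        f2 = make_hist_fragment(1, [h] * 5, start_frame=2)   # overlaps f1
        f3 = make_hist_fragment(2, [h] * 5, start_frame=100)
        f4 = make_hist_fragment(3, [h] * 5, start_frame=200)
        idm = build_id_matrix([f1, f2, f3, f4], CFG)
        assert idm.values[0, 1] == 0.0 == idm.values[1, 0]

    def test_anticorrelated_profiles_clamped(self):
        frags, classes = _two_class_fragments()
        idm = build_id_matrix(frags, CFG)
        cross = [
            idm.values[i, j]
            for i in range(len(frags))
            for j in range(i + 1, len(frags))
            if classes[i] != classes[j]
        ]
        assert min(cross) >= 0.0  # negative profile correlations clamp to 0

    def test_matrix_invariants(self):
        frags, _ = _two_class_fragments(seed=3)
        sim = build_sim_matrix(frags, CFG)
        idm = build_id_matrix(frags, CFG, sim)
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-9)
        np.testing.assert_allclose(idm.values, idm.values.T, atol=1e-9)
        assert (idm.values >= 0).all() and (idm.values <= 1).all()
        np.testing.assert_array_equal(np.diag(idm.values), 1.0)
        # coexistence zeros exactly where the brute-force interval oracle says
        for i in range(len(frags)):
            for j in range(len(frags)):
                if i == j:
                    continue
                a, b = frags[i], frags[j]
                overlap = any(
                    a.start_frame <= k <= a.end_frame for k in range(b.start_frame, b.end_frame + 1)
                )
                if overlap:
                    assert idm.values[i, j] == 0.0

    def test_within_class_similarity_exceeds_between(self):
        frags, classes = _two_class_fragments(seed=7)
        sim = build_sim_matrix(frags, CFG)
        within, between = [], []
        for i in range(len(frags)):
            for j in range(i + 1, len(frags)):
                (within if classes[i] == classes[j] else between).append(sim.values[i, j])
        assert np.mean(within) > np.mean(between)

    def test_roundtrip_csv(self, tmp_path):
        frags, _ = _two_class_fragments()
        idm = build_id_matrix(frags, CFG)
        path = tmp_path / "id.csv"
        idm.to_csv(path)
        back = type(idm).from_csv(path)
        assert back.fragment_ids == idm.fragment_ids
        np.testing.assert_allclose(back.values, idm.values, atol=1e-12)
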