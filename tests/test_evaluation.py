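"""Verification metrics: pair enumeration, accuracy, ROC/AUC, FAR/FRR/EER."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.optimize import brentq

import pulsetwin as pt
from pulsetwin.evaluation import ScoreSet, far_frr_eer, score_histogram


def brute_force_auc(genuine, impostor):
    """Mann-Whitney style oracle: P(genuine > impostor), ties count 1/2."""
    total = 0.0
    for g in genuine:
        for i in impostor:
            total += 1.0 if g > i else (0.5 if g == i else 0.0)
    return total / (len(genuine) * len(impostor))


def sweep_interpolated_eer(genuine, impostor):
    """Independent EER oracle: root of the piecewise-linear FAR-FRR gap."""
    g, im = np.sort(np.asarray(genuine)), np.sort(np.asarray(impostor))
    thresholds = np.unique(np.concatenate([[0.0], g, im, [1.0]]))
    far = np.array([np.mean(im >= t) for t in thresholds])
    frr = np.array([np.mean(g < t) for t in thresholds])

    def gap(t):
        return np.interp(t, thresholds, far) - np.interp(t, thresholds, frr)

    if gap(0.0) <= 0:
        t_star = 0.0
    else:
        t_star = brentq(gap, 0.0, 1.0, xtol=1e-13)
    return float(np.interp(t_star, thresholds, far) / 2
                 + np.interp(t_star, thresholds, frr) / 2)


class TestEnumeratePairs:
    def test_paper_scale_counts(self):
        labels = [f"s{i}" for i in range(35) for _ in range(20)]
        genuine, impostor = pt.enumerate_pairs(labels)
        assert len(genuine) == 6650 == 35 * comb(20, 2)
        assert len(impostor) == 238_000 == comb(700, 2) - 6650
        assert len(genuine) + len(impostor) == 244_650

    def test_single_subject_two_items(self):
        genuine, impostor = pt.enumerate_pairs(["a", "a"])
        assert (len(genuine), len(impostor)) == (1, 0)

    def test_two_by_two_brute_force(self):
        labels = ["a", "a", "b", "b"]
        genuine, impostor = pt.enumerate_pairs(labels)
        expected_g = {(i, j) for i, j in combinations(range(4), 2)
                      if labels[i] == labels[j]}
        assert set(genuine) == expected_g
        assert len(impostor) == 4

    @pytest.mark.parametrize("subjects,items", [(2, 3), (5, 4), (3, 7)])
    def test_count_conservation(self, subjects, items):
        labels = [f"s{i}" for i in range(subjects) for _ in range(items)]
        genuine, impostor = pt.enumerate_pairs(labels)
        assert len(genuine) == subjects * comb(items, 2)
        assert len(genuine) + len(impostor) == comb(subjects * items, 2)


class TestAccuracy:
    def test_perfect_separation(self):
        scores = ScoreSet(np.full(10, 0.9), np.full(10, 0.1))
        assert pt.accuracy(scores, 0.5) == 1.0

    def test_tie_at_threshold_accepts(self):
        scores = ScoreSet(np.full(3, 0.5), np.full(7, 0.5))
        assert pt.accuracy(scores, 0.5) == pytest.approx(0.3)

    def test_matches_brute_force_recount(self, rng):
        scores = ScoreSet(rng.uniform(0, 1, 40), rng.uniform(0, 1, 60))
        t = 0.37
        expected = (np.sum(scores.genuine_scores >= t)
                    + np.sum(scores.impostor_scores < t)) / 100
        assert pt.accuracy(scores, t) == pytest.approx(expected)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        _, auc = pt.roc_auc(ScoreSet([0.8, 0.9], [0.1, 0.2]))
        assert auc == pytest.approx(1.0)

    def test_identical_score_lists_give_half(self):
        s = [0.2, 0.5, 0.8]
        _, auc = pt.roc_auc(ScoreSet(s, s))
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_sets(self, rng):
        for _ in range(50):
            n_g, n_i = rng.integers(5, 25, 2)
            # duplicated values exercise tie handling
            g = np.round(rng.uniform(0, 1, n_g), 2)
            i = np.round(rng.uniform(0, 1, n_i), 2)
            scores = ScoreSet(g, i)
            _, auc = pt.roc_auc(scores)
            assert auc == pytest.approx(brute_force_auc(g, i), abs=1e-12)

    def test_roc_is_monotone(self, rng):
        roc, auc = pt.roc_auc(ScoreSet(rng.uniform(0, 1, 30), rng.uniform(0, 1, 50)))
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)
        assert 0.0 <= auc <= 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            pt.roc_auc(ScoreSet([0.5], []))


class TestFarFrrEer:
    def test_perfect_separation_gives_zero(self):
        _, eer, _ = pt.far_frr_eer(ScoreSet([0.8, 0.9], [0.1, 0.2]))
        assert eer == pytest.approx(0.0)

    def test_anti_classifier_gives_one(self):
        _, eer, _ = pt.far_frr_eer(ScoreSet([0.1, 0.2], [0.8, 0.9]))
        assert eer == pytest.approx(1.0)

    def test_curve_monotonicity(self, rng):
        curve, eer, t = pt.far_frr_eer(ScoreSet(rng.uniform(0, 1, 30),
                                                rng.uniform(0, 1, 50)))
        _, far, frr = curve.T
        assert np.all(np.diff(far) <= 1e-15)
        assert np.all(np.diff(frr) >= -1e-15)
        assert 0.0 <= eer <= 1.0
        assert 0.0 <= t <= 1.0

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(50):
            n_g, n_i = rng.integers(5, 30, 2)
            g = rng.uniform(0.1, 0.9, n_g)
            i = rng.uniform(0.1, 0.9, n_i)
            _, eer, _ = pt.far_frr_eer(ScoreSet(g, i))
            assert eer == pytest.approx(sweep_interpolated_eer(g, i), abs=1e-9)

    def test_far_frr_definitions_at_sweep_points(self, rng):
        g, i = rng.uniform(0, 1, 12), rng.uniform(0, 1, 18)
        curve, _, _ = pt.far_frr_eer(ScoreSet(g, i))
        for t, far, frr in curve[::5]:
            assert far == pytest.approx(np.mean(i >= t))
            assert frr == pytest.approx(np.mean(g < t))


class TestHistogramAndReport:
    def test_histogram_counts_complete(self, rng):
        scores = ScoreSet(rng.uniform(0, 1, 100), rng.uniform(0, 1, 200))
        hist = score_histogram(scores, bins=50)
        assert hist.shape == (50, 3)
        assert hist[:, 1].sum() == 100
        assert hist[:, 2].sum() == 200

    def test_report_assembles_all_metrics(self, rng):
        scores = ScoreSet(rng.uniform(0.5, 1, 50), rng.uniform(0, 0.5, 80))
        report = pt.evaluate_scores(scores, threshold=0.5)
        assert report.n_genuine == 50 and report.n_impostor == 80
        assert report.accuracy_at_threshold > 0.9
        text = report.summary_text()
        assert "auc:" in text and "eer:" in text


class TestScorePairs:
    def test_counts_order_and_determinism(self, small_cycle_pools):
        from pulsetwin.verifier import ModelConfig, SimilarityModel

        _, test_cycles = small_cycle_pools
        model = SimilarityModel(ModelConfig(), seed=0).eval_mode()
        s1 = pt.score_pairs(model, test_cycles)
        s2 = pt.score_pairs(model, test_cycles)
        genuine, impostor = pt.enumerate_pairs([c.subject_id for c in test_cycles])
        assert s1.genuine_scores.size == len(genuine)
        assert s1.impostor_scores.size == len(impostor)
        np.testing.assert_array_equal(s1.genuine_scores, s2.genuine_scores)
        np.testing.assert_array_equal(s1.impostor_scores, s2.impostor_scores)

    def test_pair_scoring_matches_similarity_calls(self, small_cycle_pools):
        from pulsetwin.verifier import ModelConfig, SimilarityModel

        _, test_cycles = small_cycle_pools
        gallery = test_cycles[:6]
        model = SimilarityModel(ModelConfig(), seed=0).eval_mode()
        scores = pt.score_pairs(model, gallery)
        genuine, impostor = pt.enumerate_pairs([c.subject_id for c in gallery])
        direct_g = [model.similarity(gallery[i], gallery[j]) for i, j in genuine]
        direct_i = [model.similarity(gallery[i], gallery[j]) for i, j in impostor]
        np.testing.assert_allclose(scores.genuine_scores, direct_g, atol=1e-12)
        np.testing.assert_allclose(scores.impostor_scores, direct_i, atol=1e-12)


class TestLabelPermutationNull:
    def test_shuffled_labels_drive_auc_to_chance(self, small_cycle_pools, rng):
        """Permuting subject labels of the gallery must destroy the signal:
        mean AUC over 100 permutations is 0.5 within 0.05."""
        from pulsetwin.verifier import ModelConfig, SimilarityModel

        _, test_cycles = small_cycle_pools
        model = SimilarityModel(ModelConfig(), seed=3).eval_mode()
        emb = model.embed_batch(np.stack([c.values for c in test_cycles]))
        n = len(test_cycles)
        # full pairwise score matrix once, relabel per permutation
        pair_scores = {}
        for i, j in combinations(range(n), 2):
            d = np.abs(emb[i] - emb[j])
            pair_scores[(i, j)] = d
        from pulsetwin.verifier import _linear_forward, _relu_forward, _sigmoid
        dmat = np.stack(list(pair_scores.values()))
        h, _ = _linear_forward(dmat, model.params["fc1_w"], model.params["fc1_b"])
        h, _ = _relu_forward(h)
        z, _ = _linear_forward(h, model.params["fc2_w"], model.params["fc2_b"])
        svals = _sigmoid(z[:, 0])
        keys = list(pair_scores)
        labels = np.array([c.subject_id for c in test_cycles])
        aucs = []
        for _ in range(100):
            perm = labels[rng.permutation(n)]
            same = np.array([perm[i] == perm[j] for i, j in keys])
            _, auc = pt.roc_auc(ScoreSet(svals[same], svals[~same]))
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestNSweep:
    def test_single_value_gives_single_row(self, small_dataset):
        _, manifest = small_dataset
        config = pt.RunConfig(n_cycles=1, epochs=2, random_seed=0)
        rows = pt.n_sweep(manifest, config, [1])
        assert len(rows) == 1
        assert rows[0]["n"] == 1
        assert 0.0 <= rows[0]["auc"] <= 1.0

    def test_row_count_matches_n_values(self, small_dataset):
        _, manifest = small_dataset
        config = pt.RunConfig(n_cycles=1, epochs=1, random_seed=0)
        rows = pt.n_sweep(manifest, config, [1, 2, 3])
        assert [r["n"] for r in rows] == [1, 2, 3]
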