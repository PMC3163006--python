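import math

import numpy as np
import pytest

from tboost import boosting
from tboost.boosting import (BETA_FLOOR, alpha_from_beta, decision_scores,
                             ensemble_to_dict, init_weights, load_ensemble,
                             predict, predict_sample, save_ensemble, train,
                             update_weights, weighted_error)
from tboost.exceptions import ConfigurationError, DataError, TrainingError
from tboost.simulate import GeneratorSpec, generate
from tboost.tree import TreeNode, fit_tree

from conftest import make_table, random_table


class TestInitWeights:
    def test_uniform_over_52(self):
        w = init_weights(52)
        assert w.shape == (52,)
        assert np.allclose(w, 1 / 52)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_samples(self):
        assert init_weights(2).tolist() == [0.5, 0.5]

    def test_m_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            init_weights(1)


class TestWeightedError:
    def test_perfect_tree_has_zero_error(self, tiny_table):
        root = fit_tree(tiny_table, init_weights(4), max_depth=1)
        assert weighted_error(root, tiny_table, init_weights(4)) == 0.0

    def test_constant_positive_vote_on_imbalanced_cohort(self):
        """A +1-voting leaf misclassifies exactly the negative mass: 13/52."""
        cohort = generate(GeneratorSpec(seed=0))
        leaf = TreeNode(vote=1)
        err = weighted_error(leaf, cohort, init_weights(52))
        assert err == pytest.approx(13 / 52, abs=1e-12)

    def test_matches_loop_and_sum_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = random_table(rng, 7, 5, 2)
            w = rng.uniform(0, 1, size=12)
            w /= w.sum()
            root = fit_tree(t, init_weights(12), max_depth=1)
            from tboost.tree import predict_tree

            expected = sum(
                w[i]
                for i in range(12)
                if predict_tree(root, t.row_mapping(i)) != t.labels[i]
            )
            assert weighted_error(root, t, w) == pytest.approx(expected, abs=1e-12)


class TestAlphaFromBeta:
    def test_direct_evaluation(self):
        assert alpha_from_beta(0.1) == pytest.approx(0.5 * math.log(9), abs=1e-12)

    def test_analytic_inverse(self):
        beta = 1.0 / (1.0 + math.e**2)
        assert alpha_from_beta(beta) == pytest.approx(1.0, abs=1e-12)

    def test_limit_beta_to_half_gives_alpha_to_zero(self):
        assert 0 < alpha_from_beta(0.4999999) < 1e-6

    def test_strictly_decreasing_and_positive(self):
        alphas = [alpha_from_beta(b) for b in (0.05, 0.1, 0.2, 0.3, 0.45)]
        assert all(a > 0 for a in alphas)
        assert all(a > b for a, b in zip(alphas, alphas[1:]))

    def test_beta_zero_clamped_finite(self):
        a = alpha_from_beta(0.0)
        assert math.isfinite(a)
        assert a == pytest.approx(0.5 * math.log((1 - BETA_FLOOR) / BETA_FLOOR))

    def test_beta_at_or_above_half_rejected(self):
        with pytest.raises(ConfigurationError):
            alpha_from_beta(0.5)


class TestUpdateWeights:
    def test_alpha_zero_is_identity(self):
        w = np.array([0.1, 0.2, 0.3, 0.4])
        y = np.array([1, 1, -1, -1])
        out = update_weights(w, 0.0, y, y)
        assert np.allclose(out, w)

    def test_sum_one_after_any_update(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            w = rng.uniform(0, 1, size=n)
            w /= w.sum()
            y = rng.choice([1, -1], size=n)
            c = rng.choice([1, -1], size=n)
            out = update_weights(w, float(rng.uniform(0, 3)), y, c)
            assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_four_sample_case(self):
        """Uniform start, one of four misclassified, alpha = 0.5 ln 3: the
        misclassified sample ends up carrying exactly half the mass."""
        w = init_weights(4)
        y = np.array([1, 1, 1, -1])
        c = np.array([1, 1, 1, 1])  # last sample wrong
        out = update_weights(w, 0.5 * math.log(3), y, c)
        assert out[3] == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(out[:3], 1 / 6)

    def test_misclassified_gain_correct_lose(self):
        w = np.full(4, 0.25)
        y = np.array([1, 1, -1, -1])
        c = np.array([1, -1, -1, -1])
        out = update_weights(w, 0.8, y, c)
        assert out[1] > 0.25          # wrong: gains
        assert all(out[i] < 0.25 for i in (0, 2, 3))  # right: lose


class TestTrain:
    def test_separable_cohort_one_perfect_round(self):
        t = make_table(
            np.array([[1.0], [2.0], [3.0], [8.0], [9.0], [10.0]]),
            [1, 1, 1, -1, -1, -1],
        )
        ens = train(t, ["f0"], n_rounds=50)
        assert ens.n_rounds == 1
        assert ens.stop_reason == "perfect"
        assert ens.rounds[0].clamped
        assert np.array_equal(predict(ens, t), t.labels)

    def test_no_learner_beats_chance_raises(self):
        # all feature values identical, balanced classes: only a majority
        # leaf exists and its weighted error is exactly 0.5
        t = make_table([[5.0], [5.0], [5.0], [5.0]], [1, 1, -1, -1])
        with pytest.raises(TrainingError):
            train(t, ["f0"], n_rounds=10)

    def test_full_cohort_reaches_perfect_resubstitution(self):
        """Boosting the synthetic discovery cohort on its candidate subset
        drives training accuracy to 100% within 50 rounds."""
        cohort = generate(GeneratorSpec(seed=1))
        from tboost.ranking import candidate_subset, rank_features

        subset = candidate_subset(rank_features(cohort), 10)
        ens = train(cohort, subset, n_rounds=50)
        assert np.array_equal(predict(ens, cohort), cohort.labels)

    def test_boosting_identities_hold_every_round(self):
        """Classical AdaBoost identities: the just-fitted tree has weighted
        error exactly 1/2 under the updated weights; weights remain a
        probability distribution; training error obeys the product bound
        prod_t 2 sqrt(beta_t (1 - beta_t))."""
        cohort = generate(GeneratorSpec(seed=5))
        sub = cohort.select_features(["MCH", "CHO", "PDW", "LDL", "TCO2"])
        w = init_weights(sub.n_samples)
        betas = []
        for _ in range(25):
            tree = fit_tree(sub, w, max_depth=1)
            from tboost.tree import predict_many

            preds = predict_many(tree, sub)
            beta = float(w[preds != sub.labels].sum())
            assert beta < 0.5
            if beta < BETA_FLOOR:  # perfect round: no weight update follows
                break
            betas.append(beta)
            alpha = alpha_from_beta(beta)
            w = update_weights(w, alpha, sub.labels, preds)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert float(w[preds != sub.labels].sum()) == pytest.approx(
                0.5, abs=1e-9
            )
        ens = train(cohort, sub.feature_names, n_rounds=25)
        train_err = float(np.mean(predict(ens, cohort) != cohort.labels))
        bound = float(np.prod([2 * math.sqrt(b * (1 - b)) for b in ens.beta_trace]))
        assert train_err <= bound + 1e-12

    def test_stored_rounds_satisfy_ensemble_invariants(self):
        cohort = generate(GeneratorSpec(seed=2))
        ens = train(cohort, ["MCH", "CHO", "PDW"], n_rounds=30)
        assert ens.n_rounds >= 1
        for r in ens.rounds:
            assert r.beta < 0.5
            assert r.alpha > 0
            if not r.clamped:
                assert r.alpha == pytest.approx(
                    0.5 * math.log((1 - r.beta) / r.beta), abs=1e-12
                )

    def test_determinism_identical_ensembles(self):
        cohort = generate(GeneratorSpec(seed=3))
        e1 = train(cohort, ["MCH", "CHO", "PDW", "LDL"], n_rounds=20)
        e2 = train(cohort, ["MCH", "CHO", "PDW", "LDL"], n_rounds=20)
        assert ensemble_to_dict(e1) == ensemble_to_dict(e2)

    def test_invalid_inputs(self, tiny_table):
        with pytest.raises(ConfigurationError):
            train(tiny_table, [], n_rounds=5)
        with pytest.raises(ConfigurationError):
            train(tiny_table, ["f0"], n_rounds=0)


class TestEnsemblePredict:
    def test_single_round_matches_its_tree(self, tiny_table):
        ens = train(tiny_table, ["f0"], n_rounds=1)
        from tboost.tree import predict_many

        assert np.array_equal(predict(ens, tiny_table),
                              predict_many(ens.rounds[0].tree, tiny_table))

    def test_two_disagreeing_rounds_follow_larger_alpha(self):
        left = TreeNode(vote=1)
        right = TreeNode(vote=-1)
        from tboost.boosting import BoostEnsemble, BoostRound

        ens = BoostEnsemble(
            rounds=[BoostRound(alpha=1.0, tree=left, beta=0.1),
                    BoostRound(alpha=0.5, tree=right, beta=0.2)],
            n_requested=2, stopped_early=False, stop_reason="max_rounds",
            feature_subset=["f0"],
        )
        t = make_table([[0.0], [1.0]], [1, -1])
        assert predict(ens, t).tolist() == [1, 1]

    def test_vote_of_zero_returns_positive(self):
        from tboost.boosting import BoostEnsemble, BoostRound

        ens = BoostEnsemble(
            rounds=[BoostRound(alpha=1.0, tree=TreeNode(vote=1), beta=0.1),
                    BoostRound(alpha=1.0, tree=TreeNode(vote=-1), beta=0.1)],
            n_requested=2, stopped_early=False, stop_reason="max_rounds",
            feature_subset=["f0"],
        )
        t = make_table([[0.0], [1.0]], [1, -1])
        assert predict(ens, t).tolist() == [1, 1]

    def test_vote_matches_alpha_weighted_sum_oracle(self):
        """Independent sum(alpha * c_t(x)) recomputation on 100 samples."""
        cohort = generate(GeneratorSpec(seed=4))
        ens = train(cohort, ["MCH", "CHO", "PDW", "LDL", "TCO2"], n_rounds=20)
        rng = np.random.default_rng(0)
        probe = make_table(
            rng.normal(30, 5, size=(100, 5)), [1] * 50 + [-1] * 50,
            feature_names=["MCH", "CHO", "PDW", "LDL", "TCO2"],
        )
        from tboost.tree import predict_tree

        got = predict(ens, probe)
        scores = decision_scores(ens, probe)
        for i in range(100):
            s = sum(r.alpha * predict_tree(r.tree, probe.row_mapping(i))
                    for r in ens.rounds)
            assert s == pytest.approx(scores[i], abs=1e-9)
            assert got[i] == (1 if s >= 0 else -1)

    def test_predict_sample_requires_all_features(self):
        cohort = generate(GeneratorSpec(seed=4))
        ens = train(cohort, ["MCH", "CHO"], n_rounds=5)
        with pytest.raises(DataError, match="missing"):
            predict_sample(ens, {"MCH": 30.0})
        assert predict_sample(ens, {"MCH": 30.0, "CHO": 4.5}) in (-1, 1)


def test_save_load_round_trip(tmp_path):
    cohort = generate(GeneratorSpec(seed=6))
    ens = train(cohort, ["MCH", "CHO", "PDW"], n_rounds=15)
    p = tmp_path / "ensemble.json"
    save_ensemble(ens, p)
    back = load_ensemble(p)
    assert ensemble_to_dict(back) == ensemble_to_dict(ens)
    assert np.array_equal(predict(back, cohort), predict(ens, cohort))
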