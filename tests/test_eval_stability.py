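"""LOOCV evaluation, inference and feature-ranking stability."""

import math

import numpy as np
import pandas as pd
import pytest

from geoenrich.efs_regression import (
    CORRELATION_METHODS,
    EfsConfig,
    FeatureTable,
    FeatureWeights,
)
from geoenrich.eval_stability import (
    FoldRecord,
    RegressorSpec,
    bootstrap_r2_ci,
    importance_decline,
    jaccard_distance,
    kendall_tau,
    loocv_evaluate,
    permutation_test,
    pooled_r2,
    stability_summary,
    top_k_list,
)
from geoenrich.synthetic_fixtures import FixtureSpec, gen_feature_table

FAST_EFS = EfsConfig(methods=CORRELATION_METHODS)


def _planted_table(seed=0, n=36, f=100):
    spec = FixtureSpec(
        seed=seed, n_instances=n, n_features=f, n_planted=5,
        zero_inflation=0.2, missing_rate=0.0, noise_sd=0.3,
        n_decoy_blocks=3, block_size=4,
    )
    return gen_feature_table(spec)


def _weights(names_weights):
    s = pd.Series(dict(names_weights))
    return FeatureWeights(ensemble=s / s.sum(), per_method={})


class TestLoocv:
    def test_noiseless_linear_target_is_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 30))
        y = 2.0 * X[:, 7]
        t = FeatureTable(pd.DataFrame(X, columns=[f"f{i}" for i in range(30)]),
                         pd.Series(y))
        ev = loocv_evaluate(t, RegressorSpec("linear"), FAST_EFS, seed=0)
        assert ev.r2 >= 0.99

    def test_prediction_count_equals_instance_count(self):
        t, _ = _planted_table()
        ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=0)
        assert len(ev.predictions) == t.n_instances
        assert len(ev.folds) == t.n_instances

    def test_null_target_scores_low_in_most_seeds(self):
        """With a target independent of all features, pooled R2 stays low."""
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(24, 60))
            y = rng.normal(size=24)
            t = FeatureTable(pd.DataFrame(X, columns=[f"f{i}" for i in range(60)]),
                             pd.Series(y))
            ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=seed)
            low += ev.r2 < 0.3
        assert low >= 9

    def test_no_leakage_from_held_out_instance(self):
        """Corrupting the held-out row never changes that fold's selection."""
        t, _ = _planted_table(seed=3, n=20, f=60)
        ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=1)
        for fold in ev.folds[:10]:
            X2 = t.X.copy()
            X2.loc[fold.held_out_id] = 9999.0
            t2 = FeatureTable(X2, t.y)
            ev2 = loocv_evaluate(t2, RegressorSpec("ridge"), FAST_EFS, seed=1)
            fold2 = next(f for f in ev2.folds if f.held_out_id == fold.held_out_id)
            assert fold2.selected == fold.selected

    def test_contrast_against_constant_baseline(self):
        """A regularised linear model beats the zero-skill constant predictor
        by >= 0.5 on planted-signal data and does not on the permuted twin."""
        t, _ = _planted_table(seed=0)
        base = loocv_evaluate(t, RegressorSpec("constant"), FAST_EFS, seed=0).r2
        assert base == 0.0
        ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=0).r2
        assert ev - base >= 0.5
        rng = np.random.default_rng(42)
        tp = FeatureTable(t.X, pd.Series(rng.permutation(t.y.to_numpy()), index=t.y.index))
        evp = loocv_evaluate(tp, RegressorSpec("ridge"), FAST_EFS, seed=0).r2
        assert evp - base < 0.5

    def test_unknown_model_rejected(self):
        t, _ = _planted_table(seed=1, n=20, f=60)
        with pytest.raises(ValueError, match="unknown model"):
            loocv_evaluate(t, RegressorSpec("caret"), FAST_EFS, seed=0)


class TestBootstrap:
    def test_perfect_predictor_gives_degenerate_distribution(self):
        obs = np.arange(10.0)
        dist, ci = bootstrap_r2_ci(obs, obs, B=200, seed=0)
        assert np.allclose(dist, 1.0)
        assert ci[0] == pytest.approx(1.0, abs=1e-9)
        assert ci[1] == pytest.approx(1.0, abs=1e-9)

    def test_distribution_length_is_B(self, rng):
        p = rng.normal(size=20)
        o = p + rng.normal(scale=0.5, size=20)
        dist, _ = bootstrap_r2_ci(p, o, B=321, seed=1)
        assert len(dist) == 321

    def test_interval_reproducible_across_independent_reruns(self, rng):
        """Two independent high-B runs agree within Monte-Carlo tolerance."""
        p = rng.normal(size=30)
        o = 0.8 * p + rng.normal(scale=0.6, size=30)
        _, ci1 = bootstrap_r2_ci(p, o, B=10_000, seed=11)
        _, ci2 = bootstrap_r2_ci(p, o, B=10_000, seed=999)
        assert ci1[0] == pytest.approx(ci2[0], abs=0.02)
        assert ci1[1] == pytest.approx(ci2[1], abs=0.02)


class TestPermutationTest:
    def test_strong_signal_rejects_null(self):
        t, _ = _planted_table(seed=0)
        res = permutation_test(t, RegressorSpec("ridge"), FAST_EFS, B=50, seed=0)
        assert res.p <= 0.02
        assert res.p_label.startswith("<")

    def test_boundary_p_is_one_when_observed_is_minimum(self):
        # a constant predictor scores 0 observed and 0 for every permutation:
        # ties count into t, so t = B and p = 1
        t, _ = _planted_table(seed=2, n=20, f=60)
        res = permutation_test(t, RegressorSpec("constant"), FAST_EFS, B=10, seed=0)
        assert res.observed_r2 == 0.0
        assert res.t == res.B and res.p == 1.0


class TestRankedListDistances:
    def test_identical_rankings(self):
        x = ["a", "b", "c", "d"]
        assert kendall_tau(x, list(x)) == 1.0

    def test_reversed_rankings(self):
        x = [f"f{i}" for i in range(10)]
        assert kendall_tau(x, x[::-1]) == -1.0

    def test_single_swap_three_items(self):
        # pairs: (1,2),(1,3),(2,3); one discordant -> (2-1)/3
        assert kendall_tau(["1", "2", "3"], ["1", "3", "2"]) == pytest.approx(1 / 3)

    def test_restricted_to_intersection(self):
        x = ["a", "b", "c", "x1", "x2"]
        y = ["y1", "a", "b", "c", "y2"]
        assert kendall_tau(x, y) == 1.0

    def test_undefined_below_two_shared_items(self):
        assert math.isnan(kendall_tau(["a", "b"], ["c", "d"]))

    def test_matches_pair_counting_oracle(self, rng):
        """tau equals exhaustive O(n^2) concordant/discordant counting."""
        for n in (5, 20, 80, 200):
            perm = rng.permutation(n)
            x = [f"f{i}" for i in range(n)]
            y = [f"f{i}" for i in perm]
            got = kendall_tau(x, y)
            pos_y = {f: i for i, f in enumerate(y)}
            c = d = 0
            for i in range(n):
                for j in range(i + 1, n):
                    s = np.sign(i - j) * np.sign(pos_y[x[i]] - pos_y[x[j]])
                    c += s > 0
                    d += s < 0
            assert got == pytest.approx((c - d) / (n * (n - 1) / 2), abs=1e-12)

    def test_jaccard_identity_disjoint_and_partial(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0.0
        assert jaccard_distance({"a"}, {"b", "c"}) == 1.0
        assert jaccard_distance({"a", "b"}, {"a", "c"}) == pytest.approx(2 / 3)

    def test_jaccard_empty_union_rejected(self):
        with pytest.raises(ValueError):
            jaccard_distance(set(), set())


class TestStability:
    def _fold(self, names_weights, held="x"):
        return FoldRecord(held_out_id=held, selected=[], weights=_weights(names_weights),
                          prediction=0.0)

    def test_identical_folds_are_perfectly_stable(self):
        w = [("a", 5.0), ("b", 3.0), ("c", 1.0)]
        folds = [self._fold(w, held=i) for i in range(4)]
        s = stability_summary(folds, k=3)
        assert s.mean_jaccard == 0.0 and s.sd_jaccard == 0.0
        assert s.mean_tau == 1.0 and s.sd_tau == 0.0

    def test_disjoint_topk_gives_unit_jaccard(self):
        f1 = self._fold([("a", 2.0), ("b", 1.0)], held=1)
        f2 = self._fold([("c", 2.0), ("d", 1.0)], held=2)
        s = stability_summary([f1, f2], k=2)
        assert s.mean_jaccard == 1.0

    def test_topk_truncates_and_orders_by_weight(self):
        w = _weights([("low", 0.1), ("hi", 5.0), ("mid", 1.0)])
        assert top_k_list(w, k=2) == ["hi", "mid"]

    def test_planted_signal_is_more_stable_than_permuted_twin(self):
        """Fold-wise top-k lists drift less when a real signal anchors them."""
        wins = 0
        for seed in range(5):
            t, _ = _planted_table(seed=seed, n=24, f=80)
            ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=seed)
            rng = np.random.default_rng(500 + seed)
            tp = FeatureTable(t.X, pd.Series(rng.permutation(t.y.to_numpy()), index=t.y.index))
            evp = loocv_evaluate(tp, RegressorSpec("ridge"), FAST_EFS, seed=seed)
            sj = stability_summary(ev.folds, k=25).mean_jaccard
            sjp = stability_summary(evp.folds, k=25).mean_jaccard
            wins += sj < sjp
        assert wins >= 4


class TestImportanceDecline:
    def _fold(self, names_weights, held="x"):
        return FoldRecord(held_out_id=held, selected=[], weights=_weights(names_weights),
                          prediction=0.0)

    def test_identical_folds_have_modal_frequency_one(self):
        w = [("a", 5.0), ("b", 3.0), ("c", 1.0)]
        folds = [self._fold(w, held=i) for i in range(3)]
        df = importance_decline(folds, top_m=3)
        assert (df["modal_frequency"] == 1.0).all()

    def test_rank_one_normalised_to_unit(self):
        folds = [self._fold([("a", 4.0), ("b", 2.0)], held=1),
                 self._fold([("b", 6.0), ("a", 1.0)], held=2)]
        df = importance_decline(folds, top_m=2)
        assert df.loc[1, "norm_mean_weight"] == 1.0

    def test_planted_fixture_declines_and_destabilises_with_rank(self):
        t, _ = _planted_table(seed=1)
        ev = loocv_evaluate(t, RegressorSpec("ridge"), FAST_EFS, seed=1)
        df = importance_decline(ev.folds, top_m=20)
        # normalised weights decline overall (first rank strictly heaviest)
        assert df["norm_mean_weight"].iloc[0] == 1.0
        assert df["norm_mean_weight"].iloc[-1] < 0.9
        # top rank names repeat across folds more than deep ranks
        assert df.loc[1, "modal_frequency"] > df.loc[20, "modal_frequency"]


class TestPooledR2:
    def test_constant_predictions_score_zero(self):
        assert pooled_r2(np.ones(6), np.arange(6.0)) == 0.0

    def test_bounds(self, rng):
        p = rng.normal(size=50)
        o = rng.normal(size=50)
        assert 0.0 <= pooled_r2(p, o) <= 1.0
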