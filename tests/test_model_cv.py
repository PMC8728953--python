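import itertools

import numpy as np
import pytest

from m2pp.features import FEATURE_NAMES, build_feature_table
from m2pp.model_cv import (
    CVConfig,
    CVResult,
    ForestParams,
    aupr,
    auroc,
    category_eval,
    influence_coefficients,
    rank_targets_for_disease,
    rank_whole_network,
    run_cv,
    run_cv_subsets,
    sample_negatives,
    train_forest,
)
from m2pp.pipeline import build_similarities
from m2pp.reference import aupr_ref, auroc_ref
from m2pp.synthetic import SyntheticConfig, generate_network

# small, strongly structured network: fast CV with clear signal
FAST_CFG = SyntheticConfig(
    n_targets=40, n_diseases=40, n_drugs=25, n_groups=4,
    p_in=0.35, p_out=0.01, p_in_tdi=0.4, p_out_tdi=0.02,
    p_in_dda=0.4, p_out_dda=0.02, signal=0.9, noise_sd=0.02, seed=5,
)
FAST_FOREST = ForestParams(n_trees=60, seed=0)


@pytest.fixture(scope="module")
def structured():
    sn = generate_network(FAST_CFG)
    tts, dds, mms_t, mms_d = build_similarities(sn.network, sn.tts_s, sn.dds_s)
    return sn, tts, dds, mms_t, mms_d


class TestMetrics:
    def test_perfect_ranking(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_constant_scores(self):
        labels = [1, 0, 0, 0]
        assert auroc(labels, [0.5] * 4) == 0.5
        assert aupr(labels, [0.5] * 4) == pytest.approx(0.25)  # prevalence

    def test_hand_case_auroc(self):
        assert auroc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.1, 0.2])
        with pytest.raises(ValueError):
            aupr([0, 0], [0.1, 0.2])

    def test_agrees_with_exhaustive_oracle_on_small_lists(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 15))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert auroc(labels, scores) == pytest.approx(auroc_ref(labels, scores))
            assert aupr(labels, scores) == pytest.approx(aupr_ref(labels, scores))


class TestNegativeSampling:
    def test_counts_and_determinism(self, structured):
        sn, *_ = structured
        n_pos = sn.network.tda.n_edges
        a = sample_negatives(sn.network, n_pos, seed=3)
        b = sample_negatives(sn.network, n_pos, seed=3)
        np.testing.assert_array_equal(a, b)
        assert len(a) == n_pos
        assert sn.network.tda.values[a[:, 0], a[:, 1]].sum() == 0
        assert len({tuple(p) for p in a}) == n_pos  # without replacement

    def test_zero_and_oversized_requests(self, structured):
        sn, *_ = structured
        assert sample_negatives(sn.network, 0, seed=1).shape == (0, 2)
        with pytest.raises(ValueError):
            sample_negatives(sn.network, 10**7, seed=1)

    def test_excluded_diseases_never_sampled(self, structured):
        sn, *_ = structured
        neg = sample_negatives(sn.network, 50, seed=2, exclude_diseases=[0, 1])
        assert not np.isin(neg[:, 1], [0, 1]).any()


class TestForest:
    def _table(self, structured, n=120):
        sn, tts, dds, mms_t, mms_d = structured
        tda = sn.network.tda.values
        pos = np.argwhere(tda == 1)[: n // 2]
        neg = sample_negatives(sn.network, n // 2, seed=0)
        pairs = [tuple(p) for p in np.vstack([pos, neg])]
        labels = [1] * len(pos) + [0] * len(neg)
        return build_feature_table(
            pairs, sn.network, tts, dds, mms_t, mms_d, labels=labels
        )

    def test_scores_lie_in_unit_interval_and_are_deterministic(self, structured):
        table = self._table(structured)
        s1 = train_forest(table, FAST_FOREST).score(table)
        s2 = train_forest(table, FAST_FOREST).score(table)
        np.testing.assert_array_equal(s1, s2)
        assert s1.min() >= 0 and s1.max() <= 1

    def test_separable_features_reach_training_auroc_near_one(self, structured):
        table = self._table(structured)
        frame = table.frame.copy()
        # plant a perfectly separating feature
        frame["fea1"] = frame["label"].astype(float)
        from m2pp.features import FeatureTable

        scorer = train_forest(FeatureTable(frame=frame), FAST_FOREST)
        assert auroc(frame["label"], scorer.score(FeatureTable(frame=frame))) > 0.99

    def test_default_mtry_is_third_of_feature_count(self):
        assert ForestParams().mtry(9) == 3
        assert ForestParams().mtry(8) == 2
        with pytest.raises(ValueError):
            ForestParams(n_vars_per_split=10).mtry(9)

    def test_single_class_table_warns_but_fits(self, structured, caplog):
        table = self._table(structured)
        frame = table.frame.copy()
        frame["label"] = 1
        from m2pp.features import FeatureTable

        import logging

        with caplog.at_level(logging.WARNING):
            train_forest(FeatureTable(frame=frame), FAST_FOREST)
        assert any("single class" in r.message for r in caplog.records)


class TestRunCV:
    def test_planted_signal_beats_chance_and_is_deterministic(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        cfg = CVConfig(n_repeats=2, seed=11)
        r1 = run_cv(sn.network, tts, dds, mms_t, mms_d, cfg, FAST_FOREST)
        r2 = run_cv(sn.network, tts, dds, mms_t, mms_d, cfg, FAST_FOREST)
        np.testing.assert_array_equal(r1.fold_auroc, r2.fold_auroc)
        assert r1.fold_auroc.shape == (2, 5)
        assert r1.auroc_mean > 0.7

    def test_overall_mean_is_mean_of_repeat_means(self):
        res = CVResult(
            fold_auroc=np.array([[0.9, 0.8, 0.7, 0.6, 0.5], [1.0, 0.9, 0.8, 0.7, 0.6]]),
            fold_aupr=np.full((2, 5), 0.3),
        )
        assert res.auroc_mean == pytest.approx(0.75)
        assert res.auroc_sd == pytest.approx(np.std([0.7, 0.8], ddof=1))

    def test_too_few_positives_rejected(self, structured):
        from conftest import make_network

        net = make_network(
            np.eye(4, dtype=int)[:, :4] * 0,  # no positives
            np.ones((4, 3), dtype=int),
            np.ones((4, 3), dtype=int),
        )
        _, tts, dds, mms_t, mms_d = structured
        sn = structured[0]
        with pytest.raises(ValueError, match="fewer positives"):
            run_cv_subsets(
                net,
                tts=sn.tts_s, dds=sn.dds_s,  # registries won't be reached
                mms_t=mms_t, mms_d=mms_d,
            )

    def test_feature_subset_restricts_model_inputs(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        cfg = CVConfig(n_repeats=1, seed=1)
        res = run_cv(
            sn.network, tts, dds, mms_t, mms_d, cfg, FAST_FOREST,
            feature_subset=[1, 2, 3],
        )
        assert res.fold_auroc.shape == (1, 5)


class TestInfluence:
    def _result(self, values):
        arr = np.asarray(values, dtype=float)
        return CVResult(fold_auroc=arr, fold_aupr=arr)

    def test_noop_ablation_gives_exactly_half(self):
        full = self._result(np.full((5, 5), 0.9))
        rep = influence_coefficients(full, {"fea1": full})
        assert rep.loc["fea1", "influence"] == 0.5
        assert rep.loc["fea1", "difference_auroc"] == 0.5

    def test_sigmoid_monotonicity(self):
        full = self._result(np.full((5, 5), 0.9))
        worse = self._result(np.full((5, 5), 0.85))
        better = self._result(np.full((5, 5), 0.95))
        rep = influence_coefficients(full, {"w": worse, "b": better})
        assert rep.loc["w", "influence"] > 0.5 > rep.loc["b", "influence"]

    def test_invariant_to_fold_reordering(self, rng):
        a = rng.random((5, 5))
        b = rng.random((5, 5))
        perm = rng.permutation(25).reshape(5, 5)
        rep1 = influence_coefficients(self._result(a), {"f": self._result(b)})
        rep2 = influence_coefficients(
            self._result(a.ravel()[perm.ravel()].reshape(5, 5)),
            {"f": self._result(b.ravel()[perm.ravel()].reshape(5, 5))},
        )
        assert rep1.loc["f", "influence"] == pytest.approx(rep2.loc["f", "influence"])

    def test_fold_structure_mismatch_rejected(self):
        full = self._result(np.full((5, 5), 0.9))
        with pytest.raises(ValueError, match="fold structure"):
            influence_coefficients(full, {"f": self._result(np.full((2, 5), 0.9))})

    def test_repeat_level_option(self):
        full = self._result(np.full((2, 5), 0.9))
        abl = self._result(np.full((2, 5), 0.8))
        rep_f = influence_coefficients(full, {"f": abl}, level="fold")
        rep_r = influence_coefficients(full, {"f": abl}, level="repeat")
        # fold-level sums 10 differences of 0.1; repeat-level 2 of 0.1
        assert rep_f.loc["f", "difference_auroc"] == pytest.approx(1 / (1 + np.exp(-1.0)))
        assert rep_r.loc["f", "difference_auroc"] == pytest.approx(1 / (1 + np.exp(-0.2)))


class TestCategoryEval:
    def test_planted_category_beats_chance(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        code = "G00"
        res = category_eval(
            sn.network, tts, dds, mms_t, mms_d, sn.categories, code,
            CVConfig(n_repeats=2, seed=3), FAST_FOREST,
        )
        assert res.repeat_auroc.shape == (2,)
        assert res.auroc_mean > 0.55
        assert res.n_diseases + res.n_skipped == len(sn.categories.diseases_in(code))

    def test_unknown_category_rejected(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        with pytest.raises(ValueError, match="no diseases"):
            category_eval(
                sn.network, tts, dds, mms_t, mms_d, sn.categories, "NOPE"
            )


class TestRankings:
    def test_leave_disease_out_enriches_planted_targets(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        # pick a disease with at least 3 associations
        deg = sn.network.tda.values.sum(axis=0)
        j = int(np.argmax(deg))
        disease = sn.network.diseases.ids[j]
        ranked = rank_targets_for_disease(
            sn.network, tts, dds, mms_t, mms_d, disease,
            CVConfig(n_repeats=2, seed=7), FAST_FOREST,
        )
        n_unconfirmed = int((sn.network.tda.values[:, j] == 0).sum())
        assert len(ranked) == n_unconfirmed
        # same-group targets should be enriched in the top half
        group = sn.disease_groups[j]
        top = ranked.head(len(ranked) // 2)
        top_idx = [sn.network.targets.index[t] for t in top["target_id"]]
        frac_top = np.mean(sn.target_groups[top_idx] == group)
        frac_all = np.mean(sn.target_groups == group)
        assert frac_top > frac_all

    def test_unknown_disease_rejected(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        with pytest.raises(KeyError):
            rank_targets_for_disease(sn.network, tts, dds, mms_t, mms_d, "NOPE")

    def test_whole_network_ranking_covers_all_unconfirmed_pairs(self, structured):
        sn, tts, dds, mms_t, mms_d = structured
        cfg = CVConfig(n_repeats=1, seed=9)
        ranked = rank_whole_network(sn.network, tts, dds, mms_t, mms_d, cfg, FAST_FOREST)
        n_unconfirmed = int((sn.network.tda.values == 0).sum())
        assert len(ranked) == n_unconfirmed
        assert list(ranked["rank"]) == list(range(1, n_unconfirmed + 1))
        again = rank_whole_network(sn.network, tts, dds, mms_t, mms_d, cfg, FAST_FOREST)
        assert list(again["target_id"].head(20)) == list(ranked["target_id"].head(20))
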