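import numpy as np
import pytest

from m2pp import reference
from m2pp.features import (
    FEATURE_NAMES,
    build_feature_table,
    fea_drug_inferred,
    fea_nearest_path,
    fea_neighborhood,
    fea_path2,
    fea_path3,
    feature_matrices,
    pair_features,
)
from m2pp.netio import SimilarityMatrix

from conftest import make_network, random_instance, random_similarity


def identity_instance(nT=4, nD=4, nM=3):
    TDA = np.zeros((nT, nD), dtype=np.int8)
    TDI = np.zeros((nT, nM), dtype=np.int8)
    DDA = np.zeros((nD, nM), dtype=np.int8)
    return TDA, TDI, DDA, np.eye(nT), np.eye(nD), np.eye(nM), np.eye(nM)


class TestNeighborhood:
    def test_fully_associated_target_has_empty_neighborhood(self, rng):
        TDA, TDI, DDA, TTS, DDS, *_ = random_instance(rng)
        TDA[2, :] = 1
        f1, _ = fea_neighborhood(2, 0, TDA, DDS, TTS)
        assert f1 == 0.0

    def test_identity_similarity_forced_arithmetic(self):
        TDA, _, _, TTS, DDS, _, _ = identity_instance()
        f1, _ = fea_neighborhood(0, 1, TDA, DDS, TTS)
        assert f1 == pytest.approx(1 / 4)  # column mean of identity over all 4


class TestNearestPath:
    def test_zero_tda_kills_all_terms(self, rng):
        _, _, _, TTS, DDS, *_ = random_instance(rng)
        assert fea_nearest_path(1, 2, np.zeros((6, 6), dtype=int), DDS, TTS) == 0.0

    def test_upper_bound_of_three_attained(self):
        TTS = np.ones((2, 2))
        DDS = np.ones((2, 2))
        TDA = np.ones((2, 2), dtype=np.int8)
        assert fea_nearest_path(0, 0, TDA, DDS, TTS) == pytest.approx(3.0)

    def test_requires_two_entities_per_side(self):
        with pytest.raises(ValueError):
            fea_nearest_path(0, 0, np.zeros((1, 3), dtype=int), np.eye(3), np.eye(1))


class TestDrugInferred:
    def test_no_shared_drug_gives_zero(self):
        TDI = np.array([[1, 0]], dtype=np.int8)
        DDA = np.array([[0, 1]], dtype=np.int8)
        assert fea_drug_inferred(0, 0, TDI, DDA, np.eye(2), np.eye(2)) == 0.0

    def test_single_shared_drug_identity_similarity(self):
        TDI = np.array([[0, 1, 0]], dtype=np.int8)
        DDA = np.array([[0, 1, 0]], dtype=np.int8)
        assert fea_drug_inferred(0, 0, TDI, DDA, np.eye(3), np.eye(3)) == pytest.approx(1.0)


class TestPathFeatures:
    def test_zero_tda_gives_zero_everywhere(self, rng):
        _, _, _, TTS, DDS, *_ = random_instance(rng)
        Z = np.zeros((6, 6), dtype=np.int8)
        assert fea_path2(0, 0, Z, DDS, TTS) == (0.0, 0.0)
        assert fea_path3(0, 0, Z, DDS, TTS) == (0.0, 0.0, 0.0)

    def test_identity_similarity_single_path(self):
        TDA, _, _, TTS, DDS, _, _ = identity_instance()
        TDA[1, 2] = 1
        f5, f6 = fea_path2(1, 2, TDA, DDS, TTS)
        f7, f8, f9 = fea_path3(1, 2, TDA, DDS, TTS)
        assert (f5, f6, f7, f8, f9) == (1.0, 1.0, 1.0, 1.0, 1.0)


class TestAgainstReference:
    def test_all_features_match_literal_loops_on_random_networks(self, rng):
        for _ in range(60):
            TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
            fm = feature_matrices(TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D)
            for i in range(TDA.shape[0]):
                for j in range(TDA.shape[1]):
                    ref = reference.features_ref(
                        i, j, TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D
                    )
                    np.testing.assert_allclose(fm[i, j], ref, atol=1e-10)
                    np.testing.assert_allclose(
                        pair_features(i, j, TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D),
                        ref,
                        atol=1e-10,
                    )

    def test_sparse_zero_rich_instances(self, rng):
        # sparse similarities exercise the 0/0 conventions
        for _ in range(40):
            TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng, p=0.15)
            for S in (TTS, DDS, MMS_T, MMS_D):
                S *= rng.random(S.shape) < 0.4
                S[:] = (S + S.T) / 2
                np.fill_diagonal(S, 1.0)
            fm = feature_matrices(TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D)
            for i in range(6):
                for j in range(6):
                    ref = reference.features_ref(
                        i, j, TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D
                    )
                    np.testing.assert_allclose(fm[i, j], ref, atol=1e-10)


class TestInvariantsAndBounds:
    def test_bounds_on_random_instances(self, rng):
        for _ in range(50):
            TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
            fm = feature_matrices(TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D)
            assert np.isfinite(fm).all()
            assert (fm >= 0).all()
            assert (fm[:, :, 0] <= 1).all() and (fm[:, :, 1] <= 1).all()  # fea1, fea2
            assert (fm[:, :, 2] <= 3).all()  # fea3
            assert (fm[:, :, 4:] <= 1 + 1e-12).all()  # path averages of [0,1] weights

    def test_permutation_equivariance(self, rng):
        TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
        pt = rng.permutation(6)
        pd_ = rng.permutation(6)
        fm = feature_matrices(TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D)
        fm_p = feature_matrices(
            TDA[np.ix_(pt, pd_)],
            TDI[pt],
            DDA[pd_],
            TTS[np.ix_(pt, pt)],
            DDS[np.ix_(pd_, pd_)],
            MMS_T,
            MMS_D,
        )
        # fea3's argmax tie-breaking is index-order dependent; compare the rest
        keep = [0, 1, 3, 4, 5, 6, 7, 8]
        np.testing.assert_allclose(
            fm_p[:, :, keep], fm[np.ix_(pt, pd_)][:, :, keep], atol=1e-10
        )


class TestFeatureTable:
    def _sims(self, net, rng):
        return (
            SimilarityMatrix(net.targets, random_similarity(rng, net.n_targets)),
            SimilarityMatrix(net.diseases, random_similarity(rng, net.n_diseases)),
            SimilarityMatrix(net.drugs, random_similarity(rng, net.n_drugs)),
            SimilarityMatrix(net.drugs, random_similarity(rng, net.n_drugs)),
        )

    def test_empty_mask_equals_unmasked_computation(self, rng):
        TDA, TDI, DDA, *_ = random_instance(rng)
        net = make_network(TDA, TDI, DDA)
        tts, dds, mt, md = self._sims(net, rng)
        pairs = [(i, j) for i in range(6) for j in range(6)]
        t0 = build_feature_table(pairs, net, tts, dds, mt, md)
        t1 = build_feature_table(pairs, net, tts, dds, mt, md, mask=[])
        np.testing.assert_allclose(t0.X, t1.X)

    def test_masking_changes_only_affected_rows_and_labels(self, rng):
        TDA, TDI, DDA, *_ = random_instance(rng)
        TDA[2, 3] = 1
        net = make_network(TDA, TDI, DDA)
        tts, dds, mt, md = self._sims(net, rng)
        pairs = [(i, j) for i in range(6) for j in range(6)]
        t0 = build_feature_table(pairs, net, tts, dds, mt, md)
        t1 = build_feature_table(pairs, net, tts, dds, mt, md, mask=[(2, 3)])
        assert t1.frame.loc[2 * 6 + 3, "label"] == 0
        # features that read only TDA row i or column j are untouched for
        # pairs away from the masked row/column (fea3 and fea8 scan all of
        # TDA, fea4 never reads it and stays put everywhere)
        local = [0, 1, 4, 5, 6, 8]  # fea1, fea2, fea5, fea6, fea7, fea9
        for k, (i, j) in enumerate(pairs):
            np.testing.assert_allclose(t0.X[k, 3], t1.X[k, 3])  # fea4
            if i != 2 and j != 3:
                np.testing.assert_allclose(t0.X[k, local], t1.X[k, local])
        # and the masked pair itself must move
        assert not np.allclose(t0.X[2 * 6 + 3], t1.X[2 * 6 + 3])

    def test_table_rows_compose_the_feature_operations(self, rng):
        TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
        net = make_network(TDA, TDI, DDA)
        sims = (
            SimilarityMatrix(net.targets, TTS),
            SimilarityMatrix(net.diseases, DDS),
            SimilarityMatrix(net.drugs, MMS_T),
            SimilarityMatrix(net.drugs, MMS_D),
        )
        pairs = [(0, 0), (3, 4), (5, 5)]
        table = build_feature_table(pairs, net, *sims)
        for row, (i, j) in zip(table.X, pairs):
            np.testing.assert_allclose(
                row, pair_features(i, j, TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D)
            )

    def test_out_of_range_pair_rejected(self, rng):
        TDA, TDI, DDA, *_ = random_instance(rng)
        net = make_network(TDA, TDI, DDA)
        tts, dds, mt, md = self._sims(net, rng)
        with pytest.raises(IndexError):
            build_feature_table([(0, 99)], net, tts, dds, mt, md)

    def test_exclude_self_drops_query_entities_from_sets(self, rng):
        TDA, TDI, DDA, TTS, DDS, MMS_T, MMS_D = random_instance(rng)
        TDA[0, 0] = 0
        net = make_network(TDA, TDI, DDA)
        sims = (
            SimilarityMatrix(net.targets, TTS),
            SimilarityMatrix(net.diseases, DDS),
            SimilarityMatrix(net.drugs, MMS_T),
            SimilarityMatrix(net.drugs, MMS_D),
        )
        t = build_feature_table([(0, 0)], net, *sims, exclude_self=True)
        P = [y for y in range(6) if TDA[0, y] == 0 and y != 0]
        exp_f1 = np.mean([DDS[y, 0] for y in P]) if P else 0.0
        assert t.X[0, 0] == pytest.approx(exp_f1)
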