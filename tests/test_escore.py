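import numpy as np
import pandas as pd
import pytest

from emocog.escore import (
    DEFAULT_ANCHORS,
    FeatureEmbedding,
    choose_k,
    cluster_features,
    compute_escores,
    derive_escores,
    embed_features,
    inertia_curve,
    loo_cluster_stability,
    winsorized_zscore,
)
from emocog.indices import build_feature_matrix


def _frame(array, prefix="f"):
    array = np.asarray(array, float)
    return pd.DataFrame(array, columns=[f"{prefix}{j}" for j in range(array.shape[1])],
                        index=[f"P{i}" for i in range(array.shape[0])])


def _blob_embedding(rng, centers, per=6, spread=0.01):
    pts, names = [], []
    for c, center in enumerate(centers):
        for i in range(per):
            pts.append(center + rng.normal(0, spread, 2))
            names.append(f"c{c}_{i}")
    coords = pd.DataFrame(pts, index=names, columns=["pc1", "pc2"])
    return FeatureEmbedding(coords=coords, explained_variance_ratio=np.array([0.5, 0.3]))


class TestWinsorizedZ:
    def test_capping_above(self):
        rng = np.random.default_rng(1)
        col = rng.normal(0, 1, 40)
        col[0] = col.mean() + 10 * col.std()  # far outlier
        z = winsorized_zscore(_frame(col[:, None]))
        assert z.values.iloc[0, 0] == 2.5
        assert (z.values.abs() <= 2.5).all().all()

    def test_capping_symmetric(self):
        rng = np.random.default_rng(2)
        col = rng.normal(0, 1, 40)
        col[0] = col.mean() - 12 * col.std()
        z = winsorized_zscore(_frame(col[:, None]))
        assert z.values.iloc[0, 0] == -2.5

    def test_standardization_moments(self):
        rng = np.random.default_rng(3)
        frame = _frame(rng.normal(5, 3, (30, 4)))
        z = winsorized_zscore(frame)
        # no value was capped here, so columns have mean 0 / sd 1 exactly
        assert np.allclose(z.values.mean(), 0, atol=1e-12)
        assert np.allclose(z.values.std(ddof=1), 1, atol=1e-12)

    def test_idempotent_when_nothing_capped(self):
        rng = np.random.default_rng(4)
        frame = _frame(np.clip(rng.normal(0, 1, (25, 3)), -1.5, 1.5))
        once = winsorized_zscore(frame)
        twice = winsorized_zscore(once.values)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_missing_cells_imputed_at_zero(self):
        rng = np.random.default_rng(5)
        frame = _frame(rng.normal(0, 1, (20, 2)))
        frame.iloc[3, 1] = np.nan
        z = winsorized_zscore(frame)
        assert z.values.iloc[3, 1] == 0.0
        assert z.imputed.iloc[3, 1]
        assert int(z.imputed.to_numpy().sum()) == 1

    def test_zero_variance_column_raises_with_name(self):
        frame = _frame(np.random.default_rng(6).normal(0, 1, (10, 2)))
        frame["f1"] = 7.0
        with pytest.raises(ValueError, match="f1"):
            winsorized_zscore(frame)

    def test_zero_variance_column_dropped_on_request(self):
        frame = _frame(np.random.default_rng(7).normal(0, 1, (10, 2)))
        frame["f1"] = 7.0
        z = winsorized_zscore(frame, on_constant="drop")
        assert z.dropped_columns == ["f1"]
        assert list(z.values.columns) == ["f0"]


class TestEmbedding:
    def test_identical_columns_share_coordinates(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        frame = _frame(np.column_stack([x, x, rng.normal(0, 1, 30)]))
        emb = embed_features(winsorized_zscore(frame))
        a, b = emb.coords.iloc[0], emb.coords.iloc[1]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_negated_column_mirrors_through_origin(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        frame = _frame(np.column_stack([x, -x, rng.normal(0, 1, 30)]))
        emb = embed_features(winsorized_zscore(frame))
        assert np.allclose(emb.coords.iloc[0].to_numpy(),
                           -emb.coords.iloc[1].to_numpy(), atol=1e-10)

    def test_planted_blocks_cluster_in_embedding(self):
        rng = np.random.default_rng(10)
        factors = rng.normal(0, 1, (60, 3))
        cols = [factors[:, j] + 0.3 * rng.normal(0, 1, 60)
                for j in range(3) for _ in range(2)]
        emb = embed_features(winsorized_zscore(_frame(np.column_stack(cols))))
        coords = emb.coords.to_numpy()
        within, between = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                d = np.linalg.norm(coords[i] - coords[j])
                (within if i // 2 == j // 2 else between).append(d)
        assert max(within) < min(between)

    def test_loadings_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        frame = _frame(rng.normal(0, 1, (25, 6)))
        z = winsorized_zscore(frame)
        emb = embed_features(z)
        X = z.values.to_numpy()
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        for pc, col in enumerate(["pc1", "pc2"]):
            v = evecs[:, -1 - pc]
            got = emb.coords[col].to_numpy()
            sign = np.sign(np.dot(v, got))
            assert np.allclose(got, sign * v, atol=1e-8)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(12)
        emb = embed_features(winsorized_zscore(_frame(rng.normal(0, 1, (30, 8)))))
        evr = emb.explained_variance_ratio
        assert evr[0] >= evr[1]

    def test_rank_too_low(self):
        frame = _frame(np.random.default_rng(13).normal(0, 1, (10, 1)))
        with pytest.raises(ValueError, match="rank"):
            embed_features(winsorized_zscore(frame))


class TestChooseK:
    def test_elbow_from_second_differences(self):
        # second differences: k=2 -> -50, k=3 -> 57, k=4 -> 1, k=5 -> 1
        assert choose_k([100, 90, 30, 27, 25, 24]) == 3

    def test_linear_inertia_ties_to_smallest_k(self):
        assert choose_k([100, 80, 60, 40, 20]) == 2

    def test_override_wins(self):
        assert choose_k([100, 90, 30, 27, 25, 24], override=5) == 5

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            choose_k([100, 90, 95, 80, 70])

    def test_needs_four_candidates(self):
        with pytest.raises(ValueError, match="at least 4"):
            choose_k([10, 5, 2])


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        emb = _blob_embedding(rng, [(1, 0), (0, 1), (-1, -1)])
        grouping = cluster_features(emb, 3, seed=0)
        labels = grouping.labels
        for c in range(3):
            block = labels[[f"c{c}_{i}" for i in range(6)]]
            assert block.nunique() == 1

    def test_k1_single_group_inertia_total_ss(self, rng):
        emb = _blob_embedding(rng, [(1, 0), (-1, 0)])
        grouping = cluster_features(emb, 1, seed=0)
        assert (grouping.labels == 1).all()
        X = emb.coords.to_numpy()
        total_ss = ((X - X.mean(axis=0)) ** 2).sum()
        assert grouping.inertia[1] == pytest.approx(total_ss)

    def test_duplicated_points_share_labels(self, rng):
        emb = _blob_embedding(rng, [(2, 0), (-2, 0)], per=4, spread=0.0)
        grouping = cluster_features(emb, 2, seed=0)
        for c in range(2):
            assert grouping.labels[[f"c{c}_{i}" for i in range(4)]].nunique() == 1

    def test_k_exceeding_indices_rejected(self, rng):
        emb = _blob_embedding(rng, [(1, 0)], per=3)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_features(emb, 4, seed=0)

    def test_canonical_ordering_by_kind(self, rng):
        emb = _blob_embedding(rng, [(0, 1), (1, 0), (-1, 0)])
        kinds = {}
        for name in emb.coords.index:
            c = int(name[1])
            kinds[name] = {0: "contrast", 1: "accuracy", 2: "rt"}[c]
        grouping = cluster_features(emb, 3, seed=0, kinds=kinds)
        # group 1 = RT blob, group 2 = contrast blob, group 3 = accuracy blob
        assert (grouping.labels[[f"c2_{i}" for i in range(6)]] == 1).all()
        assert (grouping.labels[[f"c0_{i}" for i in range(6)]] == 2).all()
        assert (grouping.labels[[f"c1_{i}" for i in range(6)]] == 3).all()

    def test_inertia_nonincreasing_in_k(self, rng):
        emb = _blob_embedding(rng, [(1, 0), (0, 1), (-1, -1)], per=8, spread=0.3)
        curve = inertia_curve(emb, k_max=6, seed=0, restarts=20)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))


class TestLOOStability:
    def test_well_separated_blobs_fully_stable(self, rng):
        emb = _blob_embedding(rng, [(1, 0), (0, 1), (-1, -1)], spread=0.02)
        grouping = cluster_features(emb, 3, seed=0)
        assert loo_cluster_stability(emb, grouping, seed=0) == 1.0

    def test_k1_trivially_stable_with_warning(self, rng):
        emb = _blob_embedding(rng, [(0, 0)])
        grouping = cluster_features(emb, 1, seed=0)
        with pytest.warns(UserWarning, match="k=1"):
            assert loo_cluster_stability(emb, grouping, seed=0) == 1.0


class TestEScores:
    def test_single_index_group_equals_column(self, rng):
        frame = _frame(rng.normal(0, 1, (20, 3)))
        z = winsorized_zscore(frame)
        emb = embed_features(z)
        grouping = cluster_features(emb, 1, seed=0)
        table = compute_escores(z, grouping, anchors={})
        # k=1: score = first PC of all three columns; use a real single group
        labels = pd.Series([1, 2, 3], index=z.values.columns)
        grouping.labels = labels
        grouping.k = 3
        table = compute_escores(z, grouping, anchors={})
        col = z.values["f1"] - z.values["f1"].mean()
        got = table.scores["escore2"]
        assert np.allclose(np.abs(got), np.abs(col), atol=1e-12)
        anchor = table.anchors[2]
        assert table.loadings[2][anchor] > 0

    def test_two_identical_columns_closed_form(self, rng):
        x = rng.normal(0, 1, 30)
        frame = _frame(np.column_stack([x, x]))
        z = winsorized_zscore(frame)
        labels = pd.Series([1, 1], index=z.values.columns)
        from emocog.escore import FeatureGrouping
        grouping = FeatureGrouping(k=1, labels=labels, centers=np.zeros((1, 2)),
                                   inertia={})
        table = compute_escores(z, grouping, anchors={})
        v = table.loadings[1]
        assert np.allclose(np.abs(v.to_numpy()), 1 / np.sqrt(2), atol=1e-12)
        zc = z.values - z.values.mean()
        expected = zc.mean(axis=1) * np.sqrt(2)
        assert np.allclose(table.scores["escore1"], expected, atol=1e-10)

    def test_anchor_sign_convention(self, cohort_clean):
        fm = build_feature_matrix(cohort_clean.trials, cohort_clean.participants)
        z, emb, grouping, table, _ = derive_escores(fm, k=3, seed=0,
                                                    compute_stability=False,
                                                    compute_curve=False)
        for g, anchor in table.anchors.items():
            assert table.loadings[g][anchor] > 0
        # negating the anchor column flips the loadings back
        flipped = fm.values.copy()
        anchor1 = DEFAULT_ANCHORS[1]
        flipped[anchor1] = -flipped[anchor1]
        z2 = winsorized_zscore(flipped, on_constant="drop")
        table2 = compute_escores(z2, grouping)
        if table2.anchors[1] == anchor1:
            assert table2.loadings[1][anchor1] > 0

    def test_scores_centered_loadings_unit_norm(self, cohort_clean):
        fm = build_feature_matrix(cohort_clean.trials, cohort_clean.participants)
        z, emb, grouping, table, _ = derive_escores(fm, k=3, seed=0,
                                                    compute_stability=False,
                                                    compute_curve=False)
        for col in table.scores:
            sd = table.scores[col].std()
            assert abs(table.scores[col].mean()) < 1e-10 * max(sd, 1.0)
        for g, load in table.loadings.items():
            assert np.linalg.norm(load.to_numpy()) == pytest.approx(1.0)

    def test_first_pc_matches_eigendecomposition_oracle(self, rng):
        from emocog.escore import _first_pc
        for _ in range(25):
            n = int(rng.integers(5, 11))
            p = int(rng.integers(2, 11))
            X = rng.normal(0, 1, (n, p))
            scores, v, _ = _first_pc(X)
            Xc = X - X.mean(axis=0)
            evals, evecs = np.linalg.eigh(Xc.T @ Xc)
            ref = evecs[:, -1]
            sign = np.sign(np.dot(ref, v)) or 1.0
            assert np.allclose(v, sign * ref, atol=1e-8)
            assert np.allclose(scores, Xc @ (sign * ref), atol=1e-8)

    def test_pipeline_deterministic(self, cohort_clean):
        fm = build_feature_matrix(cohort_clean.trials, cohort_clean.participants)
        out1 = derive_escores(fm, k=3, seed=0, compute_stability=False,
                              compute_curve=False)
        out2 = derive_escores(fm, k=3, seed=0, compute_stability=False,
                              compute_curve=False)
        pd.testing.assert_frame_equal(out1[3].scores, out2[3].scores)
        pd.testing.assert_series_equal(out1[2].labels, out2[2].labels)

    def test_empty_group_rejected(self, rng):
        frame = _frame(rng.normal(0, 1, (15, 2)))
        z = winsorized_zscore(frame)
        from emocog.escore import FeatureGrouping
        labels = pd.Series([1, 1], index=z.values.columns)
        grouping = FeatureGrouping(k=2, labels=labels, centers=np.zeros((2, 2)),
                                   inertia={})
        with pytest.raises(ValueError, match="group 2"):
            compute_escores(z, grouping, anchors={})
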