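"""Reference co-embedding, gated KNN transfer, Jaccard, pseudobulk, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiomap import simulate
from cardiomap.containers import (
    UNASSIGNED,
    ClusterLabels,
    Embedding,
    GeneSet,
    MarkerTable,
    ValidationError,
)
from cardiomap.mapping import (
    combined_pca,
    jaccard_similarity,
    knn_assign_types,
    map_to_reference,
    normalize_reference,
    pseudobulk_profile,
    top_marker_set,
)
from cardiomap.preprocess import compute_size_factors, normalize_log
from conftest import make_matrix


def _joint_embedding(rng, n_query=60, n_ref=200, d=5, sep=8.0, types=("t1", "t2")):
    """Two well-separated reference types; query cells near type centers."""
    centers = {t: rng.normal(scale=1.0, size=d) + i * sep for i, t in enumerate(types)}
    ref_labels = [types[i % len(types)] for i in range(n_ref)]
    ref = np.vstack([centers[t] + 0.3 * rng.normal(size=d) for t in ref_labels])
    query_truth = [types[i % len(types)] for i in range(n_query)]
    qry = np.vstack([centers[t] + 0.3 * rng.normal(size=d) for t in query_truth])
    coords = np.vstack([qry, ref])
    ids = [f"q{i}" for i in range(n_query)] + [f"r{i}" for i in range(n_ref)]
    is_ref = np.array([False] * n_query + [True] * n_ref)
    emb = Embedding(coordinates=coords, cell_ids=ids, space="mnn-corrected")
    return emb, is_ref, ref_labels, query_truth


class TestKnnAssign:
    def test_unanimous_vote_full_confidence(self, rng):
        emb, is_ref, ref_labels, truth = _joint_embedding(rng, sep=50.0)
        res = knn_assign_types(
            emb, is_ref, ref_labels, None, k=20,
            distance_threshold=1e9, min_cluster=0,
        )
        t = res.table
        assert (t["confidence"] == 1.0).all()
        assert list(t["assigned_type"]) == truth

    def test_low_confidence_gated(self, rng):
        # 100 reference cells of 3 types arranged so votes split 40/30/30
        d = 3
        ref = rng.normal(scale=0.01, size=(100, d))
        labels = ["a"] * 40 + ["b"] * 30 + ["c"] * 30
        qry = np.zeros((1, d))
        emb = Embedding(
            coordinates=np.vstack([qry, ref]),
            cell_ids=["q0"] + [f"r{i}" for i in range(100)],
            space="mnn-corrected",
        )
        is_ref = np.array([False] + [True] * 100)
        res = knn_assign_types(
            emb, is_ref, labels, None, k=100,
            confidence_threshold=0.5, distance_threshold=1e9, min_cluster=0,
        )
        row = res.table.iloc[0]
        assert row["confidence"] == pytest.approx(0.4)
        assert row["assigned_type"] == UNASSIGNED
        assert row["gate_reason"] == "confidence"

    def test_matches_all_pairs_oracle_exactly(self, rng):
        emb, is_ref, ref_labels, _ = _joint_embedding(
            rng, n_query=80, n_ref=300, sep=4.0
        )
        k = 50
        res = knn_assign_types(
            emb, is_ref, ref_labels, None, k=k,
            confidence_threshold=0.0, distance_threshold=1e9, min_cluster=0,
        )
        ref_coords = emb.coordinates[is_ref]
        qry_coords = emb.coordinates[~is_ref]
        labels = np.array(ref_labels)
        for i in range(len(qry_coords)):
            dist = np.linalg.norm(ref_coords - qry_coords[i], axis=1)
            order = np.argsort(dist, kind="stable")[:k]
            votes = pd.Series(labels[order]).value_counts()
            row = res.table.iloc[i]
            assert row["confidence"] == votes.max() / k
            assert row["mean_nn_distance"] == pytest.approx(dist[order].mean())
            assert votes[row["assigned_type"]] == votes.max()

    def test_small_cluster_gate(self, rng):
        emb, is_ref, ref_labels, _ = _joint_embedding(rng, n_query=12, sep=50.0)
        qids = [c for c, r in zip(emb.cell_ids, is_ref) if not r]
        qcl = ClusterLabels(
            cell_ids=qids, labels=np.array([0] * 9 + [1] * 3), resolution=1.0
        )
        res = knn_assign_types(
            emb, is_ref, ref_labels, qcl, k=10,
            distance_threshold=1e9, min_cluster=5,
        )
        t = res.table.set_index("cell_id")
        for cid in qids[9:]:
            assert t.loc[cid, "gate_reason"] == "small-cluster"
            assert t.loc[cid, "assigned_type"] == UNASSIGNED
        for cid in qids[:9]:
            assert t.loc[cid, "gate_reason"] == "none"

    def test_gating_monotone_in_thresholds(self, rng):
        emb, is_ref, ref_labels, _ = _joint_embedding(
            rng, n_query=60, n_ref=200, sep=2.0
        )
        assigned_counts = []
        for conf in (0.0, 0.3, 0.6, 0.9):
            res = knn_assign_types(
                emb, is_ref, ref_labels, None, k=30,
                confidence_threshold=conf, distance_threshold=1e9, min_cluster=0,
            )
            assigned_counts.append(int(res.assigned_mask.sum()))
        assert assigned_counts == sorted(assigned_counts, reverse=True)
        assigned_counts = []
        for dist_thr in (10.0, 3.0, 1.0, 0.3):
            res = knn_assign_types(
                emb, is_ref, ref_labels, None, k=30,
                confidence_threshold=0.0, distance_threshold=dist_thr, min_cluster=0,
            )
            assigned_counts.append(int(res.assigned_mask.sum()))
        assert assigned_counts == sorted(assigned_counts, reverse=True)

    def test_k_exceeding_reference_rejected(self, rng):
        emb, is_ref, ref_labels, _ = _joint_embedding(rng, n_ref=20)
        with pytest.raises(ValidationError):
            knn_assign_types(emb, is_ref, ref_labels, None, k=50)


from functools import lru_cache


@lru_cache(maxsize=None)
def _mapping_scenario(seed, batch_sd=0.3, absent_population=True):
    n_genes = 800
    gb = simulate.draw_gene_baseline(n_genes, simulate.GENE_MEAN_SD, seed=99)
    pops = simulate.default_query_populations(
        n_genes=n_genes, n_cells=100, n_markers=40
    )
    n_ref_pops = 2 if absent_population else 3
    ref_pops = [
        simulate.PopulationSpec(
            p.name, 300, p.baseline_mean, p.marker_genes,
            p.marker_log2fc, p.dispersion,
        )
        for p in pops[:n_ref_pops]
    ]
    atlas, _ = simulate.generate_reference_atlas(
        ref_pops, n_genes, seed=seed + 1000, gene_baseline=gb
    )
    query, truth = simulate.generate_query_batches(
        pops, n_genes=n_genes, n_replicates=2, batch_sd=batch_sd,
        cycle_fraction=0.0, cycle_gene_count=0, contaminant=None,
        seed=seed, gene_baseline=gb,
    )
    qnm = normalize_log(query, compute_size_factors(query, method="library"))
    rnm = normalize_reference(atlas)
    reps = qnm.replicates
    batches = [qnm.subset_cells((reps == r).to_numpy()) for r in ("R1", "R2")]
    return batches, rnm, atlas, truth


class TestMapToReference:
    def _scenario(self, seed, batch_sd=0.3, absent_population=True):
        return _mapping_scenario(seed, batch_sd, absent_population)

    def test_same_type_centroids_converge(self):
        """Cross-origin centroid gaps shrink to <= 25% of the uncorrected gap."""
        batches, rnm, atlas, truth = self._scenario(0, absent_population=False)
        joint, is_ref = map_to_reference(batches, rnm, d=20, k=50)
        labels = np.array(truth.cells["true_type"].tolist() + list(atlas.cell_types))

        # pre-mapping baseline: same feature space and joint PCA, no MNN
        from cardiomap.integrate import _pca, cosine_normalize
        from cardiomap.preprocess import select_hvgs

        hvgs = select_hvgs(rnm, fraction=0.10)
        shared = [
            g for g in hvgs.gene_ids
            if all(g in set(b.gene_ids) for b in batches)
        ]
        blocks = [b.subset_genes(shared) for b in batches] + [rnm.subset_genes(shared)]
        pre, _, _ = _pca(
            np.vstack([cosine_normalize(b.values.T) for b in blocks]), 20
        )

        def gap(coords, t):
            q = coords[(~is_ref) & (labels == t)].mean(0)
            r = coords[is_ref & (labels == t)].mean(0)
            return np.linalg.norm(q - r)

        for t in ("intramyocardial_EC", "endocardium"):
            assert gap(joint.coordinates, t) <= 0.25 * gap(pre, t)

    def test_output_row_count_and_origin_tags(self):
        batches, rnm, atlas, _ = self._scenario(1)
        joint, is_ref = map_to_reference(batches, rnm, d=20, k=50)
        n_query = sum(b.n_cells for b in batches)
        assert len(joint.cell_ids) == n_query + atlas.matrix.n_cells
        assert is_ref.sum() == atlas.matrix.n_cells
        assert not is_ref[:n_query].any()

    def test_label_transfer_recovery_with_absent_population(self):
        batches, rnm, atlas, truth = self._scenario(2)
        joint, is_ref = map_to_reference(batches, rnm, d=20, k=50)
        res = knn_assign_types(
            joint, is_ref, atlas.cell_types, None, k=100,
            distance_threshold="quantile:99", min_cluster=0,
        )
        t = res.table.merge(truth.cells, on="cell_id")
        assigned = t[t["assigned_type"] != UNASSIGNED]
        acc = (assigned["assigned_type"] == assigned["true_type"]).mean()
        absent = t[t["true_type"] == "immature_EC"]
        assert acc >= 0.95
        assert (absent["assigned_type"] == UNASSIGNED).mean() >= 0.9

    def test_too_few_shared_hvgs_rejected(self):
        batches, rnm, _, _ = self._scenario(3)
        tiny = [b.subset_genes(b.gene_ids[:5]) for b in batches]
        with pytest.raises(ValidationError):
            map_to_reference(tiny, rnm, d=5, k=10)


class TestMarkerSets:
    def _table(self, n, rng):
        return MarkerTable(
            table=pd.DataFrame(
                {
                    "gene_id": [f"g{i:04d}" for i in range(n)],
                    "log2fc": rng.normal(scale=2, size=n),
                    "p_raw": rng.random(n),
                    "p_adj": rng.random(n),
                }
            )
        )

    def test_fewer_passing_than_top_n(self):
        mt = MarkerTable(
            table=pd.DataFrame(
                {
                    "gene_id": ["a", "b", "c", "d"],
                    "log2fc": [3.0, 2.0, 1.0, 4.0],
                    "p_raw": [0.01] * 4,
                    "p_adj": [0.01, 0.01, 0.01, 0.99],
                }
            )
        )
        assert top_marker_set(mt, top_n=478).members == {"a", "b", "c"}

    def test_boundary_p_excluded(self):
        mt = MarkerTable(
            table=pd.DataFrame(
                {"gene_id": ["a"], "log2fc": [2.0], "p_raw": [0.05], "p_adj": [0.05]}
            )
        )
        assert len(top_marker_set(mt, p_cut=0.05)) == 0

    def test_matches_brute_force_filter_sort_slice(self, rng):
        mt = self._table(500, rng)
        top_n = 50
        got = top_marker_set(mt, p_cut=0.3, top_n=top_n)
        df = mt.table
        passing = df[(df["p_adj"] < 0.3) & (df["log2fc"] > 0)]
        expected = set(
            passing.sort_values(
                ["log2fc", "gene_id"], ascending=[False, True]
            )["gene_id"].head(top_n)
        )
        assert got.members == expected


class TestJaccard:
    def test_worked_example(self):
        a = GeneSet("a", frozenset({"A", "B", "C"}))
        b = GeneSet("b", frozenset({"B", "C", "D"}))
        assert jaccard_similarity(a, b) == 0.5

    def test_identical_and_disjoint(self):
        a = GeneSet("a", frozenset({"X", "Y"}))
        assert jaccard_similarity(a, a) == 1.0
        assert jaccard_similarity(a, GeneSet("b", frozenset({"Z"}))) == 0.0

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard_similarity(GeneSet("a", frozenset()), GeneSet("b", frozenset())) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(
        st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30))
    )
    def test_symmetric_bounded_and_equality_iff_equal(self, xs, ys):
        a = GeneSet("a", frozenset(map(str, xs)))
        b = GeneSet("b", frozenset(map(str, ys)))
        if not xs and not ys:
            return
        j1, j2 = jaccard_similarity(a, b), jaccard_similarity(b, a)
        assert j1 == j2
        assert 0.0 <= j1 <= 1.0
        assert (j1 == 1.0) == (a.members == b.members)


class TestPseudobulk:
    def test_single_cell_is_identity(self, small_matrix):
        pb = pseudobulk_profile(small_matrix, [small_matrix.cell_ids[0]])
        np.testing.assert_array_equal(pb.to_numpy(), small_matrix.counts[:, 0])

    def test_two_cell_sum(self):
        m = make_matrix(np.array([[1, 3], [2, 4]]))
        pb = pseudobulk_profile(m, m.cell_ids)
        assert pb.tolist() == [4, 6]

    def test_random_subset_matches_brute_force(self, small_matrix, rng):
        pick = rng.choice(small_matrix.n_cells, size=10, replace=False)
        cells = [small_matrix.cell_ids[i] for i in pick]
        pb = pseudobulk_profile(small_matrix, cells)
        np.testing.assert_array_equal(
            pb.to_numpy(), small_matrix.counts[:, sorted(pick)].sum(axis=1)
        )

    def test_empty_subset_rejected(self, small_matrix):
        with pytest.raises(ValidationError):
            pseudobulk_profile(small_matrix, [])


class TestCombinedPca:
    def _samples(self, rng, n_genes=40, n_samples=8, group_shift=True):
        base = rng.poisson(50.0, size=(n_genes, n_samples)).astype(float)
        if group_shift:
            base[:10, n_samples // 2 :] *= 8  # marker genes high in group 2
        genes = [f"g{i:03d}" for i in range(n_genes)]
        return pd.DataFrame(base, index=genes, columns=[f"s{i}" for i in range(n_samples)])

    def test_standardization_exact(self, rng):
        samples = self._samples(rng)
        markers = GeneSet("m", frozenset(samples.index))
        X = np.log2(1 + samples.to_numpy())
        sd = X.std(axis=1)
        usable = sd > 0
        Z = (X[usable] - X[usable].mean(axis=1, keepdims=True)) / sd[usable][:, None]
        assert np.abs(Z.mean(axis=1)).max() < 1e-9
        assert np.abs(Z.std(axis=1) - 1).max() < 1e-9

    def test_duplicate_samples_identical_coordinates(self, rng):
        samples = self._samples(rng)
        samples["dup"] = samples["s0"]
        markers = GeneSet("m", frozenset(samples.index))
        coords = combined_pca(samples, markers)
        np.testing.assert_allclose(
            coords.loc["s0"].to_numpy(), coords.loc["dup"].to_numpy(), atol=1e-9
        )

    def test_group_separation_on_pc1(self, rng):
        samples = self._samples(rng, group_shift=True)
        markers = GeneSet("m", frozenset(list(samples.index)[:10]))
        coords = combined_pca(samples, markers)
        pc1 = coords["PC1"].to_numpy()
        g1, g2 = pc1[:4], pc1[4:]
        # silhouette on PC1 > 0 means within-group distances < between-group
        from sklearn.metrics import silhouette_score

        score = silhouette_score(pc1[:, None], [0] * 4 + [1] * 4)
        assert score > 0

    def test_too_few_samples_rejected(self, rng):
        samples = self._samples(rng, n_samples=2)
        with pytest.raises(ValidationError):
            combined_pca(samples, GeneSet("m", frozenset(samples.index)))
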