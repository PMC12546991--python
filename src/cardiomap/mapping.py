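"""Reference mapping and cell-type transfer.

A two-step MNN co-embedding first merges the query replicates with each
other, then maps the labeled reference onto the combined query, all in a
joint PCA space over the reference's top highly variable genes.  Each query
cell is then assigned the modal type among its k nearest reference cells,
with abstention (UNASSIGNED) when the vote is too split, the neighbors too
distant, or the cell sits in a tiny query cluster.  Marker-set overlap is
quantified by Jaccard similarity of top-ranked marker genes, and bulk and
pseudobulk samples are co-embedded by PCA on a marker gene panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import (
    UNASSIGNED,
    AssignmentResult,
    ClusterLabels,
    Embedding,
    GeneSet,
    GeneExpressionMatrix,
    MarkerTable,
    NormalizedMatrix,
    ReferenceAtlas,
    ValidationError,
)
from .integrate import _pca, cosine_normalize, merge_blocks_mnn
from .preprocess import compute_size_factors, normalize_log, select_hvgs


def normalize_reference(ref: ReferenceAtlas) -> NormalizedMatrix:
    """Pooled size factors + log normalization of the reference counts."""
    sf = compute_size_factors(ref.matrix)
    return normalize_log(ref.matrix, sf)


def map_to_reference(
    query_batches: list[NormalizedMatrix],
    reference: NormalizedMatrix,
    hvg_fraction_ref: float = 0.10,
    d: int = 30,
    k: int = 100,
    bandwidth_mult: float = 1.0,
    min_shared_hvgs: int = 10,
) -> tuple[Embedding, np.ndarray]:
    """Two-step MNN co-embedding of query replicates and reference.

    Feature space: top ``hvg_fraction_ref`` HVGs of the reference restricted
    to genes shared with the query.  Step 1 merges the query replicates in
    input order; step 2 maps the reference onto the combined query.  Returns
    the corrected joint embedding (query cells first, then reference, in
    input order) and a boolean mask that is True for reference cells.
    """
    if not query_batches:
        raise ValidationError("at least one query batch required")
    hvgs = select_hvgs(reference, fraction=hvg_fraction_ref)
    shared = [g for g in hvgs.gene_ids if all(g in set(b.gene_ids) for b in query_batches)]
    if len(shared) < min_shared_hvgs:
        raise ValidationError(
            f"only {len(shared)} reference HVGs shared with the query "
            f"(minimum {min_shared_hvgs})"
        )
    blocks = [b.subset_genes(shared) for b in query_batches] + [
        reference.subset_genes(shared)
    ]
    coords = [cosine_normalize(b.values.T) for b in blocks]
    X = np.vstack(coords)
    d_use = min(d, min(X.shape))
    scores, _, _ = _pca(X, d_use)
    sizes = [b.n_cells for b in blocks]
    offsets = np.cumsum([0] + sizes)
    coord_blocks = [scores[offsets[i] : offsets[i + 1]] for i in range(len(blocks))]

    # step 1: merge query replicates with each other
    query_corrected = merge_blocks_mnn(coord_blocks[:-1], k=k, bandwidth_mult=bandwidth_mult)
    combined_query = np.vstack(query_corrected)
    # step 2: map the reference onto the combined query
    _, ref_corrected = merge_blocks_mnn(
        [combined_query, coord_blocks[-1]], k=k, bandwidth_mult=bandwidth_mult
    )
    all_coords = np.vstack(query_corrected + [ref_corrected])
    cell_ids = [c for b in blocks for c in b.cell_ids]
    is_ref = np.zeros(len(cell_ids), dtype=bool)
    is_ref[offsets[-2] :] = True
    return (
        Embedding(coordinates=all_coords, cell_ids=cell_ids, space="mnn-corrected"),
        is_ref,
    )


def _resolve_distance_threshold(
    threshold: float | str, ref_coords: np.ndarray, k: int
) -> float:
    """A numeric threshold passes through; "quantile:q" uses the q-th
    percentile of reference-internal mean k-NN distances."""
    if isinstance(threshold, str):
        if not threshold.startswith("quantile:"):
            raise ValidationError(f"bad distance threshold {threshold!r}")
        q = float(threshold.split(":", 1)[1])
        k_int = min(k, len(ref_coords) - 1)
        nn = NearestNeighbors(n_neighbors=k_int + 1).fit(ref_coords)
        dist, _ = nn.kneighbors(ref_coords)
        mean_d = dist[:, 1:].mean(axis=1)  # drop self
        return float(np.percentile(mean_d, q))
    return float(threshold)


def knn_assign_types(
    joint: Embedding,
    is_reference: np.ndarray,
    reference_labels: list[str],
    query_cluster_labels: ClusterLabels | None = None,
    k: int = 100,
    confidence_threshold: float = 0.5,
    distance_threshold: float | str = "quantile:99",
    min_cluster: int = 10,
) -> AssignmentResult:
    """Confidence- and distance-gated k-NN label transfer.

    Each query cell takes the modal type among its k nearest reference
    cells (Euclidean, in the joint corrected space); confidence is the
    modal vote share.  UNASSIGNED if mean neighbor distance exceeds the
    distance gate, the vote share falls below the confidence gate, or the
    cell's query cluster has fewer than ``min_cluster`` members.  Vote ties
    are broken by smaller mean distance to the tied types' voting
    neighbors, then lexicographically.
    """
    is_reference = np.asarray(is_reference, dtype=bool)
    ref_coords = joint.coordinates[is_reference]
    qry_coords = joint.coordinates[~is_reference]
    qry_ids = [c for c, r in zip(joint.cell_ids, is_reference) if not r]
    labels = np.asarray(reference_labels).astype(str)
    if len(labels) != len(ref_coords):
        raise ValidationError("one label per reference cell required")
    if k > len(ref_coords):
        raise ValidationError(f"k={k} exceeds reference size {len(ref_coords)}")

    dist_gate = _resolve_distance_threshold(distance_threshold, ref_coords, k)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_coords)
    dist, idx = nn.kneighbors(qry_coords)

    small_cluster_cells: set[str] = set()
    if query_cluster_labels is not None:
        lab = query_cluster_labels.labels
        counts = pd.Series(lab).value_counts()
        small = set(counts[counts < min_cluster].index)
        small_cluster_cells = {
            c for c, l in zip(query_cluster_labels.cell_ids, lab) if l in small
        }
    elif min_cluster > 0:
        warnings.warn("no query cluster labels; small-cluster gate skipped", stacklevel=2)

    rows = []
    for i, cid in enumerate(qry_ids):
        neigh_labels = labels[idx[i]]
        neigh_dist = dist[i]
        mean_dist = float(neigh_dist.mean())
        types, votes = np.unique(neigh_labels, return_counts=True)
        top = votes.max()
        tied = [t for t, v in zip(types, votes) if v == top]
        if len(tied) > 1:  # break by mean distance to each tied type's voters
            tied.sort(
                key=lambda t: (float(neigh_dist[neigh_labels == t].mean()), t)
            )
        assigned = tied[0]
        confidence = top / k
        gate = "none"
        if cid in small_cluster_cells:
            gate = "small-cluster"
        elif mean_dist > dist_gate:
            gate = "distance"
        elif confidence < confidence_threshold:
            gate = "confidence"
        rows.append(
            {
                "cell_id": cid,
                "assigned_type": assigned if gate == "none" else UNASSIGNED,
                "confidence": confidence,
                "mean_nn_distance": mean_dist,
                "gate_reason": gate,
            }
        )
    return AssignmentResult(table=pd.DataFrame(rows))


def top_marker_set(
    mt: MarkerTable,
    p_cut: float = 0.05,
    top_n: int = 478,
    name: str = "",
    positive_only: bool = True,
) -> GeneSet:
    """Genes with p_adj < p_cut, ranked by log2fc descending, first top_n.

    ``positive_only`` (default) additionally requires log2fc > 0: a marker
    of a group is an upregulated gene.  When more than ``top_n`` genes pass
    the p filter the descending-log2fc slice makes this implicit; on smaller
    gene universes it must be explicit or downregulated genes leak in.
    """
    t = mt.table
    mask = t["p_adj"] < p_cut
    if positive_only:
        mask &= t["log2fc"] > 0
    passing = t[mask].copy()
    passing = passing.sort_values(
        ["log2fc", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return GeneSet(name=name or mt.contrast, members=frozenset(passing["gene_id"].head(top_n)))


def jaccard_similarity(a: GeneSet, b: GeneSet) -> float:
    """|intersection| / |union|; two empty sets give 0 with a warning."""
    union = a.members | b.members
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a.members & b.members) / len(union)


def pseudobulk_profile(counts: GeneExpressionMatrix, cells) -> pd.Series:
    """Exact per-gene integer sum over the selected cells."""
    idx = counts._cell_indexer(cells)
    if len(idx) == 0:
        raise ValidationError("pseudobulk over an empty cell subset")
    return pd.Series(
        counts.counts[:, idx].sum(axis=1), index=counts.gene_ids, name="pseudobulk"
    )


def combined_pca(
    samples: pd.DataFrame, marker_genes: GeneSet, n_components: int = 2
) -> pd.DataFrame:
    """PCA of bulk + pseudobulk samples on a marker gene panel.

    ``samples``: genes x samples table of per-gene totals.  Values are
    log2(1+x) transformed, restricted to the marker genes, standardized
    gene-wise to mean 0 / SD 1 across samples (zero-SD genes dropped with a
    warning), and embedded by PCA with the deterministic sign convention.
    """
    if samples.shape[1] < 3:
        raise ValidationError("need >= 3 samples for the combined PCA")
    genes = [g for g in samples.index if g in marker_genes.members]
    if len(genes) < 2:
        raise ValidationError("fewer than 2 marker genes present in the samples")
    X = np.log2(1.0 + samples.loc[genes].to_numpy(dtype=float))  # genes x samples
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    usable = sd[:, 0] > 0
    if not usable.all():
        warnings.warn(f"dropping {(~usable).sum()} zero-variance marker genes", stacklevel=2)
    if usable.sum() < 2:
        raise ValidationError("fewer than 2 usable (non-constant) marker genes")
    Z = ((X - mu) / np.where(sd == 0, 1.0, sd))[usable]
    scores, _, _ = _pca(Z.T, min(n_components, min(Z.T.shape)))
    return pd.DataFrame(
        scores,
        index=samples.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
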