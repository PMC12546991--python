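"""PCA embedding, mutual-nearest-neighbor batch correction, SNN graph
construction, Louvain clustering, and cluster-exclusion rules.

The MNN correction follows the sequential-merge scheme: cells are cosine
normalized, jointly embedded by PCA, and batches are merged in input order.
For each incoming batch, mutual k-nearest-neighbor pairs against the current
reference set define per-pair correction vectors (reference minus incoming);
each incoming cell is shifted by a Gaussian-kernel weighted average of the
pair vectors, with bandwidth tied to the median pair distance.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterLabels, Embedding, HvgSet, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    comp = components.copy()
    for i in range(comp.shape[0]):
        j = np.argmax(np.abs(comp[i]))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return comp


def _pca(X: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA via SVD: (scores n x d, components d x p, explained var)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    comps = _fix_signs(Vt[:d])
    scores = Xc @ comps.T
    expl = (s[:d] ** 2) / max(X.shape[0] - 1, 1)
    return scores, comps, expl


def pca_embed(nm: NormalizedMatrix, genes: HvgSet | list[str] | None, d: int = 30) -> Embedding:
    """Top-d principal components of cells over the HVG feature space."""
    sub = nm if genes is None else nm.subset_genes(
        genes.gene_ids if isinstance(genes, HvgSet) else list(genes)
    )
    X = sub.values.T  # cells x genes
    if d > min(X.shape):
        raise ValidationError(f"d={d} exceeds min(n_cells, n_genes)={min(X.shape)}")
    scores, comps, expl = _pca(X, d)
    emb = Embedding(coordinates=scores, cell_ids=list(nm.cell_ids), space="pca")
    emb.components_ = comps
    emb.explained_variance_ = expl
    return emb


def cosine_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _mutual_pairs(ref: np.ndarray, inc: np.ndarray, k: int) -> np.ndarray:
    """Mutual k-NN pairs between reference and incoming coordinate sets."""
    k_ref = min(k, len(ref))
    k_inc = min(k, len(inc))
    nn_of_inc = NearestNeighbors(n_neighbors=k_ref).fit(ref).kneighbors(
        inc, return_distance=False
    )  # for each incoming cell: its k nearest reference cells
    nn_of_ref = NearestNeighbors(n_neighbors=k_inc).fit(inc).kneighbors(
        ref, return_distance=False
    )
    ref_sets = [set(row) for row in nn_of_ref]
    pairs = [
        (r, i)
        for i in range(len(inc))
        for r in nn_of_inc[i]
        if i in ref_sets[r]
    ]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def _correct_batch(
    ref: np.ndarray, inc: np.ndarray, k: int, bandwidth_mult: float,
    n_iterations: int = 3,
) -> np.ndarray:
    """Shift incoming cells by smoothed MNN correction vectors.

    The pair-find/correct step is repeated ``n_iterations`` times: mutual
    pair selection is biased along any remaining batch shift, and the bias
    shrinks with the shift, so iterating contracts the residual offset
    geometrically toward zero.
    """
    for _ in range(max(n_iterations, 1)):
        inc = _correct_batch_once(ref, inc, k, bandwidth_mult)
    return inc


def _correct_batch_once(
    ref: np.ndarray, inc: np.ndarray, k: int, bandwidth_mult: float
) -> np.ndarray:
    pairs = _mutual_pairs(ref, inc, k)
    if len(pairs) == 0:
        raise ValidationError(
            "no mutual nearest-neighbor pairs found between batches; "
            "increase k or check that the batches share populations"
        )
    vec = ref[pairs[:, 0]] - inc[pairs[:, 1]]  # per-pair correction
    # anchor smoothing at pair midpoints: for batches that are (shifted)
    # copies of each other the twin pairs (r,i)/(i,r) share a midpoint and
    # their noise components cancel exactly, leaving the pure batch shift
    anchors = 0.5 * (ref[pairs[:, 0]] + inc[pairs[:, 1]])
    pair_dist = np.linalg.norm(vec, axis=1)
    sigma = bandwidth_mult * max(np.median(pair_dist), 1e-12)
    # Gaussian-kernel weights from each incoming cell to every pair anchor
    d2 = ((inc[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * sigma**2))
    wsum = w.sum(axis=1, keepdims=True)
    # cells too far from every anchor fall back to the mean correction
    far = wsum[:, 0] < 1e-300
    w = np.where(wsum > 0, w / np.maximum(wsum, 1e-300), 0.0)
    corr = w @ vec
    if far.any():
        corr[far] = vec.mean(axis=0)
    return inc + corr


def mnn_correct(
    batches: list[NormalizedMatrix],
    d: int = 30,
    k: int = 20,
    bandwidth_mult: float = 1.0,
    n_iterations: int = 3,
) -> Embedding:
    """Cosine-normalize, jointly embed, and sequentially MNN-merge batches.

    Batches are merged in input order; the output preserves the input cell
    order (batch 1 cells first).  A single batch passes through unchanged
    (joint PCA only).
    """
    if not batches:
        raise ValidationError("at least one batch required")
    gene_sets = {tuple(b.gene_ids) for b in batches}
    if len(gene_sets) != 1:
        raise ValidationError("batches must share an identical gene space")
    blocks = [cosine_normalize(b.values.T) for b in batches]
    X = np.vstack(blocks)
    if d > min(X.shape):
        raise ValidationError(f"d={d} exceeds data rank bound {min(X.shape)}")
    scores, _, _ = _pca(X, d)

    sizes = [b.n_cells for b in batches]
    offsets = np.cumsum([0] + sizes)
    coord_blocks = [scores[offsets[i] : offsets[i + 1]] for i in range(len(batches))]
    corrected = merge_blocks_mnn(
        coord_blocks, k=k, bandwidth_mult=bandwidth_mult, n_iterations=n_iterations
    )
    cell_ids = [c for b in batches for c in b.cell_ids]
    return Embedding(coordinates=np.vstack(corrected), cell_ids=cell_ids, space="mnn-corrected")


def merge_blocks_mnn(
    coord_blocks: list[np.ndarray], k: int, bandwidth_mult: float = 1.0,
    n_iterations: int = 3,
) -> list[np.ndarray]:
    """Sequentially merge coordinate blocks; returns corrected blocks in order."""
    corrected = [coord_blocks[0]]
    ref = coord_blocks[0]
    for inc in coord_blocks[1:]:
        fixed = _correct_batch(
            ref, inc, k=k, bandwidth_mult=bandwidth_mult, n_iterations=n_iterations
        )
        corrected.append(fixed)
        ref = np.vstack([ref, fixed])
    return corrected


def build_snn_graph(e: Embedding, k: int = 2, d: int = 30) -> nx.Graph:
    """Shared-nearest-neighbor graph with Jaccard weights.

    k-NN by Euclidean distance in the first d embedding coordinates.  Two
    cells are connected iff their (self-inclusive) neighbor sets intersect;
    the edge weight is |shared| / |union| of those sets, so mutual neighbors
    are always connected with positive weight.
    """
    n = len(e.cell_ids)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k >= n:
        raise ValidationError(f"k={k} must be < n_cells={n}")
    d_use = min(d, e.d)
    X = e.coordinates[:, :d_use]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    sets = []
    for i in range(n):
        row = [int(j) for j in idx[i] if j != i][:k]  # distance-ordered
        s = set(row)
        s.add(i)  # self-inclusive neighbor set
        sets.append(s)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.graph["kind"] = "snn"
    g.graph["k"] = k
    g.graph["d"] = d_use
    g.graph["cell_ids"] = list(e.cell_ids)
    # candidate edges: pairs of cells whose neighbor sets share some member m
    # (reverse index: every pair of cells listing m is a candidate)
    containing: dict[int, list[int]] = {}
    for i in range(n):
        for m in sets[i]:
            containing.setdefault(m, []).append(i)
    candidates = set()
    for members in containing.values():
        members = sorted(members)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                candidates.add((members[a], members[b]))
    for i, j in candidates:
        shared = sets[i] & sets[j]
        if shared:
            w = len(shared) / len(sets[i] | sets[j])
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def louvain_cluster(g: nx.Graph, resolution: float, seed: int) -> ClusterLabels:
    """Louvain modularity clustering; labels relabeled by descending size."""
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if resolution <= 0:
        raise ValidationError("resolution must be > 0")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    # stable ordering: by size desc, then smallest member asc
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(g.number_of_nodes(), dtype=int)
    node_order = {node: i for i, node in enumerate(sorted(g.nodes()))}
    for lab, comm in enumerate(communities):
        for node in comm:
            labels[node_order[node]] = lab
    cell_ids = g.graph.get("cell_ids") or [str(n) for n in sorted(g.nodes())]
    return ClusterLabels(cell_ids=list(cell_ids), labels=labels, resolution=resolution)


def apply_cluster_exclusion(
    labels: ClusterLabels,
    nm: NormalizedMatrix,
    replicate_labels=None,
    pluripotency_genes: set[str] | list[str] = (),
    min_cells: int = 10,
    imbalance_threshold: float = 0.9,
) -> ClusterLabels:
    """Flag clusters for exclusion; removal is left to the caller.

    Flags (first matching rule wins, checked in this order):
      pluripotency        mean pluripotency-marker expression of the cluster
                          exceeds the mean + 2 SD of per-cluster means
      replicate-imbalance max replicate share > imbalance_threshold
      too-small           cluster size < min_cells
    """
    pluri = [g for g in pluripotency_genes if g in set(nm.gene_ids)]
    if not list(pluripotency_genes):
        raise ValidationError("pluripotency gene set must be non-empty")
    if replicate_labels is None:
        replicate_labels = nm.replicates
    replicate_labels = pd.Series(np.asarray(replicate_labels, dtype=object), dtype=str)

    lab = labels.labels
    clusters = np.unique(lab)
    flags: dict[int, str] = {}

    cluster_means = {}
    if pluri:
        pexpr = nm.subset_genes(pluri).values  # pluripotency genes x cells
        for c in clusters:
            cluster_means[c] = pexpr[:, lab == c].mean()
        vals = np.array([cluster_means[c] for c in clusters])

    def _pluri_outlier(c: int) -> bool:
        # leave-one-out: a cluster is an outlier against the OTHER clusters'
        # mean + 2 SD (with a 10%-of-scale floor on the SD).  Including the
        # candidate itself caps the max z-score at (n-1)/sqrt(n) < 2 for up
        # to 5 clusters, which would make the rule vacuous at atlas scale.
        others = vals[clusters != c]
        if len(others) == 0:
            return False
        floor = 0.1 * max(vals.mean(), 1e-12)
        return cluster_means[c] > others.mean() + 2.0 * max(others.std(ddof=0), floor)

    for c in clusters:
        members = lab == c
        if pluri and _pluri_outlier(c):
            flags[int(c)] = "pluripotency"
            continue
        shares = replicate_labels[members].value_counts(normalize=True)
        if len(shares) and shares.max() > imbalance_threshold:
            flags[int(c)] = "replicate-imbalance"
            continue
        if members.sum() < min_cells:
            flags[int(c)] = "too-small"
            continue
        flags[int(c)] = "none"
    return ClusterLabels(
        cell_ids=list(labels.cell_ids),
        labels=lab,
        resolution=labels.resolution,
        exclusion_flags=flags,
    )
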