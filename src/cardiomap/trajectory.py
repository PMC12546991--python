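"""Diffusion components, diffusion pseudotime, and cluster-level connectivity.

The diffusion operator is built from a k-NN graph with a Gaussian kernel and
per-cell adaptive bandwidth (the distance to the ceil(k/2)-th neighbor):
K_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j)), symmetrized and
row-normalized.  Diffusion components are the non-trivial right eigenvectors
of this operator; pseudotime is the Euclidean distance from the root in the
lambda/(1-lambda)-rescaled eigenvector space, a closed-form equivalent of
accumulating random-walk transitions over the retained spectrum.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

from .containers import ClusterLabels, Embedding, PseudotimeResult, ValidationError


def diffusion_components(e: Embedding, n_comps: int = 10, k: int = 20) -> Embedding:
    """Eigenvectors 2..(n_comps+1) of the diffusion operator, scaled by
    their eigenvalues; the trivial constant eigenvector is dropped."""
    X = e.coordinates
    n = X.shape[0]
    if n_comps >= n:
        raise ValidationError("n_comps must be < n_cells")
    k_use = min(k, n - 1)
    D = cdist(X, X)
    Dsort = np.sort(D, axis=1)  # col 0 = self distance 0
    # adaptive bandwidth: distance to the ceil(k/2)-th neighbor
    h = int(np.ceil(k_use / 2))
    sigma = np.maximum(Dsort[:, h], 1e-12)
    # tie-inclusive kNN mask: everything within the k-th neighbor distance,
    # so duplicate points get exactly symmetric kernel rows
    radius = Dsort[:, k_use] * (1.0 + 1e-12)
    mask = D <= radius[:, None]
    np.fill_diagonal(mask, False)

    K = np.where(mask, np.exp(-(D**2) / np.outer(sigma, sigma)), 0.0)
    K = np.maximum(K, K.T)  # symmetrize the kNN kernel
    np.fill_diagonal(K, 1.0)

    deg = K.sum(axis=1)
    if nx.number_connected_components(nx.from_numpy_array(K > 0)) > 1:
        warnings.warn("neighbor graph is disconnected; spectrum computed jointly", stacklevel=2)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    M = K * np.outer(d_inv_sqrt, d_inv_sqrt)  # symmetric conjugate of D^-1 K
    evals, evecs = eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the row-normalized operator
    psi = evecs * d_inv_sqrt[:, None]
    # deterministic sign and unit normalization
    for c in range(psi.shape[1]):
        nrm = np.linalg.norm(psi[:, c])
        if nrm > 0:
            psi[:, c] /= nrm
        jmax = np.argmax(np.abs(psi[:, c]))
        if psi[jmax, c] < 0:
            psi[:, c] = -psi[:, c]
    lam = evals[1 : n_comps + 1]
    comps = psi[:, 1 : n_comps + 1] * lam[None, :]
    out = Embedding(
        coordinates=comps, cell_ids=list(e.cell_ids), space="diffusion", eigenvalues=lam
    )
    out.psi_ = psi[:, 1 : n_comps + 1]
    return out


def diffusion_pseudotime(dc: Embedding, root: str) -> PseudotimeResult:
    """dpt(i) = || (lambda/(1-lambda)) * (psi(i) - psi(root)) ||."""
    if dc.space != "diffusion" or dc.eigenvalues is None:
        raise ValidationError("diffusion_pseudotime requires a diffusion embedding")
    try:
        r = dc.cell_ids.index(str(root))
    except ValueError:
        raise ValidationError(f"root cell {root!r} not found") from None
    lam = dc.eigenvalues
    psi = getattr(dc, "psi_", None)
    if psi is None:  # reconstruct raw eigenvectors from scaled coordinates
        psi = dc.coordinates / np.where(lam == 0, 1.0, lam)[None, :]
    keep = lam < 1.0 - 1e-12
    if not keep.all():
        warnings.warn("dropping eigenvalue(s) at 1 from pseudotime", stacklevel=2)
    scale = lam[keep] / (1.0 - lam[keep])
    delta = (psi[:, keep] - psi[r, keep][None, :]) * scale[None, :]
    dpt = np.linalg.norm(delta, axis=1)
    return PseudotimeResult(
        cell_ids=list(dc.cell_ids),
        pseudotime=dpt,
        root=str(root),
        n_components=int(keep.sum()),
    )


def paga_connectivity(g: nx.Graph, labels: ClusterLabels) -> np.ndarray:
    """Observed/expected inter-cluster edge ratio, scaled to [0, 1].

    connectivity(a, b) = e_obs(a, b) / E_total * C(n_total, 2) / (n_a n_b),
    then divided by the matrix maximum and clipped to [0, 1].  The diagonal
    is zero.  A single cluster yields an empty matrix.
    """
    lab = labels.labels
    node_order = {node: i for i, node in enumerate(sorted(g.nodes()))}
    clusters = np.unique(lab)
    nc = len(clusters)
    if nc < 2:
        return np.zeros((nc, nc))
    sizes = {c: int((lab == c).sum()) for c in clusters}
    e_total = g.number_of_edges()
    n_total = len(lab)
    obs = np.zeros((nc, nc))
    for u, v in g.edges():
        cu, cv = lab[node_order[u]], lab[node_order[v]]
        if cu != cv:
            obs[cu, cv] += 1
            obs[cv, cu] += 1
    conn = np.zeros((nc, nc))
    if e_total > 0:
        pairs_total = n_total * (n_total - 1) / 2.0
        for a in range(nc):
            for b in range(a + 1, nc):
                expected = e_total * sizes[clusters[a]] * sizes[clusters[b]] / pairs_total
                conn[a, b] = conn[b, a] = obs[a, b] / expected if expected > 0 else 0.0
    mx = conn.max()
    if mx > 0:
        conn = np.clip(conn / mx, 0.0, 1.0)
    return conn
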