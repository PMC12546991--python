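"""QC filtering, normalization, HVG selection, cell-cycle scoring and
covariate regression.

The normalization follows the pooling/deconvolution idea: cells are pooled
into overlapping windows on a ring ordered by library size, pool-level size
estimates are computed against an average reference cell, and per-cell
factors are recovered by non-negative least squares, then rescaled to
mean 1.  Log-normalized expression is log2(1 + count / size_factor).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import (
    CellCycleCall,
    GeneExpressionMatrix,
    HvgSet,
    NormalizedMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_POOL_SIZES = (21, 41, 61)


class EmptyResultError(ValueError):
    """A filter removed every cell (or an operation has nothing to work on)."""


def filter_cells(m: GeneExpressionMatrix, min_genes: int) -> GeneExpressionMatrix:
    """Keep cells detecting (count > 0) at least ``min_genes`` genes."""
    if min_genes < 0:
        raise ValidationError("min_genes must be >= 0")
    detected = (m.counts > 0).sum(axis=0)
    keep = detected >= min_genes
    if not keep.any():
        raise EmptyResultError(
            f"cell filter at min_genes={min_genes} removed all {m.n_cells} cells"
        )
    return m.subset_cells(keep)


def filter_genes(m: GeneExpressionMatrix, min_cells: int = 2, min_count: int = 2) -> GeneExpressionMatrix:
    """Keep genes with >= ``min_cells`` cells at count >= ``min_count``.

    The defaults drop genes whose expression never rises above 1 in more
    than one cell — i.e. genes carrying no usable signal after cell QC.
    """
    strong = (m.counts >= min_count).sum(axis=1)
    keep = strong >= min_cells
    if not keep.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return m.subset_genes(keep)


def _pool_ring(order: np.ndarray, sizes) -> list[np.ndarray]:
    n = len(order)
    pools = []
    for size in sizes:
        if size > n:
            continue
        for start in range(n):
            pools.append(order[(start + np.arange(size)) % n])
    return pools


def compute_size_factors(
    m: GeneExpressionMatrix, method: str = "pooled", pool_sizes=DEFAULT_POOL_SIZES
) -> np.ndarray:
    """Per-cell size factors, rescaled to mean 1.

    method="library": proportional to total counts.  method="pooled"
    (default): deconvolution of pool-level estimates; falls back to library
    factors with a warning if the pool system is singular.
    """
    totals = m.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValidationError("all-zero cells present; filter cells first")
    if method == "library":
        sf = totals / totals.mean()
        return sf
    if method != "pooled":
        raise ValidationError(f"unknown size-factor method {method!r}")

    n = m.n_cells
    counts = m.counts.astype(float)
    ref = counts.mean(axis=1)  # average cell profile
    usable = ref > 0
    if usable.sum() < 2 or n < min(pool_sizes, default=n + 1):
        warnings.warn("too few cells/genes for pooling; using library factors", stacklevel=2)
        return totals / totals.mean()

    # alternate low/high library sizes around a ring so pools are balanced
    order_by_total = np.argsort(totals, kind="stable")
    ring = np.empty(n, dtype=int)
    ring[0::2] = order_by_total[: (n + 1) // 2]
    ring[1::2] = order_by_total[(n + 1) // 2 :][::-1]

    pools = _pool_ring(ring, pool_sizes)
    rows, cols, b = [], [], []
    for r, pool in enumerate(pools):
        pooled = counts[:, pool].sum(axis=1)
        ratio = np.median(pooled[usable] / ref[usable])
        rows.extend([r] * len(pool))
        cols.extend(pool.tolist())
        b.append(ratio)
    # anchor the overall scale: sum of factors equals sum of per-cell ratios
    cell_ratio = np.array(
        [np.median(counts[usable, j] / ref[usable]) for j in range(n)]
    )
    A = np.zeros((len(pools) + 1, n))
    A[np.array(rows), np.array(cols)] = 1.0
    A[-1, :] = 1.0
    b.append(cell_ratio.sum())
    b = np.asarray(b)

    from scipy.optimize import nnls

    try:
        sf, _ = nnls(A, b)
    except Exception:
        warnings.warn("pool system could not be solved; using library factors", stacklevel=2)
        return totals / totals.mean()
    if (sf <= 0).any() or not np.isfinite(sf).all():
        warnings.warn("degenerate pooled factors; using library factors", stacklevel=2)
        return totals / totals.mean()
    return sf / sf.mean()


def normalize_log(m: GeneExpressionMatrix, sf: np.ndarray) -> NormalizedMatrix:
    """values = log2(1 + count / size_factor), elementwise."""
    sf = np.asarray(sf, dtype=float)
    if sf.shape != (m.n_cells,):
        raise ValidationError("one size factor per cell required")
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    values = np.log2(1.0 + m.counts / sf[np.newaxis, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        cell_meta=m.cell_meta,
        size_factors=sf,
    )


def _robust_trend_fit(mu: np.ndarray, cv2: np.ndarray) -> np.ndarray:
    """Fit cv2 ~ a + b/mu by iteratively reweighted (Huber) least squares.

    Returns fitted values.  Uses lstsq so a collinear design (e.g. all genes
    at the same mean) degrades gracefully to a robust location fit.
    """
    X = np.column_stack([np.ones_like(mu), 1.0 / np.maximum(mu, 1e-12)])
    w = np.ones(len(mu))
    beta = np.zeros(2)
    for _ in range(25):
        Xw = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ cv2, rcond=None)
        resid = cv2 - X @ beta_new
        scale = np.median(np.abs(resid)) / 0.6745 + 1e-12
        u = np.abs(resid) / (1.345 * scale)
        w = np.where(u <= 1.0, 1.0, 1.0 / np.maximum(u, 1e-12))
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return X @ beta


def select_hvgs(
    nm: NormalizedMatrix,
    replicate_labels=None,
    exclude: dict[str, set[str]] | None = None,
    fraction: float = 0.05,
    combine: str = "mean",
) -> HvgSet:
    """Rank genes by excess squared coefficient of variation.

    Per replicate, the technical trend CV^2 ~ a + b/mu is fitted robustly on
    per-gene means and CV^2 of de-logged normalized counts; the variability
    statistic is observed CV^2 minus the trend, combined across replicates
    (mean by default; "min"/"max" available), with exclusion-list genes
    removed before ranking.  The top ``ceil(fraction * eligible)`` genes are
    returned.
    """
    if replicate_labels is None:
        replicate_labels = nm.replicates
    replicate_labels = pd.Series(np.asarray(replicate_labels, dtype=object), dtype=str)
    expr = nm.log_base**nm.values - 1.0  # back to normalized count scale

    stats = []
    for rep in sorted(replicate_labels.unique()):
        cols = np.flatnonzero((replicate_labels == rep).to_numpy())
        if len(cols) < 2:
            raise ValidationError(f"replicate {rep} has fewer than 2 cells")
        sub = expr[:, cols]
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv2 = np.where(mu > 0, var / mu**2, 0.0)
        ok = mu > 0
        fitted = np.zeros_like(cv2)
        if ok.sum() >= 2:
            fitted[ok] = _robust_trend_fit(mu[ok], cv2[ok])
        stats.append(cv2 - fitted)
    stats = np.vstack(stats)
    if combine == "mean":
        stat = stats.mean(axis=0)
    elif combine == "min":
        stat = stats.min(axis=0)
    elif combine == "max":
        stat = stats.max(axis=0)
    else:
        raise ValidationError(f"unknown combine rule {combine!r}")

    excluded_ids: set[str] = set()
    for genes in (exclude or {}).values():
        excluded_ids |= {str(g) for g in genes}
    eligible = [i for i, g in enumerate(nm.gene_ids) if g not in excluded_ids]
    n_want = int(np.ceil(fraction * len(eligible)))
    if n_want > len(eligible):
        warnings.warn("fewer eligible genes than requested; returning all", stacklevel=2)
        n_want = len(eligible)
    order = sorted(eligible, key=lambda i: (-stat[i], nm.gene_ids[i]))[:n_want]
    return HvgSet(
        gene_ids=[nm.gene_ids[i] for i in order],
        statistic=stat[order],
        fraction=fraction,
    )


def score_cell_cycle(
    nm: NormalizedMatrix,
    marker_pairs: list[tuple[str, str]],
    threshold: float = 0.2,
) -> CellCycleCall:
    """Pair-voting G2/M score: fraction of (hi, lo) pairs with hi > lo.

    Ties contribute 0.5.  Cells scoring above ``threshold`` are called G2/M,
    the rest G1/S.
    """
    gene_index = {g: i for i, g in enumerate(nm.gene_ids)}
    usable = [
        (gene_index[a], gene_index[b])
        for a, b in marker_pairs
        if a in gene_index and b in gene_index
    ]
    if not usable:
        missing = sorted({g for pair in marker_pairs for g in pair} - set(nm.gene_ids))
        raise ValidationError(f"no usable marker pairs; missing genes: {missing[:10]}")
    hi = nm.values[[a for a, _ in usable], :]
    lo = nm.values[[b for _, b in usable], :]
    score = (np.sign(hi - lo) * 0.5 + 0.5).mean(axis=0)  # >: 1, ==: 0.5, <: 0
    phase = ["G2/M" if s > threshold else "G1/S" for s in score]
    return CellCycleCall(
        cell_ids=list(nm.cell_ids), g2m_score=score, phase=phase, threshold=threshold
    )


def regress_out_covariate(nm: NormalizedMatrix, covariate) -> NormalizedMatrix:
    """OLS-remove a binary per-cell covariate gene-wise; grand mean restored."""
    x = np.asarray(covariate, dtype=float)
    if x.shape != (nm.n_cells,):
        raise ValidationError("one covariate value per cell required")
    if np.unique(x).size < 2:
        raise ValidationError("covariate is constant; nothing to regress out")
    xc = x - x.mean()
    Y = nm.values
    grand = Y.mean(axis=1, keepdims=True)
    beta = (Y @ xc) / (xc @ xc)  # per-gene slope on centered covariate
    resid = Y - grand - np.outer(beta, xc)
    return NormalizedMatrix(
        values=resid + grand,
        gene_ids=list(nm.gene_ids),
        cell_ids=list(nm.cell_ids),
        cell_meta=nm.cell_meta,
        size_factors=nm.size_factors,
        log_base=nm.log_base,
    )
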