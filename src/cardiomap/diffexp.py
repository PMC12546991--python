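"""Negative-binomial GLM differential expression on raw counts.

Per gene, log mu = X beta is fitted by iteratively reweighted least squares
at fixed dispersion phi (Var = mu + phi mu^2).  Predictors are cluster and
replicate (categorical) plus sequencing depth (log total counts per cell,
as a free covariate by default or as an offset).  Contrasts are tested by a
likelihood-ratio test against the null-constrained refit, and p-values are
Benjamini-Hochberg adjusted across genes.

Dispersion is estimated gene-wise by a method-of-moments estimator on the
residuals of a Poisson fit and shrunk toward the median dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .containers import GeneExpressionMatrix, MarkerTable, ValidationError

DISPERSION_FLOOR = 1e-8
LINPRED_CLIP = 30.0


@dataclass
class DesignSpec:
    """Per-cell predictors and how depth enters the model.

    depth_mode: "log" (free covariate on log total counts, default),
    "raw" (free covariate on raw totals), "offset" (log totals as offset),
    or "none".
    """

    cluster: np.ndarray
    replicate: np.ndarray | None = None
    depth: np.ndarray | None = None
    depth_mode: str = "log"

    def __post_init__(self) -> None:
        self.cluster = np.asarray(self.cluster).astype(str)
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate).astype(str)
            if len(self.replicate) != len(self.cluster):
                raise ValidationError("replicate length mismatch")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if (self.depth <= 0).any():
                raise ValidationError("depth must be positive")
        if self.depth_mode not in {"log", "raw", "offset", "none"}:
            raise ValidationError(f"unknown depth_mode {self.depth_mode!r}")

    @property
    def cluster_levels(self) -> list[str]:
        return sorted(set(self.cluster.tolist()))

    def build(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        """Return (design matrix, column names, offset vector)."""
        n = len(self.cluster)
        cols: list[np.ndarray] = [np.ones(n)]
        names = ["intercept"]
        for lvl in self.cluster_levels[1:]:  # treatment coding, first = baseline
            cols.append((self.cluster == lvl).astype(float))
            names.append(f"cluster[{lvl}]")
        if self.replicate is not None:
            for lvl in sorted(set(self.replicate.tolist()))[1:]:
                cols.append((self.replicate == lvl).astype(float))
                names.append(f"replicate[{lvl}]")
        offset = np.zeros(n)
        if self.depth is not None and self.depth_mode != "none":
            if self.depth_mode == "log":
                cols.append(np.log(self.depth))
                names.append("log_depth")
            elif self.depth_mode == "raw":
                cols.append(self.depth.astype(float))
                names.append("depth")
            else:  # offset
                offset = np.log(self.depth)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError("design matrix is rank deficient")
        return X, names, offset

    def cluster_contrast(self, target: str, names: list[str]) -> np.ndarray:
        """Contrast vector for target cluster vs the average of the others.

        Replicate coefficients cancel in the additive model, so the contrast
        lives purely on the cluster coefficients (baseline effect = 0).
        """
        levels = self.cluster_levels
        if target not in levels:
            raise ValidationError(f"unknown cluster {target!r}")
        others = [l for l in levels if l != target]
        if not others:
            raise ValidationError("need >= 2 clusters for a contrast")
        weights = {target: 1.0}
        for o in others:
            weights[o] = -1.0 / len(others)
        c = np.zeros(len(names))
        for lvl, w in weights.items():
            name = f"cluster[{lvl}]"
            if name in names:
                c[names.index(name)] = w
            # baseline level has implicit coefficient 0: nothing to add
        return c

    def pairwise_contrast(self, a: str, b: str, names: list[str]) -> np.ndarray:
        """Contrast for cluster a minus cluster b."""
        c = np.zeros(len(names))
        for lvl, w in ((a, 1.0), (b, -1.0)):
            if lvl not in self.cluster_levels:
                raise ValidationError(f"unknown cluster {lvl!r}")
            name = f"cluster[{lvl}]"
            if name in names:
                c[names.index(name)] = w
        return c


def design_from_matrix(
    m: GeneExpressionMatrix, cluster_labels, depth_mode: str = "log"
) -> DesignSpec:
    """Build a DesignSpec with replicate from metadata and depth from totals."""
    return DesignSpec(
        cluster=np.asarray(cluster_labels),
        replicate=m.replicates.to_numpy(),
        depth=m.counts.sum(axis=0).astype(float),
        depth_mode=depth_mode,
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    mu = np.maximum(mu, 1e-300)
    if phi < 1e-10:  # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """IRLS for the NB log-link GLM at fixed phi. Returns (beta, ll, converged)."""
    n, p = X.shape
    # initialize from a crude log-scale least squares
    z0 = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -LINPRED_CLIP, LINPRED_CLIP)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(Xw.T @ X, Xw.T @ z, rcond=None)[0]
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = np.clip(X @ beta + offset, -LINPRED_CLIP, LINPRED_CLIP)
    ll = _nb_loglik(y, np.exp(eta), phi)
    return beta, ll, converged


def estimate_dispersion(
    counts: GeneExpressionMatrix | np.ndarray,
    design: DesignSpec,
    shrink_weight: float = 0.3,
) -> np.ndarray:
    """Gene-wise moment estimate of phi from Poisson-fit residuals,
    shrunk toward the median, floored at 1e-8."""
    Y = counts.counts if isinstance(counts, GeneExpressionMatrix) else np.asarray(counts)
    X, _, offset = design.build()
    n, p = X.shape
    if n - p < 2:
        raise ValidationError("fewer than 2 residual degrees of freedom")
    raw = np.full(Y.shape[0], DISPERSION_FLOOR)
    for g in range(Y.shape[0]):
        y = Y[g].astype(float)
        if y.sum() == 0:
            continue  # untestable; keep floor
        beta, _, _ = _irls(y, X, offset, phi=0.0, max_iter=50)
        mu = np.exp(np.clip(X @ beta + offset, -LINPRED_CLIP, LINPRED_CLIP))
        est = np.sum(((y - mu) ** 2 - mu) / mu**2) / (n - p)
        raw[g] = max(est, DISPERSION_FLOOR)
    med = float(np.median(raw))
    return np.maximum((1.0 - shrink_weight) * raw + shrink_weight * med, DISPERSION_FLOOR)


@dataclass
class NBFit:
    beta: np.ndarray  # genes x p
    loglik: np.ndarray
    converged: np.ndarray
    dispersions: np.ndarray
    design: DesignSpec
    X: np.ndarray
    colnames: list[str]
    offset: np.ndarray
    gene_ids: list[str]
    counts: np.ndarray = field(repr=False, default=None)


def fit_nb_glm(
    counts: GeneExpressionMatrix, design: DesignSpec, dispersions: np.ndarray
) -> NBFit:
    """Fit the NB GLM per gene at fixed gene-wise dispersions."""
    X, names, offset = design.build()
    Y = counts.counts
    dispersions = np.asarray(dispersions, dtype=float)
    if dispersions.shape != (Y.shape[0],):
        raise ValidationError("one dispersion per gene required")
    G, p = Y.shape[0], X.shape[1]
    beta = np.zeros((G, p))
    ll = np.zeros(G)
    conv = np.zeros(G, dtype=bool)
    for g in range(G):
        beta[g], ll[g], conv[g] = _irls(Y[g].astype(float), X, offset, dispersions[g])
    if not conv.all():
        import warnings

        warnings.warn(f"{(~conv).sum()} gene fits did not converge", stacklevel=2)
    return NBFit(
        beta=beta,
        loglik=ll,
        converged=conv,
        dispersions=dispersions,
        design=design,
        X=X,
        colnames=names,
        offset=offset,
        gene_ids=list(counts.gene_ids),
        counts=Y,
    )


def test_contrast(fit: NBFit, contrast: np.ndarray, name: str = "") -> MarkerTable:
    """Likelihood-ratio test of c'beta = 0 per gene, BH-adjusted."""
    c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.X.shape[1],):
        raise ValidationError("contrast length must match design columns")
    if not c.any():
        raise ValidationError("contrast is identically zero (inestimable)")
    N = null_space(c[None, :])  # basis of {beta : c'beta = 0}
    X_null = fit.X @ N
    G = fit.beta.shape[0]
    log2fc = (fit.beta @ c) / np.log(2.0)
    p_raw = np.ones(G)
    for g in range(G):
        y = fit.counts[g].astype(float)
        _, ll0, _ = _irls(y, X_null, fit.offset, fit.dispersions[g])
        stat = max(2.0 * (fit.loglik[g] - ll0), 0.0)
        p_raw[g] = chi2.sf(stat, df=1)
    p_adj = benjamini_hochberg(p_raw)
    table = pd.DataFrame(
        {
            "gene_id": fit.gene_ids,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return MarkerTable(table=table, contrast=name)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def derive_markers(
    counts: GeneExpressionMatrix,
    design: DesignSpec,
    target_cluster: str,
    min_cells: int = 3,
) -> MarkerTable:
    """Markers of one cluster: contrast target vs the mean of the others."""
    sizes = pd.Series(design.cluster).value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 clusters for marker derivation")
    small = sizes[sizes < min_cells]
    if str(target_cluster) in small.index:
        raise ValidationError(
            f"cluster {target_cluster!r} has fewer than {min_cells} cells"
        )
    disp = estimate_dispersion(counts, design)
    fit = fit_nb_glm(counts, design, disp)
    c = design.cluster_contrast(str(target_cluster), fit.colnames)
    mt = test_contrast(fit, c, name=f"{target_cluster} vs rest")
    # per-group mean raw counts for reference
    in_t = design.cluster == str(target_cluster)
    mt.table["mean_target"] = counts.counts[:, in_t].mean(axis=1)
    mt.table["mean_rest"] = counts.counts[:, ~in_t].mean(axis=1)
    return mt


def compare_deg_sets(
    table_a: MarkerTable,
    table_b: MarkerTable,
    p_cut: float,
    fc_cut: float,
) -> dict:
    """Set algebra on significant genes (p_adj < p_cut and |FC| > fc_cut)."""
    ua = set(table_a.table["gene_id"])
    ub = set(table_b.table["gene_id"])
    if ua != ub:
        raise ValidationError("marker tables cover different gene universes")

    def sig(mt: MarkerTable) -> set[str]:
        t = mt.table
        mask = (t["p_adj"] < p_cut) & (2.0 ** t["log2fc"].abs() > fc_cut)
        return set(t.loc[mask, "gene_id"])

    A, B = sig(table_a), sig(table_b)
    return {
        "n_a": len(A),
        "n_b": len(B),
        "n_both": len(A & B),
        "n_a_only": len(A - B),
        "n_b_only": len(B - A),
        "a": sorted(A),
        "b": sorted(B),
        "both": sorted(A & B),
        "a_only": sorted(A - B),
        "b_only": sorted(B - A),
    }
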