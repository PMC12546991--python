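"""Synthetic single-cell count data with full ground truth.

The generator emulates the structure the downstream analysis assumes:
negative-binomial UMI counts with population-specific marker programs,
per-replicate multiplicative batch shifts, per-cell library-size variation,
an additive cell-cycle program on a subset of cells, and an optional small
contaminant population carrying a pluripotency-like marker program.

Counts are drawn gene-wise NB(mu, phi) with Var = mu + phi * mu^2.  A
population's marker genes have mu = baseline_mean * 2**marker_log2fc;
all other genes sit at baseline_mean.  Library-size variation multiplies
mu by a per-cell log-normal(0, 0.25^2) factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneExpressionMatrix, ReferenceAtlas, ValidationError

LIBRARY_SIZE_SD = 0.25  # sd of per-cell log library factor (natural log scale)
GENE_MEAN_SD = 0.5  # sd of per-gene log baseline factor (natural log scale)


@dataclass
class PopulationSpec:
    """One simulated cell population and its marker program."""

    name: str
    n_cells: int
    baseline_mean: float
    marker_genes: list[int]
    marker_log2fc: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"population {self.name}: n_cells must be >= 1")
        if self.dispersion <= 0:
            raise ValidationError(f"population {self.name}: dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValidationError(f"population {self.name}: baseline_mean must be > 0")
        if self.marker_log2fc < 0:
            raise ValidationError(f"population {self.name}: marker_log2fc must be >= 0")
        self.marker_genes = sorted(int(g) for g in self.marker_genes)


@dataclass
class SyntheticTruth:
    """Ground-truth ledger emitted alongside every generated dataset."""

    cells: pd.DataFrame  # cell_id, true_type, replicate, cycle_phase, library_factor
    genes: pd.DataFrame  # gene_id, is_marker_of, true_log2fc, is_cycle_gene
    batch_factors: pd.DataFrame | None = None  # genes x replicates, multiplicative on mu


def _validate_populations(
    populations: list[PopulationSpec], n_genes: int, allow_marker_overlap: bool
) -> None:
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValidationError("population names must be unique")
    for p in populations:
        if p.marker_genes and p.marker_genes[-1] >= n_genes:
            raise ValidationError(
                f"population {p.name}: marker index {p.marker_genes[-1]} >= n_genes"
            )
    if not allow_marker_overlap:
        for i, a in enumerate(populations):
            for b in populations[i + 1 :]:
                shared = set(a.marker_genes) & set(b.marker_genes)
                if shared:
                    raise ValidationError(
                        f"populations {a.name} and {b.name} share undeclared "
                        f"markers {sorted(shared)[:5]}"
                    )


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2 via the gamma-Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if phi < 1e-12:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = 1.0 / phi
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def _gene_truth(
    populations: list[PopulationSpec], n_genes: int, cycle_genes: np.ndarray | None
) -> pd.DataFrame:
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    is_marker_of = [[] for _ in range(n_genes)]
    log2fc = np.zeros(n_genes)
    for p in populations:
        for g in p.marker_genes:
            is_marker_of[g].append(p.name)
            log2fc[g] = p.marker_log2fc
    is_cycle = np.zeros(n_genes, dtype=bool)
    if cycle_genes is not None:
        is_cycle[cycle_genes] = True
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_marker_of": [";".join(m) for m in is_marker_of],
            "true_log2fc": log2fc,
            "is_cycle_gene": is_cycle,
        }
    )


def draw_gene_baseline(n_genes: int, sd: float, seed: int) -> np.ndarray:
    """Per-gene multiplicative baseline factors, log-normal(0, sd^2).

    Real transcriptomes span orders of magnitude in per-gene abundance;
    share one draw between a query and its reference so both datasets
    describe the same genes.
    """
    if sd <= 0:
        return np.ones(n_genes)
    return np.exp(np.random.default_rng(seed).normal(0.0, sd, size=n_genes))


def _population_mu(
    p: PopulationSpec, n_genes: int, gene_baseline: np.ndarray
) -> np.ndarray:
    mu = gene_baseline * p.baseline_mean
    if p.marker_genes:
        mu = mu.copy()
        mu[p.marker_genes] *= 2.0**p.marker_log2fc
    return mu


def generate_reference_atlas(
    populations: list[PopulationSpec],
    n_genes: int,
    seed: int,
    *,
    library_sd: float = LIBRARY_SIZE_SD,
    gene_mean_sd: float = GENE_MEAN_SD,
    gene_baseline: np.ndarray | None = None,
    allow_marker_overlap: bool = False,
    cell_prefix: str = "ref",
) -> tuple[ReferenceAtlas, SyntheticTruth]:
    """Generate a labeled atlas with exactly the specified type proportions."""
    _validate_populations(populations, n_genes, allow_marker_overlap)
    rng = np.random.default_rng(seed)
    if gene_baseline is None:
        gene_baseline = draw_gene_baseline(n_genes, gene_mean_sd, seed + 1)
    gene_baseline = np.asarray(gene_baseline, dtype=float)
    n_total = sum(p.n_cells for p in populations)
    counts = np.zeros((n_genes, n_total), dtype=np.int64)
    labels: list[str] = []
    lib = np.exp(rng.normal(0.0, library_sd, size=n_total)) if library_sd > 0 else np.ones(n_total)
    col = 0
    for p in populations:
        mu = _population_mu(p, n_genes, gene_baseline)
        for _ in range(p.n_cells):
            counts[:, col] = _nb_sample(rng, mu * lib[col], p.dispersion)
            labels.append(p.name)
            col += 1
    cell_ids = [f"{cell_prefix}{i:05d}" for i in range(n_total)]
    meta = pd.DataFrame({"replicate": ["R1"] * n_total}, index=cell_ids)
    gem = GeneExpressionMatrix(
        counts=counts,
        gene_ids=[f"gene{i:05d}" for i in range(n_genes)],
        cell_ids=cell_ids,
        cell_meta=meta,
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "true_type": labels,
                "replicate": "R1",
                "cycle_phase": "G1/S",
                "library_factor": lib,
            }
        ),
        genes=_gene_truth(populations, n_genes, None).assign(
            baseline_factor=gene_baseline
        ),
    )
    return ReferenceAtlas(matrix=gem, cell_types=labels, provenance="synthetic"), truth


def generate_query_batches(
    populations: list[PopulationSpec],
    n_genes: int,
    n_replicates: int,
    batch_sd: float,
    cycle_fraction: float,
    cycle_gene_count: int,
    contaminant: PopulationSpec | None,
    seed: int,
    *,
    library_sd: float = LIBRARY_SIZE_SD,
    gene_mean_sd: float = GENE_MEAN_SD,
    gene_baseline: np.ndarray | None = None,
    cycle_log2_shift: float = 1.0,
    allow_marker_overlap: bool = False,
    cell_prefix: str = "cell",
) -> tuple[GeneExpressionMatrix, SyntheticTruth]:
    """Generate a multi-replicate query dataset.

    Each replicate contains ``n_cells`` cells of every population and applies
    gene-wise multiplicative batch factors 2**N(0, batch_sd^2) shared by all
    its cells.  Exactly ``floor(cycle_fraction * n_total)`` cells receive an
    additive ``cycle_log2_shift`` on the log2-mean of ``cycle_gene_count``
    designated (non-marker) cycle genes and are labeled G2/M.  Contaminant
    cells, if requested, are spread as evenly as possible over replicates.
    """
    all_pops = list(populations) + ([contaminant] if contaminant is not None else [])
    _validate_populations(all_pops, n_genes, allow_marker_overlap)
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if batch_sd < 0:
        raise ValidationError("batch_sd must be >= 0")
    if not 0.0 <= cycle_fraction <= 1.0:
        raise ValidationError("cycle_fraction must be in [0, 1]")
    if cycle_gene_count > n_genes:
        raise ValidationError("cycle_gene_count exceeds n_genes")

    rng = np.random.default_rng(seed)
    if gene_baseline is None:
        gene_baseline = draw_gene_baseline(n_genes, gene_mean_sd, seed + 1)
    gene_baseline = np.asarray(gene_baseline, dtype=float)
    replicate_names = [f"R{r + 1}" for r in range(n_replicates)]
    batch = 2.0 ** rng.normal(0.0, batch_sd, size=(n_genes, n_replicates))

    marker_idx = sorted({g for p in all_pops for g in p.marker_genes})
    eligible = np.setdiff1d(np.arange(n_genes), np.array(marker_idx, dtype=int))
    if cycle_gene_count > len(eligible):
        raise ValidationError("not enough non-marker genes for the cycle program")
    cycle_genes = np.sort(rng.choice(eligible, size=cycle_gene_count, replace=False))

    # plan cells: (population, replicate) blocks in declared order
    plan: list[tuple[PopulationSpec, int]] = []
    for r in range(n_replicates):
        for p in populations:
            plan.extend([(p, r)] * p.n_cells)
    if contaminant is not None:
        per_rep = np.full(n_replicates, contaminant.n_cells // n_replicates)
        per_rep[: contaminant.n_cells % n_replicates] += 1
        for r in range(n_replicates):
            plan.extend([(contaminant, r)] * int(per_rep[r]))

    n_total = len(plan)
    n_cycling = int(np.floor(cycle_fraction * n_total))
    cycling = np.zeros(n_total, dtype=bool)
    cycling[rng.choice(n_total, size=n_cycling, replace=False)] = True

    lib = np.exp(rng.normal(0.0, library_sd, size=n_total)) if library_sd > 0 else np.ones(n_total)
    counts = np.zeros((n_genes, n_total), dtype=np.int64)
    cell_type, cell_rep, cell_phase = [], [], []
    for i, (p, r) in enumerate(plan):
        mu = _population_mu(p, n_genes, gene_baseline) * batch[:, r] * lib[i]
        if cycling[i]:
            mu = mu.copy()
            mu[cycle_genes] *= 2.0**cycle_log2_shift
        counts[:, i] = _nb_sample(rng, mu, p.dispersion)
        cell_type.append(p.name)
        cell_rep.append(replicate_names[r])
        cell_phase.append("G2/M" if cycling[i] else "G1/S")

    cell_ids = [f"{cell_prefix}{i:05d}" for i in range(n_total)]
    meta = pd.DataFrame({"replicate": cell_rep}, index=cell_ids)
    gem = GeneExpressionMatrix(
        counts=counts,
        gene_ids=[f"gene{i:05d}" for i in range(n_genes)],
        cell_ids=cell_ids,
        cell_meta=meta,
    )
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {
                "cell_id": cell_ids,
                "true_type": cell_type,
                "replicate": cell_rep,
                "cycle_phase": cell_phase,
                "library_factor": lib,
            }
        ),
        genes=_gene_truth(all_pops, n_genes, cycle_genes).assign(
            baseline_factor=gene_baseline
        ),
        batch_factors=pd.DataFrame(
            batch,
            index=[f"gene{i:05d}" for i in range(n_genes)],
            columns=replicate_names,
        ),
    )
    return gem, truth


def cycle_marker_pairs(
    truth: SyntheticTruth, cycle_log2_shift: float = 1.0
) -> list[tuple[str, str]]:
    """Ground-truth (hi, lo) pairs for the pair-voting G2/M score.

    Each designated cycle gene is paired with a quiet gene (no cycle or
    marker program) whose baseline sits near the geometric midpoint of the
    cycle gene's off/on means, so the hi > lo comparison flips exactly when
    the cycle program is active.
    """
    g = truth.genes
    if "baseline_factor" not in g.columns:
        raise ValidationError("truth table lacks baseline factors")
    cyc = g[g["is_cycle_gene"]]
    quiet = g[~g["is_cycle_gene"] & (g["is_marker_of"] == "")]
    if cyc.empty or quiet.empty:
        raise ValidationError("need both cycle and quiet genes for pairs")
    target_log = np.log2(cyc["baseline_factor"].to_numpy()) + cycle_log2_shift / 2.0
    quiet_log = np.log2(quiet["baseline_factor"].to_numpy())
    pairs, used = [], set()
    for hi, t in zip(cyc["gene_id"], target_log):
        order = np.argsort(np.abs(quiet_log - t), kind="stable")
        for j in order:
            if j not in used:
                used.add(int(j))
                pairs.append((hi, quiet["gene_id"].iloc[int(j)]))
                break
    return pairs


def generate_trajectory_dataset(
    n_cells: int,
    n_genes: int,
    program_length: int,
    seed: int,
    *,
    low_mean: float = 1.0,
    high_mean: float = 20.0,
    noise_mean: float = 2.0,
    dispersion: float = 0.1,
) -> tuple[GeneExpressionMatrix, np.ndarray]:
    """Cells evenly spaced on a latent position t in [0, 1].

    The first ``program_length`` genes interpolate log-linearly (hence
    monotonically) between two extreme states along t, half increasing and
    half decreasing; remaining genes are stationary noise.  Returns the
    matrix and the true t per cell.
    """
    if n_cells < 3:
        raise ValidationError("n_cells must be >= 3")
    if program_length > n_genes:
        raise ValidationError("program_length exceeds n_genes")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_cells)
    log_lo, log_hi = np.log(low_mean), np.log(high_mean)
    mu = np.full((n_genes, n_cells), noise_mean, dtype=float)
    half = program_length // 2
    for g in range(program_length):
        if g < half:
            logmu = log_lo + t * (log_hi - log_lo)  # increasing along t
        else:
            logmu = log_hi + t * (log_lo - log_hi)  # decreasing along t
        mu[g] = np.exp(logmu)
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for i in range(n_cells):
        counts[:, i] = _nb_sample(rng, mu[:, i], dispersion)
    cell_ids = [f"traj{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame({"replicate": ["R1"] * n_cells}, index=cell_ids)
    gem = GeneExpressionMatrix(
        counts=counts,
        gene_ids=[f"gene{i:05d}" for i in range(n_genes)],
        cell_ids=cell_ids,
        cell_meta=meta,
    )
    return gem, t


def default_query_populations(
    n_genes: int = 2000,
    n_cells: int = 300,
    n_markers: int = 40,
    marker_log2fc: float = 3.0,
    baseline_mean: float = 2.0,
    dispersion: float = 0.2,
    names: tuple[str, ...] = ("intramyocardial_EC", "endocardium", "immature_EC"),
) -> list[PopulationSpec]:
    """Standard scenario: well-separated populations with disjoint marker blocks."""
    pops = []
    for i, name in enumerate(names):
        start = i * n_markers
        pops.append(
            PopulationSpec(
                name=name,
                n_cells=n_cells,
                baseline_mean=baseline_mean,
                marker_genes=list(range(start, start + n_markers)),
                marker_log2fc=marker_log2fc,
                dispersion=dispersion,
            )
        )
    return pops


def default_contaminant(
    n_genes: int = 2000,
    n_cells: int = 40,
    n_markers: int = 20,
    marker_log2fc: float = 3.0,
    baseline_mean: float = 2.0,
    dispersion: float = 0.2,
    marker_offset: int = 200,
) -> PopulationSpec:
    """A small pluripotency-marker-positive contaminant population."""
    return PopulationSpec(
        name="pluripotent_contaminant",
        n_cells=n_cells,
        baseline_mean=baseline_mean,
        marker_genes=list(range(marker_offset, marker_offset + n_markers)),
        marker_log2fc=marker_log2fc,
        dispersion=dispersion,
    )
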