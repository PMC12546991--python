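"""Core in-memory containers for the pipeline.

All expression matrices are oriented genes x cells in memory.  Counts are
dense int64 arrays (the pipeline operates at the scale of a few thousand
cells, where dense arithmetic is both faster and simpler than sparse);
normalized values are float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class FormatError(ValueError):
    """A file on disk does not match the declared format."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            if i in seen:
                dups.add(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what}: {sorted(dups)[:5]}")
    return ids


@dataclass
class GeneExpressionMatrix:
    """Raw UMI counts (genes x cells) with identifiers and per-cell metadata.

    ``cell_meta`` is indexed by cell id and carries at least a ``replicate``
    column; an optional ``condition`` column tags experimental condition.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts contain non-integer entries")
            self.counts = np.round(self.counts).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts contain negative entries")
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(
                {"replicate": ["R1"] * len(self.cell_ids)}, index=self.cell_ids
            )
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta.index = self.cell_meta.index.astype(str)
        if "replicate" not in self.cell_meta.columns:
            raise ValidationError("cell_meta must have a 'replicate' column")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValidationError(f"cells missing from cell_meta: {sorted(missing)[:5]}")
        if self.cell_meta.index.has_duplicates:
            raise ValidationError("cell_meta index has duplicate cell ids")
        self.cell_meta = self.cell_meta.loc[self.cell_ids]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def replicates(self) -> pd.Series:
        return self.cell_meta["replicate"].astype(str)

    def subset_cells(self, mask_or_ids) -> "GeneExpressionMatrix":
        idx = self._cell_indexer(mask_or_ids)
        return GeneExpressionMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask_or_ids) -> "GeneExpressionMatrix":
        idx = self._gene_indexer(mask_or_ids)
        return GeneExpressionMatrix(
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta,
        )

    def _cell_indexer(self, sel) -> np.ndarray:
        return _as_index(sel, self.cell_ids, "cell")

    def _gene_indexer(self, sel) -> np.ndarray:
        return _as_index(sel, self.gene_ids, "gene")


def _as_index(sel, ids: list[str], what: str) -> np.ndarray:
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.shape != (len(ids),):
            raise ValidationError(f"{what} mask length mismatch")
        return np.flatnonzero(sel)
    if np.issubdtype(sel.dtype, np.integer):
        return sel.astype(int)
    lookup = {g: i for i, g in enumerate(ids)}
    try:
        return np.array([lookup[str(s)] for s in sel], dtype=int)
    except KeyError as e:
        raise ValidationError(f"unknown {what} id {e.args[0]!r}") from None


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: ``log2(1 + count / size_factor)``."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame
    size_factors: np.ndarray
    log_base: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("values shape mismatch")
        if self.size_factors.shape != (len(self.cell_ids),):
            raise ValidationError("one size factor per cell required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def replicates(self) -> pd.Series:
        return self.cell_meta["replicate"].astype(str)

    def subset_genes(self, sel) -> "NormalizedMatrix":
        idx = _as_index(sel, self.gene_ids, "gene")
        return NormalizedMatrix(
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            cell_meta=self.cell_meta,
            size_factors=self.size_factors,
            log_base=self.log_base,
        )

    def subset_cells(self, sel) -> "NormalizedMatrix":
        idx = _as_index(sel, self.cell_ids, "cell")
        return NormalizedMatrix(
            values=self.values[:, idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx],
            size_factors=self.size_factors[idx],
            log_base=self.log_base,
        )


@dataclass
class Embedding:
    """Cell coordinates in a reduced space (cells x d)."""

    coordinates: np.ndarray
    cell_ids: list[str]
    space: str  # pca | mnn-corrected | diffusion
    eigenvalues: np.ndarray | None = None  # diffusion space only

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise ValidationError("one coordinate row per cell required")
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("embedding has non-finite entries")

    @property
    def d(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class CellCycleCall:
    """Per-cell G2/M score in [0,1] and binary phase call."""

    cell_ids: list[str]
    g2m_score: np.ndarray
    phase: list[str]  # "G2/M" or "G1/S"
    threshold: float = 0.2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "g2m_score": self.g2m_score, "phase": self.phase}
        )


@dataclass
class HvgSet:
    """Ordered highly-variable-gene list with the per-gene excess-CV2 statistic."""

    gene_ids: list[str]
    statistic: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "statistic": self.statistic})


@dataclass
class ClusterLabels:
    """Per-cell integer cluster labels with per-cluster exclusion flags."""

    cell_ids: list[str]
    labels: np.ndarray
    resolution: float
    exclusion_flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.cell_ids),):
            raise ValidationError("one label per cell required")
        present = np.unique(self.labels)
        if len(present) and not np.array_equal(present, np.arange(len(present))):
            raise ValidationError("labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def to_frame(self) -> pd.DataFrame:
        flags = [self.exclusion_flags.get(int(l), "none") for l in self.labels]
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "cluster": self.labels, "exclusion": flags}
        )


@dataclass
class PseudotimeResult:
    cell_ids: list[str]
    pseudotime: np.ndarray
    root: str
    n_components: int

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if not np.isfinite(self.pseudotime).all():
            raise ValidationError("pseudotime has non-finite values")
        if (self.pseudotime < 0).any():
            raise ValidationError("pseudotime must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "pseudotime": self.pseudotime})


@dataclass
class MarkerTable:
    """Per-gene differential-expression results for one contrast."""

    table: pd.DataFrame  # columns: gene_id, log2fc, p_raw, p_adj, mean_* per group
    contrast: str = ""

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "p_raw", "p_adj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"marker table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)


UNASSIGNED = "UNASSIGNED"


@dataclass
class AssignmentResult:
    """Per-query-cell reference label call with abstention gates applied."""

    table: pd.DataFrame  # cell_id, assigned_type, confidence, mean_nn_distance, gate_reason

    def __post_init__(self) -> None:
        required = {"cell_id", "assigned_type", "confidence", "mean_nn_distance", "gate_reason"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"assignment table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def assigned_mask(self) -> np.ndarray:
        return (self.table["assigned_type"] != UNASSIGNED).to_numpy()


@dataclass
class ReferenceAtlas:
    """A labeled reference expression dataset (e.g. a fetal heart atlas).

    Holds raw counts plus a ground-truth/curated type label per cell.
    """

    matrix: GeneExpressionMatrix
    cell_types: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.cell_types) != self.matrix.n_cells:
            raise ValidationError("one cell-type label per reference cell required")
        self.cell_types = [str(t) for t in self.cell_types]

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.cell_types))


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(str(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)
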