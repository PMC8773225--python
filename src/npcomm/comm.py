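"""Per-dataset communication counting and the stable-communication ratio.

The model: in one single-cell dataset with ``y`` cells, a ligand-receptor
pair (L, R) establishes an ordered communication from every cell actively
expressing L (sender) to every cell actively expressing R (receiver),
self-communication included.  "Active" means the log2 TPM value is at or
above a threshold (default 1.0).  The communication count is therefore

    x = n_senders * n_receivers

and never requires enumerating cell pairs.  The stable-communication ratio

    s = x / y**2

measures which fraction of all conceivable ordered cell pairs the pair
realizes; a pair is called *stable* in the dataset when s exceeds 0.5,
i.e. when it spans more than half of all possible cell-to-cell links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import PairCatalog, _normalize_symbol

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Raised for malformed expression matrices (negative/non-finite values,
    shape mismatches, zero cells)."""


@dataclass
class ExpressionMatrix:
    """A gene x cell matrix of non-negative log2-TPM values for one dataset.

    Gene symbols are case-normalized; duplicate gene rows are collapsed by
    taking the per-cell maximum (a gene is active in a cell if any duplicate
    row passes the threshold), with a log message.
    """

    dataset_id: str
    cancer_type: str
    values: pd.DataFrame  # index = gene symbols, columns = cell ids

    def __post_init__(self) -> None:
        df = self.values
        df = df.astype(float)
        arr = df.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[:5]
            raise ExpressionError(
                f"{self.dataset_id}: non-finite expression values at "
                f"(gene,cell) indices {bad.tolist()}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[:5]
            raise ExpressionError(
                f"{self.dataset_id}: negative expression values at "
                f"(gene,cell) indices {bad.tolist()}"
            )
        df.index = [_normalize_symbol(g) for g in df.index]
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            logger.warning(
                "%s: duplicate gene rows %s collapsed by max", self.dataset_id, dups
            )
            df = df.groupby(level=0, sort=False).max()
        if df.columns.has_duplicates:
            raise ExpressionError(f"{self.dataset_id}: duplicate cell ids")
        self.values = df

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cells(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ActiveMask:
    """Boolean gene x cell activity calls at a fixed threshold."""

    active: pd.DataFrame  # boolean, index = genes, columns = cells
    threshold: float = 1.0

    @property
    def genes(self) -> list[str]:
        return list(self.active.index)

    @property
    def cells(self) -> list[str]:
        return list(self.active.columns)

    @property
    def n_cells(self) -> int:
        return self.active.shape[1]

    def gene_vector(self, gene: str) -> np.ndarray:
        """Per-cell activity of *gene*; all-False if the gene is absent."""
        g = _normalize_symbol(gene)
        if g in self.active.index:
            return self.active.loc[g].to_numpy()
        return np.zeros(self.n_cells, dtype=bool)


@dataclass
class PairCommunication:
    """Communication statistics for one catalog pair in one dataset."""

    dataset_id: str
    ligand: str
    receptor: str
    n_senders: int
    n_receivers: int
    x: int  # ordered sender->receiver cell pairs, self-pairs included
    y: int  # total cells in the dataset
    s: float  # x / y**2
    stable: bool


@dataclass
class CommunicationEdge:
    """One directed sender -> receiver link realized by one pair."""

    sender_cell: str
    receiver_cell: str
    ligand: str
    receptor: str


def call_active(
    expr: ExpressionMatrix,
    threshold: float = 1.0,
    catalog: PairCatalog | None = None,
) -> tuple[ActiveMask, list[str]]:
    """Threshold the matrix into a boolean activity mask (value >= threshold).

    Returns the mask and, when a catalog is given, the catalog genes absent
    from the matrix (not measured, as opposed to measured-but-inactive).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    mask = ActiveMask(active=expr.values >= threshold, threshold=threshold)
    missing: list[str] = []
    if catalog is not None:
        present = set(mask.genes)
        missing = [g for g in catalog.genes if g not in present]
        if missing:
            logger.info(
                "%s: %d catalog genes absent from matrix", expr.dataset_id, len(missing)
            )
    return mask, missing


def count_pair_communications(
    mask: ActiveMask, ligand: str, receptor: str
) -> tuple[int, int, int]:
    """Sender count, receiver count and communication count for one pair.

    x counts ordered (sender, receiver) cell pairs including
    sender == receiver, computed as the product of the two cell counts —
    linear in the number of cells, never by pair enumeration.  A gene
    absent from the mask contributes zero.
    """
    n_senders = int(mask.gene_vector(ligand).sum())
    n_receivers = int(mask.gene_vector(receptor).sum())
    return n_senders, n_receivers, n_senders * n_receivers


def total_possible(y: int) -> int:
    """All conceivable ordered cell-cell communications in a y-cell dataset: y**2."""
    if y < 0 or int(y) != y:
        raise ValueError(f"cell count must be a non-negative integer, got {y}")
    return int(y) ** 2


def stability_ratio(x: int, y: int) -> float:
    """The stable-communication ratio s = x / y**2, in [0, 1]."""
    if y < 1:
        raise ValueError(f"ratio undefined for cell count y={y}")
    if not 0 <= x <= y * y:
        raise ValueError(f"inconsistent communication count x={x} for y={y} cells")
    return x / (y * y)


def is_stable(s: float, stable_threshold: float = 0.5) -> bool:
    """Stable-pair call: strictly greater than the threshold ("over 50%")."""
    if not 0 <= s <= 1:
        raise ValueError(f"ratio out of [0,1]: {s}")
    return s > stable_threshold


def ligand_union_communications(
    mask: ActiveMask, ligand: str, receptors: list[str]
) -> tuple[int, int, int]:
    """Communications from a ligand through ANY of several receptors.

    The receiver set is the union of the per-receptor receiver cell sets, so
    a cell pair reachable via two receptors is counted once.
    """
    if not receptors:
        raise ValueError("receptors list must be non-empty")
    senders = mask.gene_vector(ligand)
    union = np.zeros(mask.n_cells, dtype=bool)
    for rec in receptors:
        union |= mask.gene_vector(rec)
    n_senders = int(senders.sum())
    n_union = int(union.sum())
    return n_senders, n_union, n_senders * n_union


def run_dataset(
    expr: ExpressionMatrix,
    catalog: PairCatalog,
    active_threshold: float = 1.0,
    stable_threshold: float = 0.5,
) -> list[PairCommunication]:
    """Score every catalog pair in one dataset.

    Pairs with x == 0 are omitted from the output (the log records how many);
    a dataset in which no catalog pair communicates yields an empty list,
    mirroring datasets eliminated for lacking actively expressed catalog
    genes.
    """
    if expr.n_cells == 0:
        raise ExpressionError(f"{expr.dataset_id}: dataset has no cells")
    mask, missing = call_active(expr, active_threshold, catalog)
    y = expr.n_cells
    out: list[PairCommunication] = []
    n_silent = 0
    for ligand, receptor in catalog:
        n_s, n_r, x = count_pair_communications(mask, ligand, receptor)
        if x == 0:
            n_silent += 1
            continue
        s = stability_ratio(x, y)
        out.append(
            PairCommunication(
                dataset_id=expr.dataset_id,
                ligand=ligand,
                receptor=receptor,
                n_senders=n_s,
                n_receivers=n_r,
                x=x,
                y=y,
                s=s,
                stable=is_stable(s, stable_threshold),
            )
        )
    total_x = sum(p.x for p in out)
    n_stable = sum(p.stable for p in out)
    logger.info(
        "%s: y=%d y^2=%d sum_x=%d pairs=%d silent=%d stable=%d missing_genes=%d "
        "(top ratio %s)",
        expr.dataset_id,
        y,
        y * y,
        total_x,
        len(out),
        n_silent,
        n_stable,
        len(missing),
        format_percent(max((p.s for p in out), default=0.0)),
    )
    if not out:
        logger.warning("%s: no active catalog pairs; dataset eliminated", expr.dataset_id)
    return out


def format_percent(s: float) -> str:
    """Render a ratio as a percentage with one decimal, half-up (0.97619 -> '97.6%')."""
    from decimal import Decimal, ROUND_HALF_UP

    pct = Decimal(repr(s * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{pct}%"


def enumerate_edges(
    mask: ActiveMask,
    pairs: list[tuple[str, str]],
    max_edges: int,
    seed: int = 0,
) -> list[CommunicationEdge]:
    """All communication edges, or a uniform sample of ``max_edges`` of them.

    The sample is drawn without replacement over the global edge index space
    (pairs laid out consecutively, each pair's edges in sender-major order),
    so no cell x cell structure is ever allocated.  Deterministic given seed.
    """
    if max_edges < 0:
        raise ValueError("max_edges must be >= 0")
    cells = np.asarray(mask.cells, dtype=object)
    layout: list[tuple[str, str, np.ndarray, np.ndarray]] = []
    counts: list[int] = []
    for ligand, receptor in pairs:
        s_idx = np.flatnonzero(mask.gene_vector(ligand))
        r_idx = np.flatnonzero(mask.gene_vector(receptor))
        layout.append((ligand, receptor, s_idx, r_idx))
        counts.append(len(s_idx) * len(r_idx))
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])

    def edge_at(gidx: int) -> CommunicationEdge:
        p = int(np.searchsorted(offsets, gidx, side="right") - 1)
        ligand, receptor, s_idx, r_idx = layout[p]
        local = gidx - offsets[p]
        si, ri = divmod(int(local), len(r_idx))
        return CommunicationEdge(
            sender_cell=str(cells[s_idx[si]]),
            receiver_cell=str(cells[r_idx[ri]]),
            ligand=ligand,
            receptor=receptor,
        )

    if total <= max_edges:
        return [edge_at(i) for i in range(total)]
    rng = np.random.default_rng(seed)
    if max_edges == 0:
        return []
    # rejection-sample distinct global indices; max_edges << total here
    chosen: set[int] = set()
    while len(chosen) < max_edges:
        draw = rng.integers(0, total, size=max_edges - len(chosen))
        chosen.update(int(d) for d in draw)
    return [edge_at(i) for i in sorted(chosen)]


@dataclass
class DatasetResult:
    """Convenience bundle: the per-pair table plus dataset-level tallies."""

    dataset_id: str
    cancer_type: str
    communications: list[PairCommunication] = field(default_factory=list)

    @property
    def total_x(self) -> int:
        return sum(p.x for p in self.communications)

    @property
    def stable_pairs(self) -> list[PairCommunication]:
        return [p for p in self.communications if p.stable]
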