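"""Readers and writers for the pipeline's on-disk formats.

Expression matrices come in two dialects: a dense TSV/CSV with gene symbols
in the first column and one column per cell, and a MatrixMarket triplet
(.mtx) with row-label and column-label sidecar files.  Results are flat
TSVs; communication edges export as SIF or GraphML for Cytoscape.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
import scipy.io
import scipy.sparse

from .comm import CommunicationEdge, ExpressionMatrix, PairCommunication

RESULT_COLUMNS = [
    "dataset_id",
    "cancer_type",
    "ligand",
    "receptor",
    "n_senders",
    "n_receivers",
    "x",
    "y",
    "s",
    "stable",
]


# -- expression matrices ---------------------------------------------------


def read_expression_tsv(
    path: str | Path, dataset_id: str | None = None, cancer_type: str = "unknown"
) -> ExpressionMatrix:
    """Dense TSV/CSV: first column gene symbols, remaining columns cells."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        dataset_id=dataset_id or path.stem,
        cancer_type=cancer_type,
        values=frame.astype(float),
    )


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.values.copy()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    dataset_id: str | None = None,
    cancer_type: str = "unknown",
) -> ExpressionMatrix:
    """MatrixMarket triplet (genes x cells) with one-label-per-line sidecars."""
    mtx_path = Path(mtx_path)
    if not mtx_path.exists():
        raise FileNotFoundError(f"matrix not found: {mtx_path}")
    mat = scipy.io.mmread(str(mtx_path))
    genes = _read_lines(genes_path)
    cells = _read_lines(cells_path)
    dense = mat.toarray() if scipy.sparse.issparse(mat) else mat
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"{mtx_path.name}: shape {dense.shape} does not match "
            f"{len(genes)} gene labels x {len(cells)} cell labels"
        )
    frame = pd.DataFrame(dense, index=genes, columns=cells, dtype=float)
    return ExpressionMatrix(
        dataset_id=dataset_id or mtx_path.stem, cancer_type=cancer_type, values=frame
    )


def write_expression_mtx(
    expr: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(expr.values.to_numpy())
    scipy.io.mmwrite(str(mtx_path), sparse)
    Path(genes_path).write_text("\n".join(expr.genes) + "\n")
    Path(cells_path).write_text("\n".join(expr.cells) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


# -- per-dataset result tables --------------------------------------------


def write_result_tsv(
    comms: Sequence[PairCommunication], cancer_type: str, path: str | Path
) -> None:
    """Write a per-dataset pair table; s serialized to 12 significant digits
    so written tables round-trip the ratio faithfully."""
    rows = [
        {
            "dataset_id": p.dataset_id,
            "cancer_type": cancer_type,
            "ligand": p.ligand,
            "receptor": p.receptor,
            "n_senders": p.n_senders,
            "n_receivers": p.n_receivers,
            "x": p.x,
            "y": p.y,
            "s": f"{p.s:.12g}",
            "stable": p.stable,
        }
        for p in comms
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_result_tsv(path: str | Path) -> tuple[list[PairCommunication], dict[str, str]]:
    """Read a result TSV back; returns the rows and a dataset_id->cancer_type map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"result table not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: result table missing columns {missing}")
    comms = []
    meta: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        comms.append(
            PairCommunication(
                dataset_id=str(row.dataset_id),
                ligand=str(row.ligand),
                receptor=str(row.receptor),
                n_senders=int(row.n_senders),
                n_receivers=int(row.n_receivers),
                x=int(row.x),
                y=int(row.y),
                s=float(row.s),
                stable=bool(row.stable),
            )
        )
        meta[str(row.dataset_id)] = str(row.cancer_type)
    return comms, meta


# -- edge exports ----------------------------------------------------------


def write_sif(edges: Iterable[CommunicationEdge], path: str | Path) -> None:
    """SIF: sender TAB 'ligand|receptor' TAB receiver, one edge per line."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.sender_cell}\t{e.ligand}|{e.receptor}\t{e.receiver_cell}\n")


def write_graphml(edges: Iterable[CommunicationEdge], path: str | Path) -> None:
    graph = nx.MultiDiGraph()
    for e in edges:
        graph.add_edge(
            e.sender_cell, e.receiver_cell, ligand=e.ligand, receptor=e.receptor
        )
    nx.write_graphml(graph, str(path))


# -- small tables ----------------------------------------------------------


def read_metadata_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (dataset_id, cancer_type), with or without header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata table not found: {path}")
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str).dropna()
    meta: dict[str, str] = {}
    for ds, ct in frame.iloc[:, :2].itertuples(index=False):
        if str(ds).strip().lower() == "dataset_id":
            continue
        meta[str(ds).strip()] = str(ct).strip()
    return meta


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blanks and '#' comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    return [
        ln.strip().upper()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Pipeline settings; file values are overridden by CLI flags."""

    active_threshold: float = 1.0
    stable_threshold: float = 0.5
    edge_cap: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.active_threshold <= 0:
            raise ValueError("active_threshold must be positive")
        if self.stable_threshold <= 0:
            raise ValueError("stable_threshold must be positive")


def read_config(path: str | Path) -> RunConfig:
    """Flat ``key = value`` text config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    known = {f.name: f.type for f in dc_fields(RunConfig)}
    kwargs: dict[str, float | int] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key in ("active_threshold", "stable_threshold"):
            kwargs[key] = float(val.strip())
        elif key in ("edge_cap", "seed"):
            kwargs[key] = int(val.strip())
        elif key not in known:
            raise ValueError(f"unknown config key {key!r} in {path.name}")
    return RunConfig(**kwargs)
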