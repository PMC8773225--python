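"""Ligand-receptor pair catalog: loading, validation, annotation, queries.

The catalog is the fixed prior knowledge of the pipeline: which neuropeptide
(ligand) genes signal to which receptor genes.  Gene symbols are matched by
exact string comparison after upper-casing and whitespace trimming; no alias
or synonym resolution is attempted, because silently remapping symbols would
change communication counts in ways the user cannot audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel module label for genes with no functional-module annotation.
UNKNOWN_MODULE = "unknown module"


class CatalogError(ValueError):
    """Raised for schema problems or empty catalogs."""


def _normalize_symbol(symbol: str) -> str:
    """Upper-case and trim a gene symbol; reject empty or internal whitespace."""
    s = str(symbol).strip().upper()
    if not s or any(ch.isspace() for ch in s):
        raise CatalogError(f"invalid gene symbol: {symbol!r}")
    return s


@dataclass
class PairCatalog:
    """An ordered, deduplicated list of (ligand, receptor) gene pairs.

    A gene may occur in both columns (uniqueness is over pairs, not genes),
    and a self-pair (ligand == receptor) is allowed but logged.  Optional
    partial maps attach a neuropeptide-family name and a functional-module
    label to individual genes; genes absent from ``module_of`` fall in the
    sentinel :data:`UNKNOWN_MODULE`.
    """

    pairs: list[tuple[str, str]]
    family_of: dict[str, str] = field(default_factory=dict)
    module_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        cleaned: list[tuple[str, str]] = []
        for lig, rec in self.pairs:
            pair = (_normalize_symbol(lig), _normalize_symbol(rec))
            if pair in seen:
                logger.warning("duplicate pair %s-%s dropped", *pair)
                continue
            if pair[0] == pair[1]:
                logger.info("self-pair %s-%s kept", *pair)
            seen.add(pair)
            cleaned.append(pair)
        if not cleaned:
            raise CatalogError("catalog contains no valid ligand-receptor pairs")
        self.pairs = cleaned

    # -- queries -----------------------------------------------------------

    @property
    def ligands(self) -> list[str]:
        """Distinct ligand-column symbols, first-occurrence order."""
        return list(dict.fromkeys(l for l, _ in self.pairs))

    @property
    def receptors(self) -> list[str]:
        """Distinct receptor-column symbols, first-occurrence order."""
        return list(dict.fromkeys(r for _, r in self.pairs))

    @property
    def genes(self) -> list[str]:
        """Union of ligand and receptor symbols, first-occurrence order."""
        out: dict[str, None] = {}
        for lig, rec in self.pairs:
            out.setdefault(lig)
            out.setdefault(rec)
        return list(out)

    def receptors_of(self, ligand: str) -> list[str]:
        lig = _normalize_symbol(ligand)
        return [r for l, r in self.pairs if l == lig]

    def module_label(self, gene: str) -> str:
        return self.module_of.get(_normalize_symbol(gene), UNKNOWN_MODULE)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def read_pair_table(
    path: str | Path,
    ligand_column: str = "ligand",
    receptor_column: str = "receptor",
) -> PairCatalog:
    """Load a ligand-receptor pair catalog from a delimited text table.

    The file must have a header row containing both named columns; the
    delimiter (tab or comma) is sniffed by pandas.  Duplicate pairs are
    dropped with a warning, keeping first-occurrence order.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    CatalogError
        If a named column is missing or no valid rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair table not found: {path}")
    table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in (ligand_column, receptor_column):
        if col not in table.columns:
            raise CatalogError(
                f"column {col!r} not in {path.name}; available: {list(table.columns)}"
            )
    rows = table[[ligand_column, receptor_column]].dropna()
    pairs = [(str(l), str(r)) for l, r in rows.itertuples(index=False)]
    if not pairs:
        raise CatalogError(f"no valid ligand-receptor rows in {path}")
    return PairCatalog(pairs=pairs)


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read a headerless or headered two-column TSV mapping gene -> label.

    A header row is detected by the literal first-column value ``gene``.
    Later rows override earlier ones for the same (case-normalized) gene.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation table not found: {path}")
    table = pd.read_csv(path, sep="\t", header=None, dtype=str).dropna()
    if table.shape[1] < 2:
        raise CatalogError(f"annotation table {path.name} needs two columns")
    mapping: dict[str, str] = {}
    for gene, label in table.iloc[:, :2].itertuples(index=False):
        if str(gene).strip().lower() == "gene":
            continue  # header row
        mapping[_normalize_symbol(gene)] = str(label).strip()
    return mapping


def write_pair_table(catalog: PairCatalog, path: str | Path) -> None:
    """Write the catalog as a two-column TSV that round-trips through
    :func:`read_pair_table` exactly (pairs and order)."""
    frame = pd.DataFrame(catalog.pairs, columns=["ligand", "receptor"])
    frame.to_csv(path, sep="\t", index=False)


def catalog_stats(catalog: PairCatalog) -> dict[str, int]:
    """Summary counts: pairs, unique genes, per-column symbols, annotations."""
    return {
        "n_pairs": len(catalog.pairs),
        "n_unique_genes": len(catalog.genes),
        "n_ligands": len(catalog.ligands),
        "n_receptors": len(catalog.receptors),
        "n_families": len(set(catalog.family_of.values())),
        "n_modules": len(set(catalog.module_of.values())),
    }


def family_gene_counts(
    family_of: Mapping[str, str], genes: Iterable[str] | None = None
) -> dict[str, int]:
    """Count annotated genes per family, optionally restricted to *genes*."""
    pool = None if genes is None else {_normalize_symbol(g) for g in genes}
    counts: dict[str, int] = {}
    for gene, fam in family_of.items():
        if pool is not None and gene not in pool:
            continue
        counts[fam] = counts.get(fam, 0) + 1
    return counts
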