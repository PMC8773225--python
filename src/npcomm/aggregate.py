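"""Cross-dataset aggregation: stable pairs/genes, family and module matrices,
and hypergeometric enrichment of the stable gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .catalog import UNKNOWN_MODULE, _normalize_symbol
from .comm import PairCommunication

logger = logging.getLogger(__name__)


@dataclass
class StablePairRecord:
    ligand: str
    receptor: str
    dataset_ids: list[str]
    total_x: int


@dataclass
class StabilitySummary:
    """Roll-up of stable communications across datasets.

    ``stable_pairs`` is keyed on (ligand, receptor) regardless of dataset;
    each record carries its supporting datasets and summed communication
    count.  Genes are partitioned by the column they appear in; a gene can
    hold both roles and is then reported in both sets (and flagged).
    """

    stable_pairs: dict[tuple[str, str], StablePairRecord] = field(default_factory=dict)
    ligand_genes: set[str] = field(default_factory=set)
    receptor_genes: set[str] = field(default_factory=set)
    n_datasets_retained: int = 0
    cancer_types_covered: set[str] = field(default_factory=set)

    @property
    def stable_genes(self) -> set[str]:
        return self.ligand_genes | self.receptor_genes

    @property
    def dual_role_genes(self) -> set[str]:
        """Genes appearing as both ligand and receptor among stable pairs."""
        return self.ligand_genes & self.receptor_genes

    @property
    def total_stable_x(self) -> int:
        return sum(rec.total_x for rec in self.stable_pairs.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ligand": rec.ligand,
                "receptor": rec.receptor,
                "n_datasets": len(rec.dataset_ids),
                "dataset_ids": ",".join(rec.dataset_ids),
                "total_x": rec.total_x,
            }
            for rec in self.stable_pairs.values()
        ]
        return pd.DataFrame(
            rows, columns=["ligand", "receptor", "n_datasets", "dataset_ids", "total_x"]
        )


def combine_datasets(
    results: Mapping[str, Sequence[PairCommunication]],
    metadata: Mapping[str, str],
) -> StabilitySummary:
    """Merge per-dataset pair tables into a cross-dataset stability summary.

    *results* maps dataset_id -> PairCommunication list; *metadata* maps
    dataset_id -> cancer type and must cover every dataset in *results*.
    """
    for ds in results:
        if ds not in metadata:
            raise KeyError(f"dataset {ds!r} has no cancer-type metadata")
    summary = StabilitySummary()
    for ds, comms in results.items():
        stable = [p for p in comms if p.stable]
        if not stable:
            continue
        summary.n_datasets_retained += 1
        summary.cancer_types_covered.add(metadata[ds])
        for p in stable:
            key = (p.ligand, p.receptor)
            rec = summary.stable_pairs.get(key)
            if rec is None:
                rec = StablePairRecord(p.ligand, p.receptor, [], 0)
                summary.stable_pairs[key] = rec
            rec.dataset_ids.append(ds)
            rec.total_x += p.x
            summary.ligand_genes.add(p.ligand)
            summary.receptor_genes.add(p.receptor)
    logger.info(
        "combined %d datasets: %d retained, %d unique stable pairs, %d genes "
        "(%d ligand-role, %d receptor-role, %d dual-role), %d cancer types",
        len(results),
        summary.n_datasets_retained,
        len(summary.stable_pairs),
        len(summary.stable_genes),
        len(summary.ligand_genes),
        len(summary.receptor_genes),
        len(summary.dual_role_genes),
        len(summary.cancer_types_covered),
    )
    return summary


def family_matrix(
    results: Mapping[str, Sequence[PairCommunication]],
    family_of: Mapping[str, str],
    metadata: Mapping[str, str],
    min_genes: int = 3,
    statistic: str = "sum_x",
) -> pd.DataFrame:
    """Cancer type x neuropeptide family matrix.

    Families are kept only when they annotate at least *min_genes* ligand
    genes of the catalog annotation map.  ``statistic`` is ``sum_x`` (total
    communications initiated by the family's ligands) or
    ``unique_neuropeptides`` (distinct active ligand genes).  Unannotated
    ligands are excluded and logged.
    """
    if statistic not in ("sum_x", "unique_neuropeptides"):
        raise ValueError(f"unknown statistic {statistic!r}")
    fam_norm = {_normalize_symbol(g): f for g, f in family_of.items()}
    sizes: dict[str, int] = {}
    for fam in fam_norm.values():
        sizes[fam] = sizes.get(fam, 0) + 1
    kept = {fam for fam, n in sizes.items() if n >= min_genes}
    dropped = set(sizes) - kept
    if dropped:
        logger.info("families below min_genes=%d dropped: %s", min_genes, sorted(dropped))

    cells: dict[tuple[str, str], float] = {}
    seen_genes: dict[tuple[str, str], set[str]] = {}
    n_unannotated = 0
    for ds, comms in results.items():
        ctype = metadata[ds]
        for p in comms:
            fam = fam_norm.get(p.ligand)
            if fam is None:
                n_unannotated += 1
                continue
            if fam not in kept:
                continue
            key = (ctype, fam)
            if statistic == "sum_x":
                cells[key] = cells.get(key, 0) + p.x
            else:
                seen_genes.setdefault(key, set()).add(p.ligand)
    if n_unannotated:
        logger.info("%d result rows with unannotated ligand excluded", n_unannotated)
    if statistic == "unique_neuropeptides":
        cells = {k: len(v) for k, v in seen_genes.items()}
    return _cells_to_frame(cells, sorted(kept))


def module_matrix(
    results: Mapping[str, Sequence[PairCommunication]],
    module_of: Mapping[str, str],
    metadata: Mapping[str, str],
    statistic: str = "sum_x",
) -> pd.DataFrame:
    """Cancer type x functional-module matrix.

    A result row counts toward module m only when BOTH its ligand and its
    receptor carry label m (modules are fully connected subnetworks);
    otherwise it falls in the trailing "unknown module" column.
    """
    if statistic not in ("sum_x", "unique_neuropeptides"):
        raise ValueError(f"unknown statistic {statistic!r}")
    mod_norm = {_normalize_symbol(g): m for g, m in module_of.items()}
    cells: dict[tuple[str, str], float] = {}
    seen_genes: dict[tuple[str, str], set[str]] = {}
    modules_seen: set[str] = set()
    for ds, comms in results.items():
        ctype = metadata[ds]
        for p in comms:
            m_l = mod_norm.get(p.ligand)
            m_r = mod_norm.get(p.receptor)
            mod = m_l if (m_l is not None and m_l == m_r) else UNKNOWN_MODULE
            modules_seen.add(mod)
            key = (ctype, mod)
            if statistic == "sum_x":
                cells[key] = cells.get(key, 0) + p.x
            else:
                seen_genes.setdefault(key, set()).add(p.ligand)
    if statistic == "unique_neuropeptides":
        cells = {k: len(v) for k, v in seen_genes.items()}
    ordered = sorted(m for m in modules_seen if m != UNKNOWN_MODULE)
    ordered.append(UNKNOWN_MODULE)  # trailing column, present even if empty
    return _cells_to_frame(cells, ordered)


def _cells_to_frame(
    cells: Mapping[tuple[str, str], float], columns: list[str]
) -> pd.DataFrame:
    rows = sorted({ct for ct, _ in cells})
    frame = pd.DataFrame(0, index=rows, columns=columns, dtype=int)
    for (ct, col), val in cells.items():
        if col in frame.columns:
            frame.loc[ct, col] = int(val)
    frame.index.name = "cancer_type"
    return frame


@dataclass
class EnrichmentResult:
    """One hypergeometric overlap test of a query gene set against a
    reference set within a finite gene universe."""

    reference_name: str
    k: int  # overlap
    K: int  # reference genes in universe
    n: int  # query genes in universe
    N: int  # universe size
    p_value: float
    adjusted_p: float | None = None


def hypergeom_enrichment(
    query: Iterable[str],
    references: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of *query* in each reference set.

    p = P[X >= k] for X ~ Hypergeom(N, K, n), the observed overlap included
    (equivalent to R's phyper(k-1, K, N-K, n, lower.tail=FALSE)).  Reference
    sets are intersected with the universe before testing; the query must be
    a subset of the universe.  Benjamini-Hochberg adjustment is applied
    across the tested reference sets.
    """
    uni = {_normalize_symbol(g) for g in universe}
    qry = {_normalize_symbol(g) for g in query}
    if not uni:
        raise ValueError("universe is empty")
    if not qry:
        raise ValueError("query gene set is empty")
    if not qry <= uni:
        raise ValueError(f"query genes outside universe: {sorted(qry - uni)[:5]}")
    out: list[EnrichmentResult] = []
    for name, ref in references.items():
        ref_in = {_normalize_symbol(g) for g in ref} & uni
        k = len(qry & ref_in)
        K, n, N = len(ref_in), len(qry), len(uni)
        p = float(hypergeom.sf(k - 1, N, K, n))
        out.append(EnrichmentResult(name, k, K, n, N, min(p, 1.0)))
    if out:
        adj = multipletests([r.p_value for r in out], method="fdr_bh")[1]
        for r, a in zip(out, adj):
            r.adjusted_p = float(a)
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "reference": r.reference_name,
                "overlap_k": r.k,
                "reference_K": r.K,
                "query_n": r.n,
                "universe_N": r.N,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )
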