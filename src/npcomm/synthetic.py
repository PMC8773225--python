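"""Synthetic expression matrices with planted per-gene activity fractions.

Real inputs to this pipeline are uniformly processed cancer scRNA-seq
matrices of log2 TPM values.  Because every downstream statistic depends on
the data only through the boolean "active at threshold" calls, the
generator plants activity exactly: each gene is on in each cell with a
known probability, on-values are drawn from a range at or above the active
threshold and off-values from a range strictly below it, so the planted
on/off indicator is recovered bit-for-bit by thresholding.  Distributional
realism (UMI counts, library size, dropout mechanics) is deliberately not
simulated — it would not change any downstream number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import PairCatalog
from .comm import ExpressionMatrix


class SpecError(ValueError):
    """Raised for invalid synthetic-matrix specifications."""


@dataclass
class GeneSpec:
    """Planted behaviour of one gene: active with probability ``p_on`` per
    cell; active values uniform in ``on_range``, inactive in ``off_range``.
    ``latent`` optionally names a shared latent group for co-expression."""

    gene: str
    p_on: float
    on_range: tuple[float, float] = (1.0, 10.0)
    off_range: tuple[float, float] = (0.0, 0.999)
    latent: str | None = None


@dataclass
class SyntheticSpec:
    """Full specification of one synthetic dataset.

    ``latent_mix`` in [0, 1] is the co-expression knob: with that
    probability a cell's activity draw for a gene reuses the cell's shared
    uniform for the gene's latent group instead of an independent one.  The
    marginal activity frequency stays ``p_on``; genes sharing a latent group
    become positively correlated.  Defaults to 0 (independence).
    """

    n_cells: int
    gene_specs: list[GeneSpec]
    active_threshold: float = 1.0
    seed: int = 0
    latent_mix: float = 0.0
    dataset_id: str = "synthetic"
    cancer_type: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise SpecError(f"n_cells must be >= 0, got {self.n_cells}")
        if not 0.0 <= self.latent_mix <= 1.0:
            raise SpecError(f"latent_mix out of [0,1]: {self.latent_mix}")
        for gs in self.gene_specs:
            if not 0.0 <= gs.p_on <= 1.0:
                raise SpecError(f"{gs.gene}: p_on out of [0,1]: {gs.p_on}")
            if gs.on_range[0] < self.active_threshold or gs.on_range[1] < gs.on_range[0]:
                raise SpecError(
                    f"{gs.gene}: on_range {gs.on_range} must lie at/above "
                    f"threshold {self.active_threshold}"
                )
            if gs.off_range[0] < 0 or gs.off_range[1] >= self.active_threshold:
                raise SpecError(
                    f"{gs.gene}: off_range {gs.off_range} must lie in "
                    f"[0, {self.active_threshold})"
                )


def generate_dataset(spec: SyntheticSpec) -> ExpressionMatrix:
    """Draw one expression matrix from a :class:`SyntheticSpec`.

    Identical spec (including seed) gives an identical matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    cells = [f"cell_{i + 1}" for i in range(n)]
    latent_groups = {gs.latent for gs in spec.gene_specs if gs.latent is not None}
    shared = {g: rng.random(n) for g in sorted(latent_groups)}
    rows = {}
    for gs in spec.gene_specs:
        u = rng.random(n)
        if gs.latent is not None and spec.latent_mix > 0:
            use_shared = rng.random(n) < spec.latent_mix
            u = np.where(use_shared, shared[gs.latent], u)
        on = u < gs.p_on
        vals = np.where(
            on,
            rng.uniform(gs.on_range[0], gs.on_range[1], size=n),
            rng.uniform(gs.off_range[0], gs.off_range[1], size=n),
        )
        # uniform(a, b) can return b==high only at a==b; clip the off side
        # defensively so planted-off never touches the threshold
        vals = np.where(on, np.maximum(vals, gs.on_range[0]), np.minimum(vals, gs.off_range[1]))
        rows[gs.gene] = vals
    values = pd.DataFrame(rows, index=cells).T
    values.columns = cells
    return ExpressionMatrix(
        dataset_id=spec.dataset_id, cancer_type=spec.cancer_type, values=values
    )


def make_cervix_fixture() -> ExpressionMatrix:
    """Deterministic 42-cell cervix-cancer-cell-line-like fixture.

    NXPH1 is active in exactly 41 of the 42 cells, NRXN1 in all 42, and
    NRXN3 in 30 cells (an arbitrary but fixed strict subset of NRXN1's
    receivers).  The NXPH1->NRXN1 pair then realizes 41 x 42 = 1722 of the
    42^2 = 1764 conceivable ordered cell pairs, a stable-communication ratio
    of 1722/1764 = 0.97619 (97.6%), and the receiver union over
    {NRXN1, NRXN3} adds nothing.  Only the 41/42 counts and the union are
    constrained by the reported percentages; the NRXN3 choice of 30 cells
    is this fixture's own convention.
    """
    n = 42
    cells = [f"cc_{i + 1}" for i in range(n)]
    nxph1 = np.full(n, 2.0)
    nxph1[-1] = 0.0  # the single cell not expressing the ligand
    nrxn1 = np.full(n, 3.0)
    nrxn3 = np.zeros(n)
    nrxn3[:30] = 1.5
    decoy = np.zeros(n)  # never active; must vanish from all outputs
    values = pd.DataFrame(
        {"NXPH1": nxph1, "NRXN1": nrxn1, "NRXN3": nrxn3, "DECOYL1": decoy},
        index=cells,
    ).T
    values.columns = cells
    return ExpressionMatrix(
        dataset_id="cervix_fixture", cancer_type="cervix", values=values
    )


def cervix_fixture_catalog() -> PairCatalog:
    """The two catalog pairs exercised by :func:`make_cervix_fixture`,
    plus a decoy pair that never communicates."""
    return PairCatalog(
        pairs=[("NXPH1", "NRXN1"), ("NXPH1", "NRXN3"), ("DECOYL1", "DECOYR1")]
    )


@dataclass
class RecoverySuite:
    """A planted-signal dataset bundled with its catalog and ground truth."""

    expr: ExpressionMatrix
    catalog: PairCatalog
    expected_stable: set[tuple[str, str]]
    p_on: dict[str, float] = field(default_factory=dict)


#: Planted activity fractions for the recovery suite: expected ratios
#: s = p_l * p_r of ~0.9, 0.64, 0.36 and 0.04 straddle the 0.5 stable cut.
_RECOVERY_PAIRS: list[tuple[str, str, float]] = [
    ("LIGHI1", "RECHI1", 0.95),
    ("LIGMID1", "RECMID1", 0.80),
    ("LIGLOW1", "RECLOW1", 0.60),
    ("LIGRARE1", "RECRARE1", 0.20),
]


def make_recovery_suite(n_cells: int = 1000, seed: int = 0) -> RecoverySuite:
    """Planted-stable-pair recovery benchmark.

    Four ligand-receptor pairs with per-gene activity fractions 0.95, 0.8,
    0.6 and 0.2 (expected ratios ~0.9025, 0.64, 0.36, 0.04) plus two decoy
    genes that are never active.  The ground truth is the set of pairs with
    expected ratio above 0.5; at n_cells >= 100 the realized ratios
    concentrate far from the boundary.
    """
    if n_cells < 100:
        raise SpecError(f"recovery suite needs n_cells >= 100, got {n_cells}")
    gene_specs = []
    p_on: dict[str, float] = {}
    for lig, rec, p in _RECOVERY_PAIRS:
        gene_specs.append(GeneSpec(gene=lig, p_on=p))
        gene_specs.append(GeneSpec(gene=rec, p_on=p))
        p_on[lig] = p_on[rec] = p
    gene_specs.append(GeneSpec(gene="DECOYL1", p_on=0.0))
    gene_specs.append(GeneSpec(gene="DECOYR1", p_on=0.0))
    spec = SyntheticSpec(
        n_cells=n_cells,
        gene_specs=gene_specs,
        seed=seed,
        dataset_id=f"recovery_{n_cells}_{seed}",
        cancer_type="synthetic",
    )
    catalog = PairCatalog(
        pairs=[(l, r) for l, r, _ in _RECOVERY_PAIRS] + [("DECOYL1", "DECOYR1")]
    )
    expected = {(l, r) for l, r, p in _RECOVERY_PAIRS if p * p > 0.5}
    return RecoverySuite(
        expr=generate_dataset(spec), catalog=catalog, expected_stable=expected, p_on=p_on
    )


def make_synthetic_catalog(seed: int = 20211222) -> PairCatalog:
    """SYNTHETIC stand-in for the curated neuropeptide-receptor catalog.

    The curated catalog itself is not redistributed here; this constructs a
    synthetic table with the same reported shape: 260 unique pairs over 226
    genes, 93 distinct ligand-column symbols and 133 distinct
    receptor-column symbols (the two columns are disjoint), four functional
    modules of >= 10 genes with module "2" holding 39 genes (15 neuropeptides
    + 24 receptors) and module "4" holding 17 genes (6 neuropeptides), and 15
    neuropeptide families of >= 3 genes, the largest with 7.  Gene symbols
    other than the NXPH1/NRXN1/NRXN3 trio are synthetic tokens.
    """
    ligands = ["NXPH1"] + [f"SYNPEP{i:03d}" for i in range(2, 94)]
    receptors = ["NRXN1", "NRXN3"] + [f"SYNREC{i:03d}" for i in range(3, 134)]
    assert len(ligands) == 93 and len(receptors) == 133

    pairs: list[tuple[str, str]] = [("NXPH1", "NRXN1"), ("NXPH1", "NRXN3")]
    seen = set(pairs)
    # cover every ligand and receptor at least once
    for i, rec in enumerate(receptors):
        pair = (ligands[i % 93], rec)
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    for j, lig in enumerate(ligands):
        pair = (lig, receptors[j % 133])
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    rng = np.random.default_rng(seed)
    while len(pairs) < 260:
        pair = (
            ligands[int(rng.integers(93))],
            receptors[int(rng.integers(133))],
        )
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)

    module_of: dict[str, str] = {}
    for g in ligands[:15] + receptors[:24]:  # 39 genes, 15 peptides + 24 receptors
        module_of[g] = "2"
    for g in ligands[15:21] + receptors[24:35]:  # 17 genes, 6 peptides
        module_of[g] = "4"
    for g in ligands[21:25] + receptors[35:43]:  # 12 genes
        module_of[g] = "1"
    for g in ligands[25:28] + receptors[43:50]:  # 10 genes
        module_of[g] = "3"

    family_of: dict[str, str] = {}
    for g in ligands[1:8]:  # largest family, 7 neuropeptides
        family_of[g] = "insulin"
    idx = 8
    for fam in range(2, 16):  # 14 more families of 3
        for g in ligands[idx : idx + 3]:
            family_of[g] = f"family_{fam:02d}"
        idx += 3

    return PairCatalog(pairs=pairs, family_of=family_of, module_of=module_of)


# -- plain-text spec files -------------------------------------------------


def read_spec_file(path: str | Path) -> SyntheticSpec:
    """Parse a flat key-value spec file with a trailing gene table.

    Format::

        n_cells = 500
        seed = 7
        active_threshold = 1.0
        latent_mix = 0.0
        [genes]
        gene    p_on    on_low  on_high off_low off_high
        LIGHI1  0.95    1.0     10.0    0.0     0.999
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spec file not found: {path}")
    scalars: dict[str, str] = {}
    gene_rows: list[list[str]] = []
    in_genes = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "[genes]":
            in_genes = True
            continue
        if in_genes:
            fields = line.split()
            if fields[0].lower() == "gene":
                continue  # header
            if len(fields) < 2:
                raise SpecError(f"gene row needs at least gene and p_on: {line!r}")
            gene_rows.append(fields)
        else:
            if "=" not in line:
                raise SpecError(f"expected key = value, got {line!r}")
            key, _, val = line.partition("=")
            scalars[key.strip()] = val.strip()
    try:
        n_cells = int(scalars["n_cells"])
    except KeyError:
        raise SpecError("spec file missing required key 'n_cells'") from None
    threshold = float(scalars.get("active_threshold", 1.0))
    gene_specs = []
    for fields in gene_rows:
        on_range = (
            (float(fields[2]), float(fields[3])) if len(fields) >= 4 else (threshold, 10.0)
        )
        off_range = (
            (float(fields[4]), float(fields[5])) if len(fields) >= 6 else (0.0, 0.999)
        )
        gene_specs.append(
            GeneSpec(gene=fields[0], p_on=float(fields[1]), on_range=on_range, off_range=off_range)
        )
    return SyntheticSpec(
        n_cells=n_cells,
        gene_specs=gene_specs,
        active_threshold=threshold,
        seed=int(scalars.get("seed", 0)),
        latent_mix=float(scalars.get("latent_mix", 0.0)),
        dataset_id=scalars.get("dataset_id", "synthetic"),
        cancer_type=scalars.get("cancer_type", "synthetic"),
    )
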