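# Methods

## Model and assumptions

The pipeline treats one single-cell dataset as a gene × cell matrix of
non-negative, finite log2-transformed TPM values. Values are consumed as
given: no re-normalization, imputation or dropout correction is applied.
Restricting attention to *actively expressed* genes — log2 TPM at or above a
threshold — is itself the dropout-handling strategy: a gene clearly above
background in a cell is trusted, everything else is ignored.

For a catalog pair (ligand L, receptor R) in a dataset of `y` cells:

- senders = cells with L active; receivers = cells with R active;
- the communication count `x = n_senders × n_receivers` counts **ordered**
  (sender, receiver) cell pairs, **including** sender == receiver. A pair of
  cells each expressing both genes therefore contributes two directed edges
  plus the two self-edges. The product form means counting is linear in the
  number of cells; no cell × cell structure is ever built.
- the stable-communication ratio is `s = x / y²`, the fraction of all
  conceivable ordered cell pairs the pair realizes; `0 ≤ s ≤ 1` with `s = 1`
  exactly when both genes are active in every cell.
- the pair is **stable** in the dataset when `s > 0.5` (strict inequality:
  "more than half"). The boundary case s = 0.5 is therefore *not* stable;
  the comparison threshold is a parameter for users who want `≥` or a
  different cut.

Conventions worth making explicit:

- **Inclusive activity boundary**: a value exactly equal to the threshold is
  active.
- **Self-communication included in both x and y²**: the denominator is the
  full y × y grid including the diagonal, so numerator and denominator count
  the same universe of ordered pairs. The bundled 42-cell fixture
  (41 × 42 = 1722 of 42² = 1764 links, 97.6%) is consistent with this
  convention; if a dataset's provenance used a diagonal-excluded convention
  its ratios would differ by O(1/y).
- **Multi-receptor unions** (`ligand_union_communications`) deduplicate
  receiver cells across receptors, so x_union counts unique ordered pairs
  reachable via *any* listed receptor: max per-receptor x ≤ x_union ≤ sum of
  per-receptor x.
- Gene symbols are matched exactly after upper-casing and trimming; no alias
  resolution. Duplicate gene rows in a matrix are collapsed by per-cell max
  (active if any duplicate row is active), logged. Catalog genes absent from
  a matrix are reported as *not measured* rather than silently never-active.
- Pairs with x = 0 are omitted from per-dataset outputs (totals go to the
  log); a dataset where no catalog pair communicates yields an empty table
  and is effectively eliminated from downstream aggregation.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `active_threshold` | 1.0 | log2 TPM | minimum value for a gene to count as actively expressed in a cell |
| `stable_threshold` | 0.5 | ratio | strict lower bound on s for the stable-pair call |
| `min_genes` (family matrix) | 3 | genes | a neuropeptide family must annotate at least this many ligand genes to get a column |
| `edge_cap` / `seed` | 0 / 0 | edges | max exported edges per dataset; seed for the uniform edge sample |

## Aggregation

`combine_datasets` keys stable pairs on (ligand, receptor) regardless of
dataset, accumulating supporting dataset ids and summed x. Genes are
partitioned by role (column of appearance); a gene appearing in both columns
is reported in both role sets and flagged, rather than forced into one role.

Group matrices are cancer type × group with either summed communication
counts or unique active ligand counts. Family columns require `min_genes`
annotated neuropeptides. Module assignment is deliberately strict: a result
row counts toward module m only when **both** endpoints carry label m —
modules are defined as fully connected subnetworks, so a half-in edge is not
module evidence — and otherwise falls in the trailing "unknown module"
column, which is always present.

Enrichment uses the upper-tail hypergeometric probability **including** the
observed overlap, P[X ≥ k] for X ~ Hypergeom(N, K, n), computed as
`scipy.stats.hypergeom.sf(k-1, N, K, n)` (the same tail as R's
`phyper(k-1, K, N-K, n, lower.tail=FALSE)`), with Benjamini–Hochberg
adjustment across the reference sets tested in one call. The default
universe is explicit and user-supplied (typically the catalog gene set
intersected with the reference source); there is no hidden genome-wide
universe.

## Synthetic data

The generator plants per-gene activity: each gene is on in each cell
independently with probability `p_on`; on-values are uniform in `[1, 10]`
and off-values in `[0, 0.999]` (log2 TPM units), so thresholding at 1.0
recovers the planted indicator bit-for-bit and every downstream count is
exact by construction. Values are uniform rather than a fitted TPM
distribution on purpose: the pipeline only thresholds values, so
distributional realism would change nothing downstream. A `latent_mix` knob
mixes in a shared per-cell uniform for genes tagged with the same latent
group, producing positive co-expression while preserving marginal
frequencies; it defaults to 0 (independence), matching the absence of any
co-expression structure in the model. The generator does **not** emulate UMI
counting, library-size variation, batch effects or realistic dropout
mechanics — so passing tests demonstrate the correctness of the counting and
aggregation machinery on data satisfying the model's assumptions, not
robustness to those real-data artifacts.

Under independence a pair's expected ratio is E[s] ≈ p_L · p_R, with
delta-method standard error sqrt(p_R²·p_L(1−p_L)/y + p_L²·p_R(1−p_R)/y);
tests use a 4-SE band. The recovery suite plants pairs at p = 0.95, 0.8,
0.6, 0.2 (expected s ≈ 0.90, 0.64, 0.36, 0.04), bracketing the 0.5 cut from
both sides far enough that misclassification probability is negligible for
y ≥ a few hundred; tests and the acceptance script use y = 1000.

Two deterministic fixtures are bundled:

- `make_cervix_fixture`: 42 cells; NXPH1 active in 41, NRXN1 in all 42,
  NRXN3 in 30 (an arbitrary but fixed strict subset of NRXN1's receivers),
  plus a never-active decoy. The 41/42 sender/receiver counts are the unique
  integers reproducing a communication count of 1722 at 97.6% of all links;
  the NRXN3 count of 30 is this fixture's own choice, constrained only to
  keep the receptor union at 42 cells.
- `make_synthetic_catalog`: a synthetic stand-in for the curated 260-pair
  neuropeptide–receptor table, which is not redistributed. It reproduces the
  reported shape — 260 pairs over 226 genes, 93 ligand-column and 133
  receptor-column symbols (necessarily disjoint columns, since 93 + 133 =
  226), four functional modules of ≥ 10 genes with module 2 at 39 genes
  (15 peptides + 24 receptors) and module 4 at 17 genes, and 15 families of
  ≥ 3 neuropeptides, the largest with 7 — with synthetic gene symbols apart
  from the NXPH1/NRXN1/NRXN3 trio shared with the fixture. Analyses of this
  stand-in validate the machinery, not the biology of the curated table.

## Numerical and design choices

- s is an exact integer ratio evaluated in floating point; TSVs serialize it
  to 12 significant digits so written tables round-trip the value, and
  percentages in logs round half-up to one decimal (0.97619 → "97.6%").
- Edge export samples uniformly **without replacement** over the global edge
  index space (pairs laid out consecutively, sender-major within a pair) by
  rejection sampling of indices, so sampling is deterministic given a seed
  and never materializes the edge set.
- `combine_datasets` requires cancer-type metadata for every dataset id and
  fails loudly on a missing id rather than inventing an "unknown" type.
- The CLI processes matrices one at a time and holds at most one expression
  matrix in memory.

## Known limitations

- Corpus-scale results (multi-dataset totals over tens of millions of
  communications, the specific 26-pair/39-gene stable network, and any
  mutation/survival statistics) depend on the original 72-dataset corpus and
  external portals; the package recomputes the per-dataset statistics and
  worked examples, not the corpus.
- Stability at exactly the threshold is a convention (strict `>`); datasets
  with ratios near 0.5 are sensitive to it.
- No alias/synonym handling means symbol-convention mismatches between a
  catalog and a matrix silently reduce counts — mitigated by the explicit
  missing-gene report.
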