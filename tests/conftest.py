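import numpy as np
import pandas as pd
import pytest

from npcomm import ActiveMask, ExpressionMatrix


@pytest.fixture
def toy_mask():
    """5-cell mask: ligand LIG active in cells 1-2, receptor REC in 2-4."""
    active = pd.DataFrame(
        {
            f"c{i}": [lig, rec]
            for i, (lig, rec) in enumerate(
                [(True, False), (True, True), (False, True), (False, True), (False, False)],
                start=1,
            )
        },
        index=["LIG", "REC"],
    )
    return ActiveMask(active=active)


@pytest.fixture
def rng():
    return np.random.default_rng(20211222)


def random_expression(rng, n_genes, n_cells, tag="rnd"):
    """Random small matrix with values straddling the 1.0 threshold."""
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"c{j}" for j in range(n_cells)]
    vals = rng.uniform(0, 2, size=(n_genes, n_cells))
    return ExpressionMatrix(
        dataset_id=tag,
        cancer_type="test",
        values=pd.DataFrame(vals, index=genes, columns=cells),
    )


def brute_force_x(mask: ActiveMask, ligand: str, receptor: str) -> int:
    """Oracle: enumerate every ordered (sender, receiver) cell pair."""
    lig = mask.gene_vector(ligand)
    rec = mask.gene_vector(receptor)
    count = 0
    for i in range(mask.n_cells):
        for j in range(mask.n_cells):
            if lig[i] and rec[j]:
                count += 1
    return count
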