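import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcomm import (
    ExpressionMatrix,
    PairCatalog,
    call_active,
    count_pair_communications,
    enumerate_edges,
    format_percent,
    is_stable,
    ligand_union_communications,
    run_dataset,
    stability_ratio,
    total_possible,
)
from npcomm.comm import ExpressionError

from conftest import brute_force_x, random_expression


class TestCallActive:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, True), (0.999, False), (0.0, False), (5.2, True)],
    )
    def test_threshold_boundary_inclusive(self, value, expected):
        expr = ExpressionMatrix(
            "d", "t", pd.DataFrame({"c1": [value]}, index=["G"])
        )
        mask, _ = call_active(expr)
        assert bool(mask.active.loc["G", "c1"]) is expected

    def test_all_zero_matrix(self):
        expr = ExpressionMatrix(
            "d", "t", pd.DataFrame(np.zeros((3, 4)), index=list("ABC"))
        )
        mask, _ = call_active(expr)
        assert not mask.active.to_numpy().any()

    def test_missing_catalog_genes_reported(self):
        expr = ExpressionMatrix("d", "t", pd.DataFrame({"c1": [2.0]}, index=["A"]))
        _, missing = call_active(expr, catalog=PairCatalog(pairs=[("A", "B")]))
        assert missing == ["B"]

    def test_negative_values_rejected(self):
        with pytest.raises(ExpressionError, match="negative"):
            ExpressionMatrix("d", "t", pd.DataFrame({"c1": [-0.5]}, index=["G"]))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ExpressionError, match="non-finite"):
            ExpressionMatrix("d", "t", pd.DataFrame({"c1": [np.nan]}, index=["G"]))

    def test_duplicate_gene_rows_max_collapsed(self):
        values = pd.DataFrame(
            [[0.2, 1.5], [1.2, 0.0]], index=["G", "g"], columns=["c1", "c2"]
        )
        mask, _ = call_active(ExpressionMatrix("d", "t", values))
        assert mask.active.loc["G"].tolist() == [True, True]


class TestPairCounting:
    def test_toy_counts(self, toy_mask):
        assert count_pair_communications(toy_mask, "LIG", "REC") == (2, 3, 6)

    def test_absent_ligand_zero(self, toy_mask):
        n_s, n_r, x = count_pair_communications(toy_mask, "GHOST", "REC")
        assert (n_s, x) == (0, 0) and n_r == 3

    def test_all_active_square(self):
        active = pd.DataFrame(
            np.ones((2, 42), dtype=bool),
            index=["L", "R"],
            columns=[f"c{i}" for i in range(42)],
        )
        from npcomm import ActiveMask

        assert count_pair_communications(ActiveMask(active=active), "L", "R") == (
            42,
            42,
            1764,
        )

    def test_matches_brute_force_on_random_matrices(self, rng):
        """Product formula equals ordered-cell-pair enumeration, 200 matrices."""
        for trial in range(200):
            n_genes = int(rng.integers(2, 21))
            n_cells = int(rng.integers(1, 101))
            expr = random_expression(rng, n_genes, n_cells, tag=f"rnd{trial}")
            mask, _ = call_active(expr)
            genes = expr.genes
            lig, rec = rng.choice(genes, size=2, replace=True)
            n_s, n_r, x = count_pair_communications(mask, lig, rec)
            assert x == brute_force_x(mask, lig, rec)
            assert x == n_s * n_r

    def test_threshold_monotonicity(self, rng):
        """Lowering the active threshold never loses senders/receivers/x."""
        expr = random_expression(rng, 6, 40)
        lo, _ = call_active(expr, 0.5)
        hi, _ = call_active(expr, 1.5)
        for lig in expr.genes:
            for rec in expr.genes:
                s_lo = count_pair_communications(lo, lig, rec)
                s_hi = count_pair_communications(hi, lig, rec)
                assert all(a >= b for a, b in zip(s_lo, s_hi))


class TestRatio:
    def test_total_possible_worked_example(self):
        assert total_possible(4043) == 16_345_849

    @pytest.mark.parametrize("y,expected", [(0, 0), (1, 1), (42, 1764)])
    def test_total_possible_small(self, y, expected):
        assert total_possible(y) == expected

    def test_oligodendroglioma_ratio_rounds_to_61_percent(self):
        s = stability_ratio(9_928_473, 4043)
        assert round(s * 100) == 61

    @pytest.mark.parametrize("x,y,expected", [(0, 100, 0.0), (10_000, 100, 1.0)])
    def test_ratio_extremes(self, x, y, expected):
        assert stability_ratio(x, y) == expected

    def test_ratio_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            stability_ratio(0, 0)
        with pytest.raises(ValueError, match="inconsistent"):
            stability_ratio(101, 10)

    @pytest.mark.parametrize(
        "s,expected", [(0.976, True), (0.50, False), (0.6074, True), (0.0, False)]
    )
    def test_is_stable_strict_boundary(self, s, expected):
        assert is_stable(s) is expected

    def test_stable_threshold_configurable(self):
        assert is_stable(0.5, stable_threshold=0.4)
        assert not is_stable(0.976, stable_threshold=0.99)

    @given(
        st.integers(min_value=1, max_value=10_000),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=100, derandomize=True)
    def test_ratio_in_unit_interval(self, y, frac):
        x = int(frac * y * y)
        assert 0.0 <= stability_ratio(x, y) <= 1.0

    def test_threshold_nesting(self, rng):
        """Stable set at a higher threshold nests inside the lower one."""
        expr = random_expression(rng, 8, 50)
        cat = PairCatalog(pairs=[(a, b) for a in expr.genes[:4] for b in expr.genes[4:]])
        loose = {(p.ligand, p.receptor) for p in run_dataset(expr, cat, 1.0, 0.2) if p.stable}
        strict = {(p.ligand, p.receptor) for p in run_dataset(expr, cat, 1.0, 0.6) if p.stable}
        assert strict <= loose

    def test_format_percent_half_up(self):
        assert format_percent(1722 / 1764) == "97.6%"
        assert format_percent(0.12345) == "12.3%"
        assert format_percent(0.125) == "12.5%"


class TestLigandUnion:
    def test_union_bounds(self, rng):
        """max per-receptor x <= x_union <= sum per-receptor x."""
        for trial in range(20):
            expr = random_expression(rng, 5, 30, tag=f"u{trial}")
            mask, _ = call_active(expr)
            lig = expr.genes[0]
            recs = expr.genes[1:4]
            per = [count_pair_communications(mask, lig, r)[2] for r in recs]
            _, _, x_union = ligand_union_communications(mask, lig, recs)
            assert max(per) <= x_union <= sum(per)

    def test_single_receptor_equals_pair_count(self, toy_mask):
        assert (
            ligand_union_communications(toy_mask, "LIG", ["REC"])
            == count_pair_communications(toy_mask, "LIG", "REC")
        )

    def test_duplicate_receptor_sets_not_double_counted(self, toy_mask):
        _, n_u, x_u = ligand_union_communications(toy_mask, "LIG", ["REC", "REC"])
        assert (n_u, x_u) == (3, 6)

    def test_empty_receptor_list_rejected(self, toy_mask):
        with pytest.raises(ValueError, match="non-empty"):
            ligand_union_communications(toy_mask, "LIG", [])


class TestRunDataset:
    def test_single_cell_self_communication(self):
        expr = ExpressionMatrix(
            "solo", "t", pd.DataFrame({"c1": [1.5, 2.0]}, index=["L", "R"])
        )
        (p,) = run_dataset(expr, PairCatalog(pairs=[("L", "R")]))
        assert (p.x, p.s, p.stable) == (1, 1.0, True)

    def test_dataset_with_no_active_catalog_genes_eliminated(self):
        expr = ExpressionMatrix(
            "dead", "t", pd.DataFrame(np.zeros((2, 5)), index=["L", "R"])
        )
        assert run_dataset(expr, PairCatalog(pairs=[("L", "R")])) == []

    def test_zero_cell_dataset_rejected(self):
        expr = ExpressionMatrix("empty", "t", pd.DataFrame(index=["L", "R"]))
        with pytest.raises(ExpressionError, match="no cells"):
            run_dataset(expr, PairCatalog(pairs=[("L", "R")]))

    def test_silent_pairs_omitted_totals_consistent(self, rng):
        expr = random_expression(rng, 6, 25)
        cat = PairCatalog(
            pairs=[("G0", "G1"), ("G2", "G3"), ("GHOSTL", "GHOSTR")]
        )
        res = run_dataset(expr, cat)
        assert all(p.x > 0 for p in res)
        assert sum(p.x for p in res) == sum(
            count_pair_communications(call_active(expr)[0], l, r)[2]
            for l, r in cat
        )

    def test_large_dataset_runs_linear_in_cells(self, rng):
        """5000 cells x 250 genes completes; x values verified by product."""
        expr = random_expression(rng, 250, 5000, tag="big")
        cat = PairCatalog(pairs=[(f"G{i}", f"G{i+1}") for i in range(0, 20, 2)])
        res = run_dataset(expr, cat)
        mask, _ = call_active(expr)
        for p in res:
            assert p.x == int(mask.gene_vector(p.ligand).sum()) * int(
                mask.gene_vector(p.receptor).sum()
            )


class TestEnumerateEdges:
    def test_small_counts_return_all_edges(self, toy_mask):
        edges = enumerate_edges(toy_mask, [("LIG", "REC")], max_edges=100)
        assert len(edges) == 6
        expected = {
            (s, r) for s in ("c1", "c2") for r in ("c2", "c3", "c4")
        }
        assert {(e.sender_cell, e.receiver_cell) for e in edges} == expected

    def test_max_edges_zero(self, toy_mask):
        assert enumerate_edges(toy_mask, [("LIG", "REC")], max_edges=0) == []

    def test_sampling_deterministic_and_valid(self, rng):
        expr = random_expression(rng, 4, 80)
        mask, _ = call_active(expr)
        pairs = [("G0", "G1"), ("G2", "G3")]
        a = enumerate_edges(mask, pairs, max_edges=50, seed=7)
        b = enumerate_edges(mask, pairs, max_edges=50, seed=7)
        assert [(e.sender_cell, e.receiver_cell, e.ligand) for e in a] == [
            (e.sender_cell, e.receiver_cell, e.ligand) for e in b
        ]
        assert len(a) == 50
        for e in a:  # every sampled edge is a real edge
            assert mask.active.loc[e.ligand, e.sender_cell]
            assert mask.active.loc[e.receptor, e.receiver_cell]
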