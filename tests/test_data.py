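import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import perturbcf as pcf
from perturbcf.data import AlignmentError


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[1])]
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    return pcf.ExpressionMatrix(values, genes, samples)


class TestLoadScreen:
    def test_csv_trio_aligns_by_name(self, csv_trio):
        screen = pcf.load_screen(*csv_trio())
        assert screen.n_samples == 3
        assert screen.outcome_kind == "scalar"
        assert screen.design.perturbation_ids == ["p1", "p2"]
        # pairing resolved by id, not position
        assert [screen.controls.sample_ids[j] for j in screen.pairing] == ["s1", "s2", "s3"]

    def test_unknown_control_sample_raises_alignment_error(self, csv_trio):
        paths = csv_trio(bad_control="missing_sample")
        with pytest.raises(AlignmentError, match="missing_sample"):
            pcf.load_screen(*paths)

    def test_mtx_load_matches_csv_load(self, csv_trio, tmp_path):
        from scipy.io import mmwrite

        expr_csv, design, outcome = csv_trio()
        screen_csv = pcf.load_screen(expr_csv, design, outcome)
        mtx = tmp_path / "expr.mtx"
        mmwrite(mtx, screen_csv.controls.values)
        (tmp_path / "expr.mtx.genes.txt").write_text("\n".join(screen_csv.controls.gene_ids))
        (tmp_path / "expr.mtx.samples.txt").write_text("\n".join(screen_csv.controls.sample_ids))
        screen_mtx = pcf.load_screen(mtx, design, outcome, format="mtx")
        np.testing.assert_array_equal(screen_mtx.controls.values, screen_csv.controls.values)
        np.testing.assert_array_equal(screen_mtx.design.matrix, screen_csv.design.matrix)

    def test_nan_expression_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            _matrix([[1.0, np.nan]])

    def test_write_then_load_round_trips_values(self, tiny_screen, tmp_path):
        screen, _ = tiny_screen
        paths = pcf.write_screen(screen, tmp_path / "screen")
        back = pcf.load_screen(paths["expr"], paths["design"], paths["outcome"])
        np.testing.assert_allclose(back.controls.values, screen.controls.values, rtol=1e-12)
        np.testing.assert_allclose(back.outcome_matrix, screen.outcome_matrix, rtol=1e-12)
        np.testing.assert_array_equal(back.design.matrix, screen.design.matrix)
        np.testing.assert_array_equal(back.pairing, screen.pairing)


class TestFilterGenes:
    def test_low_expression_low_variance_gene_dropped(self):
        # constant 0.5: never reaches 1.0 and variance 0 < 0.8 -> dropped
        expr = _matrix(np.column_stack([np.full(4, 0.5), np.full(4, 3.0)]))
        kept = pcf.filter_genes(expr, min_expr=1.0, min_var=0.8)
        assert kept.gene_ids == ["g1"]

    def test_single_high_value_passes_expression_rule(self):
        col = np.zeros(10)
        col[3] = 2.0  # max 2.0 >= 1.0 keeps the gene despite variance < 0.8
        expr = _matrix(np.column_stack([col, np.ones(10)]))
        kept = pcf.filter_genes(expr, min_expr=1.0, min_var=0.8)
        assert "g0" in kept.gene_ids

    def test_matches_per_gene_brute_force(self):
        rng = np.random.default_rng(5)
        expr = _matrix(rng.gamma(1.0, 1.5, size=(20, 10)))
        kept = pcf.filter_genes(expr, min_expr=1.0, min_var=0.8)
        expected = [
            g
            for j, g in enumerate(expr.gene_ids)
            if not (expr.values[:, j].max() < 1.0 and expr.values[:, j].var() < 0.8)
        ]
        assert kept.gene_ids == expected

    def test_all_genes_removed_is_error(self):
        expr = _matrix(np.full((3, 2), 0.1))
        with pytest.raises(ValueError, match="every gene"):
            pcf.filter_genes(expr, min_expr=1.0, min_var=0.8)


class TestSelectHVG:
    def test_n_equal_gene_count_is_identity(self):
        expr = _matrix(np.random.default_rng(0).random((5, 4)))
        kept = pcf.select_hvg(expr, 4)
        assert kept.gene_ids == expr.gene_ids
        np.testing.assert_array_equal(kept.values, expr.values)

    def test_matches_full_variance_sort(self):
        rng = np.random.default_rng(1)
        expr = _matrix(rng.random((8, 10)) * rng.integers(1, 5, size=10))
        kept = pcf.select_hvg(expr, 3)
        var = expr.values.var(axis=0)
        expected = set(np.argsort(-var)[:3])
        assert {expr.gene_ids.index(g) for g in kept.gene_ids} == expected

    def test_tie_at_cutoff_keeps_earlier_gene(self):
        base = np.array([0.0, 1.0, 2.0])
        expr = _matrix(np.column_stack([base * 2, base, base]))  # g1, g2 tie
        kept = pcf.select_hvg(expr, 2)
        assert kept.gene_ids == ["g0", "g1"]

    def test_nonpositive_n_rejected(self):
        expr = _matrix(np.ones((2, 2)))
        with pytest.raises(ValueError):
            pcf.select_hvg(expr, 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_filter_then_hvg_equals_single_pass(self, seed):
        rng = np.random.default_rng(seed)
        expr = _matrix(rng.gamma(1.5, 1.0, size=(12, 15)))
        filtered = pcf.filter_genes(expr, 1.0, 0.5)
        n = max(1, filtered.n_genes - 2)
        combined = pcf.select_hvg(filtered, n)
        # one-pass oracle over the original matrix
        survive = [
            j
            for j in range(expr.n_genes)
            if not (expr.values[:, j].max() < 1.0 and expr.values[:, j].var() < 0.5)
        ]
        var = expr.values.var(axis=0)
        order = sorted(survive, key=lambda j: (-var[j], survive.index(j)))[:n]
        assert set(combined.gene_ids) == {expr.gene_ids[j] for j in order}


class TestPairControls:
    def test_single_control_always_selected(self):
        perturbed = _matrix(np.ones((5, 2)))
        controls = _matrix(np.zeros((1, 2)))
        pairing, mat = pcf.pair_controls(perturbed, controls, "random_control", seed=1)
        assert (pairing == 0).all()

    def test_random_pairing_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        perturbed = _matrix(rng.random((20, 3)))
        controls = _matrix(rng.random((7, 3)))
        p1, _ = pcf.pair_controls(perturbed, controls, "random_control", seed=42)
        p2, _ = pcf.pair_controls(perturbed, controls, "random_control", seed=42)
        np.testing.assert_array_equal(p1, p2)

    def test_mean_control_is_arithmetic_mean(self):
        perturbed = _matrix(np.ones((3, 2)))
        controls = _matrix(np.array([[0.0, 2.0], [4.0, 6.0]]))
        pairing, mat = pcf.pair_controls(perturbed, controls, "mean_control", seed=0)
        np.testing.assert_allclose(mat.values[pairing], np.tile([2.0, 4.0], (3, 1)))

    def test_empty_controls_rejected(self):
        perturbed = _matrix(np.ones((2, 2)))
        controls = pcf.ExpressionMatrix(np.empty((0, 2)), ["g0", "g1"], [])
        with pytest.raises(ValueError, match="empty"):
            pcf.pair_controls(perturbed, controls)
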