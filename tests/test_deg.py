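import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metanmf import (
    ExpressionDataset,
    bh_adjust,
    collapse_probes,
    filter_low_expression,
    moderated_t,
    select_degs,
)
from metanmf.deg import squeeze_variances

from oracles import bh_stepup, pooled_t


def _dataset(rows, genes=None, n_ctrl=3, n_case=3):
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[1]
    assert n == n_ctrl + n_case
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_case)]
    probes = [f"p{i}" for i in range(rows.shape[0])]
    matrix = pd.DataFrame(rows, index=probes, columns=samples)
    groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case,
                       index=samples, name="group")
    if genes is None:
        genes = [f"G{i}" for i in range(rows.shape[0])]
    annotation = pd.Series(genes, index=probes, name="gene_symbol")
    return ExpressionDataset(matrix=matrix, groups=groups,
                             annotation=annotation)


class TestLowExpressionFilter:
    def test_quantile_zero_is_identity(self, tiny_dataset):
        out = filter_low_expression(tiny_dataset, 0.0)
        assert out.probe_ids == tiny_dataset.probe_ids

    def test_quantile_cut_matches_brute_force(self):
        # 10 probes with medians 1..10
        rows = [[m, m, m, m, m, m] for m in range(1, 11)]
        ds = _dataset(rows)
        out = filter_low_expression(ds, 0.25)
        medians = np.arange(1, 11)
        cutoff = np.quantile(medians, 0.25)
        survivors = (medians >= cutoff).sum()
        assert len(out.probe_ids) == survivors

    def test_ties_at_cutoff_retained(self):
        ds = _dataset(np.full((5, 6), 3.0))
        out = filter_low_expression(ds, 0.5)
        assert len(out.probe_ids) == 5

    def test_quantile_one_rejected(self):
        # with ties retained a valid quantile can never empty the matrix,
        # so only the degenerate quantile = 1 is an error
        ds = _dataset([[1, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError):
            filter_low_expression(ds, 1.0)
        out = filter_low_expression(ds, 0.99)
        assert len(out.probe_ids) == 1


class TestCollapseProbes:
    def test_mean_of_two_probes(self):
        ds = _dataset([[1, 3, 1, 3, 1, 3], [3, 5, 3, 5, 3, 5]],
                      genes=["G", "G"])
        out = collapse_probes(ds)
        np.testing.assert_allclose(out.matrix.loc["G"],
                                   [2, 4, 2, 4, 2, 4])

    def test_single_probe_unchanged(self, tiny_dataset):
        out = collapse_probes(tiny_dataset)
        np.testing.assert_allclose(out.matrix.loc["GA"],
                                   tiny_dataset.matrix.loc["p1"])

    def test_three_probe_mean_matches_oracle(self):
        rng = np.random.default_rng(0)
        rows = rng.uniform(2, 10, size=(3, 6))
        ds = _dataset(rows, genes=["G", "G", "G"])
        out = collapse_probes(ds)
        np.testing.assert_allclose(out.matrix.loc["G"], rows.mean(axis=0))

    def test_unannotated_probes_dropped(self):
        ds = _dataset([[1] * 6, [2] * 6])
        ds.annotation = ds.annotation.drop("p1")
        out = collapse_probes(ds)
        assert list(out.matrix.index) == ["G0"]


class TestModeratedT:
    def test_identical_groups_give_null_result(self):
        ds = _dataset([[5, 5, 5, 5, 5, 5], [1, 2, 3, 1, 2, 3]])
        table = moderated_t(collapse_probes(ds)).set_index("gene")
        assert table.loc["G0", "logFC"] == 0
        assert table.loc["G0", "t"] == 0
        assert table.loc["G0", "p"] == 1
        assert table.loc["G1", "logFC"] == 0

    def test_unmoderated_matches_hand_pooled_t(self):
        ds = _dataset([[1, 2, 3, 4, 5, 6], [2, 4, 6, 2, 4, 6]])
        table = moderated_t(collapse_probes(ds),
                            moderation=False).set_index("gene")
        lfc, t, df = pooled_t([1, 2, 3], [4, 5, 6])
        assert table.loc["G0", "logFC"] == pytest.approx(3.0)
        assert table.loc["G0", "t"] == pytest.approx(3 / np.sqrt(2 / 3))
        assert table.loc["G0", "t"] == pytest.approx(t)
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert table.loc["G0", "p"] == pytest.approx(p_hand)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_unmoderated_equals_textbook_t_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.normal(6, 1, size=(8, 9))
        ds = _dataset(rows, n_ctrl=4, n_case=5)
        table = moderated_t(collapse_probes(ds),
                            moderation=False).set_index("gene")
        for i in range(8):
            lfc, t, _ = pooled_t(rows[i, :4], rows[i, 4:])
            assert table.loc[f"G{i}", "logFC"] == pytest.approx(lfc)
            assert table.loc[f"G{i}", "t"] == pytest.approx(t)

    def test_shrinkage_limit_large_d0_pulls_to_prior(self):
        # nearly equal sample variances -> huge d0 -> posterior ~ s0^2
        rng = np.random.default_rng(1)
        df = 4
        s2 = np.full(200, 2.0) * np.exp(rng.normal(0, 1e-8, 200))
        post, d0, s0 = squeeze_variances(s2, df)
        assert d0 > 1e4 or np.isinf(d0)
        np.testing.assert_allclose(post, s0, rtol=1e-3)

    def test_all_zero_variance_without_moderation_errors(self):
        ds = _dataset([[1, 1, 1, 2, 2, 2], [3, 3, 3, 3, 3, 3]])
        with pytest.raises(ValueError, match="zero within-group variance"):
            moderated_t(ds, moderation=False)

    def test_table_sorted_by_p_and_padj_dominates_p(self, small_study):
        ds, _ = small_study
        table = moderated_t(collapse_probes(ds))
        assert (np.diff(table["p"]) >= 0).all()
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        assert ((table["direction"] == "up") == (table["logFC"] > 0)).all()


class TestBHAdjust:
    def test_hand_computed_examples(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_adjust(np.array([0.005, 0.1])),
                                   [0.01, 0.1])
        np.testing.assert_allclose(bh_adjust(np.array([0.7])), [0.7])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([-0.1]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(np.array(pvals)),
                                   bh_stepup(pvals), atol=1e-12)


class TestSelectDegs:
    @staticmethod
    def _table():
        return pd.DataFrame({
            "gene": ["a", "b", "c", "d", "e", "f"],
            "logFC": [0.6, 0.5, -0.8, 0.1, -1.2, 0.9],
            "t": [2.0] * 6,
            "p": [0.04, 0.04, 0.01, 0.001, 0.2, 0.049],
            "p_adj": [0.08, 0.08, 0.04, 0.006, 0.24, 0.09],
            "direction": ["up", "up", "down", "up", "down", "up"],
            "mean_expr": [5.0] * 6,
        })

    def test_strict_boundaries(self):
        out = select_degs(self._table(), p_cut=0.05, lfc_cut=0.5)
        # b fails |logFC| > 0.5 (equality), d fails lfc, e fails p < 0.05
        assert set(out["gene"]) == {"a", "c", "f"}

    def test_survivor_count_matches_brute_force(self):
        t = self._table()
        expected = sum((p < 0.05) and (abs(l) > 0.5)
                       for p, l in zip(t["p"], t["logFC"]))
        out = select_degs(t, 0.05, 0.5)
        assert len(out) == expected == 3

    def test_loose_cuts_keep_all_nonzero_lfc(self):
        out = select_degs(self._table(), p_cut=1.0, lfc_cut=0.0)
        assert set(out["gene"]) == {"a", "b", "c", "d", "e", "f"}

    def test_adjusted_filter_flag(self):
        out = select_degs(self._table(), 0.05, 0.5, use_adjusted=True)
        assert set(out["gene"]) == {"c"}

    def test_empty_result_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            out = select_degs(self._table(), p_cut=1e-9, lfc_cut=5.0)
        assert out.empty
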