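"""CPM normalization, the zero-count filter, site-to-gene aggregation, the
strict matching step, and the built-in DE screen."""

import numpy as np
import pytest

from morgan5c import (
    MorganError,
    SampleSheet,
    aggregate_gene_methylation,
    cpm_normalize,
    filter_low_expression,
    match,
    simple_de,
)
from conftest import make_expression, make_methylation, make_site_table


class TestCPM:
    def test_column_fractions_scale_to_one_million(self):
        mat = make_expression([[100], [300], [600]])
        out = cpm_normalize(mat)
        np.testing.assert_allclose(out.values.iloc[:, 0], [1e5, 3e5, 6e5])
        assert out.scale == "cpm"

    def test_single_gene_column_becomes_one_million(self):
        out = cpm_normalize(make_expression([[7.0]]))
        assert out.values.iloc[0, 0] == pytest.approx(1e6)

    def test_random_matrix_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        out = cpm_normalize(make_expression(rng.integers(0, 500, (20, 6)) + 1))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_column_sum_names_sample(self):
        with pytest.raises(MorganError, match="s1"):
            cpm_normalize(make_expression([[1, 0], [2, 0]], samples=["s0", "s1"]))

    def test_refuses_already_normalized_input(self):
        cpm = cpm_normalize(make_expression([[1, 2]]))
        with pytest.raises(MorganError, match="raw counts"):
            cpm_normalize(cpm)


class TestLowExpressionFilter:
    def test_exact_boundary_fraction_is_retained(self):
        # 2 zeros in 8 samples = exactly 25%: kept (the rule is strictly "more than")
        vals = np.ones((1, 8))
        vals[0, :2] = 0
        assert filter_low_expression(make_expression(vals)).values.shape[0] == 1

    def test_above_boundary_is_removed(self):
        vals = np.ones((1, 8))
        vals[0, :3] = 0
        assert filter_low_expression(make_expression(vals)).values.empty

    def test_all_nonzero_matrix_unchanged_and_idempotent(self):
        mat = make_expression(np.arange(1, 13).reshape(3, 4))
        once = filter_low_expression(mat)
        twice = filter_low_expression(once)
        assert once.values.equals(mat.values)
        assert twice.values.equals(once.values)


class TestAggregation:
    def test_pooled_and_mean_hand_arithmetic(self):
        table = make_site_table(
            "s1",
            [("chr1", 10, "+", 10, 2, 0.2, "gA"),
             ("chr1", 50, "+", 90, 58, 58 / 90, "gA")],
        )
        pooled = aggregate_gene_methylation([table], method="pooled")
        mean = aggregate_gene_methylation([table], method="mean")
        assert pooled.values.loc["gA", "s1"] == pytest.approx(0.60)
        assert mean.values.loc["gA", "s1"] == pytest.approx((0.2 + 58 / 90) / 2)

    def test_single_site_agrees_under_both_methods(self):
        table = make_site_table("s1", [("chr1", 10, "+", 50, 25, 0.5, "gA")])
        for method in ("pooled", "mean"):
            out = aggregate_gene_methylation([table], method=method)
            assert out.values.loc["gA", "s1"] == pytest.approx(0.5)

    def test_absent_gene_sample_pair_is_missing_not_zero(self):
        t1 = make_site_table("s1", [("chr1", 10, "+", 10, 5, 0.5, "gA")])
        t2 = make_site_table("s2", [("chr1", 99, "+", 10, 5, 0.5, "gB")])
        out = aggregate_gene_methylation([t1, t2])
        assert np.isnan(out.values.loc["gA", "s2"])
        assert np.isnan(out.values.loc["gB", "s1"])

    def test_equal_coverage_makes_pooled_equal_mean(self):
        rng = np.random.default_rng(4)
        rows = []
        for i, m in enumerate(rng.integers(0, 41, size=8)):
            rows.append(("chr1", 10 + i, "+", 40, int(m), m / 40, "gA"))
        table = make_site_table("s1", rows)
        pooled = aggregate_gene_methylation([table], method="pooled")
        mean = aggregate_gene_methylation([table], method="mean")
        assert pooled.values.loc["gA", "s1"] == pytest.approx(
            mean.values.loc["gA", "s1"], abs=1e-12
        )

    def test_unknown_method_rejected(self):
        table = make_site_table("s1", [("chr1", 1, "+", 10, 5, 0.5, "gA")])
        with pytest.raises(MorganError, match="method"):
            aggregate_gene_methylation([table], method="median")


class TestMatch:
    def test_keeps_name_intersection(self, toy_metadata):
        meth = make_methylation(np.full((3, 5), 0.5), genes=["A", "B", "C"],
                                samples=["t1", "t2", "t3", "n1", "n2"])
        expr = make_expression(np.ones((3, 5)), genes=["B", "C", "D"],
                               samples=["t1", "t2", "t3", "n1", "n2"], scale="cpm")
        out = match(meth, expr, toy_metadata)
        assert out.genes == ["B", "C"]
        assert out.methylation.samples == out.expression.samples

    def test_disjoint_samples_error(self, toy_metadata):
        meth = make_methylation([[0.5]], genes=["A"], samples=["t1"])
        expr = make_expression([[1.0]], genes=["A"], samples=["x9"], scale="cpm")
        with pytest.raises(MorganError, match="samples"):
            match(meth, expr, toy_metadata)

    def test_identical_labels_fully_retained(self, toy_metadata):
        samples = ["t1", "t2", "t3", "n1", "n2"]
        meth = make_methylation(np.full((2, 5), 0.3), genes=["A", "B"], samples=samples)
        expr = make_expression(np.ones((2, 5)), genes=["A", "B"], samples=samples,
                               scale="cpm")
        out = match(meth, expr, toy_metadata)
        assert out.genes == ["A", "B"]
        assert sorted(out.samples) == sorted(samples)


class TestSimpleDE:
    def test_flat_gene_not_returned(self, toy_metadata):
        expr = make_expression(np.full((1, 5), 100.0),
                               samples=["t1", "t2", "t3", "n1", "n2"], scale="cpm")
        meta = SampleSheet({"t1": "cancer", "t2": "cancer", "t3": "cancer",
                            "n1": "normal", "n2": "normal"})
        assert simple_de(expr, meta).empty

    def test_bh_adjustment_hand_oracle(self):
        # worked BH case: p = (.01,.02,.03,.04), m=4 -> padj all 0.04
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(padj, [0.04] * 4)

    def test_planted_strong_up_gene_is_detected(self):
        # 8-fold planted shift at n=8 vs 8 with low noise: detected as "up"
        # in at least 95% of seeds
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 16
            samples = [f"c{i}" for i in range(8)] + [f"n{i}" for i in range(8)]
            meta = SampleSheet(dict(zip(samples, ["cancer"] * 8 + ["normal"] * 8)))
            base = rng.normal(100, 5, size=(30, n)).clip(min=1)
            base[0, :8] *= 8.0  # planted 8-fold up gene
            cpm = make_expression(base, samples=samples, scale="cpm")
            de = simple_de(cpm, meta)
            hits += "g0" in set(de.loc[de["direction"] == "up", "gene"])
        assert hits / n_seeds >= 0.95

    def test_one_small_group_is_hard_error(self):
        expr = make_expression(np.ones((1, 3)), samples=["a", "b", "c"], scale="cpm")
        meta = SampleSheet({"a": "cancer", "b": "cancer", "c": "normal"})
        with pytest.raises(MorganError, match="2 samples"):
            simple_de(expr, meta)
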