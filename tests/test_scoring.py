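import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crcsig.expression import ExpressionMatrix
from crcsig.scoring import (
    DegenerateScoreError,
    MissingSignatureError,
    NormalizationError,
    ScoringError,
    assign_quartiles,
    component_means,
    normalize_cell_line_probes,
    score_pipeline,
    signature_score,
    standardize,
)
from crcsig.signatures import GeneSignature


class TestComponentScore:
    def test_gene_level_mean(self, gene_matrix):
        means = component_means(gene_matrix, {"G1", "G2"}, min_coverage=0)
        assert means["A"] == pytest.approx(3.0)
        assert means["B"] == pytest.approx(2.0)

    def test_probes_pooled_not_per_gene_averaged(self, probe_matrix):
        # pooled: (1+3+5)/3 = 3.0; the per-gene-first alternative would give
        # mean(mean(1,3), 5) = 3.5 — the pooling decision changes the answer
        means = component_means(probe_matrix, {"G1", "G2"}, min_coverage=0)
        assert means["A"] == pytest.approx(3.0)
        per_gene_first = np.mean([np.mean([1.0, 3.0]), 5.0])
        assert per_gene_first == pytest.approx(3.5)
        assert means["A"] != per_gene_first

    def test_absent_genes_raise(self, gene_matrix):
        with pytest.raises(MissingSignatureError, match="MYSIG"):
            component_means(gene_matrix, {"G9"}, signature_name="MYSIG")

    def test_low_coverage_warns_but_scores(self, gene_matrix):
        with pytest.warns(UserWarning, match="coverage"):
            means = component_means(gene_matrix, {"G1", "G8", "G9"}, min_coverage=0.5)
        assert means["A"] == pytest.approx(2.0)

    def test_low_coverage_can_error(self, gene_matrix):
        with pytest.raises(MissingSignatureError, match="coverage"):
            component_means(
                gene_matrix, {"G1", "G8", "G9"}, min_coverage=0.5, on_low_coverage="error"
            )


class TestSignatureScore:
    def test_up_minus_down(self, gene_matrix):
        sig = GeneSignature(name="S", up_genes=frozenset({"G2"}), down_genes=frozenset({"G1"}))
        score = signature_score(gene_matrix, sig, min_coverage=0)
        assert score["A"] == pytest.approx(4.0 - 2.0)
        assert score["B"] == pytest.approx(3.0 - 1.0)

    def test_up_only_ignores_other_components(self, gene_matrix):
        sig = GeneSignature(
            name="SRC", up_genes=frozenset({"G1"}), down_genes=frozenset({"G2"})
        )
        score = signature_score(gene_matrix, sig, mode="up_only", min_coverage=0)
        assert score["A"] == pytest.approx(2.0)

    def test_full_composite_symmetry_gives_zero(self):
        # all four component means equal -> (UP + PLUSINF) - (DOWN + MINUSINF) = 0
        values = pd.DataFrame({"s1": [5.0, 5.0, 5.0, 5.0]}, index=["U", "D", "P", "M"])
        expr = ExpressionMatrix(values=values, feature_kind="gene")
        sig = GeneSignature(
            name="C",
            up_genes=frozenset({"U"}),
            down_genes=frozenset({"D"}),
            plus_inf_genes=frozenset({"P"}),
            minus_inf_genes=frozenset({"M"}),
        )
        score = signature_score(expr, sig, mode="full_composite", min_coverage=0)
        assert score["s1"] == pytest.approx(0.0)

    def test_up_minus_down_requires_down(self, gene_matrix):
        sig = GeneSignature(name="S", up_genes=frozenset({"G1"}))
        with pytest.raises(ScoringError, match="DOWN"):
            signature_score(gene_matrix, sig, mode="up_minus_down", min_coverage=0)

    def test_shift_invariance_of_up_minus_down(self, rng):
        # adding a constant to every value of a sample shifts UP and DOWN
        # means equally, leaving UP - DOWN unchanged
        genes = [f"G{i}" for i in range(10)]
        values = pd.DataFrame(rng.normal(size=(10, 4)), index=genes,
                              columns=list("abcd"))
        sig = GeneSignature(
            name="S", up_genes=frozenset(genes[:6]), down_genes=frozenset(genes[6:])
        )
        base = signature_score(ExpressionMatrix(values=values), sig, min_coverage=0)
        shifted_values = values.copy()
        shifted_values["b"] += 7.5
        shifted = signature_score(ExpressionMatrix(values=shifted_values), sig, min_coverage=0)
        assert np.allclose(base, shifted)


class TestStandardize:
    def test_five_point_example(self):
        out = standardize(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert np.allclose(out, [-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateScoreError):
            standardize(pd.Series([2.0, 2.0, 2.0]))

    def test_median_zero_iqr_one_on_continuous_draws(self, rng):
        out = standardize(pd.Series(rng.gamma(2.0, size=1000)))
        q1, med, q3 = np.quantile(out, [0.25, 0.5, 0.75])
        assert abs(med) < 1e-9
        assert abs((q3 - q1) - 1.0) < 1e-9

    def test_idempotent_fixed_point(self, rng):
        once = standardize(pd.Series(rng.normal(size=200)))
        twice = standardize(once)
        assert np.allclose(once, twice)

    def test_spearman_invariant_under_standardization(self, rng):
        x = pd.Series(rng.normal(size=100))
        y = pd.Series(0.5 * x + rng.normal(size=100))
        before = sps.spearmanr(x, y).statistic
        after = sps.spearmanr(standardize(x), standardize(y)).statistic
        assert before == pytest.approx(after, abs=1e-12)


class TestCellLineNormalization:
    def test_row_divided_by_mean(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"a": [2.0, 5.0], "b": [4.0, 5.0]}, index=["p", "q"])
        )
        out = normalize_cell_line_probes(expr)
        assert np.allclose(out.values.loc["p"], [2 / 3, 4 / 3])
        assert np.allclose(out.values.loc["q"], [1.0, 1.0])

    def test_all_row_means_one(self, rng):
        values = pd.DataFrame(rng.uniform(0.1, 100.0, size=(30, 10)))
        out = normalize_cell_line_probes(ExpressionMatrix(values=values))
        assert np.allclose(out.values.mean(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_mean_rejected_by_name(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"a": [1.0, -3.0], "b": [1.0, 1.0]}, index=["ok", "bad"])
        )
        with pytest.raises(NormalizationError, match="bad"):
            normalize_cell_line_probes(expr)


class TestQuartiles:
    def test_four_points(self):
        out = assign_quartiles(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert list(out) == ["Q1", "Q2", "Q3", "Q4"]

    def test_degenerate_all_q1(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = assign_quartiles(pd.Series([1.0, 1.0, 1.0, 1.0]))
        assert set(out) == {"Q1"}

    def test_balanced_groups_on_continuous_draws(self, rng):
        out = assign_quartiles(pd.Series(rng.normal(size=1000)))
        counts = out.value_counts()
        assert all(abs(counts[q] - 250) <= 1 for q in ("Q1", "Q2", "Q3", "Q4"))

    def test_too_few_samples(self):
        with pytest.raises(ScoringError):
            assign_quartiles(pd.Series([1.0, 2.0, 3.0]))


class TestScorePipeline:
    def test_all_columns_standardized(self, small_cohort):
        table = score_pipeline(small_cohort.expression, small_cohort.registry)
        assert table.standardized
        assert table.scores.shape[1] == len(small_cohort.registry)
        for col in table.scores:
            q1, med, q3 = np.quantile(table.scores[col], [0.25, 0.5, 0.75])
            assert abs(med) < 1e-9
            assert abs((q3 - q1) - 1.0) < 1e-9
        assert (table.coverage == 1.0).all()
        assert not table.degenerate

    def test_deterministic(self, small_cohort):
        a = score_pipeline(small_cohort.expression, small_cohort.registry)
        b = score_pipeline(small_cohort.expression, small_cohort.registry)
        assert a.scores.equals(b.scores)

    def test_pooled_equals_gene_level_for_single_probe_platform(self, rng):
        genes = [f"G{i}" for i in range(8)]
        values = pd.DataFrame(rng.normal(size=(8, 20)), index=genes)
        values.columns = [f"s{i}" for i in range(20)]
        gene_expr = ExpressionMatrix(values=values, feature_kind="gene")
        probe_expr = ExpressionMatrix(
            values=values.rename(index={g: f"{g}_p1" for g in genes}),
            feature_kind="probe",
            probe_to_gene={f"{g}_p1": g for g in genes},
        )
        sig = GeneSignature(name="S", up_genes=frozenset(genes[:5]))
        a = signature_score(gene_expr, sig, min_coverage=0)
        b = signature_score(probe_expr, sig, min_coverage=0)
        assert np.allclose(a, b)

    def test_cell_line_mode_scores_ratio_matrix(self, probe_matrix):
        from crcsig.signatures import SignatureRegistry

        reg = SignatureRegistry()
        reg.add(GeneSignature(name="S", up_genes=frozenset({"G1", "G2"})))
        table = score_pipeline(probe_matrix, reg, cell_line_mode=True)
        ratio = normalize_cell_line_probes(probe_matrix)
        expected = ratio.values.loc[["p1", "p2", "p3"]].mean(axis=0)
        # raw component mean on the ratio matrix, before standardization
        raw = table.components["S"]["UP"]
        assert np.allclose(raw, expected)

    def test_degenerate_column_flagged_not_zeroed(self):
        values = pd.DataFrame(
            {"a": [1.0, 5.0], "b": [1.0, 2.0], "c": [1.0, 9.0]}, index=["G1", "G2"]
        )
        from crcsig.signatures import SignatureRegistry

        reg = SignatureRegistry()
        reg.add(GeneSignature(name="CONST", up_genes=frozenset({"G1"})))
        with pytest.warns(UserWarning, match="zero IQR"):
            table = score_pipeline(ExpressionMatrix(values=values), reg)
        assert table.degenerate == ["CONST"]
        assert np.allclose(table.scores["CONST"], 1.0)  # raw values retained
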