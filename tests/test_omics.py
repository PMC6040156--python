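"""Expression-flux correlation: series aggregation, coefficients, filters,
summaries and genome ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fluxkit import (
    FluxSolution,
    ModelError,
    correlate_expression_flux,
    filter_by_variation,
    gene_flux_series,
    order_by_genome_position,
    summarize_correlations,
)
from fluxkit.data import OmicsMatrix
from fluxkit.omics import CorrelationRecord

from conftest import small_model


def matrix(rows: dict, times=None) -> OmicsMatrix:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = times or list(range(frame.shape[1]))
    return OmicsMatrix(frame)


def solutions_from(flux_rows: dict) -> list:
    n = len(next(iter(flux_rows.values())))
    return [
        FluxSolution(fluxes={r: flux_rows[r][i] for r in flux_rows},
                     objective_value=0.0, status="optimal")
        for i in range(n)
    ]


class TestGeneFluxSeries:
    def setup_method(self):
        self.model = small_model(
            ["A", "B", "C"],
            [
                ("R1", {"A": -1, "B": 1}, 0, 10, "g1"),
                ("R2", {"B": -1, "C": 1}, -10, 10, "g2"),
                ("R3", {"A": -1, "C": 1}, 0, 10, "g2"),
            ],
        )

    def test_single_reaction_gene_copies_fluxes(self):
        sols = solutions_from({"R1": [1, 2, 3], "R2": [0, 0, 0], "R3": [0, 0, 0]})
        series = gene_flux_series(self.model, sols)
        np.testing.assert_allclose(series["g1"], [1, 2, 3])

    def test_multi_reaction_gene_sums_absolute_fluxes(self):
        sols = solutions_from({"R1": [0, 0, 0], "R2": [-1, -1, -1], "R3": [2, 2, 2]})
        series = gene_flux_series(self.model, sols)
        np.testing.assert_allclose(series["g2"], [3, 3, 3])

    def test_gene_without_gpr_absent(self):
        from fluxkit import Gene

        self.model.add_gene(Gene("orphan"))
        sols = solutions_from({"R1": [1], "R2": [1], "R3": [1]})
        assert "orphan" not in gene_flux_series(self.model, sols)

    def test_empty_solution_list_rejected(self):
        with pytest.raises(ModelError, match="empty"):
            gene_flux_series(self.model, [])


def reference_pearson(x, y):
    """Straight-line reimplementation from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def reference_spearman(x, y):
    """Pearson of average-rank-transformed series."""
    def ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    return reference_pearson(ranks(x), ranks(y))


class TestCorrelate:
    def test_proportional_series_perfect_pearson(self):
        flux = {"g1": np.array([1.0, 2.0, 3.0, 4.0])}
        expr = matrix({"g1": [2.0, 4.0, 6.0, 8.0]})
        rec = correlate_expression_flux(expr, flux)[0]
        assert rec.pearson_r == pytest.approx(1.0)
        assert rec.spearman_rho == pytest.approx(1.0)
        assert rec.classification == "correlated"

    def test_negated_series_perfect_anticorrelation(self):
        flux = {"g1": np.array([1.0, 2.0, 3.0])}
        expr = matrix({"g1": [9.0, 8.0, 7.0]})
        rec = correlate_expression_flux(expr, flux)[0]
        assert rec.pearson_r == pytest.approx(-1.0)
        assert rec.classification == "anti-correlated"

    def test_constant_series_is_missing_not_zero(self):
        flux = {"g1": np.array([1.0, 2.0, 3.0])}
        expr = matrix({"g1": [5.0, 5.0, 5.0]})
        rec = correlate_expression_flux(expr, flux)[0]
        assert rec.pearson_r is None
        assert rec.spearman_rho is None
        assert rec.classification == "undefined"

    def test_matches_reference_computation(self):
        """The coefficients equal an independent from-the-definition
        implementation to 1e-12 on a noisy synthetic cohort."""
        rng = np.random.default_rng(7)
        flux = {f"g{i}": rng.uniform(0, 10, 12) for i in range(30)}
        expr_rows = {
            g: (1 if i % 10 else -1) * flux[g] * rng.uniform(0.5, 2)
            + rng.normal(0, 1, 12) + 20
            for i, (g, _) in enumerate(flux.items())
        }
        expr = matrix(expr_rows)
        for rec in correlate_expression_flux(expr, flux):
            e, f = expr.series(rec.gene_id), flux[rec.gene_id]
            assert rec.pearson_r == pytest.approx(reference_pearson(e, f), abs=1e-12)
            assert rec.spearman_rho == pytest.approx(reference_spearman(e, f), abs=1e-12)

    def test_proteomics_missing_values_pairwise_dropped(self):
        flux = {"g1": np.array([1.0, 2.0, 3.0, 4.0, 5.0])}
        expr = matrix({"g1": [2.0, np.nan, 6.0, 8.0, np.nan]})
        rec = correlate_expression_flux(expr, flux)[0]
        assert rec.n_timepoints == 3
        assert rec.pearson_r == pytest.approx(1.0)

    def test_too_few_complete_pairs_undefined(self):
        flux = {"g1": np.array([1.0, 2.0, 3.0, 4.0])}
        expr = matrix({"g1": [2.0, np.nan, np.nan, 8.0]})
        rec = correlate_expression_flux(expr, flux)[0]
        assert rec.pearson_r is None

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ModelError, match="shared"):
            correlate_expression_flux(matrix({"gX": [1, 2, 3]}), {"gY": np.ones(3)})

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(-500, 500), min_size=4, max_size=12, unique=True),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_affine_and_monotone_invariance(self, levels, scale, shift):
        """Pearson is invariant under positive affine transforms; Spearman
        under any strictly monotone transform (here exp of a scaled copy).
        Integer base levels keep the transforms free of float ties."""
        values = [0.1 * v for v in levels]
        flux = {"g": np.linspace(1, 2, len(values))}
        base = matrix({"g": values})
        affine = matrix({"g": [scale * v + shift for v in values]})
        monotone = matrix({"g": list(np.exp(np.asarray(values) / 50))})
        r0 = correlate_expression_flux(base, flux)[0]
        r1 = correlate_expression_flux(affine, flux)[0]
        r2 = correlate_expression_flux(monotone, flux)[0]
        assert r1.pearson_r == pytest.approx(r0.pearson_r, abs=1e-9)
        assert r1.spearman_rho == pytest.approx(r0.spearman_rho, abs=1e-9)
        assert r2.spearman_rho == pytest.approx(r0.spearman_rho, abs=1e-9)


class TestFilterByVariation:
    def _records(self, expr):
        flux = {g: np.arange(1.0, 1.0 + expr.n_timepoints) for g in expr.entities}
        return correlate_expression_flux(expr, flux)

    def test_constant_series_removed(self):
        expr = matrix({"g1": [5.0, 5.0, 5.0], "g2": [1.0, 2.0, 3.0]})
        kept = filter_by_variation(self._records(expr), expr)
        assert [r.gene_id for r in kept] == ["g2"]

    def test_thirty_percent_variation_kept(self):
        expr = matrix({"g1": [100.0, 115.0, 130.0]})
        assert len(filter_by_variation(self._records(expr), expr, 0.25)) == 1

    def test_exact_threshold_removed(self):
        expr = matrix({"g1": [100.0, 110.0, 125.0]})
        assert filter_by_variation(self._records(expr), expr, 0.25) == []

    def test_nonpositive_minimum_excluded_and_flagged(self):
        expr = matrix({"g1": [0.0, 5.0, 10.0]})
        records = self._records(expr)
        assert filter_by_variation(records, expr) == []
        assert records[0].flagged

    def test_zero_threshold_keeps_exactly_nonconstant(self):
        expr = matrix({"flat": [3.0, 3.0, 3.0], "moving": [3.0, 3.0001, 3.0]})
        kept = filter_by_variation(self._records(expr), expr, threshold=0.0)
        assert [r.gene_id for r in kept] == ["moving"]


class TestSummarizeAndOrder:
    def test_median_of_constant_spearmans(self):
        recs = [CorrelationRecord(f"g{i}", spearman_rho=1.0, pearson_r=1.0,
                                  classification="correlated") for i in range(3)]
        s = summarize_correlations(recs)
        assert s.median_spearman == 1.0

    def test_median_symmetric_values(self):
        recs = [CorrelationRecord("a", spearman_rho=-1.0, pearson_r=-1.0),
                CorrelationRecord("b", spearman_rho=0.0, pearson_r=0.0),
                CorrelationRecord("c", spearman_rho=1.0, pearson_r=1.0)]
        s = summarize_correlations(recs)
        assert s.median_spearman == 0.0
        assert s.spearman_histogram.sum() == 3
        assert len(s.histogram_bins) == 21

    def test_medians_equal_direct_recomputation(self):
        rng = np.random.default_rng(11)
        recs = [CorrelationRecord(f"g{i}", pearson_r=float(rng.uniform(-1, 1)),
                                  spearman_rho=float(rng.uniform(-1, 1)))
                for i in range(25)]
        s = summarize_correlations(recs)
        assert s.median_pearson == np.median([r.pearson_r for r in recs])
        assert s.median_spearman == np.median([r.spearman_rho for r in recs])

    def test_empty_rejected(self):
        with pytest.raises(ModelError, match="no correlation"):
            summarize_correlations([])

    def test_order_by_genome_position(self):
        recs = [CorrelationRecord("g1", genome_start=300),
                CorrelationRecord("g2", genome_start=100),
                CorrelationRecord("g3", genome_start=200)]
        ordered = order_by_genome_position(recs)
        assert [r.genome_start for r in ordered] == [100, 200, 300]

    def test_unpositioned_appended_in_id_order_and_flagged(self):
        recs = [CorrelationRecord("zz"), CorrelationRecord("aa"),
                CorrelationRecord("mid", genome_start=50)]
        ordered = order_by_genome_position(recs)
        assert [r.gene_id for r in ordered] == ["mid", "aa", "zz"]
        assert ordered[1].flagged and ordered[2].flagged

    def test_ordering_is_permutation(self):
        recs = [CorrelationRecord(f"g{i}", genome_start=(97 * i) % 13)
                for i in range(13)]
        ordered = order_by_genome_position(recs)
        assert sorted(r.gene_id for r in ordered) == sorted(r.gene_id for r in recs)
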