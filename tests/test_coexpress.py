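"""Co-expression scoring, frequency ratio, genotype comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import clonetrace as ct
from clonetrace.simulate import (
    lineage_bias_ct_config,
    null_ct_config,
    simulate_ct_table,
)

from _oracles import fisher_combined_two


def _expr_from(values: dict, panel: ct.GenePanel,
               genotype: str = "WT") -> ct.ExpressionMatrix:
    df = pd.DataFrame(values)
    df.index = pd.Index([f"c{i}" for i in range(len(df))], name="cell")
    return ct.ExpressionMatrix(
        values=df.astype(float),
        detected=df > 0,
        genotype=pd.Series(genotype, index=df.index, name="genotype"),
        panel=panel,
    )


PANEL = ct.GenePanel(
    myeloid=("Mpo", "Elane"), erythroid=("Gata1", "Klf1"),
    housekeeping=("Hprt",),
)


class TestCountCoexpression:
    def test_counts_detected_genes_per_panel(self):
        expr = _expr_from(
            {"Mpo": [0.5, 0.0], "Elane": [0.0, 0.0],
             "Gata1": [1.0, 0.0], "Klf1": [0.2, 0.0]}, PANEL
        )
        out = ct.count_coexpression(expr)
        assert tuple(out.loc["c0", ["n_myeloid", "n_erythroid"]]) == (1, 2)
        assert tuple(out.loc["c1", ["n_myeloid", "n_erythroid"]]) == (0, 0)

    def test_full_panel_detection_hits_panel_sizes(self, qc_expression):
        expr = qc_expression
        full = ct.ExpressionMatrix(
            values=expr.values.where(expr.values > 0, 1.0),
            detected=expr.detected | True,
            genotype=expr.genotype, panel=expr.panel,
        )
        out = ct.count_coexpression(full)
        assert (out["n_myeloid"] == len(expr.panel.myeloid)).all()
        assert (out["n_erythroid"] == len(expr.panel.erythroid)).all()

    def test_missing_panel_gene_is_an_error(self):
        expr = _expr_from({"Mpo": [0.5], "Gata1": [0.1], "Klf1": [0.1]},
                          PANEL)
        object.__setattr__(expr, "detected",
                           expr.detected.drop(columns=["Klf1"]))
        with pytest.raises(ValueError, match="absent"):
            ct.count_coexpression(expr)


class TestFrequencyRatio:
    def test_everything_detected_gives_ratio_one(self):
        expr = _expr_from(
            {g: [1.0, 1.0] for g in PANEL.myeloid + PANEL.erythroid}, PANEL
        )
        assert ct.frequency_ratio(expr) == pytest.approx(1.0)

    def test_no_erythroid_detection_gives_zero(self):
        expr = _expr_from(
            {"Mpo": [1.0, 1.0], "Elane": [1.0, 0.0],
             "Gata1": [0.0, 0.0], "Klf1": [0.0, 0.0]}, PANEL
        )
        assert ct.frequency_ratio(expr) == 0.0

    def test_no_myeloid_detection_is_reported_missing(self):
        expr = _expr_from(
            {"Mpo": [0.0], "Elane": [0.0], "Gata1": [1.0], "Klf1": [0.0]},
            PANEL,
        )
        assert np.isnan(ct.frequency_ratio(expr))

    def test_hand_computed_ratio(self):
        # erythroid per-gene frequencies (0.5, 1.0) -> mean 0.75;
        # myeloid (0.5, 0.5) -> mean 0.5; R = 1.5
        expr = _expr_from(
            {"Mpo": [1.0, 0.0], "Elane": [0.0, 1.0],
             "Gata1": [1.0, 0.0], "Klf1": [1.0, 1.0]}, PANEL
        )
        assert ct.frequency_ratio(expr) == pytest.approx(1.5)
        # pooled definition coincides for complete panels
        assert ct.frequency_ratio(expr, definition="pooled") == \
            pytest.approx(1.5)

    def test_invariant_to_cell_and_gene_order(self, qc_expression):
        expr = qc_expression
        r = ct.frequency_ratio(expr)
        perm_cells = expr.values.sample(frac=1.0, random_state=1).index
        perm_genes = list(expr.values.sample(frac=1.0, axis=1,
                                             random_state=2).columns)
        shuffled = ct.ExpressionMatrix(
            values=expr.values.loc[perm_cells, perm_genes],
            detected=expr.detected.loc[perm_cells, perm_genes],
            genotype=expr.genotype.loc[perm_cells],
            panel=expr.panel,
        )
        assert ct.frequency_ratio(shuffled) == pytest.approx(r)

    def test_recovers_designed_detection_ratio(self):
        # erythroid-shifted design: detection 0.5 vs 0.6 -> R = 5/6
        cfg = lineage_bias_ct_config(
            erythroid_p=0.5, myeloid_p=0.6, genotype="KLG",
            n_cells=300, seed=11,
        )
        cfg = ct.CtSimConfig(
            detection=cfg.detection, ct_params=cfg.ct_params,
            n_cells=cfg.n_cells, fail_rate=0.0, panel=cfg.panel, seed=11,
        )
        sim = simulate_ct_table(cfg)
        table = ct.CtTable(ct=sim.ct, genotype=sim.genotype, panel=sim.panel)
        expr = ct.normalize_expression(
            ct.housekeeping_qc(table, cutoff=21.0)[0]
        )
        assert ct.frequency_ratio(expr) == pytest.approx(0.5 / 0.6, abs=0.05)


class TestFishersMethod:
    def test_all_ones_combine_to_one(self):
        assert ct.fishers_method([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.3, 0.05, 0.9, 1e-6):
            assert ct.fishers_method([p]) == pytest.approx(p, rel=1e-9)

    def test_frozen_two_p_closed_form(self):
        # q(1 - ln q) with q = 0.0025: 0.017479...
        assert ct.fishers_method([0.05, 0.05]) == pytest.approx(
            fisher_combined_two(0.05, 0.05), rel=1e-9
        )
        assert ct.fishers_method([0.05, 0.05]) == pytest.approx(0.0175,
                                                                abs=1e-4)

    def test_agrees_with_scipy_reference(self):
        ps = [0.8, 0.03, 0.4]
        _, expected = stats.combine_pvalues(ps, method="fisher")
        assert ct.fishers_method(ps) == pytest.approx(expected, rel=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_arguments(self, ps):
        assert ct.fishers_method(ps) == pytest.approx(
            ct.fishers_method(list(reversed(ps))), rel=1e-9
        )

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0),
           st.floats(0.1, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_any_input_never_raises_combined(
        self, p1, p2, shrink
    ):
        assert ct.fishers_method([p1 * shrink, p2]) <= \
            ct.fishers_method([p1, p2]) + 1e-12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ct.fishers_method([0.0, 0.5])
        with pytest.raises(ValueError):
            ct.fishers_method([])


class TestCompareGenotypes:
    def test_identical_samples_yield_maximal_p(self):
        expr = _expr_from(
            {"Mpo": [0.5, 0.1, 0.9, 0.0], "Elane": [0.0] * 4,
             "Gata1": [0.2] * 4, "Klf1": [0.0, 0.3, 0.0, 0.3]}, PANEL
        )
        c = ct.compare_genotypes(expr, expr, "Mpo")
        assert c.p_frequency == 1.0
        assert c.p_expression > 0.9
        assert c.p_combined > 0.9

    def test_degenerate_detection_table_gives_frequency_one(self):
        a = _expr_from({"Mpo": [0.5, 0.2], "Elane": [0.0, 0.0],
                        "Gata1": [0.1, 0.1], "Klf1": [0.0, 0.0]}, PANEL)
        b = _expr_from({"Mpo": [0.4, 0.6], "Elane": [0.0, 0.0],
                        "Gata1": [0.3, 0.3], "Klf1": [0.0, 0.0]}, PANEL, "KLG")
        assert ct.compare_genotypes(a, b, "Mpo").p_frequency == 1.0
        assert ct.compare_genotypes(a, b, "Elane").p_frequency == 1.0

    def test_frozen_fisher_exact_tail(self):
        # detected 10/10 vs 0/10: two-sided exact p = 2/C(20,10)
        a = _expr_from({"Mpo": [1.0] * 10, "Elane": [0.0] * 10,
                        "Gata1": [0.0] * 10, "Klf1": [0.0] * 10}, PANEL)
        b = _expr_from({"Mpo": [0.0] * 10, "Elane": [0.0] * 10,
                        "Gata1": [0.0] * 10, "Klf1": [0.0] * 10}, PANEL,
                       "KLG")
        c = ct.compare_genotypes(a, b, "Mpo")
        assert c.p_frequency == pytest.approx(2 / 184756, rel=1e-9)

    def test_all_tied_values_give_p_one(self):
        a = _expr_from({"Mpo": [0.5] * 3, "Elane": [0.0] * 3,
                        "Gata1": [0.0] * 3, "Klf1": [0.0] * 3}, PANEL)
        c = ct.compare_genotypes(a, a, "Mpo")
        assert c.p_expression == 1.0
        assert c.p_combined == 1.0

    def test_absent_gene_and_tiny_samples_rejected(self):
        a = _expr_from({"Mpo": [0.5, 0.1], "Elane": [0.0, 0.0],
                        "Gata1": [0.0, 0.1], "Klf1": [0.0, 0.0]}, PANEL)
        with pytest.raises(ValueError, match="absent"):
            ct.compare_genotypes(a, a, "Nope")
        single = _expr_from({"Mpo": [0.5], "Elane": [0.0],
                             "Gata1": [0.0], "Klf1": [0.0]}, PANEL)
        with pytest.raises(ValueError, match="at least 2"):
            ct.compare_genotypes(a, single, "Mpo")

    def test_shifted_expression_detected_as_significant(self):
        rng = np.random.default_rng(3)
        a_vals = rng.lognormal(0, 0.3, 40)
        b_vals = rng.lognormal(1.5, 0.3, 40)
        a = _expr_from({"Mpo": a_vals, "Elane": [0.0] * 40,
                        "Gata1": [0.0] * 40, "Klf1": [0.0] * 40}, PANEL)
        b = _expr_from({"Mpo": b_vals, "Elane": [0.0] * 40,
                        "Gata1": [0.0] * 40, "Klf1": [0.0] * 40}, PANEL,
                       "KLG")
        c = ct.compare_genotypes(a, b, "Mpo")
        assert c.p_expression < 1e-6
        assert c.p_combined < 1e-4

    def test_compare_all_genes_table(self, qc_expression):
        a = ct.split_by_genotype(qc_expression, "A")
        b = ct.split_by_genotype(qc_expression, "B")
        out = ct.compare_all_genes(a, b)
        panel = qc_expression.panel
        assert set(out.index) == set(panel.myeloid + panel.erythroid)
        assert ((out > 0) & (out <= 1)).all().all()
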