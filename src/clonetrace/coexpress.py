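"""Lineage co-expression scoring and genotype comparison.

Per cell (or colony) the number of detected myeloid and erythroid panel
genes summarises lineage priming; the population-level erythroid-to-
myeloid expression-frequency ratio R compares the two programs. Per gene,
genotypes are compared on two axes — expression level (rank-sum test on
2^-dCt values, zeros included) and detection frequency (Fisher's exact
test on the 2x2 detected/undetected table) — and the two p-values are
combined by Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import ExpressionMatrix, GenePanel


def count_coexpression(
    expr: ExpressionMatrix, panel: GenePanel | None = None
) -> pd.DataFrame:
    """Per-cell counts of detected myeloid and erythroid panel genes.

    Returns a DataFrame (one row per cell) with ``n_myeloid``,
    ``n_erythroid`` and the cell's genotype — the scatter-ready summary of
    lineage co-expression.
    """
    panel = panel or expr.panel
    for gene in panel.myeloid + panel.erythroid:
        if gene not in expr.detected.columns:
            raise ValueError(f"panel gene {gene!r} absent from expression matrix")
    return pd.DataFrame(
        {
            "n_myeloid": expr.detected[list(panel.myeloid)].sum(axis=1),
            "n_erythroid": expr.detected[list(panel.erythroid)].sum(axis=1),
            "genotype": expr.genotype,
        }
    )


def genotype_means(coexpr: pd.DataFrame) -> pd.DataFrame:
    """Mean detected-gene counts per genotype from count_coexpression output."""
    return coexpr.groupby("genotype")[["n_myeloid", "n_erythroid"]].mean()


def frequency_ratio(
    expr: ExpressionMatrix,
    panel: GenePanel | None = None,
    definition: str = "gene_mean",
) -> float:
    """Erythroid-to-myeloid expression-frequency ratio R.

    ``gene_mean`` (default): mean over erythroid genes of the fraction of
    cells detecting the gene, divided by the same mean over myeloid genes.
    ``pooled``: total erythroid detections over (cells x erythroid panel
    size), divided by the analogous myeloid quantity. The two coincide for
    complete (no-missing-assay) panels. Returns NaN when the myeloid
    denominator is zero.
    """
    panel = panel or expr.panel
    if not panel.myeloid or not panel.erythroid:
        raise ValueError("both lineage panels must be non-empty")
    if definition not in ("gene_mean", "pooled"):
        raise ValueError(f"unknown ratio definition {definition!r}")
    ery = expr.detected[list(panel.erythroid)]
    mye = expr.detected[list(panel.myeloid)]
    if definition == "gene_mean":
        num = ery.mean(axis=0).mean()
        den = mye.mean(axis=0).mean()
    else:
        num = ery.to_numpy().sum() / ery.size
        den = mye.to_numpy().sum() / mye.size
    if den == 0:
        return float("nan")
    return float(num / den)


def detection_frequencies(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene detection frequency split by genotype."""
    return expr.detected.groupby(expr.genotype).mean()


def fishers_method(p_values: Sequence[float]) -> float:
    """Combine independent p-values: chi2 = -2 sum(ln p), df = 2k.

    The combined p is the upper chi-square tail of the summed statistic.
    For a single input the identity holds exactly (df=2 upper tail at
    -2 ln p equals p).
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("at least one p-value required")
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(chi2, df=2 * ps.size))


@dataclass(frozen=True)
class GenotypeComparison:
    """Per-gene two-axis genotype comparison with the combined p-value."""

    gene: str
    p_expression: float    # rank-sum test on 2^-dCt values (zeros included)
    p_frequency: float     # Fisher's exact test on detected/undetected 2x2
    p_combined: float      # Fisher's-method combination of the two

    def __post_init__(self) -> None:
        for p in (self.p_expression, self.p_frequency, self.p_combined):
            if not 0 < p <= 1:
                raise ValueError("p-values must lie in (0, 1]")


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0  # all values tied: no location difference measurable
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def compare_genotypes(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    gene: str,
) -> GenotypeComparison:
    """Compare one gene between two genotypes on level and frequency.

    Expression: two-sided rank-sum test on the 2^-dCt values with
    undetected cells included as zeros (detection differences are part of
    the expression difference). Frequency: two-sided Fisher's exact test
    on the 2x2 detected/undetected table; a degenerate table gives p = 1.
    The two p-values are combined by Fisher's method.
    """
    for e in (expr_a, expr_b):
        if gene not in e.values.columns:
            raise ValueError(f"gene {gene!r} absent from expression matrix")
        if len(e.cells) < 2:
            raise ValueError("each genotype needs at least 2 retained cells")
    a = expr_a.values[gene].to_numpy(dtype=float)
    b = expr_b.values[gene].to_numpy(dtype=float)
    p_expr = min(_rank_sum_p(a, b), 1.0)
    det_a = int(expr_a.detected[gene].sum())
    det_b = int(expr_b.detected[gene].sum())
    table = [[det_a, len(a) - det_a], [det_b, len(b) - det_b]]
    p_freq = float(stats.fisher_exact(table, alternative="two-sided")[1])
    p_expr = max(p_expr, np.finfo(float).tiny)
    p_freq = min(max(p_freq, np.finfo(float).tiny), 1.0)
    return GenotypeComparison(
        gene=gene,
        p_expression=p_expr,
        p_frequency=p_freq,
        p_combined=max(fishers_method([p_expr, p_freq]), np.finfo(float).tiny),
    )


def compare_all_genes(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run compare_genotypes over a gene list (default: both lineage panels)."""
    if genes is None:
        panel = expr_a.panel
        genes = list(panel.myeloid) + list(panel.erythroid)
    rows = []
    for gene in genes:
        c = compare_genotypes(expr_a, expr_b, gene)
        rows.append(
            {
                "gene": c.gene,
                "p_expression": c.p_expression,
                "p_frequency": c.p_frequency,
                "p_combined": c.p_combined,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def split_by_genotype(
    expr: ExpressionMatrix, genotype: str
) -> ExpressionMatrix:
    """Restrict an expression matrix to the cells of one genotype."""
    mask = expr.genotype == genotype
    if not mask.any():
        raise ValueError(f"no cells with genotype {genotype!r}")
    return ExpressionMatrix(
        values=expr.values.loc[mask],
        detected=expr.detected.loc[mask],
        genotype=expr.genotype.loc[mask],
        panel=expr.panel,
    )
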