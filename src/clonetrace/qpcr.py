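"""Multiplex qRT-PCR QC and housekeeping normalization.

Raw Biomark-style Ct tables (cells/colonies x gene assays) are turned into
linear-scale relative expression: assays flagged "Fail" are set to the
undetected sentinel (Ct = 999), cells failing a housekeeping Ct cutoff are
removed, and detected Ct values are normalized to the mean of the
housekeeping genes as 2^-dCt. Undetected assays map to expression 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel Ct for undetected / failed assays; strictly above any real Ct.
UNDETECTED_CT = 999.0

#: Upper bound on real Ct values (instrument cycle count).
MAX_CT = 40.0

_FAIL_TOKENS = {"fail", "failed"}


@dataclass(frozen=True)
class GenePanel:
    """Gene-to-lineage role assignment for a qPCR assay panel."""

    myeloid: tuple[str, ...]
    erythroid: tuple[str, ...]
    housekeeping: tuple[str, ...]
    other: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        genes = self.myeloid + self.erythroid + self.housekeeping + self.other
        if len(set(genes)) != len(genes):
            raise ValueError("a gene may appear in only one panel role")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.myeloid + self.erythroid + self.housekeeping + self.other

    def role_of(self, gene: str) -> str:
        for role in ("myeloid", "erythroid", "housekeeping", "other"):
            if gene in getattr(self, role):
                return role
        raise KeyError(gene)


#: Neutrophil/myeloid and erythroid TF/effector assay panels used for the
#: colony and single-cell lineage scoring, with Hprt/Gapdh as references.
DEFAULT_PANEL = GenePanel(
    myeloid=("Cebpa", "Cebpe", "Ctsg", "Elane", "Mpo", "Prtn3", "Sfpi1", "Gfi1"),
    erythroid=("Gata1", "Gata2", "Zfpm1", "Gfi1b", "Gypa", "Klf1"),
    housekeeping=("Hprt",),
)

TWO_HK_PANEL = replace(DEFAULT_PANEL, housekeeping=("Gapdh", "Hprt"))


@dataclass(frozen=True)
class CtTable:
    """Raw Ct values with the undetected sentinel and per-cell genotype."""

    ct: pd.DataFrame           # cells x genes, float; sentinel = UNDETECTED_CT
    genotype: pd.Series        # per-cell genotype label
    panel: GenePanel
    qc_applied: bool = False

    def __post_init__(self) -> None:
        detected = self.ct[self.ct < UNDETECTED_CT]
        bad = (detected <= 0) | (detected > MAX_CT)
        if bad.any().any():
            raise ValueError("detected Ct values must lie in (0, 40]")
        missing = set(self.panel.housekeeping) - set(self.ct.columns)
        if missing:
            raise ValueError(f"housekeeping assays missing: {sorted(missing)}")

    @property
    def cells(self) -> pd.Index:
        return self.ct.index

    @property
    def genes(self) -> pd.Index:
        return self.ct.columns

    def detected_mask(self) -> pd.DataFrame:
        return self.ct < UNDETECTED_CT


def load_ct(
    source,
    panel: GenePanel = DEFAULT_PANEL,
    genotype_column: str = "genotype",
) -> CtTable:
    """Read a Ct CSV (cells x genes) into a :class:`CtTable`.

    Entries may be numeric Ct values or the literal ``Fail`` (any case),
    which is mapped to the undetected sentinel. A ``genotype`` column is
    attached as metadata when present. Cells and genes keep input order.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, index_col=0)
    if df.empty:
        raise ValueError("Ct table is empty")
    if genotype_column in df.columns:
        genotype = df[genotype_column].astype(str)
        df = df.drop(columns=[genotype_column])
    else:
        genotype = pd.Series("unknown", index=df.index, name="genotype")
    missing = set(panel.housekeeping) - set(df.columns)
    if missing:
        raise ValueError(f"housekeeping column(s) missing: {sorted(missing)}")

    def _parse(value, cell, gene):
        if isinstance(value, str):
            if value.strip().lower() in _FAIL_TOKENS:
                return UNDETECTED_CT
            try:
                return float(value)
            except ValueError:
                raise ValueError(
                    f"non-numeric entry {value!r} at cell {cell!r}, gene {gene!r}"
                ) from None
        return float(value)

    parsed = pd.DataFrame(
        [
            [_parse(df.at[cell, gene], cell, gene) for gene in df.columns]
            for cell in df.index
        ],
        index=df.index,
        columns=df.columns,
        dtype=float,
    )
    genotype.name = "genotype"
    return CtTable(ct=parsed, genotype=genotype, panel=panel)


def housekeeping_qc(
    table: CtTable, cutoff: float
) -> tuple[CtTable, dict]:
    """Drop cells whose housekeeping assays miss the Ct cutoff.

    A cell is removed iff any housekeeping assay is undetected/Fail or has
    Ct strictly above ``cutoff`` (a cell exactly at the cutoff passes).
    Returns the filtered table and a QC report with per-cell drop reasons
    and a binned histogram of housekeeping Ct values to support cutoff
    choice.
    """
    if not 0 < cutoff <= MAX_CT:
        raise ValueError("cutoff must lie in (0, 40]")
    hk = table.ct[list(table.panel.housekeeping)]
    undetected = (hk >= UNDETECTED_CT).any(axis=1)
    too_high = ((hk > cutoff) & (hk < UNDETECTED_CT)).any(axis=1)
    drop = undetected | too_high
    reasons = {
        str(cell): ("housekeeping undetected" if undetected[cell]
                    else "housekeeping Ct above cutoff")
        for cell in table.cells[drop]
    }
    detected_hk = hk.to_numpy()[hk.to_numpy() < UNDETECTED_CT]
    if detected_hk.size:
        edges = np.arange(np.floor(detected_hk.min()),
                          np.ceil(detected_hk.max()) + 1.0)
        counts, edges = np.histogram(detected_hk, bins=edges if len(edges) > 1
                                     else 1)
    else:
        counts, edges = np.array([], dtype=int), np.array([])
    report = {
        "cutoff": cutoff,
        "n_input_cells": int(len(table.cells)),
        "n_retained_cells": int((~drop).sum()),
        "dropped": reasons,
        "housekeeping_histogram": {
            "bin_edges": [float(e) for e in edges],
            "counts": [int(c) for c in counts],
        },
    }
    kept = table.ct.loc[~drop]
    if kept.empty:
        import warnings

        warnings.warn("housekeeping QC removed every cell", stacklevel=2)
    return (
        CtTable(
            ct=kept,
            genotype=table.genotype.loc[~drop],
            panel=table.panel,
            qc_applied=True,
        ),
        report,
    )


def suggest_hk_cutoff(table: CtTable, bin_width: float = 1.0) -> float:
    """Propose a housekeeping Ct cutoff from the histogram.

    Returns the right edge of the deepest valley between the two largest
    modes of the pooled housekeeping Ct histogram; if the histogram is
    unimodal, falls back to the 99.5th percentile of detected values.
    An explicit cutoff chosen by inspection always takes precedence.
    """
    hk = table.ct[list(table.panel.housekeeping)].to_numpy()
    values = hk[hk < UNDETECTED_CT]
    if values.size == 0:
        raise ValueError("no detected housekeeping Ct values")
    edges = np.arange(np.floor(values.min()),
                      np.ceil(values.max()) + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    peaks = [
        i for i in range(len(counts))
        if counts[i] > 0
        and (i == 0 or counts[i] >= counts[i - 1])
        and (i == len(counts) - 1 or counts[i] >= counts[i + 1])
    ]
    if len(peaks) < 2:
        return float(np.quantile(values, 0.995))
    top_two = sorted(sorted(peaks, key=lambda i: counts[i])[-2:])
    lo, hi = top_two
    valley = lo + int(np.argmin(counts[lo:hi + 1]))
    return float(edges[valley + 1])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Housekeeping-normalized relative expression (2^-dCt) with detection calls."""

    values: pd.DataFrame       # cells x genes, >= 0; 0 where undetected
    detected: pd.DataFrame     # boolean detection calls
    genotype: pd.Series
    panel: GenePanel

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def cells(self) -> pd.Index:
        return self.values.index


def normalize_expression(table: CtTable) -> ExpressionMatrix:
    """Convert QC-passed Ct values to 2^-dCt relative expression.

    Per cell, dCt = Ct_gene - mean(Ct over housekeeping assays); detected
    genes map to 2^-dCt, undetected genes to 0. Housekeeping assays must
    all be detected, i.e. :func:`housekeeping_qc` must run first.
    """
    hk = table.ct[list(table.panel.housekeeping)]
    if (hk >= UNDETECTED_CT).any().any():
        raise ValueError(
            "housekeeping sentinel values present; run housekeeping_qc first"
        )
    href = hk.mean(axis=1)
    detected = table.detected_mask()
    values = np.power(2.0, -(table.ct.sub(href, axis=0)))
    values = values.where(detected, 0.0)
    return ExpressionMatrix(
        values=values,
        detected=detected,
        genotype=table.genotype,
        panel=table.panel,
    )


def center_for_display(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean-centered values for heatmap display.

    Subtracts each gene's mean across retained cells; detection flags are
    untouched (use ``expr.detected``).
    """
    if expr.values.empty:
        raise ValueError("expression matrix is empty")
    return expr.values - expr.values.mean(axis=0)


def remove_outliers(
    expr: ExpressionMatrix, k: float = 5.0
) -> tuple[ExpressionMatrix, dict]:
    """Optional robust outlier filter on detected expression values.

    A detected value is marked undetected (value 0) when it is more than
    ``k`` scaled median absolute deviations from its gene's median of
    detected values. Off by default in the pipelines; when used, removals
    are itemised in the returned report.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    values = expr.values.copy()
    detected = expr.detected.copy()
    removed: dict[str, list[str]] = {}
    for gene in values.columns:
        col = values[gene]
        mask = detected[gene]
        obs = col[mask]
        if len(obs) < 3:
            continue
        med = obs.median()
        mad = 1.4826 * (obs - med).abs().median()
        if mad == 0:
            continue
        outlier = mask & ((col - med).abs() > k * mad)
        if outlier.any():
            removed[gene] = [str(c) for c in values.index[outlier]]
            values.loc[outlier, gene] = 0.0
            detected.loc[outlier, gene] = False
    report = {"k_mad": k, "removed": removed,
              "n_removed": int(sum(len(v) for v in removed.values()))}
    return (
        ExpressionMatrix(values=values, detected=detected,
                         genotype=expr.genotype, panel=expr.panel),
        report,
    )
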