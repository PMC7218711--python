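"""End-to-end reproducible runs composing the analysis stages.

Two pipelines mirror the two assays: the barcode pipeline (simulate or
load reads -> extract -> depth filter -> 2-way and 3-way overlap tests ->
Venn accounting) and the qPCR pipeline (simulate or load Ct -> QC ->
normalize -> co-expression and genotype comparisons). Every output embeds
the root seed and a hash of the configuration; all randomness flows from
the root seed, split deterministically per stage, so re-running a config
reproduces results exactly (Monte-Carlo stages included).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpress, extract, overlap, qpcr, simulate
from .patterns import DEFAULT_BARCODE_PATTERN, DEFAULT_LIBRARY_SIZE

logger = logging.getLogger("clonetrace")


def split_seed(root_seed: int, n: int) -> list[int]:
    """Derive n independent per-stage seeds (< 2^31) from one root seed."""
    state = np.random.SeedSequence(root_seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _config_hash(config: dict) -> str:
    # the output location is not part of the run's identity
    canon = json.dumps({k: v for k, v in config.items() if k != "out_dir"},
                       sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump({**meta, **payload}, fh, indent=2, sort_keys=True)
        fh.write("\n")


@dataclass(frozen=True)
class RunConfig:
    """Parameters for one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "clonetrace_out"
    # barcode stage
    simulate_clones: bool = True
    n_clones: int = 400
    fate_probs: dict = field(
        default_factory=lambda: dict(
            simulate.CloneSimConfig().fate_probs
        )
    )
    depths: dict = field(
        default_factory=lambda: dict(simulate.CloneSimConfig().depths)
    )
    error_rate: float = 0.005
    library_size: int = DEFAULT_LIBRARY_SIZE
    fastq_by_sample: dict = field(default_factory=dict)
    whitelist_path: str | None = None
    filter_mode: str = "normalized"
    scan_rc: bool = False
    mc_iterations: int = 1_000_000
    pool: str = "union"            # union | library | an integer
    # qPCR stage
    simulate_ct: bool = True
    hk_cutoff: float | None = 21.0
    outlier_mad_k: float | None = None
    ratio_definition: str = "gene_mean"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _log_stage(name: str, t0: float, **counts) -> None:
    extra = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.2fs %s", name, time.time() - t0, extra)


def run_barcode_pipeline(config: RunConfig) -> dict:
    """Extraction + depth filter + overlap statistics, end to end.

    With ``simulate_clones`` a synthetic transplantation is generated
    (whitelist, clone fates, reads); otherwise FASTQ paths and a whitelist
    file must be supplied. Persists the count table, the filtered barcode
    sets, Venn region counts and the 2-way/3-way overlap results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": _config_hash(config.to_dict())}
    seeds = split_seed(config.seed, 4)

    t0 = time.time()
    if config.simulate_clones:
        whitelist = simulate.make_whitelist(
            DEFAULT_BARCODE_PATTERN, config.library_size, seed=seeds[0]
        )
        clone_cfg = simulate.CloneSimConfig(
            n_clones=config.n_clones,
            fate_probs=dict(config.fate_probs),
            depths=dict(config.depths),
            error_rate=config.error_rate,
            seed=seeds[1],
        )
        clones = simulate.simulate_clones(clone_cfg, whitelist)
        reads = simulate.simulate_reads(
            clones, clone_cfg.depths, clone_cfg.error_rate, seed=seeds[2]
        )
        clones.to_csv(out / "clone_truth.csv", index=False)
        _log_stage("simulate", t0, n_clones=len(clones),
                   n_reads=sum(map(len, reads.values())))
    else:
        if not config.fastq_by_sample or config.whitelist_path is None:
            raise ValueError(
                "fastq_by_sample and whitelist_path are required "
                "when simulate_clones is off"
            )
        whitelist = simulate.BarcodeWhitelist.from_file(config.whitelist_path)
        reads = dict(config.fastq_by_sample)

    t0 = time.time()
    table = extract.count_barcodes(
        reads, DEFAULT_BARCODE_PATTERN, whitelist, scan_rc=config.scan_rc
    )
    table.counts.to_csv(out / "barcode_counts.csv")
    table.qc_summary().to_csv(out / "extraction_qc.csv")
    _log_stage("extract", t0, matched=int(table.matched_reads.sum()))

    sets = extract.depth_floor_filter(table, mode=config.filter_mode)
    by_label = {s.sample: s.barcodes for s in sets}
    _write_json(out / "barcode_sets.json", extract.barcode_sets_to_json(sets), meta)

    t0 = time.time()
    labels = list(by_label)
    union = frozenset().union(*by_label.values())
    if config.pool == "union":
        pool3 = len(union)
    elif config.pool == "library":
        pool3 = len(whitelist)
    else:
        pool3 = int(config.pool)
    results = {}
    # 2-way tests from the library pool, pairwise
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            res = overlap.hypergeom_overlap_p(
                N=len(whitelist), nA=len(by_label[a]), nB=len(by_label[b]),
                k=len(by_label[a] & by_label[b]), labels=(a, b),
            )
            results[f"two_way_{a}_{b}"] = res.to_dict()
    if len(labels) == 3:
        sizes = [len(by_label[l]) for l in labels]
        k3 = len(by_label[labels[0]] & by_label[labels[1]] & by_label[labels[2]])
        mc = overlap.multiway_overlap_p_mc(
            pool3, sizes, k3, M=config.mc_iterations, seed=seeds[3],
            labels=tuple(labels),
        )
        results["three_way"] = mc.to_dict()
        results["three_way_exact"] = overlap.multiway_overlap_p_exact(
            pool3, sizes, k3, labels=tuple(labels)
        ).to_dict()
    venn = overlap.venn_counts(by_label)
    _write_json(out / "venn_counts.json", venn, meta)
    _write_json(out / "overlap_results.json", results, meta)
    _log_stage("overlap", t0, n_sets=len(labels))
    return {"meta": meta, "sets": by_label, "venn": venn, "overlap": results}


def run_qpcr_pipeline(config: RunConfig, ct_source=None,
                      ct_sim_config: simulate.CtSimConfig | None = None) -> dict:
    """Ct QC + normalization + co-expression statistics, end to end.

    With ``simulate_ct`` two genotype conditions are generated (a
    myeloid-committed WT-like and an erythroid-shifted mutant-like
    detection pattern, 300 cells each); otherwise pass ``ct_source`` (CSV
    path or DataFrame). ``hk_cutoff`` must be set explicitly (or use
    :func:`clonetrace.qpcr.suggest_hk_cutoff`).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": _config_hash(config.to_dict())}
    seeds = split_seed(config.seed, 2)

    if config.hk_cutoff is None:
        raise ValueError(
            "hk_cutoff is not set: choose a housekeeping Ct cutoff from the "
            "histogram (see qpcr.suggest_hk_cutoff) and pass it explicitly"
        )
    t0 = time.time()
    if ct_source is not None:
        table = qpcr.load_ct(ct_source)
    elif config.simulate_ct:
        if ct_sim_config is None:
            wt = simulate.lineage_bias_ct_config(
                erythroid_p=0.1, myeloid_p=0.9, genotype="WT",
                n_cells=300, seed=seeds[0],
            )
            mut = simulate.lineage_bias_ct_config(
                erythroid_p=0.5, myeloid_p=0.6, genotype="KLG",
                n_cells=300, seed=seeds[1],
            )
            sims = [simulate.simulate_ct_table(c) for c in (wt, mut)]
            ct = pd.concat([s.ct for s in sims])
            genotype = pd.concat([s.genotype for s in sims])
            table = qpcr.CtTable(ct=ct, genotype=genotype, panel=wt.panel)
        else:
            sim = simulate.simulate_ct_table(ct_sim_config)
            table = qpcr.CtTable(
                ct=sim.ct, genotype=sim.genotype, panel=sim.panel
            )
    else:
        raise ValueError("a Ct table source is required when simulate_ct is off")
    _log_stage("load_ct", t0, n_cells=len(table.cells))

    t0 = time.time()
    table, qc_report = qpcr.housekeeping_qc(table, cutoff=config.hk_cutoff)
    _write_json(out / "qc_report.json", qc_report, meta)
    expr = qpcr.normalize_expression(table)
    if config.outlier_mad_k is not None:
        expr, outlier_report = qpcr.remove_outliers(expr, k=config.outlier_mad_k)
        _write_json(out / "outlier_report.json", outlier_report, meta)
    expr.values.to_csv(out / "expression.csv")
    _log_stage("qc_normalize", t0, n_retained=len(expr.cells))

    t0 = time.time()
    coexpr = coexpress.count_coexpression(expr)
    coexpr.to_csv(out / "coexpression.csv")
    genotypes = list(dict.fromkeys(expr.genotype))
    ratios = {
        gt: coexpress.frequency_ratio(
            coexpress.split_by_genotype(expr, gt),
            definition=config.ratio_definition,
        )
        for gt in genotypes
    }
    summary = {
        "ratio_definition": config.ratio_definition,
        "frequency_ratio": ratios,
        "mean_counts": genotype_means_dict(coexpr),
    }
    comparisons = None
    if len(genotypes) == 2:
        comparisons = coexpress.compare_all_genes(
            coexpress.split_by_genotype(expr, genotypes[0]),
            coexpress.split_by_genotype(expr, genotypes[1]),
        )
        comparisons.to_csv(out / "genotype_comparison.csv")
    _write_json(out / "coexpression_summary.json", summary, meta)
    _log_stage("coexpress", t0, n_genotypes=len(genotypes))
    return {
        "meta": meta,
        "expression": expr,
        "coexpression": coexpr,
        "summary": summary,
        "comparisons": comparisons,
    }


def genotype_means_dict(coexpr: pd.DataFrame) -> dict:
    means = coexpress.genotype_means(coexpr)
    return {
        gt: {"n_myeloid": float(row["n_myeloid"]),
             "n_erythroid": float(row["n_erythroid"])}
        for gt, row in means.iterrows()
    }
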