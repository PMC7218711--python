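"""Synthetic data with known ground truth.

Two generators mirror the two experimental assays this package analyses:

* barcoded-clone amplicon sequencing — a whitelist of legal barcodes, a
  clone population with per-clone lineage fate (which of the three sorted
  populations NMP / MB / EB the clone contributes to) and log-normal
  clonal expansion, and per-sample FASTQ reads with i.i.d. substitution
  errors;
* multiplex qRT-PCR — per-cell per-gene Ct values with configurable
  detection probabilities, normal Ct distributions, and a "Fail" rate for
  assays discarded by instrument QC.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .patterns import BASES, DegeneratePattern, DEFAULT_BARCODE_PATTERN
from .qpcr import UNDETECTED_CT, GenePanel, DEFAULT_PANEL

POPULATIONS = ("NMP", "MB", "EB")

#: Clone fates: every clone self-renews in the NMP compartment; uni- and
#: bi-lineage output adds MB and/or EB membership.
FATES = ("NMP", "NMP+MB", "NMP+EB", "NMP+MB+EB")

_FATE_POPS = {
    "NMP": ("NMP",),
    "NMP+MB": ("NMP", "MB"),
    "NMP+EB": ("NMP", "EB"),
    "NMP+MB+EB": ("NMP", "MB", "EB"),
}


@dataclass(frozen=True)
class BarcodeWhitelist:
    """The finite pool of legal barcodes (725 in the reference library)."""

    barcodes: tuple[str, ...]
    pattern: DegeneratePattern = DEFAULT_BARCODE_PATTERN

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("whitelist entries must be unique")
        for b in self.barcodes:
            if not self.pattern.matches(b):
                raise ValueError(f"whitelist entry {b!r} does not match pattern")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in set(self.barcodes)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")

    @classmethod
    def from_file(cls, path, pattern: DegeneratePattern = DEFAULT_BARCODE_PATTERN):
        with open(path) as fh:
            barcodes = tuple(line.strip() for line in fh if line.strip())
        return cls(barcodes, pattern)


def make_whitelist(
    pattern: DegeneratePattern = DEFAULT_BARCODE_PATTERN,
    n: int = 725,
    seed: int = 0,
) -> BarcodeWhitelist:
    """Draw ``n`` distinct barcodes conforming to ``pattern``.

    Sampling is uniform over the ``4**n_degenerate`` conforming sequences;
    when ``n`` equals the capacity the whitelist is the full combinatorial
    space.
    """
    capacity = pattern.capacity
    if n <= 0:
        raise ValueError("whitelist size must be positive")
    if n > capacity:
        raise ValueError(
            f"requested {n} barcodes but the pattern admits only {capacity}"
        )
    rng = np.random.default_rng(seed)
    if capacity <= 1_000_000:
        idx = rng.choice(capacity, size=n, replace=False)
    else:
        # rejection sampling; collisions are vanishingly rare at this scale
        chosen: set[int] = set()
        while len(chosen) < n:
            draw = rng.integers(0, capacity, size=n - len(chosen))
            chosen.update(int(d) for d in draw)
        idx = np.fromiter(sorted(chosen), dtype=np.int64)
        rng.shuffle(idx)
    return BarcodeWhitelist(tuple(pattern.fill(int(i)) for i in idx), pattern)


@dataclass(frozen=True)
class CloneSimConfig:
    """Ground-truth configuration for a simulated barcoding transplantation.

    Defaults model a transplant in which 400 of the 725 library barcodes
    engraft, 30% of clones are tripotent (self-renewing and feeding both
    blast compartments), clone sizes are log-normal, and each sorted
    population is sequenced to 50k reads with a 0.5% per-base substitution
    rate.
    """

    n_clones: int = 400
    fate_probs: dict[str, float] = field(
        default_factory=lambda: {
            "NMP": 0.40,
            "NMP+MB": 0.15,
            "NMP+EB": 0.15,
            "NMP+MB+EB": 0.30,
        }
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    depths: dict[str, int] = field(
        default_factory=lambda: {"NMP": 50_000, "MB": 50_000, "EB": 50_000}
    )
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if set(self.fate_probs) - set(FATES):
            raise ValueError(f"unknown fate labels: {set(self.fate_probs) - set(FATES)}")
        probs = np.array([self.fate_probs.get(f, 0.0) for f in FATES])
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("fate probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("fate probabilities must sum to 1")
        if any(d <= 0 for d in self.depths.values()):
            raise ValueError("depths must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be non-negative")

    def with_seed(self, seed: int) -> "CloneSimConfig":
        return replace(self, seed=seed)


def simulate_clones(
    config: CloneSimConfig, whitelist: BarcodeWhitelist
) -> pd.DataFrame:
    """Assign barcodes, fates and per-population abundances to clones.

    Returns a DataFrame with columns ``barcode``, ``fate`` and one
    ``abund_<pop>`` column per population. A clone has non-zero abundance
    in a population iff its fate includes that population; the NMP
    abundance is non-zero for every clone (self-renewal).
    """
    if config.n_clones > len(whitelist):
        raise ValueError(
            f"n_clones={config.n_clones} exceeds whitelist size {len(whitelist)}"
        )
    rng = np.random.default_rng(config.seed)
    barcodes = rng.choice(
        np.array(whitelist.barcodes), size=config.n_clones, replace=False
    )
    probs = [config.fate_probs.get(f, 0.0) for f in FATES]
    fates = rng.choice(len(FATES), size=config.n_clones, p=probs)
    table = pd.DataFrame(
        {"barcode": barcodes, "fate": [FATES[i] for i in fates]}
    )
    for pop in POPULATIONS:
        member = np.array(
            [pop in _FATE_POPS[f] for f in table["fate"]], dtype=bool
        )
        abund = np.zeros(config.n_clones)
        abund[member] = rng.lognormal(
            config.lognormal_mu, config.lognormal_sigma, size=int(member.sum())
        )
        table[f"abund_{pop}"] = abund
    return table


DEFAULT_FLANK_5 = "TCGATTAGCAACGGTCAGGT"
DEFAULT_FLANK_3 = "ACCTGACAGTCCAATCGAGT"

_BASE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_TO_IDX[ord(_b)] = _i
_IDX_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def _mutate(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    """Apply i.i.d. substitutions in place; a hit always changes the base."""
    if error_rate == 0:
        return
    mask = rng.random(reads.shape) < error_rate
    n = int(mask.sum())
    if n == 0:
        return
    cur = _BASE_TO_IDX[reads[mask]]
    shift = rng.integers(1, 4, size=n)
    reads[mask] = _IDX_TO_BASE[(cur + shift) % 4]


def simulate_reads(
    clone_table: pd.DataFrame,
    depths: dict[str, int],
    error_rate: float = 0.0,
    seed: int = 0,
    flank5: str = DEFAULT_FLANK_5,
    flank3: str = DEFAULT_FLANK_3,
) -> dict[str, list[str]]:
    """Simulate amplicon reads for each sorted population.

    Each read is ``flank5 + barcode + flank3`` for a clone drawn with
    probability proportional to its abundance in that population, with
    i.i.d. substitutions over the whole read at ``error_rate``. Returns a
    mapping sample -> list of read strings of length ``depth``.
    """
    if clone_table.empty:
        raise ValueError("clone table is empty")
    if any(d <= 0 for d in depths.values()):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    templates = np.vstack(
        [
            np.frombuffer((flank5 + bc + flank3).encode(), dtype=np.uint8)
            for bc in clone_table["barcode"]
        ]
    )
    length = templates.shape[1]
    out: dict[str, list[str]] = {}
    for sample, depth in depths.items():
        abund = clone_table[f"abund_{sample}"].to_numpy(dtype=float)
        total = abund.sum()
        if total <= 0:
            raise ValueError(f"no clone has abundance in population {sample!r}")
        idx = rng.choice(len(clone_table), size=depth, p=abund / total)
        reads = templates[idx].copy()
        _mutate(reads, error_rate, rng)
        flat = reads.reshape(depth, length).view(f"S{length}").ravel()
        out[sample] = [r.decode() for r in flat]
    return out


def write_fastq(reads: list[str], path, quality: str = "I") -> None:
    """Write reads as 4-line FASTQ records with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{quality * len(read)}\n")


@dataclass(frozen=True)
class CtSimConfig:
    """Configuration for synthetic multiplex qRT-PCR Ct matrices.

    ``detection`` maps genotype -> gene -> probability that the assay
    amplifies in a cell of that genotype; ``ct_params`` maps gene ->
    (mean, sd) of the Ct value when detected. An assay is flagged "Fail"
    (instrument QC) with probability ``fail_rate`` regardless of the
    underlying expression state.
    """

    detection: dict[str, dict[str, float]]
    ct_params: dict[str, tuple[float, float]]
    n_cells: dict[str, int]
    fail_rate: float = 0.02
    panel: GenePanel = DEFAULT_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.detection:
            raise ValueError("at least one genotype required")
        for genotype, probs in self.detection.items():
            for gene, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(
                        f"detection probability {p} for {genotype}/{gene} "
                        "outside [0, 1]"
                    )
        for gene, (_, sd) in self.ct_params.items():
            if sd < 0:
                raise ValueError(f"negative Ct sd for gene {gene}")
        if not 0 <= self.fail_rate <= 1:
            raise ValueError("fail_rate must be in [0, 1]")
        if any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("n_cells must be positive")
        if not self.panel.housekeeping:
            raise ValueError("panel must include housekeeping genes")

    def with_seed(self, seed: int) -> "CtSimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedCtData:
    """A synthetic Ct matrix plus its ground truth."""

    ct: pd.DataFrame            # cells x genes; Ct value or UNDETECTED_CT
    fail: pd.DataFrame          # True where the assay was flagged Fail
    truth_detected: pd.DataFrame  # ground-truth expression state
    genotype: pd.Series         # genotype label per cell
    panel: GenePanel

    def to_csv(self, path) -> None:
        """Write the raw table as instrument-style CSV ("Fail" literals)."""
        out = self.ct.astype(object).copy()
        out[self.fail] = "Fail"
        out.insert(0, "genotype", self.genotype)
        out.to_csv(path, index_label="cell")


def simulate_ct_table(config: CtSimConfig) -> SimulatedCtData:
    """Generate a Ct matrix with per-gene detection and Fail dropout.

    Per cell and gene: with probability ``fail_rate`` the assay is marked
    Fail (stored at the undetected sentinel with the fail flag set);
    otherwise the gene is detected with its genotype-specific probability
    and the Ct drawn from the gene's normal distribution (truncated into
    (0, 40]); otherwise undetected (sentinel).
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.ct_params)
    missing = set(config.panel.housekeeping) - set(genes)
    if missing:
        raise ValueError(f"housekeeping genes missing from ct_params: {missing}")
    cells, genotypes = [], []
    for genotype, n in config.n_cells.items():
        cells += [f"{genotype}_{i}" for i in range(n)]
        genotypes += [genotype] * n
    n_total = len(cells)
    ct = np.full((n_total, len(genes)), UNDETECTED_CT)
    fail = rng.random((n_total, len(genes))) < config.fail_rate
    genotype_arr = np.array(genotypes)
    truth = np.zeros((n_total, len(genes)), dtype=bool)
    for j, gene in enumerate(genes):
        mean, sd = config.ct_params[gene]
        for genotype in config.n_cells:
            rows = genotype_arr == genotype
            p = config.detection.get(genotype, {}).get(gene, 0.0)
            expressed = rng.random(int(rows.sum())) < p
            values = np.clip(
                rng.normal(mean, sd, size=int(rows.sum())), 1e-6, 40.0
            )
            col = np.full(int(rows.sum()), UNDETECTED_CT)
            col[expressed] = values[expressed]
            ct[rows, j] = col
            truth[rows, j] = expressed
    ct[fail] = UNDETECTED_CT
    index = pd.Index(cells, name="cell")
    return SimulatedCtData(
        ct=pd.DataFrame(ct, index=index, columns=genes),
        fail=pd.DataFrame(fail, index=index, columns=genes),
        truth_detected=pd.DataFrame(truth & ~fail, index=index, columns=genes),
        genotype=pd.Series(genotypes, index=index, name="genotype"),
        panel=config.panel,
    )


def null_ct_config(
    n_cells: int = 100,
    detection_p: float = 0.5,
    genotypes: tuple[str, str] = ("A", "B"),
    genes: tuple[str, ...] | None = None,
    seed: int = 0,
) -> CtSimConfig:
    """Two genotypes with identical detection — a null for genotype tests."""
    panel = DEFAULT_PANEL
    if genes is None:
        genes = panel.myeloid + panel.erythroid
    ct_params = {g: (25.0, 2.0) for g in genes}
    ct_params.update({hk: (18.0, 1.0) for hk in panel.housekeeping})
    detection = {
        gt: {**{g: detection_p for g in genes},
             **{hk: 1.0 for hk in panel.housekeeping}}
        for gt in genotypes
    }
    return CtSimConfig(
        detection=detection,
        ct_params=ct_params,
        n_cells={gt: n_cells for gt in genotypes},
        panel=GenePanel(
            myeloid=tuple(g for g in genes if g in panel.myeloid),
            erythroid=tuple(g for g in genes if g in panel.erythroid),
            housekeeping=panel.housekeeping,
            other=tuple(
                g for g in genes
                if g not in panel.myeloid and g not in panel.erythroid
            ),
        ),
        seed=seed,
    )


def lineage_bias_ct_config(
    erythroid_p: float,
    myeloid_p: float,
    genotype: str,
    n_cells: int = 300,
    seed: int = 0,
) -> CtSimConfig:
    """One genotype with uniform per-panel detection probabilities.

    ``erythroid_p=0.1, myeloid_p=0.9`` mimics a myeloid-committed (WT-like)
    progenitor; ``erythroid_p=0.5, myeloid_p=0.6`` the erythroid-shifted
    mutant pattern.
    """
    panel = DEFAULT_PANEL
    ct_params = {g: (25.0, 2.0) for g in panel.myeloid + panel.erythroid}
    ct_params.update({hk: (18.0, 1.0) for hk in panel.housekeeping})
    detection = {
        genotype: {
            **{g: myeloid_p for g in panel.myeloid},
            **{g: erythroid_p for g in panel.erythroid},
            **{hk: 1.0 for hk in panel.housekeeping},
        }
    }
    return CtSimConfig(
        detection=detection,
        ct_params=ct_params,
        n_cells={genotype: n_cells},
        panel=panel,
        seed=seed,
    )
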