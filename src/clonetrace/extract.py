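"""Barcode recovery from amplicon reads.

Reads are scanned left-to-right for the first window matching the
degenerate barcode template (fixed anchor bases exact, N any base). Exact
whitelist matches are tallied into a barcode x sample count table;
pattern hits absent from the whitelist are reported as QC only — there is
no error correction or fuzzy matching. Per-population barcode sets come
from a depth-scaled inclusion floor: a barcode needs the relative
abundance equivalent of one read in the shallowest sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .patterns import DegeneratePattern, DEFAULT_BARCODE_PATTERN, reverse_complement
from .simulate import BarcodeWhitelist

_READ_ALPHABET = frozenset("ACGTN")


def scan_read(
    read: str,
    pattern: DegeneratePattern = DEFAULT_BARCODE_PATTERN,
    scan_rc: bool = False,
) -> str | None:
    """Return the first pattern-conforming window of ``read``, or None.

    With ``scan_rc`` the reverse complement is scanned when the forward
    strand yields no match (orientation of the sequenced amplicon is
    library-dependent).
    """
    if not read:
        raise ValueError("read is empty")
    bad = set(read) - _READ_ALPHABET
    if bad:
        raise ValueError(f"read contains invalid characters: {sorted(bad)}")
    m = pattern.regex.search(read)
    if m:
        return m.group(0)
    if scan_rc:
        m = pattern.regex.search(reverse_complement(read))
        if m:
            return m.group(0)
    return None


def _iter_fastq(path) -> Iterable[str]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            for record in SeqIO.parse(fh, "fastq"):
                yield str(record.seq).upper()
    except ValueError as exc:
        raise ValueError(f"unreadable FASTQ record in {path}: {exc}") from exc


def _scan_many(reads: Sequence[str], pattern: DegeneratePattern) -> list[str | None]:
    """First pattern window per read, via one regex pass over joined reads.

    The separator '#' cannot occur inside a match because N compiles to
    [ACGT]; the leftmost match within each read is kept (first-match-wins).
    """
    if not reads:
        return []
    blob = "#".join(reads)
    lengths = np.fromiter((len(r) + 1 for r in reads), dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    hits: list[str | None] = [None] * len(reads)
    for m in pattern.regex.finditer(blob):
        i = int(np.searchsorted(starts, m.start(), side="right")) - 1
        if hits[i] is None:
            hits[i] = m.group(0)
    return hits


@dataclass(frozen=True)
class BarcodeCountTable:
    """Barcode x sample read counts with per-sample scan bookkeeping.

    ``depth`` is the total number of scanned reads per sample and
    ``matched_reads`` the number whose read carried any pattern window
    (whitelisted or not); counts sum to at most ``matched_reads``.
    """

    counts: pd.DataFrame       # whitelist barcodes x samples, int
    depth: pd.Series           # total reads scanned per sample
    matched_reads: pd.Series   # reads with any pattern window per sample

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        total = self.counts.sum(axis=0)
        for sample in self.counts.columns:
            if not (total[sample] <= self.matched_reads[sample] <= self.depth[sample]):
                raise ValueError(
                    f"count bookkeeping violated for sample {sample!r}"
                )

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def qc_summary(self) -> pd.DataFrame:
        """Per-sample scan statistics (depth, pattern hits, whitelist hits)."""
        on_whitelist = self.counts.sum(axis=0)
        return pd.DataFrame(
            {
                "depth": self.depth,
                "matched_reads": self.matched_reads,
                "whitelist_reads": on_whitelist,
                "off_whitelist_reads": self.matched_reads - on_whitelist,
            }
        )


def count_barcodes(
    reads_by_sample: Mapping[str, Sequence[str] | str | Path],
    pattern: DegeneratePattern = DEFAULT_BARCODE_PATTERN,
    whitelist: BarcodeWhitelist | None = None,
    scan_rc: bool = False,
) -> BarcodeCountTable:
    """Tally exact whitelist barcode matches per sample.

    ``reads_by_sample`` maps sample name to either a sequence of read
    strings or a FASTQ path (optionally gzipped). A read contributes one
    count to (barcode, sample) iff its first pattern window equals a
    whitelist entry exactly; reads with an off-whitelist window count
    toward ``matched_reads`` only.
    """
    if whitelist is None or len(whitelist) == 0:
        raise ValueError("a non-empty whitelist is required")
    lookup = {b: i for i, b in enumerate(whitelist.barcodes)}
    counts = np.zeros((len(lookup), len(reads_by_sample)), dtype=np.int64)
    depth, matched = {}, {}
    for j, (sample, source) in enumerate(reads_by_sample.items()):
        if isinstance(source, (str, Path)):
            reads = list(_iter_fastq(source))
        else:
            reads = list(source)
        if scan_rc:
            hits = [scan_read(r, pattern, scan_rc=True) for r in reads]
        else:
            hits = _scan_many(reads, pattern)
        depth[sample] = len(reads)
        matched[sample] = sum(h is not None for h in hits)
        for h in hits:
            if h is not None:
                i = lookup.get(h)
                if i is not None:
                    counts[i, j] += 1
    samples = pd.Index(list(reads_by_sample), name="sample")
    return BarcodeCountTable(
        counts=pd.DataFrame(
            counts, index=pd.Index(whitelist.barcodes, name="barcode"),
            columns=samples,
        ),
        depth=pd.Series(depth, name="depth").reindex(samples),
        matched_reads=pd.Series(matched, name="matched_reads").reindex(samples),
    )


@dataclass(frozen=True)
class BarcodeSet:
    """Barcodes surviving the inclusion filter in one sample."""

    sample: str
    barcodes: frozenset[str]

    def __len__(self) -> int:
        return len(self.barcodes)


def depth_floor_filter(
    table: BarcodeCountTable, mode: str = "normalized"
) -> list[BarcodeSet]:
    """Apply the minimum-representation inclusion rule per sample.

    ``normalized`` (default): with d_min the depth of the shallowest
    sample, barcode b enters sample s iff counts(b,s)/depth(s) >= 1/d_min —
    the relative-abundance floor equivalent to a single read in the
    shallowest sample. ``raw``: iff counts(b,s) >= 1 (the literal one-read
    reading). Raw sets always contain the normalized sets.
    """
    if mode not in ("normalized", "raw"):
        raise ValueError(f"unknown filter mode {mode!r}")
    if (table.depth <= 0).any():
        raise ValueError("all sample depths must be positive")
    d_min = int(table.depth.min())
    sets = []
    for sample in table.samples:
        col = table.counts[sample]
        if mode == "raw":
            keep = col >= 1
        else:
            keep = col / table.depth[sample] >= 1.0 / d_min
        sets.append(BarcodeSet(str(sample), frozenset(col.index[keep])))
    return sets


def barcode_sets_to_json(sets: Sequence[BarcodeSet]) -> dict:
    return {s.sample: sorted(s.barcodes) for s in sets}
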