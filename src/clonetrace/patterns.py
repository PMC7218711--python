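"""Degenerate barcode patterns.

A lentiviral barcode library is built around a degenerate oligo: fixed
anchor bases interleaved with random (N) positions. The template used
throughout this package by default is the 30-mer
``GGNNNACNNNGTNNNTANNNCANNNTGNNN`` (12 fixed anchor bases, 18 N), which is
the structure scanned for in amplicon reads to recover barcode identities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property

_VALID = frozenset("ACGTN")
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePattern:
    """A fixed-length DNA template over {A,C,G,T,N}.

    Fixed positions (A/C/G/T) must match exactly; N positions match any
    base. The number of distinct sequences conforming to the template is
    ``4 ** n_degenerate``.
    """

    template: str

    def __post_init__(self) -> None:
        if not self.template:
            raise ValueError("pattern template must be non-empty")
        bad = set(self.template) - _VALID
        if bad:
            raise ValueError(
                f"pattern template contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.template)

    @cached_property
    def degenerate_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.template) if c == "N")

    @cached_property
    def fixed_positions(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.template) if c != "N")

    @property
    def n_degenerate(self) -> int:
        return len(self.degenerate_positions)

    @property
    def capacity(self) -> int:
        """Number of distinct barcodes conforming to the template."""
        return 4 ** self.n_degenerate

    @cached_property
    def regex(self) -> re.Pattern[str]:
        # N -> [ACGT] (not '.') so scans over joined/annotated text cannot
        # match across record separators.
        return re.compile(self.template.replace("N", "[ACGT]"))

    def matches(self, seq: str) -> bool:
        """Position-wise conformity check for a candidate barcode."""
        if len(seq) != len(self.template):
            return False
        return all(
            t == "N" or t == s for t, s in zip(self.template, seq)
        ) and not (set(seq) - set(BASES))

    def fill(self, digits: int) -> str:
        """Barcode obtained by writing ``digits`` in base 4 into the N slots.

        ``digits`` indexes the conforming sequences (0 .. capacity-1);
        used for uniform sampling of whitelists without materialising the
        full combinatorial space.
        """
        if not 0 <= digits < self.capacity:
            raise ValueError("fill index out of range")
        out = list(self.template)
        for pos in reversed(self.degenerate_positions):
            out[pos] = BASES[digits & 3]
            digits >>= 2
        return "".join(out)


#: Barcode region of the 725-barcode lentiviral library.
DEFAULT_BARCODE_PATTERN = DegeneratePattern("GGNNNACNNNGTNNNTANNNCANNNTGNNN")

#: Library size of the default barcode pool.
DEFAULT_LIBRARY_SIZE = 725
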