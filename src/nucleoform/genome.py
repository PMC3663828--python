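"""Genome assembly container and nucleotide-level utilities.

Sequences are held in memory as uppercase strings over {A, C, G, T, N};
all coordinates in the package are 0-based, half-open.  Conversion to the
1-based inclusive convention used by GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List

import numpy as np

__all__ = [
    "GenomeAssembly",
    "encode_sequence",
    "decode_sequence",
    "reverse_complement",
    "iupac_to_regex",
    "IUPAC_CODES",
]

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = np.array(list("ACGT"))

#: IUPAC degenerate nucleotide alphabet.
IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes: A=0, C=1, G=2, T=3, anything else -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; code -1 decodes to N."""
    chars = np.where(codes >= 0, _CODE_TO_BASE[np.clip(codes, 0, 3)], "N")
    return "".join(chars)


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern (e.g. GTYRAC) into a regex character-class string."""
    parts: List[str] = []
    for sym in pattern.upper():
        try:
            bases = IUPAC_CODES[sym]
        except KeyError:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass
class GenomeAssembly:
    """A multi-chromosome genome held in memory.

    Parameters
    ----------
    sequences
        Mapping chromosome name -> uppercase DNA string.  Insertion order is
        the canonical chromosome order for all per-genome iteration.
    """

    sequences: Dict[str, str]
    _codes: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("chromosome names must be unique")
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}

    @property
    def chrom_names(self) -> List[str]:
        return list(self.sequences)

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def codes(self, chrom: str) -> np.ndarray:
        """Integer-encoded sequence for ``chrom`` (cached)."""
        if chrom not in self._codes:
            self._codes[chrom] = encode_sequence(self.sequences[chrom])
        return self._codes[chrom]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Subsequence [start, end); reverse-complemented when strand is '-'."""
        seq = self.sequences[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq

    def find_pattern(self, chrom: str, pattern: str, both_strands: bool = True) -> List[tuple]:
        """All (start, end) matches of an IUPAC pattern, overlapping matches included.

        With ``both_strands`` the reverse-complement pattern is also scanned on
        the forward strand (equivalent to scanning the reverse strand), and
        duplicate intervals are dropped.
        """
        seq = self.sequences[chrom]
        patterns = {pattern.upper()}
        if both_strands:
            patterns.add(reverse_complement(pattern.upper()))
        hits = set()
        for pat in patterns:
            rx = re.compile(f"(?=({iupac_to_regex(pat)}))")
            for m in rx.finditer(seq):
                hits.add((m.start(), m.start() + len(pat)))
        return sorted(hits)

    def with_sequences(self, sequences: Dict[str, str]) -> "GenomeAssembly":
        """New assembly with some chromosomes replaced."""
        merged = dict(self.sequences)
        merged.update(sequences)
        return GenomeAssembly(merged)
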