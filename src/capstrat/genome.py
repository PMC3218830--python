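"""Reference genome container, FASTA I/O and GC-content utilities.

Sequences are held as uppercase ASCII byte arrays (``numpy.uint8``) so that
windowed GC profiles and k-mer scans over multi-megabase chromosomes stay
vectorised.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .regions import GenomicInterval

__all__ = ["ReferenceGenome", "gc_content", "windowed_gc_fraction"]

_A, _C, _G, _T = (ord(b) for b in "ACGT")


class ReferenceGenome:
    """An in-memory multi-chromosome reference.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to an ASCII ``uint8`` array (uppercased).
    """

    def __init__(self, sequences: dict[str, np.ndarray]):
        self.sequences = {
            name: np.asarray(arr, dtype=np.uint8) for name, arr in sequences.items()
        }

    @classmethod
    def from_strings(cls, sequences: dict[str, str]) -> "ReferenceGenome":
        return cls(
            {
                name: np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
                for name, seq in sequences.items()
            }
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        seqs: dict[str, np.ndarray] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            seqs[record.id] = np.frombuffer(
                str(record.seq).upper().encode("ascii"), dtype=np.uint8
            ).copy()
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        records = [
            SeqRecord(Seq(arr.tobytes().decode("ascii")), id=name, description="")
            for name, arr in self.sequences.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(arr) for name, arr in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.sequences[chrom]

    def seq(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)`` as a string."""
        return self.sequences[chrom][start:end].tobytes().decode("ascii")

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.sequences[chrom][pos])


def gc_content(genome: ReferenceGenome, interval: GenomicInterval) -> float:
    """GC fraction of an interval: (#G + #C) / (#A + #C + #G + #T).

    Ambiguous bases (N etc.) are excluded from the denominator; an interval
    with no unambiguous base has undefined GC and returns NaN.
    """
    if interval.chrom not in genome:
        raise KeyError(f"chromosome {interval.chrom!r} not in reference")
    arr = genome[interval.chrom]
    if interval.end > len(arr):
        raise ValueError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(arr)}"
        )
    window = arr[interval.start : interval.end]
    gc = int(np.count_nonzero((window == _G) | (window == _C)))
    at = int(np.count_nonzero((window == _A) | (window == _T)))
    denom = gc + at
    if denom == 0:
        return math.nan
    return gc / denom


def windowed_gc_fraction(
    genome: ReferenceGenome, chrom: str, window: int = 100
) -> np.ndarray:
    """Per-base GC fraction in a ``window`` bp window centred on each base.

    Windows are truncated at chromosome ends (the divisor shrinks with the
    window). Ambiguous bases count as non-GC; the synthetic reference never
    contains them.
    """
    arr = genome[chrom]
    is_gc = ((arr == _G) | (arr == _C)).astype(np.float64)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(is_gc)))
    n = len(arr)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (window - half), n)
    return (csum[hi] - csum[lo]) / (hi - lo)
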