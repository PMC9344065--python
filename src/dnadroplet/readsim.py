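"""Simplified Illumina-like single-end read simulator.

A deliberately minimal model of short-read sequencing over a pool of
encoded oligos: per sequence, ``ceil(coverage * L / read_nt)`` reads with
uniform start positions, independent per-base substitutions at a fixed
rate (1% by default, the commonly cited short-read error rate), no indels,
and constant base quality. A base counts as *detected* when at least one
read covers its position; substitution errors do not remove coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np

from .codec import SequenceRecord

_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUALITY_CHAR = "I"  # Phred+33 quality 40


class Read(NamedTuple):
    source: str
    start: int
    bases: str
    quality: str


@dataclass(frozen=True)
class ReadSet:
    """Simulated reads plus the per-sequence detected-base fractions."""

    reads: Tuple[Read, ...]
    read_nt: int
    per_sequence_detected: Dict[str, float]

    @property
    def mean_detected(self) -> float:
        values = list(self.per_sequence_detected.values())
        return sum(values) / len(values) if values else 0.0

    @classmethod
    def from_reads(cls, records: Sequence[SequenceRecord], reads: Sequence[Read],
                   read_nt: int) -> "ReadSet":
        detected = {
            rec.id: detected_fraction(rec, [r for r in reads if r.source == rec.id])
            for rec in records
        }
        return cls(tuple(reads), read_nt, detected)


def detected_fraction(record: SequenceRecord, reads: Sequence[Read]) -> float:
    """Fraction of the record's positions covered by at least one read."""
    length = len(record.bases)
    covered = np.zeros(length, dtype=bool)
    for read in reads:
        covered[read.start:read.start + len(read.bases)] = True
    return float(covered.sum()) / length


def simulate_reads(records: Sequence[SequenceRecord], read_nt: int = 150,
                   coverage: float = 20.0, sub_rate: float = 0.01,
                   rng_seed: int = 0) -> ReadSet:
    """Simulate single-end reads over every record.

    Reads are exact-length substrings (the whole sequence when it is
    shorter than ``read_nt``) with iid substitutions to a uniformly chosen
    different base. Deterministic given ``rng_seed``.
    """
    if not records:
        raise ValueError("no sequences to simulate reads from")
    if read_nt < 1:
        raise ValueError("read_nt must be >= 1")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (0.0 <= sub_rate < 1.0):
        raise ValueError("sub_rate must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    reads: List[Read] = []
    detected: Dict[str, float] = {}
    for rec in records:
        length = len(rec.bases)
        rlen = min(read_nt, length)
        n_reads = ceil(coverage * length / read_nt)
        starts = rng.integers(0, length - rlen + 1, size=n_reads)
        src = np.frombuffer(rec.bases.encode("ascii"), dtype=np.uint8)
        codes = np.searchsorted(_CODES, src)  # A,C,G,T are sorted
        windows = np.stack([codes[s:s + rlen] for s in starts])
        if sub_rate > 0.0:
            mask = rng.random(windows.shape) < sub_rate
            offsets = rng.integers(1, 4, size=windows.shape)
            windows = np.where(mask, (windows + offsets) % 4, windows)
        covered = np.zeros(length, dtype=bool)
        quality = _QUALITY_CHAR * rlen
        for s, row in zip(starts, windows):
            bases = _CODES[row].tobytes().decode("ascii")
            reads.append(Read(rec.id, int(s), bases, quality))
            covered[s:s + rlen] = True
        detected[rec.id] = float(covered.sum()) / length
    return ReadSet(tuple(reads), read_nt, detected)


def write_fastq(readset: ReadSet, handle) -> None:
    """Four-line FASTQ records with ``@<source>:<start>`` headers."""
    for read in readset.reads:
        handle.write(f"@{read.source}:{read.start}\n{read.bases}\n+\n{read.quality}\n")


def read_fastq(handle) -> List[Read]:
    """Parse FASTQ written by :func:`write_fastq` back into reads."""
    reads = []
    lines = [ln.rstrip("\n") for ln in handle]
    if len(lines) % 4:
        raise ValueError("truncated FASTQ: record count not a multiple of 4")
    for i in range(0, len(lines), 4):
        header, bases, plus, quality = lines[i:i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ record at line {i + 1}")
        source, _, start = header[1:].rpartition(":")
        reads.append(Read(source, int(start), bases, quality))
    return reads


def write_coverage_tsv(readset: ReadSet, handle) -> None:
    """Per-sequence detected-base fractions, plus the mean."""
    handle.write("sequence\tdetected_fraction\n")
    for name, frac in readset.per_sequence_detected.items():
        handle.write(f"{name}\t{frac:.6f}\n")
    handle.write(f"#mean\t{readset.mean_detected:.6f}\n")
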