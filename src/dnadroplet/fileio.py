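"""Readers and writers: FASTA pools, reference-order tables, fixtures, config.

All text outputs use LF line endings and uppercase bases; readers fold
lowercase input up. The reference-order table is a TSV with two comment
header lines (original byte length and config fingerprint) followed by
``index_fragment<TAB>ordinal`` rows in ordinal order.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import List, Union

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .codec import ReferenceOrderTable, SequenceRecord
from .config import EncodingConfig

PathLike = Union[str, Path]


def write_fasta(records: List[SequenceRecord], path: PathLike) -> None:
    """One FASTA record per oligo, 80-column wrapping, informative header."""
    bio_records = [
        BioSeqRecord(
            Seq(rec.bases),
            id=rec.id,
            description=f"len={len(rec.bases)} group={rec.ordinal}",
        )
        for rec in records
    ]
    with open(path, "w", newline="\n") as handle:
        writer = FastaWriter(handle, wrap=80)
        writer.write_file(bio_records)


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a pool; headers are informative only and never trusted.

    The ``group=`` tag is parsed back when present purely for reporting;
    decoding identifies sequences by their index fragment alone.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        match = re.search(r"\bgroup=(\d+)\b", rec.description or "")
        ordinal = int(match.group(1)) if match else None
        records.append(SequenceRecord(ordinal, str(rec.seq).upper(), rec.id))
    return records


def write_table(table: ReferenceOrderTable, path: PathLike) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write(f"#length={table.original_length}\n")
        handle.write(f"#config={table.fingerprint}\n")
        for bases, ordinal in sorted(table.rows, key=lambda r: r[1]):
            handle.write(f"{bases}\t{ordinal}\n")


def read_table(path: PathLike) -> ReferenceOrderTable:
    length = None
    fingerprint = None
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#length="):
                length = int(line.split("=", 1)[1])
            elif line.startswith("#config="):
                fingerprint = line.split("=", 1)[1]
            elif line.startswith("#"):
                continue
            else:
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 TSV columns")
                rows.append((parts[0].upper(), int(parts[1])))
    if length is None or fingerprint is None:
        raise ValueError(f"{path}: missing #length= or #config= header")
    return ReferenceOrderTable(length, fingerprint, tuple(rows))


def fixture(size: int, seed: int) -> bytes:
    """Deterministic pseudo-random payload bytes for a given (size, seed)."""
    if size < 1:
        raise ValueError("fixture size must be >= 1")
    return np.random.default_rng(seed).bytes(size)


def load_config(path: PathLike | None = None, **overrides) -> EncodingConfig:
    """Build an EncodingConfig from an optional YAML file plus overrides.

    Unknown keys in either source are rejected.
    """
    data = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config file must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    return EncodingConfig.from_dict(data)
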