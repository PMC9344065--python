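"""File preprocessing: split a byte payload into groups of bit segments.

Each group is an independently decodable unit of ``segments_per_group``
fixed-width bit segments (36 bits each at defaults, i.e. 36 bytes per
group). The last group is zero-padded; the original byte length is carried
separately (in the reference-order table header) so padding needs no
in-band signalling. Segments are most-significant-bit-first slices of the
payload stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .config import EncodingConfig
from .exceptions import EncodeError, MissingGroupsError


@dataclass(frozen=True)
class DataGroup:
    """One group: a 0-based ordinal and its ordered bit segments.

    Segments are stored as non-negative integers of ``segment_bits`` width.
    """

    ordinal: int
    segments: Tuple[int, ...]


def pad_and_group(payload: bytes, cfg: EncodingConfig) -> Tuple[List[DataGroup], int]:
    """Split ``payload`` into zero-padded groups in file order.

    Returns the groups plus the original byte length (needed to strip the
    padding on decode).
    """
    if not payload:
        raise EncodeError("nothing to encode")
    gb = cfg.group_bytes
    n_groups = -(-len(payload) // gb)
    padded = payload.ljust(n_groups * gb, b"\x00")
    total_bits = gb * 8
    mask = (1 << cfg.segment_bits) - 1
    groups: List[DataGroup] = []
    for i in range(n_groups):
        value = int.from_bytes(padded[i * gb:(i + 1) * gb], "big")
        segments = tuple(
            (value >> (total_bits - (j + 1) * cfg.segment_bits)) & mask
            for j in range(cfg.segments_per_group)
        )
        groups.append(DataGroup(i, segments))
    return groups, len(payload)


def ungroup(groups: Sequence[DataGroup], original_length: int,
            cfg: EncodingConfig) -> bytes:
    """Reassemble bytes from a complete, gap-free set of groups.

    Inverse of :func:`pad_and_group`: concatenates segment bits and
    truncates to ``original_length``.
    """
    ordered = sorted(groups, key=lambda g: g.ordinal)
    missing = sorted(set(range(len(ordered))) - {g.ordinal for g in ordered})
    if missing:
        raise MissingGroupsError(
            "missing group " + ", ".join(str(m) for m in missing)
        )
    gb = cfg.group_bytes
    if original_length > gb * len(ordered):
        raise MissingGroupsError(
            f"{len(ordered)} groups hold only {gb * len(ordered)} bytes, "
            f"expected {original_length}"
        )
    chunks = []
    for group in ordered:
        value = 0
        for seg in group.segments:
            value = (value << cfg.segment_bits) | seg
        chunks.append(value.to_bytes(gb, "big"))
    return b"".join(chunks)[:original_length]
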