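"""Sequence assembly and pool decoding.

Encoding concatenates one index fragment and seven payload fragments into a
184-nt region, packs it to 46 bytes (4 bases/byte), computes Reed-Solomon
parity over those bytes and appends the parity rendered as 8 nt, giving a
192-nt oligo. Decoding is order-free: each sequence is RS-corrected, its
leading fragment looked up in the reference-order table to recover the group
ordinal, its eight droplets regenerated from their seeds, and the group
solved by GF(2) elimination.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .alphabet import bases_to_bits, bits_to_bases, passes_constraints
from .config import EncodingConfig
from .exceptions import (
    DecodeError,
    MissingGroupsError,
    RSDecodeError,
    UncorrectableSequenceError,
    UndecodableGroupError,
    UnknownIndexError,
)
from .fountain import DegreeDistribution, Droplet, droplet_plan, robust_soliton
from .preprocess import DataGroup, pad_and_group, ungroup
from .rs import rs_protect, rs_recover
from .selection import (
    IndexSelector,
    SelectionResult,
    build_pool,
    enumerate_plans,
    select_group,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceRecord:
    """One output oligo; ``ordinal`` is informative only (may be None)."""

    ordinal: Optional[int]
    bases: str
    id: str


@dataclass(frozen=True)
class ReferenceOrderTable:
    """Decode-side map from index fragment to group ordinal.

    The header carries the original payload length in bytes (padding is not
    signalled in-band) and a fingerprint of the decode-relevant config.
    """

    original_length: int
    fingerprint: str
    rows: Tuple[Tuple[str, int], ...]

    def __post_init__(self):
        ordinals = [o for _, o in self.rows]
        if sorted(ordinals) != list(range(len(self.rows))):
            raise ValueError("table ordinals must be a complete 0..N-1 set")
        if len({b for b, _ in self.rows}) != len(self.rows):
            raise ValueError("index fragments must be unique")

    @property
    def lookup(self) -> Dict[str, int]:
        return dict(self.rows)


@lru_cache(maxsize=8)
def _cached_dist(n: int, c: float, delta: float) -> DegreeDistribution:
    return robust_soliton(n, c, delta)


@lru_cache(maxsize=65536)
def _segment_mask(ordinal: int, index: int, bits: int) -> int:
    """Fixed public whitening mask for one segment.

    Low-entropy payloads (runs of zero bytes, repeated text) would render
    droplets as long homopolymers that the constraint filter rejects
    wholesale, leaving empty pools. XORing every segment with a keyed-hash
    keystream before fountain encoding makes any payload look uniform;
    the mask depends only on (ordinal, segment index), so the decoder
    regenerates and removes it after solving. This is whitening, not
    encryption: the keystream is public and fixed.
    """
    seed = f"dnadroplet-whiten:{ordinal}:{index}".encode()
    digest = hashlib.blake2b(seed, digest_size=16).digest()
    return int.from_bytes(digest, "big") & ((1 << bits) - 1)


def whiten_group(group: DataGroup, cfg: EncodingConfig) -> DataGroup:
    """XOR a group's segments with the fixed keystream (involutive)."""
    return DataGroup(group.ordinal, tuple(
        seg ^ _segment_mask(group.ordinal, j, cfg.segment_bits)
        for j, seg in enumerate(group.segments)
    ))


def pack_bases(dna: str) -> bytes:
    """Pack bases to bytes, 4 bases per byte (big-endian bit pairs)."""
    if len(dna) % 4:
        raise ValueError("sequence length must be a multiple of 4")
    return bytes(
        bases_to_bits(dna[i:i + 4]) for i in range(0, len(dna), 4)
    )


def unpack_bases(data: bytes) -> str:
    """Inverse of :func:`pack_bases`."""
    return "".join(bits_to_bases(b, 8) for b in data)


def assemble(sel: SelectionResult, cfg: EncodingConfig) -> SequenceRecord:
    """Ligate index + payload fragments and append RS parity bases."""
    if not sel.rank_certificate:
        raise ValueError(f"group {sel.ordinal}: rank certificate not satisfied")
    region = sel.index_fragment.bases + "".join(
        f.bases for f in sel.payload_fragments
    )
    message = pack_bases(region)
    codeword = rs_protect(message, cfg.rs_parity_bytes)
    parity_bases = unpack_bases(codeword[len(message):])
    return SequenceRecord(sel.ordinal, region + parity_bases, f"seq-{sel.ordinal}")


def encode_file(payload: bytes,
                cfg: EncodingConfig) -> Tuple[List[SequenceRecord], ReferenceOrderTable]:
    """Full encode pipeline: preprocess, fountain-encode, select, assemble.

    Deterministic given (payload, cfg): one record per group plus the
    reference-order table mapping each index fragment to its ordinal.
    """
    groups, original_length = pad_and_group(payload, cfg)
    dist = _cached_dist(cfg.segments_per_group, cfg.soliton_c, cfg.soliton_delta)
    plans = enumerate_plans(cfg, dist)
    selector = IndexSelector(cfg)
    records: List[SequenceRecord] = []
    rows: List[Tuple[str, int]] = []
    for group in groups:
        pool = build_pool(whiten_group(group, cfg), cfg, dist, plans)
        index_fragment = selector.choose(pool)
        sel = select_group(pool, index_fragment, cfg)
        records.append(assemble(sel, cfg))
        rows.append((index_fragment.bases, group.ordinal))
    table = ReferenceOrderTable(original_length, cfg.fingerprint(), tuple(rows))
    return records, table


def disassemble(bases: str, table: ReferenceOrderTable,
                cfg: EncodingConfig) -> Tuple[int, List[Droplet]]:
    """RS-correct one sequence and recover its ordinal and eight droplets.

    After correction every fragment is re-validated against the biochemical
    constraints; a violation means the RS stage settled on a wrong codeword
    (possible when more errors occurred than the parity can correct) and the
    sequence is reported as uncorrectable rather than passed on.
    """
    if len(bases) != cfg.sequence_nt:
        raise ValueError(
            f"expected a {cfg.sequence_nt}-nt sequence, got {len(bases)} nt"
        )
    try:
        message, n_corrected = rs_recover(pack_bases(bases), cfg.rs_parity_bytes)
    except RSDecodeError as exc:
        raise UncorrectableSequenceError(f"uncorrectable sequence: {exc}") from exc
    region = unpack_bases(message)
    frags = [
        region[i:i + cfg.fragment_nt]
        for i in range(0, cfg.fragment_region_nt, cfg.fragment_nt)
    ]
    for frag in frags:
        if not passes_constraints(frag, cfg):
            raise UncorrectableSequenceError(
                "uncorrectable sequence: corrected fragment violates constraints"
            )
    ordinal = table.lookup.get(frags[0])
    if ordinal is None:
        raise UnknownIndexError("unknown index fragment")
    dist = _cached_dist(cfg.segments_per_group, cfg.soliton_c, cfg.soliton_delta)
    droplets = []
    for frag in frags:
        seed = bases_to_bits(frag[:cfg.seed_nt])
        if seed == 0:
            raise UncorrectableSequenceError(
                "uncorrectable sequence: zero seed after correction"
            )
        degree, members = droplet_plan(seed, cfg.segments_per_group, dist)
        payload = bases_to_bits(frag[cfg.seed_nt:])
        droplets.append(Droplet(seed, degree, members, payload))
    return ordinal, droplets


def solve_group(droplets: Sequence[Droplet], n: int) -> List[int]:
    """Solve the group's GF(2) system for its ``n`` segments.

    Degree-1 rows are peeled first (substituted into the rest); any
    remainder goes through Gaussian elimination on the membership masks
    with the XOR payloads as right-hand sides.
    """
    rows = []
    for d in droplets:
        mask = 0
        for m in d.members:
            if m < 0 or m >= n:
                raise UndecodableGroupError("member index out of range")
            mask |= 1 << m
        rows.append((mask, d.payload_bits))

    solution: Dict[int, int] = {}
    # peeling pass for degree-1 rows
    changed = True
    while changed:
        changed = False
        nxt = []
        for mask, rhs in rows:
            for bit, val in solution.items():
                if mask >> bit & 1:
                    mask ^= 1 << bit
                    rhs ^= val
            if mask == 0:
                continue
            if mask & (mask - 1) == 0:
                solution[mask.bit_length() - 1] = rhs
                changed = True
            else:
                nxt.append((mask, rhs))
        rows = nxt
    if len(solution) < n and rows:
        # full elimination on the residual system
        pivots: Dict[int, Tuple[int, int]] = {}
        for mask, rhs in rows:
            while mask:
                top = mask.bit_length() - 1
                if top in pivots:
                    pm, pr = pivots[top]
                    mask ^= pm
                    rhs ^= pr
                else:
                    pivots[top] = (mask, rhs)
                    break
        if len(solution) + len(pivots) < n:
            raise UndecodableGroupError(
                f"undecodable group: rank {len(solution) + len(pivots)} < {n}"
            )
        for bit in sorted(pivots):
            mask, rhs = pivots[bit]
            for low in range(bit):
                if mask >> low & 1:
                    mask ^= 1 << low
                    rhs ^= solution[low]
            solution[bit] = rhs
    if len(solution) < n:
        raise UndecodableGroupError(
            f"undecodable group: rank {len(solution)} < {n}"
        )
    return [solution[i] for i in range(n)]


def _collect_groups(records: Iterable[Union[SequenceRecord, str]],
                    table: ReferenceOrderTable,
                    cfg: EncodingConfig) -> Dict[int, List[List[Droplet]]]:
    """Disassemble a pool into per-ordinal droplet candidates.

    Exact post-RS duplicates are dropped; sequences that cannot be restored
    to a constraint-valid codeword are skipped with a warning (a group left
    uncovered surfaces as a missing-group error downstream).
    """
    if table.fingerprint != cfg.fingerprint():
        raise DecodeError(
            "reference table was written under a different configuration "
            f"(fingerprint {table.fingerprint} != {cfg.fingerprint()})"
        )
    candidates: Dict[int, List[List[Droplet]]] = {}
    seen = set()
    for rec in records:
        bases = rec.bases if isinstance(rec, SequenceRecord) else rec
        try:
            ordinal, droplets = disassemble(bases, table, cfg)
        except (UncorrectableSequenceError, UnknownIndexError) as exc:
            name = rec.id if isinstance(rec, SequenceRecord) else "<sequence>"
            logger.warning("dropping %s: %s", name, exc)
            continue
        key = (ordinal, tuple((d.seed, d.payload_bits) for d in droplets))
        if key in seen:
            continue
        seen.add(key)
        candidates.setdefault(ordinal, []).append(droplets)
    return candidates


def _solve_ordinals(candidates: Dict[int, List[List[Droplet]]],
                    wanted: Sequence[int], cfg: EncodingConfig) -> List[DataGroup]:
    missing = [o for o in wanted if o not in candidates]
    if missing:
        raise MissingGroupsError(
            "missing groups: " + ", ".join(str(m) for m in missing)
        )
    n = cfg.segments_per_group
    groups = []
    for ordinal in wanted:
        solved = None
        last_error: Optional[DecodeError] = None
        for droplets in candidates[ordinal]:
            try:
                segments = solve_group(droplets, n)
            except UndecodableGroupError as exc:
                last_error = exc
                continue
            # verification identity: re-XOR the solution through each droplet
            if all(
                _xor_members(segments, d.members) == d.payload_bits
                for d in droplets
            ):
                solved = segments
                break
        if solved is None:
            raise last_error or UndecodableGroupError(
                f"group {ordinal}: no candidate record solves"
            )
        # solved segments are still whitened; XOR the keystream back out
        groups.append(whiten_group(DataGroup(ordinal, tuple(solved)), cfg))
    return groups


def _xor_members(segments: Sequence[int], members: Sequence[int]) -> int:
    acc = 0
    for m in members:
        acc ^= segments[m]
    return acc


def decode_pool(records: Iterable[Union[SequenceRecord, str]],
                table: ReferenceOrderTable, cfg: EncodingConfig) -> bytes:
    """Decode an unordered (possibly corrupted) pool back to the payload.

    Input order never matters; exact post-RS duplicates are tolerated, and
    conflicting records for one ordinal fall back to the first candidate
    whose solution verifies.
    """
    candidates = _collect_groups(records, table, cfg)
    wanted = list(range(len(table.rows)))
    groups = _solve_ordinals(candidates, wanted, cfg)
    return ungroup(groups, table.original_length, cfg)


def decode_groups(records: Iterable[Union[SequenceRecord, str]],
                  table: ReferenceOrderTable, cfg: EncodingConfig,
                  start: int, stop: int) -> bytes:
    """Random access: decode only groups [start, stop).

    Returns bytes ``[start*group_bytes, stop*group_bytes)`` of the padded
    payload; only the requested groups' records need to be present.
    """
    if not (0 <= start <= stop <= len(table.rows)):
        raise ValueError("group range out of bounds")
    candidates = _collect_groups(records, table, cfg)
    wanted = list(range(start, stop))
    groups = _solve_ordinals(candidates, wanted, cfg)
    chunks = []
    for group in groups:
        value = 0
        for seg in group.segments:
            value = (value << cfg.segment_bits) | seg
        chunks.append(value.to_bytes(cfg.group_bytes, "big"))
    return b"".join(chunks)
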