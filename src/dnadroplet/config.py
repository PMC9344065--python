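"""Codec configuration.

The defaults describe the published oligo geometry: each oligo carries eight
23-nt fragments (one index fragment plus seven payload fragments) followed by
8 nt of Reed-Solomon parity. A fragment is a 5-nt seed (10 bits) plus an
18-nt payload (36 bits), so one group of data holds eight 36-bit segments
(36 bytes). Every fragment must keep its GC fraction within [0.45, 0.55] and
contain no homopolymer run longer than two bases.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class EncodingConfig:
    """Geometry, constraint bounds and tuning knobs for the codec.

    Parameters
    ----------
    segments_per_group : int
        n, the number of fixed-width segments per independently decodable
        group. Must equal ``fragments_per_sequence`` (each oligo must carry
        enough droplets to solve its group).
    segment_bits : int
        Width of one segment in bits; tied to the fragment geometry by
        ``segment_bits == 2 * (fragment_nt - seed_bits / 2)``.
    seed_bits : int
        Width of the droplet seed; rendered as ``seed_bits / 2`` nucleotides
        at the start of each fragment.
    fragment_nt : int
        Length of one fragment in nucleotides (seed + payload).
    fragments_per_sequence : int
        Fragments concatenated into one oligo (1 index + the rest payload).
    gc_lo, gc_hi : float
        Inclusive GC-fraction bounds applied to every fragment.
    max_homopolymer : int
        Longest allowed run of one base (2 forbids runs of three or more).
    rs_parity_bytes : int
        Reed-Solomon parity bytes appended per oligo (rendered 4 nt/byte).
    soliton_c, soliton_delta : float
        Robust soliton distribution parameters.
    index_k : int
        k-mer size used when screening index fragments for similarity.
    index_jaccard_max : float
        Maximum allowed k-mer Jaccard between any two chosen index fragments.
    master_seed : int
        Seed for stochastic helpers (read simulation, fixtures). The encode
        path itself is fully deterministic.
    """

    segments_per_group: int = 8
    segment_bits: int = 36
    seed_bits: int = 10
    fragment_nt: int = 23
    fragments_per_sequence: int = 8
    gc_lo: float = 0.45
    gc_hi: float = 0.55
    max_homopolymer: int = 2
    rs_parity_bytes: int = 2
    soliton_c: float = 0.025
    soliton_delta: float = 0.001
    index_k: int = 10
    index_jaccard_max: float = 0.2
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_bits < 0 or self.seed_bits % 2:
            raise ValueError("seed_bits must be a non-negative even integer")
        for name in ("segments_per_group", "segment_bits", "fragment_nt",
                     "fragments_per_sequence", "max_homopolymer", "index_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.rs_parity_bytes < 0:
            raise ValueError("rs_parity_bytes must be non-negative")
        if self.fragment_nt <= self.seed_nt:
            raise ValueError("fragment_nt must exceed the seed length")
        if self.segment_bits != 2 * (self.fragment_nt - self.seed_nt):
            raise ValueError(
                "segment_bits must equal 2*(fragment_nt - seed_bits/2); "
                f"got {self.segment_bits} for {self.fragment_nt} nt fragments"
            )
        if (self.segments_per_group * self.segment_bits) % 8:
            raise ValueError("group size must be a whole number of bytes")
        if self.fragments_per_sequence != self.segments_per_group:
            raise ValueError(
                "fragments_per_sequence must equal segments_per_group so the "
                "oligo's droplets can reach full rank"
            )
        if (self.fragments_per_sequence * self.fragment_nt) % 4:
            raise ValueError("fragment region must pack to whole bytes (4 nt/byte)")
        if not (0.0 <= self.gc_lo <= self.gc_hi <= 1.0):
            raise ValueError("need 0 <= gc_lo <= gc_hi <= 1")
        if self.rs_message_bytes + self.rs_parity_bytes > 255:
            raise ValueError("RS codeword exceeds 255 bytes")
        if self.soliton_c <= 0 or not (0.0 < self.soliton_delta < 1.0):
            raise ValueError("need soliton_c > 0 and 0 < soliton_delta < 1")
        if not (0.0 <= self.index_jaccard_max <= 1.0):
            raise ValueError("index_jaccard_max must be a fraction in [0, 1]")

    # -- derived geometry ---------------------------------------------------

    @property
    def seed_nt(self) -> int:
        """Nucleotides occupied by the seed at the start of each fragment."""
        return self.seed_bits // 2

    @property
    def payload_nt(self) -> int:
        return self.fragment_nt - self.seed_nt

    @property
    def group_bytes(self) -> int:
        """Bytes of payload carried by one group (36 at defaults)."""
        return self.segments_per_group * self.segment_bits // 8

    @property
    def fragment_region_nt(self) -> int:
        """Length of the concatenated fragments (184 at defaults)."""
        return self.fragments_per_sequence * self.fragment_nt

    @property
    def rs_message_bytes(self) -> int:
        return self.fragment_region_nt // 4

    @property
    def rs_nt(self) -> int:
        return 4 * self.rs_parity_bytes

    @property
    def sequence_nt(self) -> int:
        """Total oligo length including parity (192 at defaults)."""
        return self.fragment_region_nt + self.rs_nt

    # -- serialisation ------------------------------------------------------

    def fingerprint(self) -> str:
        """Short hash of the decode-relevant fields.

        ``master_seed`` is excluded: it never influences the encoded
        sequences, only auxiliary stochastic tooling.
        """
        fields = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "master_seed"
        }
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "EncodingConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "EncodingConfig":
        """Build a config from a plain mapping, rejecting unknown keys."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)
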