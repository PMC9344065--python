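"""Binary-to-nucleotide mapping and the biochemical constraint filter.

Bit pairs map 00→A, 01→C, 10→G, 11→T in both directions. A rendered
fragment is kept only if its GC fraction lies inside the configured
inclusive window and it contains no homopolymer run longer than
``max_homopolymer`` bases. For the default 23-nt fragment and the
[0.45, 0.55] window, the admissible G+C counts are exactly {11, 12}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from itertools import groupby
from typing import Optional

from .config import EncodingConfig
from .fountain import Droplet

BASES = "ACGT"
_BASE_VALUE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class Fragment:
    """A constraint-passing nucleotide rendering of a droplet."""

    bases: str
    seed: int
    droplet: Droplet


def bits_to_bases(bits: int, width: int) -> str:
    """Render a ``width``-bit value (MSB first) as nucleotides, 2 bits/base."""
    if width % 2:
        raise ValueError("bit width must be even")
    if bits < 0 or bits >> width:
        raise ValueError(f"value does not fit in {width} bits")
    return "".join(BASES[(bits >> s) & 3] for s in range(width - 2, -1, -2))


def bases_to_bits(dna: str) -> int:
    """Exact inverse of :func:`bits_to_bases` (value of width ``2*len(dna)``)."""
    value = 0
    for pos, ch in enumerate(dna):
        try:
            value = (value << 2) | _BASE_VALUE[ch]
        except KeyError:
            raise ValueError(f"invalid base {ch!r} at position {pos}") from None
    return value


def gc_content(dna: str) -> float:
    """Fraction of G and C bases."""
    if not dna:
        raise ValueError("empty sequence")
    return (dna.count("G") + dna.count("C")) / len(dna)


def max_run(dna: str) -> int:
    """Length of the longest homopolymer run."""
    return max((sum(1 for _ in grp) for _, grp in groupby(dna)), default=0)


@lru_cache(maxsize=None)
def _run_pattern(limit: int) -> "re.Pattern[str]":
    # matches any run of limit+1 or more identical characters
    return re.compile(r"(.)\1{%d,}" % limit)


def passes_constraints(dna: str, cfg: EncodingConfig) -> bool:
    """True iff GC within [gc_lo, gc_hi] (inclusive) and runs <= max_homopolymer.

    Applied to full fragments, seed bases included.
    """
    if len(dna) != cfg.fragment_nt:
        raise ValueError(
            f"expected a {cfg.fragment_nt}-nt fragment, got {len(dna)} nt"
        )
    gc = (dna.count("G") + dna.count("C")) / len(dna)
    if not (cfg.gc_lo <= gc <= cfg.gc_hi):
        return False
    return _run_pattern(cfg.max_homopolymer).search(dna) is None


def droplet_to_fragment(droplet: Droplet, cfg: EncodingConfig) -> Optional[Fragment]:
    """Render seed ∥ payload as bases; return a Fragment or None if rejected."""
    width = cfg.seed_bits + cfg.segment_bits
    bases = bits_to_bases(
        (droplet.seed << cfg.segment_bits) | droplet.payload_bits, width
    )
    if not passes_constraints(bases, cfg):
        return None
    return Fragment(bases, droplet.seed, droplet)
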