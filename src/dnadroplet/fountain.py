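"""Luby-transform machinery: degree distribution, seeds, droplets.

A droplet is the XOR of a seed-determined subset of a group's segments.
Everything here is deterministic: the seed stream is a Galois LFSR over a
primitive polynomial (each nonzero state exactly once per period), and the
seed-to-(degree, members) mapping runs a pinned linear congruential
generator so that encoder and decoder always reconstruct identical plans.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Tuple

import numpy as np

from .config import EncodingConfig
from .preprocess import DataGroup

# Primitive feedback polynomials (coefficient masks including the top term)
# for the Galois LFSR, by register width. x^10 + x^7 + 1 is the default
# 10-bit choice; all entries verified to have full period 2^w - 1.
PRIMITIVE_POLYS = {
    2: 0b111,
    3: 0b1011,
    4: 0b10011,
    5: 0b100101,
    6: 0b1000011,
    7: 0b10000011,
    8: 0b100011101,
    9: 0b1000010001,
    10: 0b10010000001,          # x^10 + x^7 + 1
    11: 0b100000000101,
    12: 0b1000001010011,
    13: 0b10000000011011,
    14: 0b100010001000011,
    15: 0b1000000000000011,
    16: 0b10001000000001011,
}

# Pinned LCG (glibc rand() constants) used to expand a seed into a droplet
# plan. Cross-version reproducibility of encode/decode depends on these.
_LCG_A = 1103515245
_LCG_C = 12345
_LCG_M = 1 << 31


@dataclass(frozen=True)
class DegreeDistribution:
    """Degree distribution over 1..n; ``probs[d-1] = P(degree = d)``."""

    n: int
    probs: np.ndarray
    _cum: List[float] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        total = float(np.sum(self.probs))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"degree probabilities sum to {total}, not 1")
        if np.any(self.probs < 0):
            raise ValueError("degree probabilities must be non-negative")
        object.__setattr__(self, "_cum", list(np.cumsum(self.probs)))

    @property
    def cumulative(self) -> List[float]:
        return self._cum


@dataclass(frozen=True)
class Droplet:
    """One fountain symbol: seed, degree, member segments and XOR payload."""

    seed: int
    degree: int
    members: Tuple[int, ...]
    payload_bits: int


def robust_soliton(n: int, c: float, delta: float) -> DegreeDistribution:
    """Robust soliton distribution: ideal soliton rho plus spike/tail tau.

    rho(1) = 1/n, rho(d) = 1/(d(d-1)); with R = c*ln(n/delta)*sqrt(n) and
    M = floor(n/R), tau(d) = R/(dn) for d < M, tau(M) = R*ln(R/delta)/n,
    tau(d) = 0 beyond the spike; the sum is normalised by beta. When M
    falls outside [1, n] (tiny n or tiny c) the spike is dropped and the
    tail R/(dn) covers the whole support — normalisation absorbs the mass.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if c <= 0 or not (0.0 < delta < 1.0):
        raise ValueError("need c > 0 and 0 < delta < 1")
    d = np.arange(1, n + 1, dtype=float)
    rho = np.empty(n)
    rho[0] = 1.0 / n
    if n > 1:
        rho[1:] = 1.0 / (d[1:] * (d[1:] - 1.0))
    R = c * np.log(n / delta) * np.sqrt(n)
    tau = np.zeros(n)
    M = int(np.floor(n / R))
    if M >= 1:
        if M > n:
            tau = R / (d * n)
        else:
            tau[: M - 1] = R / (d[: M - 1] * n)
            tau[M - 1] = R * np.log(R / delta) / n
    total = rho + tau
    return DegreeDistribution(n, total / total.sum())


def lfsr_states(width: int, poly: Optional[int] = None) -> Iterator[int]:
    """Yield every nonzero state of a Galois LFSR exactly once.

    Starts at state 1 and multiplies by x modulo the primitive feedback
    polynomial, so the full period 2^width - 1 is traversed before the
    sequence repeats.
    """
    if width < 2:
        raise ValueError("LFSR width must be >= 2")
    if poly is None:
        try:
            poly = PRIMITIVE_POLYS[width]
        except KeyError:
            raise ValueError(f"no feedback polynomial pinned for width {width}")
    top = 1 << width
    state = 1
    for _ in range(top - 1):
        yield state
        state <<= 1
        if state & top:
            state ^= poly


def seed_stream(cfg: EncodingConfig) -> Iterator[int]:
    """The encoder's seed enumeration order for ``cfg.seed_bits``."""
    return lfsr_states(cfg.seed_bits)


def droplet_plan(seed: int, n: int, dist: DegreeDistribution) -> Tuple[int, Tuple[int, ...]]:
    """Deterministically expand a seed into (degree, member indices).

    The LCG is seeded with the seed value; the first draw picks the degree
    by inverse CDF, subsequent draws pick distinct uniform segment indices.
    Indices come from the state's high bits (``state * n >> 31``): the low
    bits of a power-of-two-modulus LCG cycle with tiny period and would
    collapse the membership patterns.
    """
    if seed == 0:
        raise ValueError("seed 0 is reserved")
    if dist.n != n:
        raise ValueError(f"distribution is over n={dist.n}, expected {n}")
    state = (_LCG_A * seed + _LCG_C) % _LCG_M
    u = state / _LCG_M
    degree = bisect_right(dist.cumulative, u) + 1
    if degree > n:
        degree = n
    members = []
    while len(members) < degree:
        state = (_LCG_A * state + _LCG_C) % _LCG_M
        idx = (state * n) >> 31
        if idx not in members:
            members.append(idx)
    return degree, tuple(sorted(members))


def make_droplet(group: DataGroup, seed: int, dist: DegreeDistribution) -> Droplet:
    """XOR the plan's member segments into a droplet payload."""
    degree, members = droplet_plan(seed, len(group.segments), dist)
    payload = 0
    for m in members:
        payload ^= group.segments[m]
    return Droplet(seed, degree, members, payload)
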