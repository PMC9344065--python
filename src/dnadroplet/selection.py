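"""Fragment selection: index fragments and decodable payload sets.

For each group the encoder renders every seed's droplet and keeps the
constraint-passing fragments (the pool, in seed order). One pool fragment
becomes the group's *index* — chosen to be globally unique and dissimilar
(k-mer Jaccard) from every earlier group's index — and seven more are chosen
greedily so that the eight droplets' membership matrix reaches full GF(2)
rank (the decodability certificate) without creating homopolymer runs
across fragment junctions.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .alphabet import Fragment, bits_to_bases, droplet_to_fragment, max_run, _run_pattern
from .config import EncodingConfig
from .exceptions import EncodeError, PoolExhaustedError, UndecodableGroupError
from .fountain import DegreeDistribution, Droplet, droplet_plan, robust_soliton, seed_stream
from .metrics import jaccard_kmer, kmer_set
from .preprocess import DataGroup

logger = logging.getLogger(__name__)

Plan = Tuple[int, Tuple[int, Tuple[int, ...]]]  # (seed, (degree, members))


@dataclass(frozen=True)
class FragmentPool:
    """All constraint-passing fragments of one group, in seed-stream order."""

    ordinal: int
    fragments: Tuple[Fragment, ...]


@dataclass(frozen=True)
class SelectionResult:
    """A group's chosen index + payload fragments and its rank certificate."""

    ordinal: int
    index_fragment: Fragment
    payload_fragments: Tuple[Fragment, ...]
    rank_certificate: bool

    @property
    def droplets(self) -> Tuple[Droplet, ...]:
        return (self.index_fragment.droplet,) + tuple(
            f.droplet for f in self.payload_fragments
        )


def enumerate_plans(cfg: EncodingConfig, dist: DegreeDistribution) -> List[Plan]:
    """Precompute every seed's droplet plan (group-independent)."""
    n = cfg.segments_per_group
    return [(seed, droplet_plan(seed, n, dist)) for seed in seed_stream(cfg)]


def build_pool(group: DataGroup, cfg: EncodingConfig,
               dist: Optional[DegreeDistribution] = None,
               plans: Optional[Sequence[Plan]] = None) -> FragmentPool:
    """Try every seed; keep the constraint-passing fragments in seed order."""
    n = cfg.segments_per_group
    if dist is None:
        dist = robust_soliton(n, cfg.soliton_c, cfg.soliton_delta)
    if plans is None:
        plans = enumerate_plans(cfg, dist)
    segs = group.segments
    seg_bits = cfg.segment_bits
    width = cfg.seed_bits + seg_bits
    gc_lo_cnt = cfg.gc_lo * cfg.fragment_nt
    gc_hi_cnt = cfg.gc_hi * cfg.fragment_nt
    run_re = _run_pattern(cfg.max_homopolymer)
    fragments: List[Fragment] = []
    for seed, (degree, members) in plans:
        payload = 0
        for m in members:
            payload ^= segs[m]
        bases = bits_to_bases((seed << seg_bits) | payload, width)
        gc = bases.count("G") + bases.count("C")
        if gc < gc_lo_cnt or gc > gc_hi_cnt or run_re.search(bases):
            continue
        fragments.append(Fragment(bases, seed, Droplet(seed, degree, members, payload)))
    if len(fragments) < cfg.fragments_per_sequence:
        raise PoolExhaustedError(
            f"group {group.ordinal}: only {len(fragments)} constraint-passing "
            f"fragments for {cfg.fragments_per_sequence} slots; increase seed_bits"
        )
    return FragmentPool(group.ordinal, tuple(fragments))


def _membership_mask(droplet: Droplet) -> int:
    mask = 0
    for m in droplet.members:
        mask |= 1 << m
    return mask


def gf2_rank(droplets: Iterable[Droplet], n: int) -> int:
    """Rank over GF(2) of the droplet x segment membership matrix."""
    pivots: Dict[int, int] = {}
    rank = 0
    for droplet in droplets:
        row = _membership_mask(droplet)
        if any(m < 0 or m >= n for m in droplet.members):
            raise ValueError("member index out of range")
        while row:
            top = row.bit_length() - 1
            if top in pivots:
                row ^= pivots[top]
            else:
                pivots[top] = row
                rank += 1
                break
    return rank


class IndexSelector:
    """Streaming index chooser: groups are processed in ascending ordinal.

    A candidate is accepted when its bases differ from every previously
    chosen index and its k-mer Jaccard against each of them stays at or
    below the configured threshold. When no pool fragment qualifies the
    threshold is relaxed: the candidate minimising the maximum pairwise
    Jaccard wins, with a logged warning. An inverted k-mer index keeps the
    common case (no shared k-mers at all) linear.
    """

    def __init__(self, cfg: EncodingConfig):
        self.k = cfg.index_k
        self.jmax = cfg.index_jaccard_max
        self.chosen: List[str] = []
        self._chosen_set: set = set()
        self._kmer_index: Dict[str, set] = defaultdict(set)

    def _conflicts(self, bases: str) -> set:
        hits: set = set()
        for km in kmer_set(bases, self.k):
            hits |= self._kmer_index.get(km, set())
        return hits

    def _accept(self, frag: Fragment) -> Fragment:
        idx = len(self.chosen)
        self.chosen.append(frag.bases)
        self._chosen_set.add(frag.bases)
        for km in kmer_set(frag.bases, self.k):
            self._kmer_index[km].add(idx)
        return frag

    def choose(self, pool: FragmentPool) -> Fragment:
        for frag in pool.fragments:
            if frag.bases in self._chosen_set:
                continue
            hits = self._conflicts(frag.bases)
            if all(
                jaccard_kmer(frag.bases, self.chosen[i], self.k) <= self.jmax
                for i in hits
            ):
                return self._accept(frag)
        # relaxation: minimise the worst pairwise Jaccard
        best = None
        best_score = None
        for frag in pool.fragments:
            if frag.bases in self._chosen_set:
                continue
            score = max(
                (jaccard_kmer(frag.bases, self.chosen[i], self.k)
                 for i in self._conflicts(frag.bases)),
                default=0.0,
            )
            if best_score is None or score < best_score:
                best, best_score = frag, score
        if best is None:
            raise EncodeError(
                f"group {pool.ordinal}: every pool fragment duplicates an "
                "earlier index"
            )
        logger.warning(
            "group %d: no index candidate under Jaccard %.3g; relaxed to "
            "max pairwise Jaccard %.3g", pool.ordinal, self.jmax, best_score,
        )
        return self._accept(best)


def select_index(pools: Sequence[FragmentPool],
                 cfg: EncodingConfig) -> Dict[int, Fragment]:
    """Choose every group's index fragment (ascending ordinal order)."""
    selector = IndexSelector(cfg)
    out: Dict[int, Fragment] = {}
    for pool in sorted(pools, key=lambda p: p.ordinal):
        out[pool.ordinal] = selector.choose(pool)
    return out


def _junction_ok(prev: str, nxt: str, limit: int) -> bool:
    return max_run(prev[-limit:] + nxt[:limit]) <= limit


def select_payload(pool: FragmentPool, index_fragment: Fragment,
                   cfg: EncodingConfig) -> List[Fragment]:
    """Greedy scan for fragments that lift the GF(2) rank to full.

    Starting from the index droplet's membership row, a pool fragment is
    appended iff it strictly increases the rank and its junction with the
    previously placed fragment creates no homopolymer run beyond the limit.
    """
    n = cfg.segments_per_group
    needed = cfg.fragments_per_sequence - 1
    limit = cfg.max_homopolymer

    pivots: Dict[int, int] = {}

    def try_add(mask: int) -> bool:
        row = mask
        while row:
            top = row.bit_length() - 1
            if top in pivots:
                row ^= pivots[top]
            else:
                pivots[top] = row
                return True
        return False

    try_add(_membership_mask(index_fragment.droplet))
    chosen: List[Fragment] = []
    prev = index_fragment.bases
    for frag in pool.fragments:
        if len(chosen) == needed:
            break
        if frag.seed == index_fragment.seed:
            continue
        if not _junction_ok(prev, frag.bases, limit):
            continue
        if try_add(_membership_mask(frag.droplet)):
            chosen.append(frag)
            prev = frag.bases
    if len(chosen) < needed or len(pivots) < n:
        raise UndecodableGroupError(
            f"group {pool.ordinal} undecodable with available seeds"
        )
    return chosen


def select_group(pool: FragmentPool, index_fragment: Fragment,
                 cfg: EncodingConfig) -> SelectionResult:
    """Bundle index + payload choices with the rank certificate."""
    payload = select_payload(pool, index_fragment, cfg)
    droplets = [index_fragment.droplet] + [f.droplet for f in payload]
    cert = gf2_rank(droplets, cfg.segments_per_group) == cfg.segments_per_group
    return SelectionResult(pool.ordinal, index_fragment, tuple(payload), cert)
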