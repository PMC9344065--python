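"""Evaluation statistics for encoded pools.

Covers the self-similarity measures (k-mer Jaccard coefficients and their
per-sequence/pool totals, word-match dotplots), windowed GC statistics, and
the geometry-derived redundancy / net information density figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .config import EncodingConfig


@dataclass(frozen=True)
class GCStats:
    """Per-window GC fractions with their population mean and variance."""

    window_nt: int
    per_window: Tuple[float, ...]
    mean: float
    variance: float


@dataclass(frozen=True)
class DotplotResult:
    """Word-match dotplot: a dot at (i, j) marks an exact shared word."""

    word_nt: int
    dots: Set[Tuple[int, int]]
    off_diagonal_count: int
    density: float


def kmer_set(seq: str, k: int) -> Set[str]:
    """All distinct length-k substrings of ``seq`` (empty if too short)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def jaccard_kmer(a: str, b: str, k: int) -> float:
    """|A∩B| / |A∪B| over the two sequences' k-mer sets."""
    sa, sb = kmer_set(a, k), kmer_set(b, k)
    if not sa and not sb:
        raise ValueError("both k-mer sets are empty")
    return len(sa & sb) / len(sa | sb)


def jaccard_total(seqs: Sequence[str], k: int) -> Tuple[List[float], float]:
    """Per-sequence sums of pairwise Jaccard plus the grand total.

    Each sequence's row-sum counts its Jaccard against every *other*
    sequence, so the grand total counts every unordered pair twice (once in
    each member's row).
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    sets = [kmer_set(s, k) for s in seqs]
    m = len(seqs)
    sums = [0.0] * m
    for i in range(m):
        for j in range(i + 1, m):
            union = len(sets[i] | sets[j])
            if union == 0:
                raise ValueError(f"sequences {i} and {j} have no k-mers")
            val = len(sets[i] & sets[j]) / union
            sums[i] += val
            sums[j] += val
    return sums, sum(sums)


def dotplot(a: str, b: str, word: int) -> DotplotResult:
    """Dot at (i, j) iff ``a[i:i+word] == b[j:j+word]``.

    ``off_diagonal_count`` excludes the main diagonal for a self-comparison
    (a == b); ``density`` is dots over all valid position pairs.
    """
    if word < 1:
        raise ValueError("word length must be >= 1")
    na = max(0, len(a) - word + 1)
    nb = max(0, len(b) - word + 1)
    where_b: Dict[str, List[int]] = {}
    for j in range(nb):
        where_b.setdefault(b[j:j + word], []).append(j)
    dots = {
        (i, j)
        for i in range(na)
        for j in where_b.get(a[i:i + word], ())
    }
    self_cmp = a == b
    off = sum(1 for (i, j) in dots if i != j) if self_cmp else len(dots)
    density = len(dots) / (na * nb) if na and nb else 0.0
    return DotplotResult(word, dots, off, density)


def gc_window_stats(seqs: Sequence[str], window: int) -> GCStats:
    """GC fraction per non-overlapping window, pooled over all sequences.

    Windows are half-open ``[t*window, (t+1)*window)``; trailing partial
    windows are dropped. Variance is the population variance.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values: List[float] = []
    for seq in seqs:
        for start in range(0, len(seq) - window + 1, window):
            win = seq[start:start + window]
            values.append((win.count("G") + win.count("C")) / window)
    if not values:
        raise ValueError("no complete window in any sequence")
    arr = np.asarray(values)
    return GCStats(window, tuple(values), float(arr.mean()), float(arr.var()))


def redundancy(cfg: EncodingConfig) -> float:
    """Fraction of the fragment region spent on seeds and RS parity.

    (seed nt per fragment x fragments + RS nt) / fragment-region nt; with
    the default geometry (5x8 + 8) / 184 ≈ 0.2609, i.e. 26%.
    """
    return (cfg.seed_nt * cfg.fragments_per_sequence + cfg.rs_nt) / cfg.fragment_region_nt


def net_information_density(cfg: EncodingConfig) -> float:
    """Payload bits per nucleotide: 2·(1 − redundancy); 1.48 at defaults."""
    return 2.0 * (1.0 - redundancy(cfg))


def write_dotplot_tsv(result: DotplotResult, handle) -> None:
    """Dotplot as TSV coordinates plus summary counts."""
    handle.write(f"#word={result.word_nt}\n")
    handle.write(f"#dots={len(result.dots)}\n")
    handle.write(f"#off_diagonal={result.off_diagonal_count}\n")
    handle.write(f"#density={result.density:.6g}\n")
    for i, j in sorted(result.dots):
        handle.write(f"{i}\t{j}\n")


def plot_dotplot(result: DotplotResult, path: str) -> None:
    """Render the dotplot to an image file (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if result.dots:
        xs, ys = zip(*sorted(result.dots))
        ax.scatter(xs, ys, s=1, marker="s", color="black")
    ax.set_xlabel("position in sequence A")
    ax.set_ylabel("position in sequence B")
    ax.set_title(f"word = {result.word_nt} nt")
    ax.invert_yaxis()
    fig.savefig(path, dpi=150)
    plt.close(fig)
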