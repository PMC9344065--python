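"""Systematic Reed-Solomon code over GF(2^8).

Encoding appends ``parity`` check bytes (generator roots alpha^0..); decoding
is Peterson-Gorenstein-Zierler bounded-distance decoding, correcting up to
floor(parity/2) byte errors and raising :class:`RSDecodeError` when the
syndromes are inconsistent with that radius. With the codec's default of two
parity bytes (minimum distance 3) a single corrupted byte anywhere in the
codeword is always corrected; two corrupted bytes are usually detected, but a
fraction of double errors necessarily lands within distance one of a
different codeword and decodes there — callers needing stronger guarantees
must re-validate the decoded message (the codec re-checks fragment
constraints and the index table).
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Sequence, Tuple

from .exceptions import RSDecodeError

_PRIM_POLY = 0x11D  # x^8 + x^4 + x^3 + x^2 + 1

_EXP = [0] * 510
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM_POLY
for _i in range(255, 510):
    _EXP[_i] = _EXP[_i - 255]


def _mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def _inv(a: int) -> int:
    if a == 0:
        raise ZeroDivisionError("inverse of 0 in GF(256)")
    return _EXP[255 - _LOG[a]]


def _pow(a: int, e: int) -> int:
    if a == 0:
        return 0
    return _EXP[(_LOG[a] * e) % 255]


@lru_cache(maxsize=None)
def _generator_poly(nsym: int) -> Tuple[int, ...]:
    """prod_{i<nsym} (x - alpha^i), coefficients highest power first."""
    g = [1]
    for i in range(nsym):
        root = _EXP[i]
        nxt = [0] * (len(g) + 1)
        for j, coef in enumerate(g):
            nxt[j] ^= coef  # times x
            nxt[j + 1] ^= _mul(coef, root)
        g = nxt
    return tuple(g)


def rs_protect(message: bytes, parity: int) -> bytes:
    """Append ``parity`` Reed-Solomon check bytes (systematic encoding)."""
    if parity < 0:
        raise ValueError("parity must be non-negative")
    if len(message) + parity > 255:
        raise ValueError(
            f"codeword of {len(message) + parity} bytes exceeds 255"
        )
    if parity == 0:
        return bytes(message)
    gen = _generator_poly(parity)
    buf = list(message) + [0] * parity
    for i in range(len(message)):
        coef = buf[i]
        if coef:
            for j in range(1, len(gen)):
                buf[i + j] ^= _mul(gen[j], coef)
    return bytes(message) + bytes(buf[-parity:])


def _syndromes(codeword: Sequence[int], nsym: int) -> List[int]:
    # codeword[0] is the highest-power coefficient
    out = []
    for i in range(nsym):
        root = _EXP[i]
        acc = 0
        for byte in codeword:
            acc = _mul(acc, root) ^ byte
        out.append(acc)
    return out


def _solve_gf256(matrix: List[List[int]], rhs: List[int]) -> List[int] | None:
    """Gaussian elimination over GF(256); None if singular."""
    size = len(rhs)
    aug = [row[:] + [rhs[i]] for i, row in enumerate(matrix)]
    for col in range(size):
        pivot = next((r for r in range(col, size) if aug[r][col]), None)
        if pivot is None:
            return None
        aug[col], aug[pivot] = aug[pivot], aug[col]
        inv = _inv(aug[col][col])
        aug[col] = [_mul(v, inv) for v in aug[col]]
        for r in range(size):
            if r != col and aug[r][col]:
                factor = aug[r][col]
                aug[r] = [a ^ _mul(factor, b) for a, b in zip(aug[r], aug[col])]
    return [aug[r][size] for r in range(size)]


def rs_recover(codeword: bytes, parity: int) -> Tuple[bytes, int]:
    """Correct up to floor(parity/2) byte errors; return (message, n_corrected).

    Raises :class:`RSDecodeError` when no codeword lies within the decoding
    radius of the received word.
    """
    if parity < 0:
        raise ValueError("parity must be non-negative")
    if parity == 0:
        return bytes(codeword), 0
    if len(codeword) > 255 or len(codeword) <= parity:
        raise ValueError("codeword length out of range")
    received = list(codeword)
    nlen = len(received)
    synd = _syndromes(received, parity)
    if not any(synd):
        return bytes(received[:-parity]), 0

    t = parity // 2
    for nu in range(t, 0, -1):
        # lambda_1..lambda_nu from S_{j+nu} = sum_k lambda_k S_{j+nu-k}
        matrix = [[synd[j + nu - k] for k in range(1, nu + 1)] for j in range(nu)]
        rhs = [synd[j + nu] for j in range(nu)]
        lam = _solve_gf256(matrix, rhs)
        if lam is None:
            continue
        # roots of Lambda(x) = 1 + lam_1 x + ... at x = alpha^{-p}
        positions = []  # coefficient powers p
        for p in range(nlen):
            x = _EXP[(255 - p) % 255]  # alpha^{-p}
            acc = 1
            xp = 1
            for coef in lam:
                xp = _mul(xp, x)
                acc ^= _mul(coef, xp)
            if acc == 0:
                positions.append(p)
        if len(positions) != nu:
            continue
        # magnitudes from the Vandermonde system S_j = sum_i e_i X_i^j
        locs = [_EXP[p % 255] for p in positions]
        vander = [[_pow(X, j) for X in locs] for j in range(nu)]
        mags = _solve_gf256(vander, synd[:nu])
        if mags is None or any(m == 0 for m in mags):
            continue
        candidate = received[:]
        for p, e in zip(positions, mags):
            candidate[nlen - 1 - p] ^= e
        if not any(_syndromes(candidate, parity)):
            return bytes(candidate[:-parity]), nu
    raise RSDecodeError(
        f"syndromes inconsistent with <= {t} byte errors"
    )
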