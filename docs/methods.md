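# Methods

This note documents the model behind `dnadroplet`, the parameters that
matter, the numerical and design choices made where the design was open,
what the synthetic inputs do and do not emulate, and the known limits of
the scheme's guarantees.

## The coding scheme

A payload of *L* bytes is zero-padded to a multiple of 36 bytes and split
into *N* = ⌈L/36⌉ groups of *n* = 8 segments of 36 bits each. Groups are
encoded and decoded independently, which is what buys random access: one
group ↔ one 192-nt oligo ↔ bytes [36·g, 36·(g+1)) of the padded stream.
Segments are most-significant-bit-first slices of the byte stream; the
original length is carried in the reference-order table header, so padding
needs no in-band marker.

Within a group, droplets are produced by a Luby transform. The degree
distribution is the robust soliton: ρ(1) = 1/n, ρ(d) = 1/(d(d−1)); with
R = c·ln(n/δ)·√n and M = ⌊n/R⌋, τ(d) = R/(dn) for d < M,
τ(M) = R·ln(R/δ)/n, zero beyond; probabilities are (ρ+τ)/β with
β = Σ(ρ+τ). Defaults c = 0.025 and δ = 0.001 follow the fountain-code DNA
storage lineage this scheme extends. At those defaults M = 12 > n = 8, so
the spike falls outside the support; we then let the tail R/(dn) run over
the whole support and let β absorb the mass. This keeps the distribution
well defined for every n ≥ 1 (for n = 1 it degenerates to P(d=1) = 1).

Seeds are the 1023 nonzero states of a 10-bit Galois LFSR with primitive
polynomial x¹⁰ + x⁷ + 1, enumerated from state 1 by multiplication by x, so
every seed appears exactly once per period and the stream is identical on
every run. Seed 0 is reserved: a zero seed would render as an all-A prefix
and cannot arise from the LFSR. Polynomials for widths 2–16 are pinned in
`fountain.PRIMITIVE_POLYS`, all verified full-period.

A seed is expanded into (degree, members) by a pinned LCG
(state ← 1103515245·state + 12345 mod 2³¹): the first draw picks the degree
by inverse CDF, subsequent draws pick distinct member indices. Member
indices are taken from the state's *high* bits, (state·n) >> 31. The low
bits of any modulus-2³¹ LCG cycle with tiny period — reducing the state
mod 8 collapses all 1023 seeds onto a few dozen membership patterns and
leaves whole pools rank-deficient — while the high-bit reduction gives the
intended near-uniform spread. Encoder and decoder share this function, so
a fragment's 5-nt seed prefix is all the decoder needs to reconstruct the
droplet's equation.

### Whitening

Droplet payloads are XORs of segments, so low-entropy input defeats the
constraint filter: an all-zero group renders every droplet as
seed + AAAAAAAAAAAAAAAAAA, nothing passes, and the pool is empty. Before
fountain encoding, each segment is therefore XORed with a fixed public
keystream — blake2b("dnadroplet-whiten:ordinal:index") truncated to the
segment width — and the decoder removes the same mask after solving. This
is whitening, not encryption: the keystream is constant, public, and
independent of any seed or key. It makes pool sizes (and hence the GC
statistics) essentially payload-independent.

### Constraints and selection

A rendered 23-nt fragment is kept iff its GC fraction lies in the inclusive
window [0.45, 0.55] — at 23 nt exactly the G+C counts {11, 12} — and it
contains no run of three or more identical bases ("no homopolymers" reads
as runs ≥ 3; doublets are legal, otherwise no 23-nt string with GC ≈ 0.5
could survive). The filter sees the whole fragment, seed included. Random
fragments pass at roughly 6–15%, so the 1023-seed space typically leaves
60–200 candidates per group; the encoder errors out (advising a wider seed
space) if fewer than 8 remain.

Index fragments are chosen per group in ascending ordinal: the first pool
fragment (seed order) that differs from every earlier index and has k-mer
Jaccard (k = 10) ≤ 0.2 against each of them. When a conflict forces a
re-pick, it is always the *later* group that re-picks — re-opening an
earlier group's choice could cascade arbitrarily — and if no candidate
clears the threshold the encoder falls back to the candidate minimising
the worst pairwise Jaccard and logs a warning (never observed at the
problem sizes exercised here; random 23-nt indices share a 10-mer with
probability ≈ 2·10⁻⁴). An inverted k-mer index keeps selection linear in
N; only candidates that actually share a 10-mer with an earlier index pay
for a Jaccard evaluation.

The seven payload fragments are a greedy scan of the pool in seed order:
a fragment is taken iff it strictly increases the GF(2) rank of the
accumulated membership matrix *and* its junction with the previously
placed fragment creates no run above the homopolymer limit (the junction
window of 2+2 bases is sufficient because each fragment is internally
clean). Since the index row contributes rank 1 and each accepted fragment
adds 1, eight droplets reach rank 8 exactly — recorded as the selection's
rank certificate. Greedy order makes encoding reproducible without
recording choices; it is not globally optimal and can in principle dead-end
where backtracking would succeed, but across every pool exercised in the
tests (thousands of random groups) it never has.

### Assembly, parity, decoding

The 184-nt fragment region packs to 46 bytes (4 bases/byte, the same 2-bit
map). Two Reed–Solomon parity bytes over GF(2⁸) (primitive polynomial
0x11D, generator roots α⁰, α¹) are appended and rendered as 8 nt, for a
192-nt oligo. The published redundancy formula divides by the 184-nt
fragment region, so redundancy = (5·8 + 8)/184 ≈ 26% and the net
information density 2·(1 − redundancy) ≈ 1.48 bit/nt; the NID expression
is our reconstruction (it reproduces the printed figure from the printed
redundancy) since no formula is given for it.

Decoding per sequence: RS-correct (PGZ bounded-distance decoding; for
ν = 1 this is the closed form p = log(S₁/S₀), e = S₀), re-validate every
corrected fragment against the constraint filter, look the leading
fragment up in the reference-order table (headers are never trusted),
regenerate the eight droplet plans from their seed prefixes, and solve the
group by peeling degree-1 rows plus GF(2) elimination for the remainder.
Duplicates identical after correction are dropped; conflicting candidates
for one ordinal fall back to the first whose solution verifies by
re-XORing through every droplet. Missing ordinals are reported by name.

### Error-handling guarantees and their limits

Two parity bytes give minimum distance 3: every single corrupted byte
(hence any single base substitution) per oligo is corrected, always. Two
corrupted bytes cannot be corrected, and *detection* of them cannot be
absolute: a weight-2 error that lands within distance 1 of a different
codeword is necessarily decoded to that codeword by any decoder that
corrects all single errors. At the RS layer the fraction of such
coincidences is about k/255 ≈ 19% for a 48-byte codeword; the codec's
post-correction constraint re-validation and index lookup screen out most
of these (measured: ≈ 98.5% of random double corruptions are flagged), but
a small residue decodes silently to a wrong group payload. Applications
needing airtight integrity at higher error rates should raise
`rs_parity_bytes`. There is also no cross-oligo erasure protection: the
scheme fixes exactly eight droplets per group, so a group whose only
records are lost or uncorrectable is unrecoverable — an inherent cost of
trading rateless redundancy for fixed geometry and random access.

## Evaluation statistics

* **k-mer Jaccard**: |A∩B|/|A∪B| over the two sequences' k-mer sets;
  per-sequence sums count every other sequence, so the pool grand total
  counts each unordered pair twice (matching a per-row "sum then total"
  procedure).
* **Dotplot**: a dot at (i, j) iff the length-w words at i in A and j in B
  match; off-diagonal dots of a self-comparison measure internal repeats.
  Emitted as TSV coordinates; rendering is optional and side-effect-free.
* **GC windows**: non-overlapping half-open windows (23 nt, aligned to
  fragments), trailing partials dropped, *population* mean and variance
  pooled over all sequences. Population (not sample) variance keeps the
  closed-form checks exact (two windows at 0.45/0.55 → 0.0025, which is
  also the Popoviciu-style upper bound for any filter-passing pool).
* **Read simulation**: per oligo of length L, ⌈coverage·L/read_nt⌉
  single-end reads of exactly 150 nt (the whole sequence when L < 150),
  uniform start positions, iid substitutions at 1% to a uniformly chosen
  different base, constant Phred-40 quality, no indels. "Detected" means
  covered by ≥ 1 read. This deliberately omits empirical platform error
  profiles, position-dependent quality, paired ends and indels; it is a
  coverage model, not a sequencer model, and the ≥ 95% detection figure
  should be read as a coverage statement only.

## Synthetic inputs

Payload fixtures are deterministic pseudo-random bytes (`fixture(size,
seed)`, PCG64). They emulate *incompressible* data — the hardest case for
the constraint filter before whitening and the typical case after it —
but not the structure of real files (headers, runs, text). Because
whitening makes the fountain stage payload-agnostic, statistics measured
on fixtures (pool sizes, GC variance, coverage) transfer to arbitrary
payloads; what fixtures cannot show is behaviour under adversarial
bit patterns aimed at the whitening keystream itself, which is public.
Default evaluation sizes: 100 KB payloads (2845 groups) for the GC and
round-trip checks, 200 oligos for read simulation — chosen to estimate the
statistics stably while keeping a full run in tens of seconds.

## Numerical choices and degenerate inputs

* Bit order is MSB-first everywhere; base map A=00, C=01, G=10, T=11 in
  both directions (a conflicting decode-direction table in the source
  material is treated as a typo — its A/T entries agree with the encode
  map and its C/G entries would break the bijection).
* GC bounds are compared inclusively on exact counts, so no floating-point
  edge can flip a fragment's eligibility at 23 nt.
* Degree inverse-CDF uses bisect on the cumulative vector; a u exactly on
  a boundary takes the higher degree, and the degree is clamped to n.
* Empty payloads, zero-length fixtures, odd bit widths, non-ACGT bases,
  short-of-one-window metric inputs and out-of-range group slices all
  raise typed errors rather than degrade.
* `EncodingConfig` validates the geometry invariants (segment width tied
  to fragment length, whole-byte groups, full-rank-capable fragment count,
  packable region) at construction; the table fingerprint covers every
  decode-relevant field and excludes `master_seed`, which never influences
  encoded output.
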