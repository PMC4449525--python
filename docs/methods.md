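# Methods

This note records the model behind each pipeline stage, the tunable
parameters and their defaults, the numerical conventions, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate model

All internal coordinates are 0-based half-open offsets into a single
concatenated string: contigs joined by one `#` sentinel each plus a terminal
sentinel. `#` sorts before `A` (so suffix order is well defined) and is
excluded from every match and substitution comparison, which is what keeps
exact matches and DP windows from leaking across contig boundaries (windows
are additionally clamped to the anchor's contig). SAM output translates back
to 1-based per-contig positions at write time. Lower-case input is
upper-cased and anything outside {A,C,G,T,N} becomes N; N never matches
anything, including another N, because an ambiguity base carries no
positional evidence.

## Enhanced sparse suffix array

The index stores the suffixes starting at positions ≡ 0 (mod s), suffix
sorted (`len(sa) = ⌈N/s⌉`), an LCP array over adjacent sampled suffixes, and
the classical collapsed up/down/next child table over that LCP array, giving
top-down traversal of the implicit lcp-interval tree.

Construction is correctness-first: the full suffix array is built by numpy
prefix doubling (O(N log N) lexsorts), filtered to sampled positions, and
the sparse LCP is obtained as range minima over the full (Kasai) LCP with
`np.minimum.reduceat`. This is deliberate — every piece is directly
checkable against a naive string-sorting oracle, which the test suite does
on hundreds of random texts. Suffix links are not implemented; each query
suffix restarts from the root. That costs speed, never correctness, and at
the problem sizes this package targets the traversal is not the bottleneck.

Serialization is three flat int64 arrays plus a JSON metadata file carrying
a magic string, format version, sparseness and the contig table; loading
verifies the magic, version and array lengths and reports the offending
field.

Default sparseness is 12, the speed/memory compromise also used as the
mapper's default elsewhere; `-s 1` degenerates to a classical enhanced
suffix array and is the reference point for tests.

## Seed finding

A MEM (i, j, ℓ) is found by matching read suffixes, stepped by the query
sampling value q, down the tree and extending every sampled occurrence in
both directions. The detection depth is K = max(1, L − q·s + 1): if a MEM of
length ℓ ≥ L exists, then by CRT (gcd(q, s) = 1) some queried read position
x ≡ 0 (mod q) inside it aligns to a sampled reference position with at
least K matching characters remaining, so descending to depth K and
extending recovers the MEM. The q rule — the largest q with gcd(q, s) = 1
and q·s ≤ L − s + 1 — makes K ≥ s for q > 1 and keeps candidate sets small.
The traversal-plus-extension kernel is numba-compiled; results are
deduplicated and sorted by (ref_start, read_start).

The minimum seed length is the pigeonhole bound L =
clamp(⌊m/(⌊e·m⌋+1)⌋, 20, 40): a read with k errors contains an exact
stretch of at least ⌊m/(k+1)⌋ bases. The clamp bounds (20, 40) are package
defaults, exposed as options; they keep L sensible for very short and very
long reads. `min_seed_len` is additionally floored at s, since a shorter
MEM need not contain any sampled suffix at all.

A seed's occurrence count is the width of the sa-interval at its full
matched depth — the number of *sampled* suffixes matching the read
interval, floored at 1. With s > 1 this undercounts true genomic
occurrences by up to a factor of s; it is the rarity proxy used both for
the "rare MEM" filter (default cap 10) and for the "unique in the read"
flag (count == 1). Rescue seeding shrinks L by 25% per level (hard floor
max(s, 10)), forces q = 1 and multiplies the rarity cap tenfold, for at
most three levels.

## Candidate regions

Only SMEMs and rare MEMs form clusters. The longest unassigned seed anchors
a region spanning the anchor's projected read interval padded by
`padding_factor·m` (default: the error rate) on each side, truncated
against previously built regions; any unassigned seed overlapping the
interval joins. Using overlap (not containment) for membership is what
guarantees the disjointness invariant: no later anchor can straddle an
existing boundary. Afterwards all MEMs (rare or not) overlapping a region
are pulled in, which raises read-base coverage without changing the anchor;
after augmentation a pulled-in MEM may be longer than the anchor, and the
anchor is deliberately left as chosen.

Regions from both strands compete in one ranking: coverage descending, then
anchor length, then reference position. The scheduler stops at
`max_feasible = 4·k` feasible alignments (k = requested alignments per
read), after 6 consecutive failed regions, or when coverage drops below
0.25 of the best region's, but always processes regions carrying a
read-unique seed. All three constants are config keys; they are not given
by any published source and were chosen once as reasonable defaults.
Region rescue first relaxes the scheduler (failure budget ×3, no coverage
cutoff) and re-runs, then falls back to rescue seeding plus re-clustering.

## Chaining

The skew between consecutive seeds is |ref-gap − read-gap|, the net indel
content between them. Chains grow greedily from the anchor, right then left
in read order, nearest seed first; a candidate is admitted iff strictly
collinear with the current chain end and its skew is at most
`base_skew + skew_slope·gap` (defaults 5 and 0.15; the linear form is this
package's concretization of a gap-dependent allowance). Overlapping
admitted seeds are trimmed on the later seed (dropped if trimmed away).
Multiple chains per region: anchors are taken in decreasing length order,
chained seeds may join later chains but no longer anchor one, at most 3
chains per region.

## Alignment

One Gotoh kernel (numba, int32 full matrices, traceback arrays) serves five
entry modes: global (gap rectangles), glocal (full read, free reference
flanks — the end-to-end mode), anchored extension with a fixed corner (flank
alignment; the left flank is reversed so the seed junction becomes the
corner), soft-clipping extension (local flanks), and plain local. The band
is expressed as diagonal-offset limits covering both matrix corners ±
band_width; with band ≥ max(|ref|, |read|) the kernel is exactly unbanded
DP, which is how the test suite cross-checks it against an independent
pure-Python implementation. Traceback ties resolve M > D > I, so CIGARs are
deterministic.

Gap bridging avoids DP for: empty/empty, pure insertion, pure deletion, one
end-anchored contiguous indel with an otherwise exact match, and
equal-length gaps with at most 2 substitutions. The substitution cap is
scoring-aware: under (1, 4, 6, 1) a mixed-indel alignment can beat three or
more substitutions, and capping keeps chain-guided scores at the DP optimum
in practice rather than merely close to it. Anything else goes to banded
global DP with band = |len difference| + base_skew + 2, guarded by
`max_dp_area` (4·10⁶ cells) against pathological rectangles.

The final CIGAR is merged and rescored in a single pass against the actual
sequences; the reported AS and NM always come from that pass, which makes
CIGAR/score/NM self-consistency structural rather than assumed (the SAM
validator re-verifies it on every emitted file).

Feasibility: an alignment is feasible iff score ≥ max(0.3·match·m,
match·m·(1 − 2e·(mismatch+match)/match)). At the defaults this is 0.5·m for
e = 0.05 and the 0.3·m floor from e ≳ 0.08 upward. The linear budget and
floor are package choices standing in for an unspecified "sufficient
similarity" notion; both constants are configurable. MAPQ is 60 for a
unique alignment, 0 for a tie, else round(60·(s1−s2)/s1) clamped to
[0, 60] — a deliberate simple margin rule.

## Paired-end mapping

Insert size is outermost-to-outermost; bounds are user-supplied (-I/-X),
not estimated. A pair is proper iff both mates sit on one contig, their
orientations match the constraint (FR default), and the insert is within
bounds. The default strategy maps mates independently and pairs the
cross-product by combined score. Bridging runs full banded DP of the mate
over the window implied by the mapped end and the constraint (truncated at
contig bounds). The joint strategies couple candidate regions before
extension: *filter* extends only regions participating in a geometrically
compatible pair; *prioritize* works through compatible region pairs in
summed-coverage order. The rescue cascade order — independent, bridge (from
either mate), joint-filter — is fixed but a package choice.

## Simulator and evaluation

The simulator emulates uniform wgsim-style data: i.i.d. uniform ACGT
genomes; read origins and strands uniform; per emitted base a substitution
with probability e·(1−f) and an indel event with probability e·f (f =
indel fraction, default 0.1), indel lengths geometric with p = 0.7
(minimum 1, an explicit package choice); paired mode draws FR outer
distances from N(insert_mean, insert_sd). Truth records carry the leftmost
forward-strand origin and the exact applied edit counts (inserted and
deleted bases counted individually). Everything is deterministic under
`rng_seed`.

What this deliberately does not model: platform-specific error profiles
(homopolymer errors, quality-dependent miscalls), coverage biases, real
repeat structure, or genomic rearrangements. Random genomes are nearly
repeat-free, so recall on them is an upper bound on real-genome behavior;
passing tests demonstrate algorithmic correctness and the machinery's
behavior under the stated error models, not performance on biological
references.

Recall counts a read whose reported leftmost position is within 10 bp of
its true origin on the true strand and contig (any reported alignment may
qualify). Accuracy additionally accepts an alignment whose NM does not
exceed the simulated edit total, so accuracy ≥ recall holds by
construction. The "simulated differences" are counted as base totals
(substitutions + inserted bases + deleted bases).

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by choice: random
texts up to 2 kb (index oracle), references up to 10 kb (seed oracle), a
100 kb single-contig genome with 500 reads or pairs per condition for the
end-to-end measurements. These sizes give stable statistics while keeping
the whole verification cycle fast. Every random draw flows from an explicit
seed; mapping output is deterministic for a fixed config, including under
multithreading (reads are independent work units reassembled in input
order).

## Known limitations

- No suffix-link acceleration and no bit-parallel DP; throughput is far
  from production mappers even though the asymptotics are right.
- Occurrence counts are sampled-suffix proxies (see above).
- A single huge indel inside a read is recovered only if the skew allowance
  or the gap-rectangle band covers it; balanced distant indel pairs beyond
  the band produce an honest infeasible result rather than a partial answer.
- The paired joint strategies extend at most a bounded number of region
  pairs; extremely repetitive genomes may need the independent strategy
  with a larger -k.
- BAM/CRAM output and gzip inputs are out of scope; SAM text only.
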