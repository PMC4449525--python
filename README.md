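# alfalign

A seed-and-extend read mapper for long (≥ 500 bp), error-prone sequencing
reads, built on an **enhanced sparse suffix array** (ESSA). It aligns
single-end and paired-end reads from FASTA/FASTQ to a multi-contig reference
and writes SAM v1.6, and it ships with a wgsim-style read simulator and an
accuracy evaluator so that every stage of the pipeline can be exercised and
verified on synthetic data of any size.

## The method

Mapping a read r (length m) to a genome T proceeds in four stages:

1. **Index.** Instead of all suffixes of T, only suffixes starting at
   positions ≡ 0 (mod s) are sorted into a suffix array (⌈N/s⌉ entries,
   in theory 9/s + 1 bytes per indexed base), augmented with an LCP array
   and a child table so the implicit lcp-interval tree can be walked top
   down. The sparseness s (option `-s`, default 12) trades memory for
   seeding speed.

2. **Seeds.** Variable-length *maximal exact matches* (MEMs) — triples
   (i, j, ℓ) with r[i..i+ℓ) = T[j..j+ℓ) blocked by mismatches at
   (i−1, j−1) and (i+ℓ, j+ℓ) — and *super-maximal* exact matches (SMEMs,
   MEMs whose read interval is contained in no other MEM's read interval).
   The minimum seed length L is tuned by pigeonhole from the read length
   and expected error rate, L = clamp(⌊m/(⌊e·m⌋+1)⌋, 20, 40), and read
   suffixes are sampled every q positions with gcd(q, s) = 1 and
   q·s ≤ L − s + 1, which guarantees no MEM of length ≥ L is missed.
   Both strands are seeded; a rescue ladder relaxes L and the rarity cap
   when nothing is found.

3. **Candidate regions.** SMEMs and rare MEMs (≤ 10 sampled occurrences)
   are binned into non-overlapping reference clusters anchored on locally
   longest seeds, re-augmented with all overlapping MEMs, and ranked by
   read-base coverage. Extension halts once enough feasible alignments
   exist, after a run of consecutive failures, or when coverage falls below
   a fraction of the best region — except for regions holding a seed unique
   in the read, which are always extended.

4. **Chains and alignment.** Within a region, seeds are greedily chained
   from an anchor outward; a seed joins only if collinear and its *skew*
   (|ref-gap − read-gap|) stays within base_skew + slope·gap. Chain seeds
   become exact match segments; inter-seed gaps are bridged without DP when
   they are pure substitutions or a single indel, otherwise by banded
   affine-gap (Gotoh) DP on the gap rectangle; read ends are extended by
   banded DP (end-to-end, the default) or soft-clipped (`--local`).
   Default scoring: match 1, mismatch 4, gap open 6, gap extend 1. MAPQ is
   60·(s1−s2)/s1 clamped to [0, 60].

Paired-end reads support four strategies (`--pair-strategy`): independent
mapping of both mates with constraint-based pairing (default), DP bridging
of the mate from a mapped end, and two joint region-level variants; when
the chosen strategy finds no proper pair a rescue cascade tries the others.

## Worked example

Simulate a 50 kb genome with 200 reads of 1 kb at 5% error (10% of errors
indels), index it, map, and score against the simulation truth:

```sh
alfalign simulate --genome-len 50000 -n 200 -l 1000 -e 0.05 \
    --indel-fraction 0.1 --seed 11 -o sim
alfalign index -r sim.genome.fa -o idx -s 12
alfalign align -x idx -U sim.fq -o out.sam -k 1
alfalign evaluate --sam out.sam --truth sim.truth.tsv
```

which prints

```
metric  value
recall  1.0000
accuracy        1.0000
proper_pair_rate        0.0000
```

`recall` is the fraction of reads with a reported alignment within 10 bp of
the simulated origin on the correct strand; `accuracy` additionally accepts
alignments whose edit distance does not exceed the number of simulated
edits; the proper-pair rate is 0 because the input was single-end. The SAM
body shows the recovered indel structure, e.g.

```
sim0  0  sim1  6547  60  135M2D205M1D140M1D52M2I177M1I132M1D143M2I11M  ...
```

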