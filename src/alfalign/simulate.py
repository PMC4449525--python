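"""Read simulation with ground truth, and mapping evaluation.

The simulator follows the wgsim model: uniform random genomes, read origins
and strands drawn uniformly, and per-base uniform errors split between
substitutions and indels (indel lengths geometric).  Every read carries a
truth record with its leftmost forward-strand origin and the exact edit
counts applied, which drives the two evaluation measures: *recall* (an
alignment within a tolerance of the simulated origin) and the laxer
*accuracy* (recall, or an edit distance no higher than the number of
simulated differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .reference_io import Read, Reference, reverse_complement

BASES = "ACGT"
INDEL_GEOM_P = 0.7
DEFAULT_TOLERANCE = 10


class EvaluationError(ValueError):
    """SAM/truth mismatch during evaluation."""


@dataclass
class SimulationConfig:
    n_reads: int
    read_len: int
    error_rate: float = 0.05
    indel_fraction: float = 0.1
    paired: bool = False
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    name: str
    mate: int  # 0 single-end, else 1 or 2
    contig: str
    pos: int  # 0-based leftmost forward-strand origin
    strand: str
    n_substitutions: int
    n_insertions: int  # inserted bases
    n_deletions: int  # deleted bases

    @property
    def total_edits(self) -> int:
        return self.n_substitutions + self.n_insertions + self.n_deletions

    def key(self) -> tuple[str, int]:
        return self.name, self.mate


def simulate_genome(length: int, rng_seed: int, name: str = "sim1") -> Reference:
    """Uniform i.i.d. ACGT genome as a single contig."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return Reference.from_contigs([(name, seq)])


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in BASES if b != base]
    return choices[rng.integers(0, len(choices))]


def _geom(rng: np.random.Generator) -> int:
    return int(rng.geometric(INDEL_GEOM_P))


def _mutate(
    genome: str, origin: int, read_len: int, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, int, int, int]:
    """Walk the genome from ``origin`` applying per-base errors until
    ``read_len`` bases are emitted; returns (seq, n_sub, n_ins, n_del)."""
    p_err = cfg.error_rate
    p_sub = p_err * (1.0 - cfg.indel_fraction)
    p_ind = p_err * cfg.indel_fraction
    out: list[str] = []
    i = origin
    ns = ni = nd = 0
    n = len(genome)
    while len(out) < read_len and i < n:
        r = rng.random()
        if r < p_sub:
            out.append(_other_base(rng, genome[i]))
            i += 1
            ns += 1
        elif r < p_sub + p_ind:
            k = _geom(rng)
            if rng.random() < 0.5:
                k = min(k, read_len - len(out))
                out.extend(BASES[rng.integers(0, 4)] for _ in range(k))
                ni += k
            else:
                i += k
                nd += k
        else:
            out.append(genome[i])
            i += 1
    return "".join(out), ns, ni, nd


def simulate_reads(
    ref: Reference, cfg: SimulationConfig
) -> tuple[list[Read], list[TruthRecord]]:
    """Simulated reads plus their truth records; deterministic under
    ``cfg.rng_seed``.  Paired mode emits FR pairs with outer distance
    N(insert_mean, insert_sd); reads are interleaved mate1, mate2."""
    rng = np.random.default_rng(cfg.rng_seed)
    name, contig_len = ref.contigs[0]
    genome = ref.contig_slice(name)
    if cfg.read_len > contig_len:
        raise ValueError("read_len exceeds genome length")
    margin = int(cfg.read_len * (1 + cfg.error_rate)) + 20
    reads: list[Read] = []
    truths: list[TruthRecord] = []

    def one_read(rname: str, mate: int, origin: int, strand: str) -> None:
        seq, ns, ni, nd = _mutate(genome, origin, cfg.read_len, rng, cfg)
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append(Read(rname, seq, "I" * len(seq), mate if mate else None))
        truths.append(TruthRecord(rname, mate, name, origin, strand, ns, ni, nd))

    if not cfg.paired:
        for i in range(cfg.n_reads):
            origin = int(rng.integers(0, contig_len - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            one_read(f"sim{i}", 0, origin, strand)
        return reads, truths

    min_insert = 2 * cfg.read_len + 10
    for i in range(cfg.n_reads):
        insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
        insert = max(min_insert, min(insert, contig_len - margin - 1))
        origin = int(rng.integers(0, contig_len - insert - margin))
        right_origin = origin + insert - cfg.read_len
        left_first = rng.random() < 0.5
        rname = f"sim{i}"
        if left_first:
            one_read(rname, 1, origin, "+")
            one_read(rname, 2, right_origin, "-")
        else:
            one_read(rname, 1, right_origin, "-")
            one_read(rname, 2, origin, "+")
    return reads, truths


# --- truth table I/O ---------------------------------------------------------

_TRUTH_HEADER = "name\tmate\tcontig\tpos\tstrand\tn_sub\tn_ins\tn_del"


def write_truth(truths: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.name}\t{t.mate}\t{t.contig}\t{t.pos}\t{t.strand}\t"
                f"{t.n_substitutions}\t{t.n_insertions}\t{t.n_deletions}\n"
            )


def load_truth(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != _TRUTH_HEADER.strip():
            raise EvaluationError(f"{path}: unrecognized truth table header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    f[0], int(f[1]), f[2], int(f[3]), f[4], int(f[5]), int(f[6]), int(f[7])
                )
            )
    return out


def write_fastq(reads: list[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            suffix = f"/{r.mate_index}" if r.mate_index else ""
            fh.write(f"@{r.name}{suffix}\n{r.sequence}\n+\n{r.qualities}\n")


# --- evaluation --------------------------------------------------------------


def _mate_of(rec: pysam.AlignedSegment) -> int:
    if rec.is_paired:
        return 1 if rec.is_read1 else 2
    return 0


def _iter_sam(sam) -> list[pysam.AlignedSegment]:
    if isinstance(sam, str):
        with pysam.AlignmentFile(sam, "r") as fh:
            return list(fh)
    return list(sam)


def _truth_map(truth) -> dict[tuple[str, int], TruthRecord]:
    records = load_truth(truth) if isinstance(truth, str) else truth
    return {t.key(): t for t in records}


def _correct_by_position(
    rec: pysam.AlignedSegment, t: TruthRecord, tolerance: int
) -> bool:
    strand = "-" if rec.is_reverse else "+"
    return (
        rec.reference_name == t.contig
        and strand == t.strand
        and abs(rec.reference_start - t.pos) <= tolerance
    )


def evaluate_recall(sam, truth, tolerance: int = DEFAULT_TOLERANCE) -> float:
    """Fraction of simulated reads with any reported alignment whose
    leftmost position is within ``tolerance`` bases of the simulated origin
    on the true strand and contig."""
    tmap = _truth_map(truth)
    correct: set[tuple[str, int]] = set()
    for rec in _iter_sam(sam):
        if rec.is_unmapped:
            continue
        key = (rec.query_name, _mate_of(rec))
        if key not in tmap:
            raise EvaluationError(f"read {key} not present in the truth table")
        if _correct_by_position(rec, tmap[key], tolerance):
            correct.add(key)
    return len(correct) / len(tmap) if tmap else 0.0


def evaluate_accuracy(sam, truth, tolerance: int = DEFAULT_TOLERANCE) -> float:
    """Recall requirement OR an edit distance (NM) no higher than the number
    of simulated differences; accuracy >= recall by construction."""
    tmap = _truth_map(truth)
    correct: set[tuple[str, int]] = set()
    for rec in _iter_sam(sam):
        if rec.is_unmapped:
            continue
        key = (rec.query_name, _mate_of(rec))
        if key not in tmap:
            raise EvaluationError(f"read {key} not present in the truth table")
        t = tmap[key]
        if _correct_by_position(rec, t, tolerance):
            correct.add(key)
            continue
        if not rec.has_tag("NM"):
            raise EvaluationError(f"read {key}: missing NM tag")
        if rec.get_tag("NM") <= t.total_edits:
            correct.add(key)
    return len(correct) / len(tmap) if tmap else 0.0


def proper_pair_rate(sam) -> float:
    """Fraction of primary paired records flagged as properly paired."""
    total = proper = 0
    for rec in _iter_sam(sam):
        if not rec.is_paired or rec.is_secondary or rec.is_supplementary:
            continue
        total += 1
        if rec.is_proper_pair:
            proper += 1
    return proper / total if total else 0.0
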