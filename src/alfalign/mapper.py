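"""End-to-end mapping workflow: seeds -> regions -> chains -> alignment ->
SAM records, for single-end reads and read pairs, plus the record validator
used to check every emitted file."""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, fields
from typing import Iterable, Iterator, Optional

import pysam

from .align import (
    END_TO_END,
    AlignmentResult,
    ScoringScheme,
    chain_guided_align,
    compute_mapq,
    full_length_align,
    rescore_cigar,
)
from .chains import ChainParams, enumerate_chains
from .index import ESSAIndex
from .paired import (
    PairConstraint,
    PairedAlignment,
    PairingContext,
    paired_rescue,
    run_strategy,
)
from .reference_io import Read, Reference, SamRecord, cigar_ops, reverse_complement
from .regions import (
    CandidateRegion,
    SchedulerCaps,
    build_regions,
    region_rescue,
    schedule_extensions,
)
from .seeds import (
    SeedParams,
    auto_min_seed_len,
    auto_query_step,
    collect_seeds,
)

logger = logging.getLogger("alfalign")

#: minimum separation between reported alternative alignments of one read
DUPLICATE_WINDOW = 10


class ConfigError(ValueError):
    pass


@dataclass
class MapperConfig:
    """Every tunable of the pipeline; unknown keys are rejected on load."""

    sparseness: int = 12
    error_rate: float = 0.05
    min_seed_len: Optional[int] = None  # None -> auto from read length
    max_occurrences: int = 10
    n_alignments: int = 4
    threads: int = 1
    mode: str = END_TO_END
    full_dp: bool = False
    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    base_skew: int = 5
    skew_slope: float = 0.15
    max_chains_per_region: int = 3
    max_failures: int = 6
    min_coverage_fraction: float = 0.25
    region_padding_factor: Optional[float] = None  # None -> error_rate
    max_dp_area: int = 4_000_000
    min_insert: int = 0
    max_insert: int = 1000
    orientation: str = "fr"
    pair_strategy: str = "independent"

    @classmethod
    def from_dict(cls, data: dict) -> "MapperConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.sparseness < 1:
            raise ConfigError("sparseness must be >= 1")
        if self.n_alignments < 1:
            raise ConfigError("n_alignments must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must be in [0, 1)")
        logger.info("effective config: %s", self)

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            mode=self.mode,
        )

    @property
    def padding(self) -> float:
        return (
            self.region_padding_factor
            if self.region_padding_factor is not None
            else self.error_rate
        )

    def chain_params(self) -> ChainParams:
        return ChainParams(
            base_skew=self.base_skew,
            skew_slope=self.skew_slope,
            max_chains_per_region=self.max_chains_per_region,
        )

    def seed_params(self, read_len: int, index: ESSAIndex) -> SeedParams:
        L = (
            self.min_seed_len
            if self.min_seed_len is not None
            else auto_min_seed_len(read_len, self.error_rate)
        )
        L = max(L, index.sparseness)
        q = auto_query_step(index.sparseness, L)
        return SeedParams(
            min_seed_len=L, query_step=q, max_occurrences=self.max_occurrences
        )

    def constraint(self) -> PairConstraint:
        return PairConstraint(self.min_insert, self.max_insert, self.orientation)


def _make_extender(index: ESSAIndex, oriented: dict[str, str], cfg: MapperConfig):
    """Region extender: enumerate chains and align each (or run full-window
    banded DP with --full-dp); window is clamped to the anchor's contig."""
    text = index.text
    scoring = cfg.scoring()
    chain_params = cfg.chain_params()

    def extend(region: CandidateRegion) -> list[AlignmentResult]:
        read = oriented[region.strand]
        bounds = index.reference.contig_bounds(region.anchor.ref_start)
        if cfg.full_dp:
            lo = max(bounds[0], region.ref_start)
            hi = min(bounds[1], region.ref_end)
            aln = full_length_align(
                text[lo:hi],
                read,
                scoring,
                error_rate=cfg.error_rate,
                window_start=lo,
                strand=region.strand,
            )
            return [aln] if aln.feasible else []
        out = []
        for chain in enumerate_chains(region.seeds, chain_params):
            aln = chain_guided_align(
                chain,
                text,
                read,
                scoring,
                error_rate=cfg.error_rate,
                base_skew=cfg.base_skew,
                max_dp_area=cfg.max_dp_area,
                bounds=bounds,
            )
            if aln.feasible:
                out.append(aln)
        return out

    return extend


def _select_alignments(
    alignments: list[AlignmentResult], cfg: MapperConfig, read_len: int
) -> list[AlignmentResult]:
    """Deduplicate by locus, sort by score, assign MAPQ to the primary."""
    ordered = sorted(
        alignments, key=lambda a: (-a.score, a.ref_start, a.strand)
    )
    kept: list[AlignmentResult] = []
    for a in ordered:
        if any(
            k.strand == a.strand and abs(k.ref_start - a.ref_start) <= DUPLICATE_WINDOW
            for k in kept
        ):
            continue
        kept.append(a)
        if len(kept) >= cfg.n_alignments + 1:
            break
    if not kept:
        return []
    second = kept[1].score if len(kept) > 1 else None
    kept[0].mapq = compute_mapq(kept[0], second, read_len)
    return kept[: cfg.n_alignments]


def align_read(read: Read, index: ESSAIndex, cfg: MapperConfig) -> list[AlignmentResult]:
    """Map one read; returns up to n_alignments deduplicated alignments
    sorted by score (possibly empty)."""
    params = cfg.seed_params(len(read), index)
    oriented = {"+": read.sequence, "-": reverse_complement(read.sequence)}
    extender = _make_extender(index, oriented, cfg)
    seeds = collect_seeds(index, read.sequence, params)
    ranked = build_regions(
        seeds,
        len(read),
        text_len=index.n_text,
        max_occurrences=params.max_occurrences,
        padding_factor=cfg.padding,
    )
    caps = SchedulerCaps(
        max_feasible=4 * cfg.n_alignments,
        max_failures=cfg.max_failures,
        min_coverage_fraction=cfg.min_coverage_fraction,
    )
    alignments = schedule_extensions(ranked, extender, caps)
    if not alignments:
        logger.debug("read %s: primary pass empty, invoking region rescue", read.name)
        alignments = region_rescue(
            read.sequence, index, params, extender, caps, padding_factor=cfg.padding
        )
    return _select_alignments(alignments, cfg, len(read))


def _oriented_seq_qual(read: Read, strand: str) -> tuple[str, Optional[str]]:
    if strand == "-":
        qual = read.qualities[::-1] if read.qualities else None
        return reverse_complement(read.sequence), qual
    return read.sequence, read.qualities


def _records_for_read(
    read: Read,
    alignments: list[AlignmentResult],
    cfg: MapperConfig,
    base_flag: int = 0,
) -> list[SamRecord]:
    if not alignments:
        return [
            SamRecord(
                qname=read.name,
                flag=base_flag | 0x4,
                seq=read.sequence,
                qual=read.qualities,
            )
        ]
    records = []
    second = alignments[1].score if len(alignments) > 1 else None
    for rank, aln in enumerate(alignments):
        flag = base_flag
        if aln.strand == "-":
            flag |= 0x10
        if rank > 0:
            flag |= 0x100
        seq, qual = _oriented_seq_qual(read, aln.strand)
        tags = {"AS": aln.score, "NM": aln.edit_distance}
        if rank == 0 and second is not None:
            tags["XS"] = second
        records.append(
            SamRecord(
                qname=read.name,
                flag=flag,
                pos=aln.ref_start,
                mapq=aln.mapq if rank == 0 else 0,
                cigar=aln.cigar_string,
                seq=seq,
                qual=qual,
                tags=tags,
            )
        )
    return records


def map_read(read: Read, index: ESSAIndex, cfg: MapperConfig) -> list[SamRecord]:
    """Single-end mapping of one read to SAM records (primary first,
    secondaries flagged 0x100; one unmapped record if nothing is feasible)."""
    return _records_for_read(read, align_read(read, index, cfg), cfg)


def map_pair(
    read1: Read, read2: Read, index: ESSAIndex, cfg: MapperConfig
) -> list[SamRecord]:
    """Map a read pair with the configured strategy plus the rescue cascade;
    emits one record per mate with full SAM pair bookkeeping."""
    constraint = cfg.constraint()
    oriented = {
        1: {"+": read1.sequence, "-": reverse_complement(read1.sequence)},
        2: {"+": read2.sequence, "-": reverse_complement(read2.sequence)},
    }
    reads = {1: read1, 2: read2}
    region_cache: dict[int, list] = {}

    def regions_for(i: int) -> list:
        if i not in region_cache:
            params = cfg.seed_params(len(reads[i]), index)
            seeds = collect_seeds(index, reads[i].sequence, params)
            region_cache[i] = build_regions(
                seeds,
                len(reads[i]),
                text_len=index.n_text,
                max_occurrences=params.max_occurrences,
                padding_factor=cfg.padding,
            )
        return region_cache[i]

    ctx = PairingContext(
        read1=read1.sequence,
        read2=read2.sequence,
        constraint=constraint,
        reference=index.reference,
        scoring=cfg.scoring(),
        error_rate=cfg.error_rate,
        align_mate=lambda i: align_read(reads[i], index, cfg),
        regions_for=regions_for,
        extender_for=lambda i: _make_extender(index, oriented[i], cfg),
    )
    pairs = run_strategy(ctx, cfg.pair_strategy)
    if not pairs:
        pairs = paired_rescue(ctx)
    if pairs:
        return _paired_records(reads, pairs[0], cfg)
    # no proper pair: report best singletons
    alns1 = ctx.alns(1)
    alns2 = ctx.alns(2)
    return _singleton_records(reads, alns1, alns2, cfg)


def _pair_flags(own: AlignmentResult | None, mate: AlignmentResult | None, first: bool, proper: bool) -> int:
    flag = 0x1 | (0x40 if first else 0x80)
    if proper:
        flag |= 0x2
    if own is None:
        flag |= 0x4
    elif own.strand == "-":
        flag |= 0x10
    if mate is None:
        flag |= 0x8
    elif mate.strand == "-":
        flag |= 0x20
    return flag


def _paired_records(
    reads: dict[int, Read], pair: PairedAlignment, cfg: MapperConfig
) -> list[SamRecord]:
    recs = []
    for i, own, mate in ((1, pair.first, pair.second), (2, pair.second, pair.first)):
        flag = _pair_flags(own, mate, i == 1, pair.proper)
        seq, qual = _oriented_seq_qual(reads[i], own.strand)
        left = min(pair.first.ref_start, pair.second.ref_start)
        right = max(pair.first.ref_end, pair.second.ref_end)
        tlen = right - left
        if own.ref_start > mate.ref_start or (
            own.ref_start == mate.ref_start and i == 2
        ):
            tlen = -tlen
        recs.append(
            SamRecord(
                qname=reads[i].name,
                flag=flag,
                pos=own.ref_start,
                mapq=own.mapq,
                cigar=own.cigar_string,
                pnext=mate.ref_start,
                tlen=tlen,
                seq=seq,
                qual=qual,
                tags={"AS": own.score, "NM": own.edit_distance},
            )
        )
    return recs


def _singleton_records(
    reads: dict[int, Read],
    alns1: list[AlignmentResult],
    alns2: list[AlignmentResult],
    cfg: MapperConfig,
) -> list[SamRecord]:
    recs = []
    best = {1: alns1[0] if alns1 else None, 2: alns2[0] if alns2 else None}
    for i in (1, 2):
        own, mate = best[i], best[3 - i]
        flag = _pair_flags(own, mate, i == 1, proper=False)
        if own is None:
            recs.append(
                SamRecord(
                    qname=reads[i].name,
                    flag=flag,
                    pos=mate.ref_start if mate is not None else -1,
                    seq=reads[i].sequence,
                    qual=reads[i].qualities,
                    pnext=mate.ref_start if mate is not None else -1,
                )
            )
        else:
            seq, qual = _oriented_seq_qual(reads[i], own.strand)
            recs.append(
                SamRecord(
                    qname=reads[i].name,
                    flag=flag,
                    pos=own.ref_start,
                    mapq=own.mapq,
                    cigar=own.cigar_string,
                    pnext=mate.ref_start if mate is not None else own.ref_start,
                    seq=seq,
                    qual=qual,
                    tags={"AS": own.score, "NM": own.edit_distance},
                )
            )
    return recs


def map_all(
    reads: Iterable[Read],
    index: ESSAIndex,
    cfg: MapperConfig,
    paired: bool = False,
) -> Iterator[SamRecord]:
    """Map a read stream in input order.  Reads are independent work units:
    with threads > 1 results are reassembled in input order, so output is
    identical for any thread count."""
    if paired:
        units = list(_pairwise(reads))
        work = lambda pair: map_pair(pair[0], pair[1], index, cfg)
    else:
        units = list(reads)
        work = lambda read: map_read(read, index, cfg)
    n_mapped = 0
    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            results = pool.map(work, units)
            for recs in results:
                n_mapped += sum(not r.is_unmapped and not r.flag & 0x100 for r in recs)
                yield from recs
    else:
        for unit in units:
            recs = work(unit)
            n_mapped += sum(not r.is_unmapped and not r.flag & 0x100 for r in recs)
            yield from recs
    logger.info("mapped %d primary records from %d units", n_mapped, len(units))


def _pairwise(reads: Iterable[Read]) -> Iterator[tuple[Read, Read]]:
    it = iter(reads)
    while True:
        try:
            r1 = next(it)
        except StopIteration:
            return
        try:
            r2 = next(it)
        except StopIteration:
            raise ValueError("odd number of reads in paired input")
        yield r1, r2


# --- SAM validation ----------------------------------------------------------


def validate_sam(
    sam_path: str,
    reference: Reference,
    scoring: ScoringScheme,
    constraint: Optional[PairConstraint] = None,
) -> list[str]:
    """Self-consistency check of an emitted SAM file.

    Verifies CIGAR read-length consistency, coordinate bounds (no alignment
    crosses a contig boundary), NM and AS agreement with a rescoring pass,
    primary-flag discipline, and (when a constraint is given) proper-pair
    geometry.  Returns a list of problems; empty means the file passes.
    """
    problems: list[str] = []
    primaries: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(sam_path, "r") as fh:
        for rec in fh:
            key = (rec.query_name, 1 if rec.is_read1 else (2 if rec.is_read2 else 0))
            if rec.is_unmapped:
                if rec.mapping_quality != 0:
                    problems.append(f"{key}: unmapped record with MAPQ != 0")
                continue
            if not rec.is_secondary and not rec.is_supplementary:
                primaries[key] = primaries.get(key, 0) + 1
            if rec.query_sequence is not None:
                qlen = sum(
                    n for op, n in cigar_ops(rec.cigarstring) if op in "MIS=X"
                )
                if qlen != len(rec.query_sequence):
                    problems.append(f"{key}: CIGAR does not consume the read")
                    continue
            contig_start = reference.offsets[rec.reference_id]
            contig_len = reference.contigs[rec.reference_id][1]
            if rec.reference_end > contig_len:
                problems.append(f"{key}: alignment exceeds contig bounds")
                continue
            concat = contig_start + rec.reference_start
            ops = cigar_ops(rec.cigarstring)
            score, nm = rescore_cigar(
                reference.sequence, concat, rec.query_sequence, ops, scoring
            )
            if rec.has_tag("NM") and rec.get_tag("NM") != nm:
                problems.append(
                    f"{key}: NM={rec.get_tag('NM')} but rescoring gives {nm}"
                )
            if rec.has_tag("AS") and rec.get_tag("AS") != score:
                problems.append(
                    f"{key}: AS={rec.get_tag('AS')} but rescoring gives {score}"
                )
            if constraint is not None and rec.is_proper_pair:
                if rec.next_reference_id != rec.reference_id:
                    problems.append(f"{key}: proper pair across contigs")
                elif not (
                    constraint.min_insert
                    <= abs(rec.template_length)
                    <= constraint.max_insert
                ):
                    problems.append(
                        f"{key}: proper pair with insert {rec.template_length}"
                    )
    for key, count in primaries.items():
        if count != 1:
            problems.append(f"{key}: {count} primary records")
    return problems
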