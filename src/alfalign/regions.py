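"""Candidate region identification, prioritization and scheduling.

Seeds (SMEMs and rare MEMs only) are sorted by reference position and binned
into non-overlapping clusters anchored on locally longest seeds; every region
spans the anchor's projected read interval padded by the error budget.  MEMs
of any rarity that overlap a region are then pulled in to improve read-base
coverage.  Regions are ranked by coverage and extended in order until enough
feasible alignments are found, too many consecutive regions fail, or coverage
drops below a fraction of the best region's — except that regions holding a
seed unique in the read are always extended.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .align import AlignmentResult
from .seeds import Seed, SeedParams, collect_seeds, seed_rescue

DEFAULT_MAX_FAILURES = 6
DEFAULT_MIN_COVERAGE_FRACTION = 0.25
DEFAULT_REQUESTED_ALIGNMENTS = 4
RESCUE_FAILURE_FACTOR = 3


@dataclass
class CandidateRegion:
    ref_start: int
    ref_end: int
    strand: str
    seeds: list[Seed]
    anchor: Seed
    coverage: int = 0
    has_unique_seed: bool = False

    def recompute(self) -> None:
        self.coverage = _interval_union_size([(s.read_start, s.read_end) for s in self.seeds])
        self.has_unique_seed = any(s.occurrence_count == 1 for s in self.seeds)


@dataclass
class SchedulerCaps:
    max_feasible: int = 4 * DEFAULT_REQUESTED_ALIGNMENTS
    max_failures: int = DEFAULT_MAX_FAILURES
    min_coverage_fraction: float = DEFAULT_MIN_COVERAGE_FRACTION


@dataclass
class SchedulerState:
    feasible_found: int = 0
    consecutive_failures: int = 0
    regions_processed: int = 0
    halted: bool = False


def _interval_union_size(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    total += cur_hi - cur_lo
    return total


def cluster_seeds(
    seeds: list[Seed],
    read_len: int,
    *,
    text_len: Optional[int] = None,
    padding_factor: float = 0.05,
) -> list[CandidateRegion]:
    """Bin seeds of one (read, strand) pass into non-overlapping regions.

    The longest unassigned seed anchors each region; the region covers the
    anchor's implied read projection padded by ``padding_factor * read_len``
    on both sides, truncated against previously built regions; unassigned
    seeds whose reference interval overlaps it join the region (so no later
    anchor can straddle a region boundary, keeping the intervals disjoint).
    """
    if not seeds:
        return []
    strands = {s.strand for s in seeds}
    if len(strands) > 1:
        raise ValueError("cluster_seeds expects seeds from a single strand")
    limit = text_len if text_len is not None else max(s.ref_end for s in seeds) + read_len
    pad = int(round(padding_factor * read_len))
    by_ref = sorted(seeds, key=lambda s: (s.ref_start, s.read_start))
    unassigned = set(range(len(by_ref)))
    order = sorted(unassigned, key=lambda i: (-by_ref[i].length, by_ref[i].ref_start))
    regions: list[CandidateRegion] = []
    taken: list[tuple[int, int]] = []  # existing region intervals
    for idx in order:
        if idx not in unassigned:
            continue
        anchor = by_ref[idx]
        lo = max(0, anchor.ref_start - anchor.read_start - pad)
        hi = min(limit, anchor.ref_start - anchor.read_start + read_len + pad)
        for t_lo, t_hi in taken:
            if t_hi <= anchor.ref_start and t_hi > lo:
                lo = t_hi
            if t_lo >= anchor.ref_end and t_lo < hi:
                hi = t_lo
        if lo >= hi:
            unassigned.discard(idx)
            continue
        members = [
            i
            for i in unassigned
            if by_ref[i].ref_start < hi and by_ref[i].ref_end > lo
        ]
        region = CandidateRegion(
            ref_start=lo,
            ref_end=hi,
            strand=anchor.strand,
            seeds=sorted(
                (by_ref[i] for i in members), key=lambda s: (s.ref_start, s.read_start)
            ),
            anchor=anchor,
        )
        region.recompute()
        regions.append(region)
        taken.append((lo, hi))
        unassigned.difference_update(members)
    regions.sort(key=lambda r: r.ref_start)
    return regions


def augment_region(region: CandidateRegion, all_mems: list[Seed]) -> CandidateRegion:
    """Add any MEM (rare or not, same strand) overlapping the region's
    reference interval; coverage is recomputed, the anchor is unchanged."""
    present = {s.key() for s in region.seeds}
    added = False
    for mem in all_mems:
        if mem.strand != region.strand or mem.key() in present:
            continue
        if mem.ref_start < region.ref_end and mem.ref_end > region.ref_start:
            region.seeds.append(mem)
            present.add(mem.key())
            added = True
    if added:
        region.seeds.sort(key=lambda s: (s.ref_start, s.read_start))
        region.recompute()
    return region


def rank_regions(regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Descending coverage; ties: longer anchor, then smaller ref_start."""
    return sorted(
        regions, key=lambda r: (-r.coverage, -r.anchor.length, r.ref_start)
    )


def schedule_extensions(
    ranked: list[CandidateRegion],
    extender: Callable[[CandidateRegion], list[AlignmentResult]],
    caps: SchedulerCaps,
    state: Optional[SchedulerState] = None,
) -> list[AlignmentResult]:
    """Extend regions in rank order under the halting rules; regions with a
    read-unique seed are extended even after halting."""
    if state is None:
        state = SchedulerState()
    results: list[AlignmentResult] = []
    best_coverage = ranked[0].coverage if ranked else 0
    for region in ranked:
        if state.feasible_found >= caps.max_feasible:
            state.halted = True
        if state.consecutive_failures >= caps.max_failures:
            state.halted = True
        if region.coverage < caps.min_coverage_fraction * best_coverage:
            state.halted = True
        if state.halted and not region.has_unique_seed:
            continue
        alignments = [a for a in extender(region) if a.feasible]
        state.regions_processed += 1
        if alignments:
            results.extend(alignments)
            state.feasible_found += len(alignments)
            state.consecutive_failures = 0
        else:
            state.consecutive_failures += 1
    return results


def build_regions(
    seeds: list[Seed],
    read_len: int,
    *,
    text_len: int,
    max_occurrences: int,
    padding_factor: float = 0.05,
) -> list[CandidateRegion]:
    """Cluster per strand from SMEMs + rare MEMs, augment with all MEMs,
    merge strands and rank (strands compete by coverage)."""
    regions: list[CandidateRegion] = []
    for strand in ("+", "-"):
        strand_seeds = [s for s in seeds if s.strand == strand]
        filtered = [
            s
            for s in strand_seeds
            if s.is_smem or s.occurrence_count <= max_occurrences
        ]
        clustered = cluster_seeds(
            filtered, read_len, text_len=text_len, padding_factor=padding_factor
        )
        for region in clustered:
            augment_region(region, strand_seeds)
        regions.extend(clustered)
    return rank_regions(regions)


def region_rescue(
    read: str,
    index,
    params: SeedParams,
    extender: Callable[[CandidateRegion], list[AlignmentResult]],
    caps: SchedulerCaps,
    *,
    padding_factor: float = 0.05,
) -> list[AlignmentResult]:
    """After a fruitless primary pass: relax the scheduler (3x the failure
    budget, no coverage cutoff) and re-run; if still empty, rebuild the seed
    set via seed rescue and redo clustering and scheduling."""
    relaxed = SchedulerCaps(
        max_feasible=caps.max_feasible,
        max_failures=caps.max_failures * RESCUE_FAILURE_FACTOR,
        min_coverage_fraction=0.0,
    )
    seeds = collect_seeds(index, read, params)
    ranked = build_regions(
        seeds,
        len(read),
        text_len=index.n_text,
        max_occurrences=params.max_occurrences,
        padding_factor=padding_factor,
    )
    results = schedule_extensions(ranked, extender, relaxed)
    if results:
        return results
    rescued = seed_rescue(index, read, params)
    if not rescued:
        return []
    ranked = build_regions(
        rescued,
        len(read),
        text_len=index.n_text,
        max_occurrences=params.max_occurrences * 10,
        padding_factor=padding_factor,
    )
    return schedule_extensions(ranked, extender, relaxed)
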