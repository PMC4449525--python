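"""Paired-end mapping strategies and their rescue cascade.

Four strategies are supported: independent mapping of both mates followed by
constraint-based pairing (the default and best overall), bridging (full
banded DP for the mate inside the window implied by a mapped end), and two
joint variants that couple the mates' candidate regions before extension
(prioritize / filter).  When the primary strategy yields no proper pair the
rescue cascade tries the other strategies in a fixed order rather than
relaxing heuristics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .align import (
    AlignmentResult,
    ScoringScheme,
    banded_align,
    min_feasible_score,
)
from .reference_io import Reference, reverse_complement

FR, RF, FF = "fr", "rf", "ff"

JOINT_MAX_PAIRS = 8


@dataclass
class PairConstraint:
    min_insert: int
    max_insert: int
    orientation: str = FR

    def __post_init__(self) -> None:
        if not 0 <= self.min_insert <= self.max_insert:
            raise ValueError("require 0 <= min_insert <= max_insert")
        if self.orientation not in (FR, RF, FF):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class PairedAlignment:
    first: AlignmentResult
    second: AlignmentResult
    insert_size: int = 0
    proper: bool = False

    @property
    def combined_score(self) -> int:
        return self.first.score + self.second.score


def _orientation_ok(up: AlignmentResult, down: AlignmentResult, orientation: str) -> bool:
    if orientation == FR:
        return up.strand == "+" and down.strand == "-"
    if orientation == RF:
        return up.strand == "-" and down.strand == "+"
    return up.strand == down.strand


def make_pair(
    a1: AlignmentResult, a2: AlignmentResult, c: PairConstraint, reference: Reference
) -> PairedAlignment:
    """Pair two mate alignments and evaluate the proper-pair predicate:
    matching orientation, insert (outermost span) within bounds, one contig."""
    left, right = (a1, a2) if a1.ref_start <= a2.ref_start else (a2, a1)
    span = right.ref_end - left.ref_start
    insert = span if a1.ref_start <= a2.ref_start else -span
    same_contig = reference.contig_index_of(a1.ref_start) == reference.contig_index_of(
        a2.ref_start
    )
    proper = (
        same_contig
        and _orientation_ok(left, right, c.orientation)
        and c.min_insert <= span <= c.max_insert
    )
    return PairedAlignment(first=a1, second=a2, insert_size=insert, proper=proper)


def pair_independent(
    alns1: list[AlignmentResult],
    alns2: list[AlignmentResult],
    c: PairConstraint,
    reference: Reference,
) -> list[PairedAlignment]:
    """All cross-product pairings satisfying the constraint, ranked by
    combined score (deterministic tie-break on coordinates)."""
    pairs = []
    for a1 in alns1:
        for a2 in alns2:
            if not (a1.feasible and a2.feasible):
                continue
            pair = make_pair(a1, a2, c, reference)
            if pair.proper:
                pairs.append(pair)
    pairs.sort(
        key=lambda p: (-p.combined_score, p.first.ref_start, p.second.ref_start)
    )
    return pairs


def _mate_window(
    mapped: AlignmentResult, mate_len: int, c: PairConstraint, reference: Reference
) -> tuple[int, int, str]:
    """(window_lo, window_hi, expected mate strand) implied by a mapped end."""
    lo_b, hi_b = reference.contig_bounds(mapped.ref_start)
    if c.orientation == FF:
        strand = mapped.strand
        lo = mapped.ref_start - c.max_insert
        hi = mapped.ref_end + c.max_insert
    else:
        strand = "-" if mapped.strand == "+" else "+"
        # fr: a forward mate is upstream of its reverse partner; rf mirrors
        downstream = (mapped.strand == "+") == (c.orientation == FR)
        if downstream:
            lo = mapped.ref_start + max(0, c.min_insert - mate_len)
            hi = mapped.ref_start + c.max_insert
        else:
            lo = mapped.ref_end - c.max_insert
            hi = mapped.ref_end - max(0, c.min_insert - mate_len)
    return max(lo_b, lo), min(hi_b, hi), strand


def pair_bridge(
    mapped: AlignmentResult,
    mate_seq: str,
    mapped_is_first: bool,
    c: PairConstraint,
    reference: Reference,
    scoring: ScoringScheme,
    error_rate: float = 0.05,
) -> Optional[PairedAlignment]:
    """Full banded DP of the mate against the window implied by the mapped
    end and the insert constraint; windows are truncated at contig bounds."""
    lo, hi, strand = _mate_window(mapped, len(mate_seq), c, reference)
    if hi - lo < 1:
        return None
    oriented = mate_seq if strand == "+" else reverse_complement(mate_seq)
    band = int(math.ceil(error_rate * len(oriented))) + 5
    threshold = min_feasible_score(len(oriented), scoring, error_rate)
    aln = banded_align(reference.sequence[lo:hi], oriented, band, scoring, threshold)
    if not aln.feasible:
        return None
    aln.ref_start += lo
    aln.strand = strand
    a1, a2 = (mapped, aln) if mapped_is_first else (aln, mapped)
    pair = make_pair(a1, a2, c, reference)
    return pair if pair.proper else None


def _regions_compatible(r1, r2, c: PairConstraint) -> bool:
    if c.orientation == FF:
        if r1.strand != r2.strand:
            return False
    else:
        if r1.strand == r2.strand:
            return False
        up, down = (r1, r2) if r1.ref_start <= r2.ref_start else (r2, r1)
        want_up = "+" if c.orientation == FR else "-"
        if up.strand != want_up:
            return False
    gap = max(0, max(r1.ref_start, r2.ref_start) - min(r1.ref_end, r2.ref_end))
    outer = max(r1.ref_end, r2.ref_end) - min(r1.ref_start, r2.ref_start)
    return gap <= c.max_insert and outer >= c.min_insert


def pair_joint(
    regions1: list,
    regions2: list,
    c: PairConstraint,
    extender1: Callable,
    extender2: Callable,
    reference: Reference,
    mode: str = "filter",
) -> list[PairedAlignment]:
    """Couple the mates' candidate regions before extension.

    ``filter``: extend only regions participating in at least one
    geometrically compatible pair.  ``prioritize``: extend region pairs in
    order of summed coverage until a proper pair appears.
    """
    compat = [
        (i, j)
        for i, r1 in enumerate(regions1)
        for j, r2 in enumerate(regions2)
        if _regions_compatible(r1, r2, c)
    ]
    if not compat:
        return []
    alns1: dict[int, list[AlignmentResult]] = {}
    alns2: dict[int, list[AlignmentResult]] = {}

    def extend(i: int, which: int) -> list[AlignmentResult]:
        cache, regions, extender = (
            (alns1, regions1, extender1) if which == 1 else (alns2, regions2, extender2)
        )
        if i not in cache:
            cache[i] = [a for a in extender(regions[i]) if a.feasible]
        return cache[i]

    if mode == "filter":
        for i in sorted({i for i, _ in compat}):
            extend(i, 1)
        for j in sorted({j for _, j in compat}):
            extend(j, 2)
    else:  # prioritize
        ranked = sorted(
            compat,
            key=lambda ij: -(regions1[ij[0]].coverage + regions2[ij[1]].coverage),
        )
        for i, j in ranked[:JOINT_MAX_PAIRS]:
            extend(i, 1)
            extend(j, 2)
            found = pair_independent(
                [a for lst in alns1.values() for a in lst],
                [a for lst in alns2.values() for a in lst],
                c,
                reference,
            )
            if found:
                break
    all1 = [a for lst in alns1.values() for a in lst]
    all2 = [a for lst in alns2.values() for a in lst]
    return pair_independent(all1, all2, c, reference)


@dataclass
class PairingContext:
    """Lazy per-pair state handed to the strategy cascade by the mapper."""

    read1: str
    read2: str
    constraint: PairConstraint
    reference: Reference
    scoring: ScoringScheme
    error_rate: float
    align_mate: Callable[[int], list[AlignmentResult]]
    regions_for: Callable[[int], list]
    extender_for: Callable[[int], Callable]
    _alns: dict = field(default_factory=dict)
    strategies_run: list = field(default_factory=list)

    def alns(self, i: int) -> list[AlignmentResult]:
        if i not in self._alns:
            self._alns[i] = self.align_mate(i)
        return self._alns[i]


def run_strategy(ctx: PairingContext, name: str) -> list[PairedAlignment]:
    ctx.strategies_run.append(name)
    c = ctx.constraint
    if name == "independent":
        return pair_independent(ctx.alns(1), ctx.alns(2), c, ctx.reference)
    if name == "bridge":
        pairs = []
        for anchor in (1, 2):
            mate_seq = ctx.read2 if anchor == 1 else ctx.read1
            for mapped in ctx.alns(anchor)[:2]:
                pair = pair_bridge(
                    mapped,
                    mate_seq,
                    anchor == 1,
                    c,
                    ctx.reference,
                    ctx.scoring,
                    ctx.error_rate,
                )
                if pair is not None:
                    pairs.append(pair)
        pairs.sort(key=lambda p: (-p.combined_score, p.first.ref_start))
        return pairs
    if name in ("joint-filter", "joint-prioritize"):
        return pair_joint(
            ctx.regions_for(1),
            ctx.regions_for(2),
            c,
            ctx.extender_for(1),
            ctx.extender_for(2),
            ctx.reference,
            mode="filter" if name == "joint-filter" else "prioritize",
        )
    raise ValueError(f"unknown pairing strategy {name!r}")


RESCUE_ORDER = ("independent", "bridge", "joint-filter")


def paired_rescue(ctx: PairingContext) -> list[PairedAlignment]:
    """Strategy cascade after the primary strategy found no proper pair:
    independent, then bridging from either mate, then joint-filter; stops at
    the first proper pair."""
    for name in RESCUE_ORDER:
        if name in ctx.strategies_run:
            continue
        pairs = run_strategy(ctx, name)
        if pairs:
            return pairs
    return []
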