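"""Collinear, skew-bounded chaining of seeds inside a candidate region.

The skew between two seeds is the absolute difference between the distance
separating them on the read and on the reference; it bounds the net indel
content between them.  Chains are grown greedily outward from an anchor
(nearest seed in read order first); a seed is admitted only while collinear
with the current chain end and with skew at most base_skew + skew_slope*gap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .seeds import Seed

DEFAULT_BASE_SKEW = 5
DEFAULT_SKEW_SLOPE = 0.15
DEFAULT_MAX_CHAINS = 3


@dataclass
class ChainParams:
    base_skew: int = DEFAULT_BASE_SKEW
    skew_slope: float = DEFAULT_SKEW_SLOPE
    max_chains_per_region: int = DEFAULT_MAX_CHAINS


@dataclass
class Chain:
    seeds: list[Seed]
    anchor: Seed

    @property
    def read_span(self) -> tuple[int, int]:
        return self.seeds[0].read_start, self.seeds[-1].read_end

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.seeds[0].ref_start, self.seeds[-1].ref_end

    @property
    def total_seed_length(self) -> int:
        return sum(s.length for s in self.seeds)

    @property
    def strand(self) -> str:
        return self.anchor.strand


def skew(a: Seed, b: Seed) -> int:
    """|ref gap - read gap| between two seeds taken in read order."""
    if b.read_start < a.read_start:
        a, b = b, a
    return abs((b.ref_start - a.ref_end) - (b.read_start - a.read_end))


def _admissible(end: Seed, cand: Seed, params: ChainParams, forward: bool) -> bool:
    if forward:
        collinear = cand.read_start > end.read_start and cand.ref_start > end.ref_start
        gap = max(0, cand.read_start - end.read_end)
    else:
        collinear = cand.read_start < end.read_start and cand.ref_start < end.ref_start
        gap = max(0, end.read_start - cand.read_end)
    if not collinear:
        return False
    return skew(end, cand) <= params.base_skew + params.skew_slope * gap


def _trim_overlaps(seeds: list[Seed]) -> list[Seed]:
    """Shorten the later of each overlapping pair (on read or reference);
    seeds trimmed to nothing are dropped."""
    out: list[Seed] = []
    for s in seeds:
        if out:
            prev = out[-1]
            overlap = max(prev.read_end - s.read_start, prev.ref_end - s.ref_start, 0)
            if overlap:
                s = replace(
                    s,
                    read_start=s.read_start + overlap,
                    ref_start=s.ref_start + overlap,
                    length=s.length - overlap,
                )
                if s.length <= 0:
                    continue
        out.append(s)
    return out


def build_chain(region_seeds: list[Seed], anchor: Seed, params: ChainParams) -> Chain:
    """Greedy chain from ``anchor``: extend right then left in read order,
    nearest seed first, admitting only collinear seeds within the skew bound;
    admitted seeds are then trimmed to restore non-overlap."""
    others = [s for s in region_seeds if s.key() != anchor.key()]
    right = sorted(
        (s for s in others if s.read_start > anchor.read_start),
        key=lambda s: (s.read_start, s.ref_start),
    )
    left = sorted(
        (s for s in others if s.read_start < anchor.read_start),
        key=lambda s: (-s.read_start, -s.ref_start),
    )
    chain = [anchor]
    end = anchor
    for cand in right:
        if _admissible(end, cand, params, forward=True):
            chain.append(cand)
            end = cand
    start = anchor
    head: list[Seed] = []
    for cand in left:
        if _admissible(start, cand, params, forward=False):
            head.append(cand)
            start = cand
    seeds = _trim_overlaps(list(reversed(head)) + chain)
    return Chain(seeds=seeds, anchor=anchor)


def enumerate_chains(region_seeds: list[Seed], params: ChainParams) -> list[Chain]:
    """Chains for one region: anchors taken in decreasing seed-length order,
    seeds already chained may join later chains but no longer anchor one;
    at most ``max_chains_per_region`` chains, ordered by total seed length."""
    if not region_seeds:
        return []
    chained: set = set()
    chains: list[Chain] = []
    for anchor in sorted(
        region_seeds, key=lambda s: (-s.length, s.ref_start, s.read_start)
    ):
        if len(chains) >= params.max_chains_per_region:
            break
        if anchor.key() in chained:
            continue
        chain = build_chain(region_seeds, anchor, params)
        chained.update(s.key() for s in chain.seeds)
        chained.add(anchor.key())
        chains.append(chain)
    chains.sort(key=lambda c: (-c.total_seed_length, c.ref_span[0]))
    return chains
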