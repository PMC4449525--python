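"""MEM/SMEM seed finding between a read and the sparse index.

A maximal exact match (MEM) is an exact read/reference match that cannot be
extended on either side without hitting a mismatch or a boundary; an SMEM is
a MEM whose read interval is not contained in any other MEM's read interval.
Because the index samples only every s-th reference suffix, a MEM is located
by matching read suffixes (stepped by the query sampling value q) down the
lcp-interval tree until depth K = L - q*s + 1 and then extending every
sampled occurrence in both directions.  With gcd(q, s) = 1 and
q*s <= L - s + 1 every MEM of length >= L contains a (query position,
sampled suffix) pair matching at least K characters, so none is missed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .index import ESSAIndex, match_prefix
from .reference_io import encode, reverse_complement

DEFAULT_ERROR_RATE = 0.05
DEFAULT_MIN_SEED_FLOOR = 20
DEFAULT_MIN_SEED_CAP = 40
DEFAULT_MAX_OCCURRENCES = 10
RESCUE_LEVELS = 3
RESCUE_SHRINK = 0.75
RESCUE_OCC_FACTOR = 10
RESCUE_HARD_FLOOR = 10

FORWARD = "+"
REVERSE = "-"


@dataclass(frozen=True)
class Seed:
    """An exact match: read[read_start:read_start+length] == ref[ref_start:...].

    ``read_start`` refers to the oriented read (the reverse complement for
    reverse-strand seeds).
    """

    read_start: int
    ref_start: int
    length: int
    strand: str = FORWARD
    is_smem: bool = False
    occurrence_count: int = 1

    @property
    def read_end(self) -> int:
        return self.read_start + self.length

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    def key(self) -> tuple:
        return (self.strand, self.read_start, self.ref_start, self.length)


@dataclass
class SeedParams:
    min_seed_len: int
    query_step: int = 1
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES
    rescue_level: int = 0


def auto_min_seed_len(
    read_len: int,
    error_rate: float,
    floor: int = DEFAULT_MIN_SEED_FLOOR,
    cap: int = DEFAULT_MIN_SEED_CAP,
) -> int:
    """Pigeonhole minimum seed length: a read with k errors keeps an exact
    stretch of at least floor(m/(k+1)) bases; clamp into [floor, cap]."""
    k = math.floor(error_rate * read_len + 1e-9)
    raw = read_len // (k + 1)
    return max(floor, min(cap, raw))


def auto_query_step(sparseness: int, min_seed_len: int) -> int:
    """Largest q >= 1 with gcd(q, s) = 1 and q*s <= L - s + 1.

    This is the coarsest read-suffix sampling that still guarantees every
    MEM of length >= L aligns a sampled reference suffix with a queried
    read position inside the match.
    """
    s, L = sparseness, min_seed_len
    for q in range((L - s + 1) // s, 1, -1):
        if math.gcd(q, s) == 1:
            return q
    return 1


@njit(cache=True)
def _interval_at_depth(codes, sa, lcp, child, pat, start, K):
    """(lo, hi) of sampled suffixes matching >= K chars of pat[start:], else (-1,-1)."""
    n = len(sa)
    N = len(codes)
    m = len(pat)
    i, j = 0, n - 1
    depth = 0
    while depth < K:
        if start + depth >= m:
            return -1, -1
        pc = pat[start + depth]
        if pc == 0 or pc == 4:  # sentinel / N never match
            return -1, -1
        if i == j:
            p = sa[i]
            l = depth
            while l < K:
                c = pat[start + l]
                if c == 0 or c == 4:
                    return -1, -1
                if p + l >= N or codes[p + l] != c:
                    return -1, -1
                l += 1
            return i, j
        # locate first l-index of [i, j]
        k = child[j]
        if not (i < k <= j):
            k = child[i]
        d = lcp[k]
        # scan child intervals for the edge starting with pc
        a, b = i, k - 1
        cur = k
        last = False
        fa, fb = -1, -1
        while True:
            edge = sa[a] + depth
            if edge < N and codes[edge] == pc:
                fa, fb = a, b
                break
            if last:
                break
            nxt = child[cur]
            if cur < nxt and nxt <= j and lcp[nxt] == d:
                a, b = cur, nxt - 1
                cur = nxt
            else:
                a, b = cur, j
                last = True
        if fa < 0:
            return -1, -1
        if fa == fb:
            i, j = fa, fb
            continue
        # depth of the child interval
        k2 = child[fb]
        if not (fa < k2 <= fb):
            k2 = child[fa]
        node_depth = lcp[k2]
        limit = node_depth if node_depth < K else K
        p = sa[fa]
        l = depth
        while l < limit:
            c = pat[start + l]
            if c == 0 or c == 4 or codes[p + l] != c:
                return -1, -1
            l += 1
        i, j = fa, fb
        depth = limit
    return i, j


@njit(cache=True)
def _find_mems_kernel(codes, sa, lcp, child, pat, q, K, L):
    m = len(pat)
    N = len(codes)
    cap = 256
    out = np.empty((cap, 3), dtype=np.int64)
    cnt = 0
    x = 0
    while x + K <= m:
        lo, hi = _interval_at_depth(codes, sa, lcp, child, pat, x, K)
        if lo >= 0:
            for t in range(lo, hi + 1):
                p = sa[t]
                r = 0
                while x + r < m and p + r < N:
                    c = pat[x + r]
                    if c == 0 or c == 4 or codes[p + r] != c:
                        break
                    r += 1
                if r < 1:
                    continue
                l = 0
                while x - l > 0 and p - l > 0:
                    c = pat[x - l - 1]
                    if c == 0 or c == 4 or codes[p - l - 1] != c:
                        break
                    l += 1
                if l + r >= L:
                    if cnt == cap:
                        cap *= 2
                        bigger = np.empty((cap, 3), dtype=np.int64)
                        bigger[:cnt] = out[:cnt]
                        out = bigger
                    out[cnt, 0] = x - l
                    out[cnt, 1] = p - l
                    out[cnt, 2] = l + r
                    cnt += 1
        x += q
    return out[:cnt]


def occurrence_count(index: ESSAIndex, read: str, read_start: int, length: int) -> int:
    """Sampled-suffix occurrence count of a read interval (floored at 1).

    Counts the width of the sa-interval at the seed's full matched depth;
    with a sparse index this is a lower-bound proxy for the true number of
    reference occurrences.
    """
    hits = match_prefix(index, read[read_start : read_start + length], min_len=length)
    if not hits:
        return 1
    lo, hi, _ = hits[0]
    return max(1, hi - lo + 1)


def find_mems(
    index: ESSAIndex,
    read: str,
    params: SeedParams,
    strand: str = FORWARD,
    count_occurrences: bool = True,
) -> list[Seed]:
    """All MEMs of length >= params.min_seed_len between ``read`` (oriented)
    and the indexed reference, deduplicated and sorted by (ref_start,
    read_start)."""
    L = params.min_seed_len
    q = params.query_step
    if len(read) < L:
        return []
    K = max(1, L - q * index.sparseness + 1)
    pat = encode(read)
    raw = _find_mems_kernel(index.codes, index.sa, index.lcp, index.child, pat, q, K, L)
    uniq = sorted({(int(r[1]), int(r[0]), int(r[2])) for r in raw})
    seeds = []
    for ref_start, read_start, length in uniq:
        occ = (
            occurrence_count(index, read, read_start, length)
            if count_occurrences
            else 1
        )
        seeds.append(
            Seed(
                read_start=read_start,
                ref_start=ref_start,
                length=length,
                strand=strand,
                occurrence_count=occ,
            )
        )
    return seeds


def filter_smems(mems: list[Seed]) -> list[Seed]:
    """MEMs whose read interval is not properly contained in another MEM's
    read interval (identical intervals are all kept, all SMEM); flags are
    set on the returned seeds.  Strands are handled independently."""
    out = []
    for strand in (FORWARD, REVERSE):
        group = [s for s in mems if s.strand == strand]
        if not group:
            continue
        order = sorted(group, key=lambda s: (s.read_start, -s.read_end))
        max_end_before = -1
        idx = 0
        while idx < len(order):
            jdx = idx
            while jdx < len(order) and order[jdx].read_start == order[idx].read_start:
                jdx += 1
            group_max_end = order[idx].read_end
            for s in order[idx:jdx]:
                contained = max_end_before >= s.read_end or s.read_end < group_max_end
                if not contained:
                    out.append(replace(s, is_smem=True))
            max_end_before = max(max_end_before, group_max_end)
            idx = jdx
    out.sort(key=lambda s: (s.strand, s.ref_start, s.read_start))
    return out


def collect_seeds(index: ESSAIndex, read: str, params: SeedParams) -> list[Seed]:
    """MEMs on both strands (the reverse complement is seeded independently),
    with SMEM flags applied."""
    fwd = find_mems(index, read, params, strand=FORWARD)
    rev = find_mems(index, reverse_complement(read), params, strand=REVERSE)
    mems = fwd + rev
    smem_keys = {s.key() for s in filter_smems(mems)}
    return [replace(s, is_smem=s.key() in smem_keys) for s in mems]


def seed_rescue(index: ESSAIndex, read: str, params: SeedParams) -> list[Seed]:
    """Progressively relax seeding after an empty primary search: per level,
    shrink L by 25% (down to max(s, 10)), force q=1 and raise the rarity cap
    tenfold; stop at the first non-empty seed set (at most 3 levels)."""
    hard_floor = max(index.sparseness, RESCUE_HARD_FLOOR)
    L = params.min_seed_len
    for level in range(1, RESCUE_LEVELS + 1):
        L = max(hard_floor, int(params.min_seed_len * RESCUE_SHRINK**level))
        relaxed = SeedParams(
            min_seed_len=L,
            query_step=1,
            max_occurrences=params.max_occurrences * RESCUE_OCC_FACTOR**level,
            rescue_level=level,
        )
        seeds = collect_seeds(index, read, relaxed)
        if seeds:
            return seeds
        if L == hard_floor:
            break
    return []
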