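"""Chain-guided banded affine-gap alignment.

Seeds of a chain contribute exact match segments; each inter-seed gap is
resolved either by a constant-time bridging rule (pure substitutions, a pure
indel, or a single end-anchored indel) or, failing that, by banded affine-gap
dynamic programming (Gotoh) on the gap rectangle.  Read ends outside the
chain are extended by banded DP (end-to-end) or soft-clipped (local mode).
The same DP kernel also powers whole-read banded alignment and the unbanded
oracle used in tests (band >= sequence length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .chains import Chain
from .reference_io import encode

# kernel modes
GLOBAL, GLOCAL, EXTEND_E2E, EXTEND_SOFT, LOCAL = 0, 1, 2, 3, 4

NEG = -(2**28)

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = 4
DEFAULT_GAP_OPEN = 6
DEFAULT_GAP_EXTEND = 1

END_TO_END = "end_to_end"
LOCAL_MODE = "local"

DEFAULT_MAX_DP_AREA = 4_000_000
MIN_SCORE_FLOOR_FRACTION = 0.3
BRIDGE_MAX_SUBSTITUTIONS = 2


@dataclass
class ScoringScheme:
    match: int = DEFAULT_MATCH
    mismatch: int = DEFAULT_MISMATCH
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND
    mode: str = END_TO_END

    def gap_cost(self, length: int) -> int:
        return self.gap_open + length * self.gap_extend if length else 0


@dataclass
class AlignmentResult:
    strand: str
    ref_start: int
    cigar: list[tuple[str, int]] = field(default_factory=list)
    score: int = NEG
    edit_distance: int = 0
    mapq: int = 0
    feasible: bool = False

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD=X")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


def infeasible(strand: str = "+") -> AlignmentResult:
    return AlignmentResult(strand=strand, ref_start=-1, feasible=False)


def min_feasible_score(read_len: int, scoring: ScoringScheme, error_rate: float) -> float:
    """Score an alignment must reach to count as feasible: a linear error
    budget, floor-clamped at 30% of the perfect-match score."""
    full = scoring.match * read_len
    budget = full * (
        1.0 - 2.0 * error_rate * (scoring.mismatch + scoring.match) / scoring.match
    )
    return max(MIN_SCORE_FLOOR_FRACTION * full, budget)


@njit(cache=True)
def _gotoh_fill(ref, read, band_lo, band_hi, match, mismatch, go, ge, mode):
    m = len(read)
    n = len(ref)
    H = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    TH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    TE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    TF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    free_ref_start = mode == 1 or mode == 4
    local = mode == 4
    H[0, 0] = 0
    jhi0 = band_hi if band_hi < n else n
    for j in range(1, jhi0 + 1):
        if free_ref_start:
            H[0, j] = 0
        else:
            e1 = H[0, j - 1] - go - ge
            e2 = E[0, j - 1] - ge
            if e1 >= e2:
                E[0, j] = e1
                TE[0, j] = 0
            else:
                E[0, j] = e2
                TE[0, j] = 1
            H[0, j] = E[0, j]
            TH[0, j] = 2
    for i in range(1, m + 1):
        jlo = i + band_lo
        jhi = i + band_hi
        if jlo < 0:
            jlo = 0
        if jhi > n:
            jhi = n
        if jlo > jhi:
            continue
        ci = read[i - 1]
        for j in range(jlo, jhi + 1):
            if j == 0:
                if local:
                    H[i, 0] = 0
                else:
                    f1 = H[i - 1, 0] - go - ge
                    f2 = F[i - 1, 0] - ge
                    if f1 >= f2:
                        F[i, 0] = f1
                        TF[i, 0] = 0
                    else:
                        F[i, 0] = f2
                        TF[i, 0] = 1
                    H[i, 0] = F[i, 0]
                    TH[i, 0] = 3
                continue
            e1 = H[i, j - 1] - go - ge
            e2 = E[i, j - 1] - ge
            if e1 >= e2:
                E[i, j] = e1
                TE[i, j] = 0
            else:
                E[i, j] = e2
                TE[i, j] = 1
            f1 = H[i - 1, j] - go - ge
            f2 = F[i - 1, j] - ge
            if f1 >= f2:
                F[i, j] = f1
                TF[i, j] = 0
            else:
                F[i, j] = f2
                TF[i, j] = 1
            cj = ref[j - 1]
            if ci == cj and ci != 0 and ci != 4:
                sub = match
            else:
                sub = -mismatch
            best = H[i - 1, j - 1] + sub
            tb = 1
            if E[i, j] > best:
                best = E[i, j]
                tb = 2
            if F[i, j] > best:
                best = F[i, j]
                tb = 3
            if local and best < 0:
                best = 0
                tb = 0
            H[i, j] = best
            TH[i, j] = tb
    return H, E, F, TH, TE, TF


def _rle(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def merge_cigar(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _traceback(H, TH, TE, TF, i, j, mode):
    """Walk traceback pointers from (i, j); returns (i0, j0, ops)."""
    ops: list[str] = []
    state = 0
    while True:
        if state == 0:
            if mode == LOCAL and H[i, j] == 0:
                break
            if i == 0 and j == 0:
                break
            t = TH[i, j]
            if t == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif t == 2:
                state = 1
            elif t == 3:
                state = 2
            else:
                break  # free boundary / local start
        elif state == 1:
            ops.append("D")
            if TE[i, j] == 0:
                state = 0
            j -= 1
        else:
            ops.append("I")
            if TF[i, j] == 0:
                state = 0
            i -= 1
    ops.reverse()
    return i, j, _rle(ops)


def _run_kernel(ref_codes, read_codes, band_lo, band_hi, scoring, mode):
    """Fill + traceback; returns (score, ref_start, ref_consumed, ops) or None."""
    m = len(read_codes)
    n = len(ref_codes)
    H, E, F, TH, TE, TF = _gotoh_fill(
        ref_codes,
        read_codes,
        band_lo,
        band_hi,
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
        mode,
    )
    if mode in (GLOCAL, EXTEND_E2E):
        j_best = int(np.argmax(H[m]))
        score = int(H[m, j_best])
        if score <= NEG // 2:
            return None
        i0, j0, ops = _traceback(H, TH, TE, TF, m, j_best, mode)
        return score, j0, j_best - j0, ops
    if mode == GLOBAL:
        score = int(H[m, n])
        if score <= NEG // 2:
            return None
        i0, j0, ops = _traceback(H, TH, TE, TF, m, n, mode)
        return score, j0, n - j0, ops
    # LOCAL / EXTEND_SOFT: best cell anywhere
    flat = int(np.argmax(H))
    i_best, j_best = divmod(flat, n + 1)
    score = int(H[i_best, j_best])
    if score <= 0:
        return 0, 0, 0, [("S", m)] if m else []
    i0, j0, ops = _traceback(H, TH, TE, TF, i_best, j_best, mode)
    if i0 > 0:
        ops = [("S", i0)] + ops
    if i_best < m:
        ops = ops + [("S", m - i_best)]
    return score, j0, j_best - j0, ops


def band_limits(m: int, n: int, band_width: int) -> tuple[int, int]:
    """Diagonal-offset band covering both matrix corners +/- band_width."""
    return min(-band_width, n - m - band_width), max(band_width, n - m + band_width)


def banded_align(
    ref_window: str,
    read: str,
    band_width: int,
    scoring: ScoringScheme,
    min_score: float | None = None,
) -> AlignmentResult:
    """Affine-gap DP of the whole read against a reference window, confined
    to a diagonal band.  ``end_to_end`` aligns the full read with free
    reference flanks (glocal); ``local`` returns the best local alignment
    with soft clips.  ``ref_start`` is relative to the window."""
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    ref_codes = encode(ref_window)
    read_codes = encode(read)
    lo, hi = band_limits(len(read), len(ref_window), band_width)
    mode = GLOCAL if scoring.mode == END_TO_END else LOCAL
    result = _run_kernel(ref_codes, read_codes, lo, hi, scoring, mode)
    if result is None:
        return infeasible()
    score, j0, _, ops = result
    _, nm = rescore_cigar(ref_window, j0, read, ops, scoring)
    aln = AlignmentResult(
        strand="+", ref_start=j0, cigar=ops, score=score, edit_distance=nm
    )
    aln.feasible = score >= (min_score if min_score is not None else NEG // 4)
    return aln


def rescore_cigar(
    ref: str, ref_start: int, read: str, ops: list[tuple[str, int]], scoring: ScoringScheme
) -> tuple[int, int]:
    """(score, NM) of an explicit alignment; the self-consistency anchor for
    every emitted record."""
    score = 0
    nm = 0
    i = 0
    j = ref_start
    valid = "ACGT"
    for op, n in ops:
        if op in "M=X":
            for _ in range(n):
                a, b = read[i], ref[j]
                if a == b and a in valid:
                    score += scoring.match
                else:
                    score -= scoring.mismatch
                    nm += 1
                i += 1
                j += 1
        elif op == "I":
            score -= scoring.gap_cost(n)
            nm += n
            i += n
        elif op == "D":
            score -= scoring.gap_cost(n)
            nm += n
            j += n
        elif op == "S":
            i += n
    return score, nm


def bridge_gap(
    ref_gap: str, read_gap: str, scoring: ScoringScheme
) -> tuple[list[tuple[str, int]], int, int] | None:
    """Resolve the gap between two consecutive chain seeds without DP.

    Handles: empty/empty, pure substitutions (up to a small cap above which
    a mixed-indel alignment could score better), a pure insertion or
    deletion, and one contiguous end-anchored indel.  Returns
    ``(cigar_ops, score, nm)`` or None when DP is needed.
    """
    rg, qg = ref_gap, read_gap
    nr, nq = len(rg), len(qg)
    if nr == 0 and nq == 0:
        return [], 0, 0
    if nq == 0:
        return [("D", nr)], -scoring.gap_cost(nr), nr
    if nr == 0:
        return [("I", nq)], -scoring.gap_cost(nq), nq
    if nr == nq:
        mism = sum(
            1 for a, b in zip(qg, rg) if a != b or a not in "ACGT"
        )
        if mism <= BRIDGE_MAX_SUBSTITUTIONS:
            score = (nq - mism) * scoring.match - mism * scoring.mismatch
            return [("M", nq)], score, mism
        return None
    def _eq(a: str, b: str) -> bool:
        return a == b and all(c in "ACGT" for c in a)
    if nr > nq:
        d = nr - nq
        if _eq(rg[d:], qg):
            return (
                [("D", d), ("M", nq)],
                nq * scoring.match - scoring.gap_cost(d),
                d,
            )
        if _eq(rg[:nq], qg):
            return (
                [("M", nq), ("D", d)],
                nq * scoring.match - scoring.gap_cost(d),
                d,
            )
    else:
        d = nq - nr
        if _eq(rg, qg[d:]):
            return (
                [("I", d), ("M", nr)],
                nr * scoring.match - scoring.gap_cost(d),
                d,
            )
        if _eq(rg, qg[:nr]):
            return (
                [("M", nr), ("I", d)],
                nr * scoring.match - scoring.gap_cost(d),
                d,
            )
    return None


def _extend_flank(
    flank: str,
    ref_segment: str,
    scoring: ScoringScheme,
    band: int,
    left: bool,
) -> tuple[list[tuple[str, int]], int]:
    """Align a read flank anchored at the seed junction.

    Returns (ops, ref_consumed).  For the left flank both strings are
    reversed so the junction becomes the fixed DP corner.
    """
    if not flank:
        return [], 0
    if not ref_segment:
        if scoring.mode == END_TO_END:
            return [("I", len(flank))], 0
        return [("S", len(flank))], 0
    fl = flank[::-1] if left else flank
    seg = ref_segment[::-1] if left else ref_segment
    mode = EXTEND_E2E if scoring.mode == END_TO_END else EXTEND_SOFT
    lo, hi = band_limits(len(fl), len(seg), band)
    result = _run_kernel(encode(seg), encode(fl), lo, hi, scoring, mode)
    if result is None:
        if scoring.mode == END_TO_END:
            return [("I", len(flank))], 0
        return [("S", len(flank))], 0
    _, _, ref_consumed, ops = result
    if left:
        ops = [(op, n) for op, n in reversed(ops)]
    return ops, ref_consumed


def chain_guided_align(
    chain: Chain,
    text: str,
    read: str,
    scoring: ScoringScheme,
    *,
    error_rate: float = 0.05,
    base_skew: int = 5,
    max_dp_area: int = DEFAULT_MAX_DP_AREA,
    bounds: tuple[int, int] | None = None,
) -> AlignmentResult:
    """Alignment of ``read`` (oriented) guided by a chain: seeds become
    exact match segments, inter-seed gaps are bridged or solved by banded
    DP, and read ends are extended (or soft-clipped in local mode).
    ``bounds`` clamps the reference window, e.g. to the anchor's contig."""
    seeds = chain.seeds
    m = len(read)
    lo_bound, hi_bound = bounds if bounds is not None else (0, len(text))
    first, last = seeds[0], seeds[-1]

    ops: list[tuple[str, int]] = []
    # left flank
    flank = read[: first.read_start]
    band = int(math.ceil(error_rate * len(flank))) + base_skew + 2
    ref_lo = max(lo_bound, first.ref_start - len(flank) - band)
    left_ops, left_ref = _extend_flank(
        flank, text[ref_lo : first.ref_start], scoring, band, left=True
    )
    ops.extend(left_ops)
    align_start = first.ref_start - left_ref

    ops.append(("M", first.length))
    prev = first
    for seed in seeds[1:]:
        rg = text[prev.ref_end : seed.ref_start]
        qg = read[prev.read_end : seed.read_start]
        bridged = bridge_gap(rg, qg, scoring)
        if bridged is not None:
            ops.extend(bridged[0])
        else:
            if len(rg) * len(qg) > max_dp_area:
                return infeasible(chain.strand)
            band_g = abs(len(rg) - len(qg)) + base_skew + 2
            lo, hi = band_limits(len(qg), len(rg), band_g)
            result = _run_kernel(encode(rg), encode(qg), lo, hi, scoring, GLOBAL)
            if result is None:
                return infeasible(chain.strand)
            ops.extend(result[3])
        ops.append(("M", seed.length))
        prev = seed

    # right flank
    flank = read[last.read_end :]
    band = int(math.ceil(error_rate * len(flank))) + base_skew + 2
    ref_hi = min(hi_bound, last.ref_end + len(flank) + band)
    right_ops, _ = _extend_flank(
        flank, text[last.ref_end : ref_hi], scoring, band, left=False
    )
    ops.extend(right_ops)

    ops = merge_cigar(ops)
    score, nm = rescore_cigar(text, align_start, read, ops, scoring)
    threshold = min_feasible_score(m, scoring, error_rate)
    return AlignmentResult(
        strand=chain.strand,
        ref_start=align_start,
        cigar=ops,
        score=score,
        edit_distance=nm,
        feasible=score >= threshold,
    )


def full_length_align(
    ref_window: str,
    read: str,
    scoring: ScoringScheme,
    *,
    error_rate: float = 0.05,
    window_start: int = 0,
    strand: str = "+",
) -> AlignmentResult:
    """Single banded DP of the whole read against a region window, with the
    band width set from the error budget: ceil(e*m) + 5."""
    band = int(math.ceil(error_rate * len(read))) + 5
    threshold = min_feasible_score(len(read), scoring, error_rate)
    aln = banded_align(ref_window, read, band, scoring, min_score=threshold)
    if aln.feasible or aln.ref_start >= 0:
        aln.ref_start += window_start
        aln.strand = strand
    return aln


def compute_mapq(
    best: AlignmentResult, second_best_score: int | None, read_len: int
) -> int:
    """Confidence from the score margin over the runner-up: 60 when unique,
    0 on a tie, linear in (s1-s2)/s1 otherwise."""
    if second_best_score is None:
        return 60
    s1, s2 = best.score, second_best_score
    if s1 <= s2:
        return 0
    return max(0, min(60, round(60.0 * (s1 - s2) / max(1, s1))))
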