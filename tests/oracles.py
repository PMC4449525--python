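"""Independent brute-force oracles used to verify the mapper's data
structures and algorithms.  These deliberately use the most naive correct
formulation (string sorts, all-diagonal scans, unbanded quadratic DP) and
share no code with the implementation under test."""

from __future__ import annotations

VALID = set("ACGT")


def naive_sparse_sa(text: str, s: int) -> list[int]:
    """Sampled suffix array by direct string sorting."""
    return sorted((i for i in range(len(text)) if i % s == 0), key=lambda i: text[i:])


def naive_lcp_pair(a: str, b: str) -> int:
    n = 0
    while n < len(a) and n < len(b) and a[n] == b[n]:
        n += 1
    return n


def naive_sparse_lcp(text: str, sa: list[int]) -> list[int]:
    return [0] + [
        naive_lcp_pair(text[sa[i - 1]:], text[sa[i]:]) for i in range(1, len(sa))
    ]


def naive_lcp_intervals(text: str, sa: list[int]) -> set[tuple[int, int, int]]:
    """All lcp-intervals (depth, lo, hi) of the (sparse) suffix array:
    maximal rank intervals of width >= 2 whose suffixes share a prefix of
    exactly `depth` characters (i.e. min of interior LCP values)."""
    lcp = naive_sparse_lcp(text, sa)
    n = len(sa)
    out = set()
    for lo in range(n):
        for hi in range(lo + 1, n):
            depth = min(lcp[lo + 1 : hi + 1])
            left_ok = lo == 0 or lcp[lo] < depth
            right_ok = hi == n - 1 or lcp[hi + 1] < depth
            if depth > 0 and left_ok and right_ok:
                out.add((depth, lo, hi))
    return out


def mem_oracle(ref: str, read: str, min_len: int) -> set[tuple[int, int, int]]:
    """All MEMs of length >= min_len as (read_start, ref_start, length),
    by scanning every diagonal for maximal match runs (N and sentinels
    never match)."""
    out = set()
    n, m = len(ref), len(read)
    for d in range(-(m - 1), n):
        i = max(0, -d)
        while i < m:
            j = i + d
            if j >= n:
                break
            if read[i] == ref[j] and read[i] in VALID:
                l = 0
                while (
                    i + l < m
                    and j + l < n
                    and read[i + l] == ref[j + l]
                    and read[i + l] in VALID
                ):
                    l += 1
                if l >= min_len:
                    out.add((i, j, l))
                i += l
            else:
                i += 1
    return out


def smem_oracle(mems: set[tuple[int, int, int]]) -> set[tuple[int, int, int]]:
    """Pairwise containment filter on read intervals: a MEM survives unless
    a different read interval properly contains (or equals-and-extends)
    its own."""
    out = set()
    for mem in mems:
        i, _, l = mem
        contained = any(
            (i2 <= i and i + l <= i2 + l2) and (i2, l2) != (i, l)
            for i2, _, l2 in mems
        )
        if not contained:
            out.add(mem)
    return out


NEG = -(10**9)


def gotoh_glocal(ref: str, read: str, match=1, mismatch=4, gap_open=6, gap_extend=1) -> int:
    """Unbanded glocal Gotoh score (simple full-matrix formulation)."""
    m, n = len(read), len(ref)
    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = 0
    for i in range(1, m + 1):
        F[i][0] = max(H[i - 1][0] - gap_open - gap_extend, F[i - 1][0] - gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            sub = (
                match
                if (read[i - 1] == ref[j - 1] and read[i - 1] in VALID)
                else -mismatch
            )
            H[i][j] = max(H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    return max(H[m])


def gotoh_local(ref: str, read: str, match=1, mismatch=4, gap_open=6, gap_extend=1) -> int:
    """Unbanded Smith-Waterman with affine gaps."""
    m, n = len(read), len(ref)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            sub = (
                match
                if (read[i - 1] == ref[j - 1] and read[i - 1] in VALID)
                else -mismatch
            )
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
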