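"""Enhanced sparse suffix array (ESSA) over the concatenated reference.

The index stores only suffixes starting at positions divisible by the
sparseness ``s`` (so ``len(sa) == ceil(N/s)``), together with an LCP array
over the sampled suffixes and a child table that exposes the implicit
lcp-interval tree for top-down string matching.  Construction builds the full
suffix array by prefix doubling, filters it to the sampled positions and
derives the sparse LCP from the full LCP by range minima.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .reference_io import (
    CODE_A,
    CODE_T,
    CODE_N,
    Reference,
    encode,
)

INDEX_FORMAT_MAGIC = "ALFALIGN_ESSA"
INDEX_FORMAT_VERSION = 1

DEFAULT_SPARSENESS = 12


class IndexError_(ValueError):
    """Bad index parameters or a corrupt serialized index."""


def _full_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(N log N) lexsorts)."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        boundary = np.empty(n, dtype=np.int64)
        boundary[0] = 0
        if n > 1:
            r, s2 = rank[order], second[order]
            boundary[1:] = np.cumsum((r[1:] != r[:-1]) | (s2[1:] != s2[:-1]))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = boundary
        rank = new_rank
        if boundary[-1] == n - 1:
            break
        k *= 2
    return order.astype(np.int64)


def _kasai_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Full LCP array (lcp[i] = lcp of suffixes sa[i-1], sa[i]); lcp[0]=0."""
    n = len(sa)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    c = codes
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and c[i + h] == c[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def _build_child_table(lcp: np.ndarray) -> np.ndarray:
    """Collapsed up/down/next child table of the lcp-interval tree."""
    n = len(lcp)
    child = np.full(n, -1, dtype=np.int64)
    # up/down values; index 0 and a virtual final entry act as -1 sentinels
    stack = [0]
    last = -1
    lcp_ext = np.concatenate([lcp, [-1]])
    lcp_ext[0] = -1
    for i in range(1, n + 1):
        li = lcp_ext[i]
        while li < lcp_ext[stack[-1]]:
            last = stack.pop()
            if li <= lcp_ext[stack[-1]] and lcp_ext[stack[-1]] != lcp_ext[last]:
                child[stack[-1]] = last  # down
        if last != -1:
            child[i - 1] = last  # up, stored at i-1
            last = -1
        if i < n:
            stack.append(i)
    # next-l-index values
    stack = [0]
    for i in range(1, n):
        while lcp[i] < lcp[stack[-1]]:
            stack.pop()
        if lcp[i] == lcp[stack[-1]]:
            child[stack.pop()] = i  # nextlIndex
        stack.append(i)
    return child


@dataclass
class ESSAIndex:
    """Sparse suffix array with LCP and child table over ``reference``."""

    sparseness: int
    sa: np.ndarray
    lcp: np.ndarray
    child: np.ndarray
    reference: Reference
    codes: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = encode(self.reference.sequence)

    @property
    def text(self) -> str:
        return self.reference.sequence

    @property
    def n_text(self) -> int:
        return len(self.reference.sequence)

    # --- lcp-interval tree navigation (Abouelhoda et al. child table) ---

    def _first_l_index(self, i: int, j: int) -> int:
        k = self.child[j]  # up(j+1) if it falls inside (i, j]
        if i < k <= j:
            return k
        return self.child[i]  # down(i)

    def interval_lcp(self, i: int, j: int) -> int:
        """String depth (lcp value) of the lcp-interval [i..j], i < j."""
        return int(self.lcp[self._first_l_index(i, j)])

    def child_intervals(self, i: int, j: int) -> list[tuple[int, int]]:
        """Child intervals of lcp-interval [i..j] (singletons included)."""
        if i == j:
            return []
        out = []
        k = self._first_l_index(i, j)
        depth = self.lcp[k]
        out.append((i, k - 1))
        while True:
            nxt = self.child[k]
            if k < nxt <= j and self.lcp[nxt] == depth:
                out.append((k, nxt - 1))
                k = nxt
            else:
                break
        out.append((k, j))
        return out

    def suffix(self, rank: int) -> str:
        return self.text[int(self.sa[rank]) :]


def build_index(reference: Reference, sparseness: int = DEFAULT_SPARSENESS) -> ESSAIndex:
    """Build the enhanced sparse suffix array for ``reference``."""
    if sparseness < 1:
        raise IndexError_(f"sparseness must be >= 1, got {sparseness}")
    if not reference.sequence:
        raise IndexError_("cannot index an empty reference")
    codes = encode(reference.sequence)
    full_sa = _full_suffix_array(codes)
    full_lcp = _kasai_lcp(codes, full_sa)
    if sparseness == 1:
        sa = full_sa
        lcp = full_lcp
    else:
        keep = np.flatnonzero(full_sa % sparseness == 0)
        sa = full_sa[keep]
        # sparse lcp[k] = min(full_lcp[keep[k-1]+1 .. keep[k]]) for k >= 1
        lcp = np.zeros(len(sa), dtype=np.int64)
        if len(sa) > 1:
            padded = np.concatenate([full_lcp, [np.iinfo(np.int64).max]])
            starts = np.concatenate([keep[:-1] + 1, [keep[-1] + 1]])
            lcp[1:] = np.minimum.reduceat(padded, starts)[:-1]
    child = _build_child_table(lcp)
    return ESSAIndex(sparseness, sa, lcp, child, reference, codes)


def match_prefix(
    index: ESSAIndex, pattern: str, min_len: int = 1
) -> list[tuple[int, int, int]]:
    """Top-down match of ``pattern`` against the sampled suffixes.

    Returns ``(lo, hi, length)`` triples, one per lcp-interval visited during
    the descent: every sampled suffix ``sa[lo..hi]`` matches the first
    ``length`` pattern characters exactly.  Triples are in increasing depth
    order and filtered to ``length >= min_len``.  N and sentinel characters
    never match.
    """
    pat = encode(pattern)
    m = len(pat)
    codes = index.codes
    sa = index.sa
    n = len(sa)
    if n == 0 or m == 0:
        return []
    out: list[tuple[int, int, int]] = []
    i, j = 0, n - 1
    depth = 0  # pattern characters confirmed so far
    while depth < m:
        pc = pat[depth]
        if pc == 0 or pc == CODE_N or pc < CODE_A or pc > CODE_T:
            break
        if i == j:
            # single suffix: extend by direct comparison
            p = int(sa[i])
            l = depth
            N = len(codes)
            while l < m:
                c = pat[l]
                if c == CODE_N or c == 0 or p + l >= N or codes[p + l] != c:
                    break
                l += 1
            if l > depth:
                out.append((i, j, l))
            depth = l
            break
        # find the child interval whose edge starts with pc at offset `depth`
        found = None
        for a, b in index.child_intervals(i, j):
            edge = int(sa[a]) + depth
            if edge < len(codes) and codes[edge] == pc:
                found = (a, b)
                break
        if found is None:
            break
        a, b = found
        if a == b:
            i, j = a, b
            continue  # handled by the singleton branch above
        node_depth = index.interval_lcp(a, b)
        # verify edge characters between depth and node_depth on a representative
        p = int(sa[a])
        l = depth
        limit = min(node_depth, m)
        ok = True
        while l < limit:
            c = pat[l]
            if c == CODE_N or c == 0 or codes[p + l] != c:
                ok = False
                break
            l += 1
        if l > depth:
            out.append((a, b, l))
        i, j = a, b
        depth = l
        if not ok or node_depth >= m:
            break
    return [(lo, hi, ln) for lo, hi, ln in out if ln >= min_len]


# --- serialization -----------------------------------------------------------

_ARRAYS = ("sa", "lcp", "child")


def save_index(index: ESSAIndex, prefix: str) -> None:
    """Serialize as flat binary arrays plus a JSON metadata file."""
    meta = {
        "magic": INDEX_FORMAT_MAGIC,
        "version": INDEX_FORMAT_VERSION,
        "sparseness": index.sparseness,
        "contigs": [[name, length] for name, length in index.reference.contigs],
        "n_sa": int(len(index.sa)),
        "n_text": index.n_text,
    }
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh)
    for name in _ARRAYS:
        getattr(index, name).astype(np.int64).tofile(f"{prefix}.{name}.bin")
    with open(prefix + ".seq", "w") as fh:
        fh.write(index.reference.sequence)


def load_index(prefix: str) -> ESSAIndex:
    meta_path = prefix + ".meta.json"
    if not os.path.exists(meta_path):
        raise IndexError_(f"missing metadata file {meta_path}")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except (json.JSONDecodeError, OSError) as exc:
        raise IndexError_(f"corrupt metadata file {meta_path}: {exc}") from exc
    if meta.get("magic") != INDEX_FORMAT_MAGIC:
        raise IndexError_(f"{meta_path}: bad magic field {meta.get('magic')!r}")
    if meta.get("version") != INDEX_FORMAT_VERSION:
        raise IndexError_(f"{meta_path}: unsupported version field {meta.get('version')!r}")
    with open(prefix + ".seq") as fh:
        sequence = fh.read()
    if len(sequence) != meta["n_text"]:
        raise IndexError_(f"{prefix}.seq: sequence field truncated")
    reference = Reference(
        contigs=[(name, length) for name, length in meta["contigs"]],
        sequence=sequence,
    )
    arrays = {}
    for name in _ARRAYS:
        path = f"{prefix}.{name}.bin"
        try:
            arr = np.fromfile(path, dtype=np.int64)
        except OSError as exc:
            raise IndexError_(f"cannot read {name} field: {exc}") from exc
        if len(arr) != meta["n_sa"]:
            raise IndexError_(
                f"{path}: {name} field has {len(arr)} entries, expected {meta['n_sa']}"
            )
        arrays[name] = arr
    return ESSAIndex(
        sparseness=meta["sparseness"],
        sa=arrays["sa"],
        lcp=arrays["lcp"],
        child=arrays["child"],
        reference=reference,
    )
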