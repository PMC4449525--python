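"""Reference and read I/O for the mapper.

The mapper works in a single concatenated coordinate space: all contigs are
joined into one string, separated by a sentinel character that sorts before
every nucleotide and can never take part in an exact match.  Internally every
coordinate is 0-based half-open over this concatenated sequence; SAM output
translates back to 1-based per-contig positions.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pysam
from Bio import SeqIO

#: Contig separator / terminator.  '#' (0x23) sorts before 'A' in ASCII.
SENTINEL = "#"

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans(
    {chr(c): "N" for c in range(256) if chr(c).upper() not in _VALID}
)

# Numeric codes preserve ASCII order of the alphabet {#, A, C, G, N, T} so
# that code-level comparisons agree with lexicographic string comparisons.
CODE_SENTINEL, CODE_A, CODE_C, CODE_G, CODE_N, CODE_T = 0, 1, 2, 3, 4, 5
_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _ch, _code in zip("#ACGNT", range(6)):
    _CODE_TABLE[ord(_ch)] = _code

_RC = str.maketrans("ACGTN", "TGCAN")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Malformed FASTA/FASTQ input."""


class InternalConsistencyError(RuntimeError):
    """A record produced by the pipeline violates its own invariants."""


def normalize_sequence(seq: str) -> str:
    """Upper-case and map every character outside {A,C,G,T,N} to N."""
    return seq.upper().translate(_NORMALIZE)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence (plus sentinels) as uint8 codes."""
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Reference:
    """A multi-contig reference in concatenated coordinates.

    ``sequence`` holds the contigs joined by single sentinels plus one
    terminal sentinel; ``offsets[i]`` is the concatenated start of contig i.
    """

    contigs: list[tuple[str, int]]
    sequence: str
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.offsets:
            off, offs = 0, []
            for _, length in self.contigs:
                offs.append(off)
                off += length + 1  # +1 for the sentinel
            self.offsets = offs

    @classmethod
    def from_contigs(cls, contigs: list[tuple[str, str]]) -> "Reference":
        names_lengths = []
        parts = []
        for name, seq in contigs:
            seq = normalize_sequence(seq)
            names_lengths.append((name, len(seq)))
            parts.append(seq)
        sequence = SENTINEL.join(parts) + SENTINEL
        return cls(contigs=names_lengths, sequence=sequence)

    @property
    def total_length(self) -> int:
        return len(self.sequence)

    def contig_index_of(self, pos: int) -> int:
        """Index of the contig whose slice contains concatenated ``pos``."""
        if not 0 <= pos < self.total_length:
            raise InternalConsistencyError(f"position {pos} outside reference")
        i = bisect_right(self.offsets, pos) - 1
        start = self.offsets[i]
        if pos >= start + self.contigs[i][1]:
            raise InternalConsistencyError(f"position {pos} lies on a separator")
        return i

    def to_contig_coords(self, pos: int) -> tuple[str, int]:
        """Translate a concatenated position to (contig name, 0-based offset)."""
        i = self.contig_index_of(pos)
        return self.contigs[i][0], pos - self.offsets[i]

    def contig_bounds(self, pos: int) -> tuple[int, int]:
        """Concatenated half-open bounds of the contig containing ``pos``."""
        i = self.contig_index_of(pos)
        start = self.offsets[i]
        return start, start + self.contigs[i][1]

    def contig_slice(self, name: str) -> str:
        for i, (n, length) in enumerate(self.contigs):
            if n == name:
                start = self.offsets[i]
                return self.sequence[start : start + length]
        raise KeyError(name)


@dataclass
class Read:
    name: str
    sequence: str
    qualities: Optional[str] = None
    mate_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.name!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.name!r}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str) -> Reference:
    """Load a (multi-contig) FASTA file into a :class:`Reference`."""
    contigs = []
    for rec in SeqIO.parse(path, "fasta"):
        contigs.append((rec.id, str(rec.seq)))
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return Reference.from_contigs(contigs)


def read_reads(path: str) -> Iterator[Read]:
    """Stream reads from a FASTQ or FASTA file (auto-detected)."""
    with open(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        else:
            raise FormatError(f"{path}: neither FASTQ nor FASTA")
        index = 0
        parser = SeqIO.parse(handle, fmt)
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(f"{path}: record {index}: {exc}") from exc
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            try:
                yield Read(rec.id, normalize_sequence(str(rec.seq)), qual)
            except FormatError as exc:
                raise FormatError(f"{path}: record {index}: {exc}") from exc
            index += 1


@dataclass
class SamRecord:
    """One SAM line.

    For mapped records ``pos`` is the 0-based *concatenated* reference offset
    (``rname`` is filled in at write time); unmapped records use ``pos=-1``.
    ``pnext`` follows the same convention.
    """

    qname: str
    flag: int
    pos: int = -1
    mapq: int = 0
    cigar: str = "*"
    pnext: int = -1
    tlen: int = 0
    seq: str = "*"
    qual: Optional[str] = None
    tags: dict = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    def query_length_from_cigar(self) -> int:
        total = 0
        for n, op in _CIGAR_RE.findall(self.cigar):
            if op in "MIS=X":
                total += int(n)
        return total


def cigar_ops(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _check_record(rec: SamRecord, reference: Reference) -> None:
    if rec.is_unmapped:
        return
    if rec.seq != "*" and rec.query_length_from_cigar() != len(rec.seq):
        raise InternalConsistencyError(
            f"{rec.qname}: CIGAR {rec.cigar} does not consume the full read"
        )
    start, end = reference.contig_bounds(rec.pos)
    ref_span = sum(n for op, n in cigar_ops(rec.cigar) if op in "MDN=X")
    if rec.pos + ref_span > end:
        raise InternalConsistencyError(
            f"{rec.qname}: alignment at {rec.pos} spans a contig boundary"
        )


def write_sam(records, reference: Reference, out: str) -> None:
    """Write records as SAM v1.6, translating concatenated coordinates."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in reference.contigs],
        "PG": [{"ID": "alfalign", "PN": "alfalign"}],
    }
    with pysam.AlignmentFile(out, "w", header=header) as sam:
        hdr = sam.header
        for rec in records:
            _check_record(rec, reference)
            a = pysam.AlignedSegment(hdr)
            a.query_name = rec.qname
            a.flag = rec.flag
            if rec.is_unmapped:
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            else:
                idx = reference.contig_index_of(rec.pos)
                a.reference_id = idx
                a.reference_start = rec.pos - reference.offsets[idx]
                a.mapping_quality = rec.mapq
                a.cigarstring = rec.cigar
            if rec.pnext >= 0:
                midx = reference.contig_index_of(rec.pnext)
                a.next_reference_id = midx
                a.next_reference_start = rec.pnext - reference.offsets[midx]
            else:
                a.next_reference_id = -1
                a.next_reference_start = -1
            a.template_length = rec.tlen
            if rec.seq != "*":
                a.query_sequence = rec.seq
                if rec.qual is not None:
                    a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            for tag, value in rec.tags.items():
                a.set_tag(tag, value)
            sam.write(a)
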