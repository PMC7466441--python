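"""Sequence and interval primitives shared across the toolkit.

Sequences are plain uppercase DNA strings over ``{A, C, G, T, N}``; RNA
input (``U``) is mapped to ``T`` on ingest so DNA and RNA FASTA files are
interchangeable. All coordinates are 0-based, half-open. Human-readable
reports elsewhere convert to 1-based inclusive and say so explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALLOWED_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TranscriptRecord:
    """A named nucleotide sequence with an organism tag and a screening role.

    ``role`` is ``"target"`` for the transcript dsRNA is designed against and
    ``"nontarget"`` for panel transcriptomes screened for off-target matches.
    """

    id: str
    seq: str
    organism: str = ""
    role: str = "target"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.role not in ("target", "nontarget"):
            raise ValueError(f"record {self.id!r}: role must be 'target' or 'nontarget'")
        for i, ch in enumerate(self.seq):
            if ch not in ALLOWED_BASES:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U to T. Does not validate the alphabet."""
    return raw.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Canonical form gives strand-symmetric match semantics: a double-stranded
    molecule presents both strands, so two k-mers are considered identical if
    either strand matches. Idempotent. N is rejected because an ambiguous
    base cannot be matched or declared specific.
    """
    km = normalize_sequence(kmer)
    for ch in km:
        if ch not in "ACGT":
            if ch == "N":
                raise ValueError("ambiguous base in k-mer")
            raise ValueError(f"invalid base {ch!r} in k-mer")
    rc = revcomp(km)
    return km if km <= rc else rc


def read_fasta(
    path: Union[str, Path], organism: str = "", role: str = "target"
) -> list[TranscriptRecord]:
    """Read a (multi-)FASTA file into TranscriptRecords.

    Sequences are uppercased with U mapped to T; entry order is preserved.
    Raises on an empty file, an illegal (non A/C/G/T/U/N) character, or a
    duplicate id.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = normalize_sequence(str(entry.seq))
        records.append(TranscriptRecord(id=entry.id, seq=seq, organism=organism, role=role))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA, 60 columns per line."""
    seqrecords = [
        SeqRecord(Seq(rec.seq), id=rec.id, description="") for rec in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) on a transcript, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


IntervalSet = list[Interval]

IntervalLike = Union[Interval, tuple]


def _coerce(iv: IntervalLike) -> Interval:
    return iv if isinstance(iv, Interval) else Interval(*iv)


def merge_intervals(intervals: Iterable[IntervalLike]) -> IntervalSet:
    """Normalize intervals: sort, coalesce overlapping and abutting ones.

    Total covered length is preserved; the result is sorted, disjoint and
    non-adjacent. Idempotent.
    """
    ivs = sorted(_coerce(iv) for iv in intervals)
    merged: IntervalSet = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def complement_intervals(iset: Sequence[IntervalLike], length: int) -> IntervalSet:
    """Complement of an interval set within [0, length)."""
    norm = merge_intervals(iset)
    if norm and norm[-1].end > length:
        raise ValueError(
            f"interval [{norm[-1].start}, {norm[-1].end}) exceeds length {length}"
        )
    out: IntervalSet = []
    cursor = 0
    for iv in norm:
        if iv.start > cursor:
            out.append(Interval(cursor, iv.start))
        cursor = iv.end
    if cursor < length:
        out.append(Interval(cursor, length))
    return out


def total_length(iset: Sequence[IntervalLike]) -> int:
    return sum(_coerce(iv).length for iv in iset)


def write_bed(iset: Sequence[IntervalLike], chrom: str, path: Union[str, Path]) -> None:
    """Write an interval set as BED3 (half-open, 0-based; one chrom)."""
    with open(path, "w") as fh:
        for iv in merge_intervals(iset):
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")
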