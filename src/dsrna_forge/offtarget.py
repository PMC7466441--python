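"""Off-target specificity screen for dsRNA design.

An ingested long dsRNA is diced into ~21-nt siRNAs, so specificity is
evaluated at 21-mer granularity: every 21-mer of the target transcript is
checked for a perfect, ungapped exact match of length >= 20 anywhere in a
panel of non-target transcriptomes, on either strand. Within a 21-nt query
every length-20 window is one of its two terminal 20-mers, so the screen
reduces to three hash-set lookups per 21-mer against canonical k-mer sets
built from the panel. Flagged 21-mer footprints form an exclusion mask on
the target; the complement is the species-specific sequence space available
to the designer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .seqcore import (
    Interval,
    IntervalSet,
    TranscriptRecord,
    canonical_kmer,
    merge_intervals,
)

KMER_LEN = 21
SUBMATCH_LEN = 20


@dataclass
class OffTargetIndex:
    """Canonical 20-mer and 21-mer sets over a non-target panel.

    Canonicalization (min of k-mer and its reverse complement) makes
    membership strand-symmetric without storing both strands.
    """

    k20: frozenset[str]
    k21: frozenset[str]
    n_sequences: int
    n_kmers: dict[int, int]
    source_organisms: list[str]
    kmer_organisms: Optional[dict[str, frozenset[str]]] = None


@dataclass(frozen=True)
class KmerHit:
    """A flagged target 21-mer: perfect non-target match of length >= 20.

    ``match_class`` records the strongest evidence: 21 for a full-length
    match, 20 when only a terminal 20-mer matches.
    """

    target_pos: int
    match_class: int
    organisms: tuple[str, ...] = ()


def enumerate_kmers(
    record: Union[TranscriptRecord, str], k: int = KMER_LEN
) -> list[tuple[int, str]]:
    """All (position, k-mer) windows of a sequence that contain no N.

    Positions are strictly increasing; a sequence shorter than k yields an
    empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = record.seq if isinstance(record, TranscriptRecord) else record
    out: list[tuple[int, str]] = []
    last_bad = -1
    for j, ch in enumerate(seq):
        if ch not in "ACGT":
            last_bad = j
        if j >= k - 1:
            i = j - k + 1
            if last_bad < i:
                out.append((i, seq[i : j + 1]))
    return out


def build_offtarget_index(
    panel: Sequence[TranscriptRecord], track_organisms: bool = False
) -> OffTargetIndex:
    """Index every N-free 20-mer and 21-mer of the panel, canonicalized.

    ``track_organisms`` additionally maps each canonical k-mer to the set of
    organism tags containing it (off by default to keep the index small).
    """
    if not panel:
        raise ValueError("no non-target sequences")
    k20: set[str] = set()
    k21: set[str] = set()
    by_org: dict[str, set[str]] = {}
    organisms: list[str] = []
    for rec in panel:
        if rec.organism and rec.organism not in organisms:
            organisms.append(rec.organism)
        for k, dest in ((SUBMATCH_LEN, k20), (KMER_LEN, k21)):
            for _, km in enumerate_kmers(rec.seq, k):
                ckm = canonical_kmer(km)
                dest.add(ckm)
                if track_organisms:
                    by_org.setdefault(ckm, set()).add(rec.organism)
    return OffTargetIndex(
        k20=frozenset(k20),
        k21=frozenset(k21),
        n_sequences=len(panel),
        n_kmers={SUBMATCH_LEN: len(k20), KMER_LEN: len(k21)},
        source_organisms=organisms,
        kmer_organisms=(
            {km: frozenset(orgs) for km, orgs in by_org.items()}
            if track_organisms
            else None
        ),
    )


def screen_transcript(
    target: TranscriptRecord, index: OffTargetIndex
) -> list[KmerHit]:
    """Flag every target 21-mer with a perfect >=20-nt panel match.

    A 21-mer is flagged with match_class 21 if its canonical form is in the
    panel 21-mer set, otherwise with match_class 20 if either terminal
    20-mer's canonical form is in the panel 20-mer set. Hits are sorted by
    position.
    """
    hits: list[KmerHit] = []
    for pos, km in enumerate_kmers(target, KMER_LEN):
        c21 = canonical_kmer(km)
        if c21 in index.k21:
            hits.append(KmerHit(pos, 21, _orgs_for(index, (c21,))))
            continue
        c20a = canonical_kmer(km[:SUBMATCH_LEN])
        c20b = canonical_kmer(km[1:])
        matched = tuple(c for c in (c20a, c20b) if c in index.k20)
        if matched:
            hits.append(KmerHit(pos, 20, _orgs_for(index, matched)))
    return hits


def _orgs_for(index: OffTargetIndex, kmers: Iterable[str]) -> tuple[str, ...]:
    if index.kmer_organisms is None:
        return ()
    orgs: set[str] = set()
    for km in kmers:
        orgs |= index.kmer_organisms.get(km, frozenset())
    return tuple(sorted(orgs))


def exclusion_mask(
    hits: Sequence[KmerHit],
    target_length: int,
    target_seq: Optional[str] = None,
) -> IntervalSet:
    """Merged union of flagged 21-mer footprints (plus N-window footprints).

    When ``target_seq`` is supplied, every 21-nt window containing an N is
    also excluded: a base we cannot verify cannot be declared specific, and
    such windows were never enumerated in the screen.
    """
    intervals: list[Interval] = []
    for h in hits:
        if h.target_pos < 0 or h.target_pos + KMER_LEN > target_length:
            raise ValueError(f"hit at {h.target_pos} out of bounds")
        intervals.append(Interval(h.target_pos, h.target_pos + KMER_LEN))
    if target_seq is not None and len(target_seq) >= KMER_LEN:
        last_window = len(target_seq) - KMER_LEN
        for j, ch in enumerate(target_seq):
            if ch == "N":
                lo = max(0, j - (KMER_LEN - 1))
                hi = min(j, last_window)
                if lo <= hi:
                    intervals.append(Interval(lo, hi + KMER_LEN))
    return merge_intervals(intervals)


def screen_and_mask(
    target: TranscriptRecord, panel: Sequence[TranscriptRecord]
) -> tuple[list[KmerHit], IntervalSet]:
    """Convenience pipeline: build index, screen, return (hits, mask)."""
    index = build_offtarget_index(panel)
    hits = screen_transcript(target, index)
    return hits, exclusion_mask(hits, len(target.seq), target.seq)


_INDEX_MAGIC = "dsrna-forge-kmer-index"
_INDEX_VERSION = "1"


def save_index(index: OffTargetIndex, path: Union[str, Path]) -> None:
    """Persist an index as sorted text: header, then one k-mer per line."""
    with open(path, "w") as fh:
        fh.write(f"{_INDEX_MAGIC}\t{_INDEX_VERSION}\t{index.n_sequences}\t"
                 f"{','.join(index.source_organisms)}\n")
        for k, kmers in ((SUBMATCH_LEN, index.k20), (KMER_LEN, index.k21)):
            fh.write(f"K\t{k}\t{len(kmers)}\n")
            for km in sorted(kmers):
                fh.write(km + "\n")


def load_index(path: Union[str, Path]) -> OffTargetIndex:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != _INDEX_MAGIC:
            raise ValueError(f"{path} is not a k-mer index file")
        if header[1] != _INDEX_VERSION:
            raise ValueError(f"unsupported index version {header[1]!r}")
        n_sequences = int(header[2])
        organisms = header[3].split(",") if len(header) > 3 and header[3] else []
        sets: dict[int, frozenset[str]] = {}
        line = fh.readline()
        while line:
            tag, k_s, count_s = line.rstrip("\n").split("\t")
            if tag != "K":
                raise ValueError(f"malformed index section header: {line!r}")
            k, count = int(k_s), int(count_s)
            kmers = [fh.readline().rstrip("\n") for _ in range(count)]
            sets[k] = frozenset(kmers)
            line = fh.readline()
    return OffTargetIndex(
        k20=sets.get(SUBMATCH_LEN, frozenset()),
        k21=sets.get(KMER_LEN, frozenset()),
        n_sequences=n_sequences,
        n_kmers={k: len(v) for k, v in sets.items()},
        source_organisms=organisms,
    )
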