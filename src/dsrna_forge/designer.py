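"""Long-dsRNA candidate design inside species-specific regions.

The complement of the off-target exclusion mask gives the specific regions
of the target transcript; the longest one is the design template. Candidate
dsRNA windows are enumerated inside it and ranked by the fraction of their
19-mer siRNA windows that pass a Reynolds-style rational-design score
(threshold 6 of a maximum 10), with GC content closest to 0.45 and then
leftmost start breaking ties.

The per-siRNA rubric (each line independently configurable via
``ScoreWeights``):

=====================================  ======
criterion (sense strand, 1-based)      points
=====================================  ======
GC fraction in [0.30, 0.52]              +1
each A/U at positions 15-19              +1 (max 5)
A at position 19                         +1
A at position 3                          +1
U at position 10                         +1
G or C at position 19                    -1
G at position 13                         -1
no inverted repeat with stem >= 5        +1
=====================================  ======
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import (
    Interval,
    IntervalSet,
    TranscriptRecord,
    complement_intervals,
    normalize_sequence,
    revcomp,
)

SIRNA_LEN = 19
DEFAULT_THRESHOLD = 6
DEFAULT_STEM = 5


@dataclass(frozen=True)
class SirnaScore:
    """Score of one 19-mer sense window; efficient iff score >= threshold."""

    position: int
    score: int
    efficient: bool


@dataclass(frozen=True)
class DsRnaCandidate:
    target_id: str
    start: int
    end: int
    seq: str
    length: int
    n_sirna: int
    n_efficient: int
    efficient_fraction: float
    gc_fraction: float
    rank: int


def specific_regions(mask: IntervalSet, target_length: int) -> IntervalSet:
    """Species-specific regions: complement of the exclusion mask."""
    return complement_intervals(mask, target_length)


def longest_specific_region(regions: IntervalSet) -> Interval:
    """The longest region; ties broken by smallest start."""
    if not regions:
        raise ValueError("no specific region available")
    return max(regions, key=lambda r: (r.end - r.start, -r.start))


def has_inverted_repeat(seq: str, stem: int = DEFAULT_STEM) -> bool:
    """True if seq contains a perfect inverted repeat with the given stem.

    A pair of non-overlapping substrings (i, j), j >= i + stem, such that
    seq[i:i+stem] == revcomp(seq[j:j+stem]) can fold back into a hairpin,
    which hinders RISC loading.
    """
    n = len(seq)
    for i in range(n - 2 * stem + 1):
        rc = revcomp(seq[i : i + stem])
        if rc in seq[i + stem :]:
            return True
    return False


def score_sirna(
    sense19: str,
    threshold: int = DEFAULT_THRESHOLD,
    stem: int = DEFAULT_STEM,
    position: int = 0,
) -> SirnaScore:
    """Score one 19-nt sense-strand siRNA window by the design rubric.

    Accepts DNA or RNA, any case. Raises on a length other than 19 or on an
    ambiguous base.
    """
    s = normalize_sequence(sense19)
    if len(s) != SIRNA_LEN:
        raise ValueError(f"siRNA window must be {SIRNA_LEN} nt, got {len(s)}")
    for ch in s:
        if ch not in "ACGT":
            if ch == "N":
                raise ValueError("ambiguous base in siRNA window")
            raise ValueError(f"invalid base {ch!r} in siRNA window")
    score = 0
    gc = (s.count("G") + s.count("C")) / SIRNA_LEN
    if 0.30 <= gc <= 0.52:
        score += 1
    score += sum(1 for ch in s[14:19] if ch in "AT")
    if s[18] == "A":
        score += 1
    if s[2] == "A":
        score += 1
    if s[9] == "T":
        score += 1
    if s[18] in "GC":
        score -= 1
    if s[12] == "G":
        score -= 1
    if not has_inverted_repeat(s, stem):
        score += 1
    return SirnaScore(position=position, score=score, efficient=score >= threshold)


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def design_candidates(
    target: TranscriptRecord,
    region: Interval,
    min_len: int = 350,
    max_len: int = 500,
    step: int = 10,
    top_n: int = 5,
    threshold: int = DEFAULT_THRESHOLD,
    stem: int = DEFAULT_STEM,
) -> list[DsRnaCandidate]:
    """Enumerate and rank dsRNA windows within one specific region.

    Windows [s, s+L) are enumerated for L in {min_len, min_len+step, ...,
    max_len} with starts stepping by ``step``; the full region is always
    evaluated too when it fits under max_len. Ranking: efficient_fraction
    descending, then GC fraction closest to 0.45, then smallest start, then
    shortest length (full determinism). Returns the top_n with 1-based rank.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if region.end > len(target.seq):
        raise ValueError("region exceeds target length")
    rlen = region.end - region.start
    if rlen < min_len:
        raise ValueError(
            "region shorter than minimum dsRNA length (override with --min-len)"
        )
    windows: set[tuple[int, int]] = set()
    for length in range(min_len, max_len + 1, step):
        for s in range(region.start, region.end - length + 1, step):
            windows.add((s, s + length))
    if rlen <= max_len:
        windows.add((region.start, region.end))

    candidates: list[DsRnaCandidate] = []
    for s, e in windows:
        seq = target.seq[s:e]
        n_sirna = 0
        n_eff = 0
        for p in range(len(seq) - SIRNA_LEN + 1):
            window = seq[p : p + SIRNA_LEN]
            if "N" in window:
                continue
            n_sirna += 1
            if score_sirna(window, threshold=threshold, stem=stem, position=p).efficient:
                n_eff += 1
        candidates.append(
            DsRnaCandidate(
                target_id=target.id,
                start=s,
                end=e,
                seq=seq,
                length=e - s,
                n_sirna=n_sirna,
                n_efficient=n_eff,
                efficient_fraction=(n_eff / n_sirna) if n_sirna else 0.0,
                gc_fraction=_gc_fraction(seq),
                rank=0,
            )
        )
    candidates.sort(
        key=lambda c: (
            -c.efficient_fraction,
            abs(c.gc_fraction - 0.45),
            c.start,
            c.length,
        )
    )
    ranked = [
        DsRnaCandidate(**{**c.__dict__, "rank": i + 1})
        for i, c in enumerate(candidates[:top_n])
    ]
    return ranked
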