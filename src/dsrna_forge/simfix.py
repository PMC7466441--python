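"""Seeded synthetic-data generators with known ground truth.

Each generator is a pure function of its arguments (one ``numpy`` Generator
seeded per call, no global state), so identical calls give byte-identical
outputs. They emulate the four data kinds of a dsRNA insecticide study:

- transcriptomes with 20-mers copied from the target and planted into a
  non-target panel at known positions (exact off-target truth);
- feeding trials with exponential per-arm hazards, daily observation
  (event times rounded up to whole days, deliberately inducing ties) and
  administrative right-censoring;
- field trials with Poisson baseline infestations (truncated to the >=15
  larvae per plant required at enrolment) and binomial per-larva survival;
- qPCR Cq tables generated from known copy numbers through a known
  standard curve with Gaussian cycle noise.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bioassay import FieldAssessment, SurvivalRecord
from .offtarget import KMER_LEN, SUBMATCH_LEN
from .seqcore import TranscriptRecord, canonical_kmer, revcomp

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _canonical_set(seq: str, k: int) -> set[str]:
    return {
        canonical_kmer(seq[i : i + k])
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    }


def synth_transcriptomes(
    seed: int,
    target_len: int = 2000,
    n_nontarget: int = 3,
    nontarget_len: int = 5000,
    n_planted: int = 10,
) -> tuple[TranscriptRecord, list[TranscriptRecord], list[int]]:
    """Random target + non-target panel with planted shared 20-mers.

    At ``n_planted`` well-separated target positions a 20-mer is copied
    from the target and written into a random panel sequence on a random
    strand. Returns (target, panel, truth) where ``truth`` is the sorted
    list of target 21-mer start positions whose terminal 20-mers overlap a
    planted 20-mer — exactly the positions a >=20-nt exact-match screen
    must flag. Rejection sampling guarantees no accidental extra >=20-mer
    is shared between target and panel, so the truth set is exact.
    """
    if target_len < 100:
        raise ValueError("target_len must be >= 100")
    if n_planted * (KMER_LEN + 4) >= target_len / 2:
        raise ValueError("infeasible packing: too many planted k-mers")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        target_seq = _random_seq(rng, target_len)
        panel_seqs = [_random_seq(rng, nontarget_len) for _ in range(n_nontarget)]

        # sample well-separated plant positions on the target
        positions: list[int] = []
        attempts = 0
        while len(positions) < n_planted and attempts < 10_000:
            attempts += 1
            p = int(rng.integers(1, target_len - KMER_LEN))
            if all(abs(p - q) >= KMER_LEN + 4 for q in positions):
                positions.append(p)
        if len(positions) < n_planted:
            raise ValueError("infeasible packing: could not place planted k-mers")
        positions.sort()

        used: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_nontarget)}
        for p in positions:
            forward = not bool(rng.integers(0, 2))
            insert = target_seq[p : p + SUBMATCH_LEN]
            if not forward:
                insert = revcomp(insert)
            placed = False
            for _ in range(1000):
                ridx = int(rng.integers(0, n_nontarget))
                off = int(rng.integers(1, nontarget_len - SUBMATCH_LEN - 1))
                # pad so neighbouring plants cannot fuse into longer matches
                if all(
                    off + SUBMATCH_LEN + KMER_LEN <= lo or off >= hi + KMER_LEN
                    for lo, hi in used[ridx]
                ):
                    s = panel_seqs[ridx]
                    # the panel bases flanking the insert must not extend the
                    # exact match to 21 nt on either strand
                    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                    if forward:
                        bad_left = target_seq[p - 1] if p > 0 else None
                        bad_right = (
                            target_seq[p + SUBMATCH_LEN]
                            if p + SUBMATCH_LEN < target_len
                            else None
                        )
                    else:
                        bad_left = (
                            comp[target_seq[p + SUBMATCH_LEN]]
                            if p + SUBMATCH_LEN < target_len
                            else None
                        )
                        bad_right = comp[target_seq[p - 1]] if p > 0 else None
                    left = s[off - 1]
                    right = s[off + SUBMATCH_LEN]
                    if left == bad_left:
                        left = "ACGT"[("ACGT".index(left) + 1) % 4]
                    if right == bad_right:
                        right = "ACGT"[("ACGT".index(right) + 1) % 4]
                    panel_seqs[ridx] = (
                        s[: off - 1] + left + insert + right
                        + s[off + SUBMATCH_LEN + 1 :]
                    )
                    used[ridx].append((off, off + SUBMATCH_LEN))
                    placed = True
                    break
            if not placed:
                raise ValueError("infeasible packing: panel too crowded")

        # verify truth exactness by independent canonical-set intersection
        t20 = _canonical_set(target_seq, SUBMATCH_LEN)
        t21 = _canonical_set(target_seq, KMER_LEN)
        p20: set[str] = set()
        p21: set[str] = set()
        for s in panel_seqs:
            p20 |= _canonical_set(s, SUBMATCH_LEN)
            p21 |= _canonical_set(s, KMER_LEN)
        planted_kmers = {
            canonical_kmer(target_seq[p : p + SUBMATCH_LEN]) for p in positions
        }
        if (t20 & p20) == planted_kmers and not (t21 & p21):
            truth = sorted(
                {
                    i
                    for p in positions
                    for i in (p - 1, p)
                    if 0 <= i <= target_len - KMER_LEN
                }
            )
            target = TranscriptRecord(
                id="target_tx", seq=target_seq, organism="target_species", role="target"
            )
            panel = [
                TranscriptRecord(
                    id=f"nontarget_{i}",
                    seq=s,
                    organism=f"species_{i}",
                    role="nontarget",
                )
                for i, s in enumerate(panel_seqs)
            ]
            return target, panel, truth
    raise ValueError("could not construct collision-free transcriptomes")


def simulate_survival_trial(
    seed: int,
    n_per_arm: int = 40,
    arms: Optional[dict[str, float]] = None,
    max_day: Optional[int] = 14,
    trial: str = "sim",
) -> list[SurvivalRecord]:
    """Exponential-hazard feeding trial with daily observation.

    ``arms`` maps arm label to hazard rate per day (default a water control
    at 0.03/day versus dsMESH at 0.15/day, hazard ratio 5). Event times are
    drawn exponentially and rounded up to whole days; subjects alive at
    ``max_day`` are administratively censored there.
    """
    if arms is None:
        arms = {"water": 0.03, "dsMESH": 0.15}
    if any(rate < 0 for rate in arms.values()):
        raise ValueError("hazard rates must be >= 0")
    if max_day is None and all(rate == 0 for rate in arms.values()):
        raise ValueError("all hazards zero and no censoring horizon")
    rng = np.random.default_rng(seed)
    records: list[SurvivalRecord] = []
    for arm in arms:  # insertion order: deterministic
        rate = arms[arm]
        for i in range(n_per_arm):
            if rate == 0:
                t, ev = float(max_day), 0
            else:
                raw = rng.exponential(1.0 / rate)
                day = math.ceil(raw)
                if max_day is not None and day > max_day:
                    t, ev = float(max_day), 0
                else:
                    t, ev = float(day), 1
            records.append(
                SurvivalRecord(
                    subject_id=f"{arm}_{i:03d}", arm=arm, time=t, event=ev, trial=trial
                )
            )
    return records


def simulate_field_trial(
    seed: int,
    n_locations: int = 3,
    reps: int = 4,
    mean_infestation: float = 20.0,
    control_survival: float = 0.9,
    treated_survival: Optional[dict[str, float]] = None,
    dpt: int = 7,
) -> list[FieldAssessment]:
    """Field trial: per-plot larval counts before/after and leaf damage.

    Baseline infestation is Poisson(mean) truncated to >=15 larvae per
    plant; after-counts are Binomial(n_before, survival). Leaf damage
    increases in proportion to surviving herbivory plus noise, clipped to
    [0, 100].
    """
    if treated_survival is None:
        treated_survival = {"dsMESH": 0.07, "spinosad": 0.02}
    all_arms = {"control": control_survival, **treated_survival}
    if any(not 0.0 <= sv <= 1.0 for sv in all_arms.values()):
        raise ValueError("survival probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[FieldAssessment] = []
    for loc in range(n_locations):
        for arm, sv in all_arms.items():
            for rep in range(reps):
                n_before = 0
                while n_before < 15:
                    n_before = int(rng.poisson(mean_infestation))
                n_after = int(rng.binomial(n_before, sv))
                damage_before = float(np.clip(rng.normal(10.0, 3.0), 0.0, 100.0))
                increment = 30.0 * sv + float(rng.normal(0.0, 2.0))
                damage_after = float(
                    np.clip(damage_before + max(increment, 0.0), 0.0, 100.0)
                )
                out.append(
                    FieldAssessment(
                        location=f"loc_{loc}",
                        plot=f"loc_{loc}_{arm}_{rep}",
                        arm=arm,
                        n_before=n_before,
                        n_after=n_after,
                        dpt=dpt,
                        damage_before=damage_before,
                        damage_after=damage_after,
                    )
                )
    return out


def simulate_qpcr_run(
    seed: int,
    true_copies: dict[str, dict[str, float]],
    groups: Optional[dict[str, str]] = None,
    slope: float = -3.321928,  # perfect doubling: -1/log10(2)
    intercept: float = 20.0,
    sigma_cq: float = 0.2,
    dilutions: Sequence[float] = (1.0, 0.1),
    n_replicates: int = 2,
    standard_dilutions: Sequence[float] = (1.0, 0.1, 0.01, 0.001, 0.0001),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq tables from known copy numbers through a known standard curve.

    ``true_copies[sample][gene]`` is the relative copy number in the
    undiluted sample; each (sample, gene) is measured at ``dilutions`` with
    ``n_replicates`` wells each, cq = intercept + slope*log10(copies *
    dilution) + N(0, sigma). Standards span five 10-fold dilutions per
    gene. Returns (standards, samples) DataFrames in the Cq CSV dialect.
    """
    if any(c <= 0 for per_gene in true_copies.values() for c in per_gene.values()):
        raise ValueError("copy numbers must be > 0")
    rng = np.random.default_rng(seed)
    genes = sorted({g for per_gene in true_copies.values() for g in per_gene})
    std_rows = []
    for gene in genes:
        for d in standard_dilutions:
            for rep in range(1, n_replicates + 1):
                cq = intercept + slope * math.log10(d) + rng.normal(0.0, sigma_cq)
                std_rows.append(
                    {
                        "sample_id": "standard",
                        "group": "standard",
                        "gene": gene,
                        "dilution": d,
                        "replicate": rep,
                        "cq": cq,
                    }
                )
    sample_rows = []
    for sample in sorted(true_copies):
        group = (groups or {}).get(sample, "na")
        for gene in genes:
            copies = true_copies[sample][gene]
            for d in dilutions:
                for rep in range(1, n_replicates + 1):
                    cq = (
                        intercept
                        + slope * math.log10(copies * d)
                        + rng.normal(0.0, sigma_cq)
                    )
                    sample_rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "dilution": d,
                            "replicate": rep,
                            "cq": cq,
                        }
                    )
    return pd.DataFrame(std_rows), pd.DataFrame(sample_rows)


def simulate_knockdown_experiment(
    seed: int,
    n_per_group: int = 4,
    knockdown: float = 0.7,
    sigma_cq: float = 0.2,
    target_gene: str = "mesh",
    ref_genes: Sequence[str] = ("LdRP4", "rRNA18S", "LdSmt3"),
    biological_cv: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treated-vs-control silencing experiment with a known true knockdown.

    Control samples carry target copy number ~1 and treated samples
    ~(1 - knockdown), with lognormal biological scatter; reference genes
    are unaffected by treatment. Returns (standards, samples) tables.
    """
    rng = np.random.default_rng(seed)
    sigma_ln = math.sqrt(math.log(1.0 + biological_cv**2))
    true_copies: dict[str, dict[str, float]] = {}
    groups: dict[str, str] = {}
    for grp, level in (("dsEGFP", 1.0), ("dsMESH", 1.0 - knockdown)):
        for i in range(n_per_group):
            sid = f"{grp}_{i+1}"
            groups[sid] = grp
            per_gene = {
                target_gene: level * float(rng.lognormal(0.0, sigma_ln))
            }
            for g in ref_genes:
                per_gene[g] = float(rng.lognormal(0.0, sigma_ln))
            true_copies[sid] = per_gene
    return simulate_qpcr_run(
        int(rng.integers(0, 2**31 - 1)),
        true_copies,
        groups=groups,
        sigma_cq=sigma_cq,
    )
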