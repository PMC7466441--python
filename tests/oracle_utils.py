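"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive algorithms (substring scans, per-subject
loops, scalar optimisation) so that they share no code path with the
package modules they validate.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_flagged_positions(target_seq: str, panel_seqs: list[str]) -> set[int]:
    """Positions i where target[i:i+21] has an exact match of length >= 20
    anywhere in the panel, either strand, found by exhaustive substring scan.

    A >=20-nt exact match of a 21-nt query is the full query or one of its
    two terminal 20-mers.
    """
    texts = [s for s in panel_seqs] + [rc(s) for s in panel_seqs]
    flagged = set()
    for i in range(len(target_seq) - 20):
        q = target_seq[i : i + 21]
        if "N" in q:
            continue
        probes = (q, q[:20], q[1:])
        if any(p in t for p in probes for t in texts):
            flagged.add(i)
    return flagged


def covered_positions(intervals) -> set[int]:
    """Brute-force position set of an interval collection."""
    out: set[int] = set()
    for iv in intervals:
        start, end = (iv.start, iv.end) if hasattr(iv, "start") else iv
        out.update(range(start, end))
    return out


def naive_cox_loglik(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray,
    ties: str = "efron",
) -> float:
    """Explicit single-covariate Cox partial log-likelihood, per-subject
    loops, no shared code with the fitting routine."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        dead = np.where((times == t) & (events == 1))[0]
        risk = np.where(times >= t)[0]
        d = len(dead)
        s0 = sum(math.exp(beta * x[j]) for j in risk)
        s0d = sum(math.exp(beta * x[j]) for j in dead)
        ll += sum(beta * x[j] for j in dead)
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            ll -= math.log(s0 - frac * s0d)
    return ll


def brute_cox_beta(
    times: np.ndarray, events: np.ndarray, x: np.ndarray, ties: str = "efron"
) -> float:
    """Maximize the explicit partial likelihood by bounded scalar search."""
    res = minimize_scalar(
        lambda b: -naive_cox_loglik(b, times, events, x, ties),
        bounds=(-8.0, 8.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
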