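"""Efficacy statistics for dsRNA feeding and field trials.

Feeding trials yield right-censored daily survival data per treatment arm
(water, non-specific dsRNA control, insecticidal dsRNA). This module
provides the Kaplan-Meier product-limit estimator and a Cox proportional
hazards fit by Newton-Raphson on the partial likelihood, with the Efron tie
correction as default — daily observation produces heavily tied event
times, so the tie correction materially matters here, and Breslow is kept
for cross-checking.

Field trials are summarised as Henderson-Tilton corrected mortality, which
adjusts the treated survival ratio for natural population change observed
in untreated control plots:

    HT% = 100 * (1 - (treated_after * control_before)
                     / (treated_before * control_after))

plus leaf-damage increase (final minus initial percent defoliation) and
adult emergence rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

DIVERGENCE_BOUND = 10.0

SURVIVAL_CSV_COLUMNS = ["subject_id", "arm", "trial", "time_days", "event"]
FIELD_CSV_COLUMNS = [
    "location", "plot", "arm", "n_before", "n_after", "dpt",
    "damage_before", "damage_after",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's right-censored outcome: time in days since first
    treatment, event=1 for observed death, 0 for censoring."""

    subject_id: str
    arm: str
    time: float
    event: int
    trial: str = ""

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"subject {self.subject_id!r}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id!r}: event must be 0 or 1")


@dataclass
class SurvivalCurve:
    """Stepwise Kaplan-Meier estimate for one arm, defined at event times."""

    arm: str
    times: np.ndarray
    S: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): product over event times <= t; 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.S[idx])


@dataclass
class CoxFit:
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    loglik_null: float
    loglik_fit: float
    lr_stat: float
    lr_p: float
    wald_p: np.ndarray
    ties_method: str
    converged: bool
    monotone_likelihood: bool = False
    n_iter: int = 0


@dataclass(frozen=True)
class FieldAssessment:
    """Per-plot larval counts and leaf-damage percentages before treatment
    and at the assessment time point (days post treatment, dpt)."""

    location: str
    plot: str
    arm: str
    n_before: int
    n_after: int
    dpt: int
    damage_before: float = 0.0
    damage_after: float = 0.0

    def __post_init__(self) -> None:
        if self.n_before < 0 or self.n_after < 0:
            raise ValueError("counts must be >= 0")
        for d in (self.damage_before, self.damage_after):
            if not 0.0 <= d <= 100.0:
                raise ValueError("leaf damage must be in [0, 100]")


def km_curve(records: Sequence[SurvivalRecord], arm: str) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator for one arm.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i;
    subjects censored at t_i remain in the risk set at t_i (deaths are
    processed before censorings at tied times).
    """
    sub = [r for r in records if r.arm == arm]
    if not sub:
        raise ValueError(f"no records in arm {arm!r}")
    times = np.array([r.time for r in sub])
    events = np.array([r.event for r in sub])
    event_times = np.unique(times[events == 1])
    S = []
    at_risk = []
    deaths = []
    surv = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d_i / n_i
        S.append(surv)
        at_risk.append(n_i)
        deaths.append(d_i)
    return SurvivalCurve(
        arm=arm,
        times=event_times,
        S=np.array(S),
        at_risk=np.array(at_risk),
        deaths=np.array(deaths),
    )


def _cox_loglik(
    beta: np.ndarray,
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score vector and observed information.

    Vectorised over the (few) distinct event times; risk sets are suffixes
    of the time-sorted arrays.
    """
    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order]
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix cumulative sums: risk set at t = subjects with time >= t
    cs0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    cs1 = np.concatenate([np.cumsum(wX[::-1], axis=0)[::-1], np.zeros((1, p))])
    cs2 = np.concatenate(
        [np.cumsum(wXX[::-1], axis=0)[::-1], np.zeros((1, p, p))]
    )
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        dead = np.arange(i, j)[event[i:j] == 1]
        d = len(dead)
        if d:
            S0 = cs0[i]
            S1 = cs1[i]
            S2 = cs2[i]
            S0d = float(np.sum(w[dead]))
            S1d = wX[dead].sum(axis=0)
            S2d = wXX[dead].sum(axis=0)
            ll += float(np.sum(eta[dead]))
            score += X[dead].sum(axis=0)
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                phi0 = S0 - frac * S0d
                phi1 = S1 - frac * S1d
                phi2 = S2 - frac * S2d
                ll -= math.log(phi0)
                score -= phi1 / phi0
                info += phi2 / phi0 - np.outer(phi1 / phi0, phi1 / phi0)
        i = j
    return ll, score, info


def cox_fit(
    records: Sequence[SurvivalRecord],
    reference_arm: str,
    ties: str = "efron",
    strata: Optional[str] = None,
) -> CoxFit:
    """Fit a Cox proportional hazards model with arm dummies vs reference.

    Newton-Raphson with step-halving on the partial likelihood; tolerance
    1e-8 on the score norm, at most 25 iterations. Complete separation
    (monotone likelihood) is reported via flags, not raised.

    ``strata="trial"`` stratifies the baseline hazard by the record's trial
    label (separate risk sets per trial, shared coefficients).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    arms = sorted({r.arm for r in records})
    if reference_arm not in arms:
        raise ValueError(f"reference arm {reference_arm!r} not present")
    if len(arms) < 2:
        raise ValueError("at least two arms required")
    if not any(r.event == 1 for r in records):
        raise ValueError("no events observed")
    terms = [a for a in arms if a != reference_arm]
    p = len(terms)
    X = np.array([[1.0 if r.arm == a else 0.0 for a in terms] for r in records])
    time = np.array([r.time for r in records])
    event = np.array([r.event for r in records])
    if strata == "trial":
        groups = [np.array([r.trial for r in records]) == g
                  for g in sorted({r.trial for r in records})]
    elif strata is None:
        groups = [np.ones(len(records), dtype=bool)]
    else:
        raise ValueError("strata must be None or 'trial'")

    def evaluate(beta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        ll, sc, info = 0.0, np.zeros(p), np.zeros((p, p))
        for g in groups:
            l_, s_, i_ = _cox_loglik(beta, X[g], time[g], event[g], ties)
            ll += l_
            sc += s_
            info += i_
        return ll, sc, info

    beta = np.zeros(p)
    ll, score, info = evaluate(beta)
    ll0 = ll
    monotone = False
    it = 0
    while it < 25 and np.max(np.abs(score)) >= 1e-8:
        it += 1
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            monotone = True
            break
        # step-halving: require the log-likelihood not to decrease
        factor = 1.0
        for _ in range(20):
            cand = beta + factor * step
            ll_new, score_new, info_new = evaluate(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.any(np.abs(beta) > DIVERGENCE_BOUND):
            monotone = True
            break
    converged = bool(np.max(np.abs(score)) < 1e-8) and not monotone
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.abs(np.diag(cov)))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    lr_stat = max(0.0, 2.0 * (ll - ll0))
    lr_p = float(stats.chi2.sf(lr_stat, df=p))
    with np.errstate(all="ignore"):
        z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        terms=terms,
        beta=beta,
        se=se,
        hr=np.exp(beta),
        loglik_null=ll0,
        loglik_fit=ll,
        lr_stat=lr_stat,
        lr_p=lr_p,
        wald_p=wald_p,
        ties_method=ties,
        converged=converged,
        monotone_likelihood=monotone,
        n_iter=it,
    )


def henderson_tilton(a: FieldAssessment, c: FieldAssessment) -> float:
    """Henderson-Tilton corrected mortality (%) of a treated plot against a
    control plot. May be negative; not clamped."""
    if a.n_before <= 0 or c.n_before <= 0:
        raise ValueError("pre-treatment counts must be > 0")
    if c.n_after == 0:
        raise ValueError("control collapsed; Henderson-Tilton undefined")
    return 100.0 * (1.0 - (a.n_after * c.n_before) / (a.n_before * c.n_after))


def henderson_tilton_summary(
    assessments: Sequence[FieldAssessment],
    treated_arm: str,
    control_arm: str,
    dpt: Optional[int] = None,
) -> dict:
    """Per-location and pooled corrected mortality.

    Each treated plot is corrected against the mean before/after counts of
    its location's control plots; per-location means are averaged into the
    pooled figure.
    """
    if dpt is not None:
        assessments = [a for a in assessments if a.dpt == dpt]
    locations = sorted({a.location for a in assessments})
    per_location: dict[str, float] = {}
    for loc in locations:
        controls = [a for a in assessments if a.location == loc and a.arm == control_arm]
        treated = [a for a in assessments if a.location == loc and a.arm == treated_arm]
        if not controls or not treated:
            continue
        c_before = float(np.mean([c.n_before for c in controls]))
        c_after = float(np.mean([c.n_after for c in controls]))
        if c_after == 0:
            raise ValueError(
                f"control collapsed at {loc!r}; Henderson-Tilton undefined"
            )
        values = [
            100.0 * (1.0 - (t.n_after * c_before) / (t.n_before * c_after))
            for t in treated
            if t.n_before > 0
        ]
        per_location[loc] = float(np.mean(values))
    if not per_location:
        raise ValueError("no treated/control pairs found")
    return {
        "per_location": per_location,
        "pooled": float(np.mean(list(per_location.values()))),
    }


def leaf_damage_increase(a: FieldAssessment) -> float:
    """Final minus initial percent defoliation; negative if foliage regrew."""
    return a.damage_after - a.damage_before


def emergence_rate(n_treated: int, n_emerged: int) -> float:
    """Percent of treated larvae that emerged as adults."""
    if n_treated <= 0:
        raise ValueError("n_treated must be > 0")
    if n_emerged > n_treated:
        raise ValueError("n_emerged cannot exceed n_treated")
    if n_emerged < 0:
        raise ValueError("n_emerged must be >= 0")
    return 100.0 * n_emerged / n_treated


def read_survival_csv(path: Union[str, Path]) -> list[SurvivalRecord]:
    """Read the fixed survival dialect: subject_id,arm,trial,time_days,event."""
    df = pd.read_csv(path, dtype={"subject_id": str, "arm": str, "trial": str})
    missing = [c for c in SURVIVAL_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival CSV missing columns: {missing}")
    return [
        SurvivalRecord(
            subject_id=row.subject_id,
            arm=row.arm,
            trial="" if pd.isna(row.trial) else str(row.trial),
            time=float(row.time_days),
            event=int(row.event),
        )
        for row in df.itertuples()
    ]


def read_field_csv(path: Union[str, Path]) -> list[FieldAssessment]:
    """Read the fixed field dialect (see FIELD_CSV_COLUMNS)."""
    df = pd.read_csv(path, dtype={"location": str, "plot": str, "arm": str})
    missing = [c for c in FIELD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"field CSV missing columns: {missing}")
    return [
        FieldAssessment(
            location=row.location,
            plot=row.plot,
            arm=row.arm,
            n_before=int(row.n_before),
            n_after=int(row.n_after),
            dpt=int(row.dpt),
            damage_before=float(row.damage_before),
            damage_after=float(row.damage_after),
        )
        for row in df.itertuples()
    ]
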