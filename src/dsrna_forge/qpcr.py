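"""Standard-curve qPCR quantification of gene silencing.

A serial dilution of calibrator cDNA gives a linear relation between
quantification cycle and log10 template amount, Cq = a*log10(x) + b, with
amplification efficiency E = 10^(-1/a) (E = 2 means perfect doubling per
cycle; the slope is then -3.3219). Sample Cq values are inverted through
the curve to dilution-corrected relative copy numbers, checked for PCR
inhibition via a paired-dilution consistency test, normalized to the
geometric mean of three endogenous control genes, and summarised per
treatment group as knockdown percent versus a control group.

The limit of quantification (LOQ) is taken from the standard curve itself:
the smallest dilution at which every replicate amplified and the mean
absolute residual from the fitted line is at most 0.5 cycles (configurable).
Back-calculated amounts below the LOQ are flagged and excluded from group
means by default (no imputation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

ND = "ND"  # not-detected marker in the Cq CSV dialect

CQ_CSV_COLUMNS = ["sample_id", "group", "gene", "dilution", "replicate", "cq"]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: Cq of a sample/gene at a given template dilution.
    ``cq`` is None when the reaction did not amplify (not detected)."""

    sample_id: str
    group: str
    gene: str
    dilution: float
    replicate: int
    cq: Optional[float]

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")
        if self.cq is not None and self.cq <= 0:
            raise ValueError("detected cq must be > 0")


@dataclass
class StandardCurve:
    gene: str
    slope: float
    intercept: float
    efficiency: float
    efficiency_pct: float
    r2: float
    loq: Optional[float]
    linear_range: tuple[float, float]


@dataclass(frozen=True)
class Quantification:
    """Back-calculated relative copy number; ``value`` is None when the
    reaction was not detected."""

    value: Optional[float]
    below_loq: bool


@dataclass(frozen=True)
class InhibitionResult:
    verdict: str  # ok | inhibited | unevaluable
    ratio: Optional[float]


def fit_standard_curve(
    points: Iterable[tuple[float, Optional[float]]],
    gene: str = "",
    loq_residual: float = 0.5,
) -> StandardCurve:
    """OLS fit of Cq on log10(dilution) over a serial-dilution series.

    ``points`` are (dilution, cq) pairs, one per replicate well; cq None
    marks a non-amplified well (it is excluded from the fit but counts
    against the LOQ rule). Requires >=3 distinct detected dilutions and a
    negative slope.
    """
    pts = list(points)
    detected = [(d, c) for d, c in pts if c is not None]
    dilutions = sorted({d for d, _ in detected})
    if len(dilutions) < 3:
        raise ValueError("need at least 3 distinct detected dilutions")
    x = np.log10([d for d, _ in detected])
    y = np.array([c for _, c in detected])
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise ValueError("invalid assay: non-negative standard-curve slope")
    ss_res = float(np.sum((y - (intercept + slope * x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    efficiency = 10.0 ** (-1.0 / slope)

    # LOQ: smallest dilution with all replicates detected and mean |residual|
    # within loq_residual cycles of the fitted line
    quantifiable: list[float] = []
    for d in sorted({d for d, _ in pts}):
        reps = [c for dd, c in pts if dd == d]
        if any(c is None for c in reps):
            continue
        resid = [abs(c - (intercept + slope * math.log10(d))) for c in reps]
        if float(np.mean(resid)) <= loq_residual:
            quantifiable.append(d)
    loq = min(quantifiable) if quantifiable else None
    linear_range = (
        (min(quantifiable), max(quantifiable))
        if quantifiable
        else (min(dilutions), max(dilutions))
    )
    return StandardCurve(
        gene=gene,
        slope=slope,
        intercept=intercept,
        efficiency=efficiency,
        efficiency_pct=(efficiency - 1.0) * 100.0,
        r2=r2,
        loq=loq,
        linear_range=linear_range,
    )


def predict_cq(curve: StandardCurve, amount: float) -> float:
    """Expected Cq for a given in-reaction relative template amount."""
    if amount <= 0:
        raise ValueError("amount must be > 0")
    return curve.intercept + curve.slope * math.log10(amount)


def quantify(
    cq: Optional[float], curve: StandardCurve, dilution: float = 1.0
) -> Quantification:
    """Invert the curve: Cq -> relative copy number in the undiluted sample.

    The in-reaction amount 10^((cq - intercept)/slope) is divided by the
    dilution used; below-LOQ is judged on the in-reaction amount, which is
    what the curve calibrates.
    """
    if dilution <= 0:
        raise ValueError("dilution must be > 0")
    if cq is None:
        return Quantification(value=None, below_loq=True)
    amount = 10.0 ** ((cq - curve.intercept) / curve.slope)
    below = curve.loq is not None and amount < curve.loq
    return Quantification(value=amount / dilution, below_loq=below)


def inhibition_qc(
    m1: QpcrMeasurement,
    m2: QpcrMeasurement,
    curve: StandardCurve,
    tolerance: float = 0.3,
) -> InhibitionResult:
    """Paired-dilution consistency check for PCR inhibitors.

    Dilution-corrected amounts from two dilutions of the same sample must
    agree; a ratio deviating from 1 by more than ``tolerance`` indicates
    inhibition in the less dilute reaction.
    """
    if (m1.sample_id, m1.gene) != (m2.sample_id, m2.gene):
        raise ValueError("inhibition QC requires the same sample and gene")
    if m1.dilution == m2.dilution:
        raise ValueError("inhibition QC requires two different dilutions")
    q1 = quantify(m1.cq, curve, m1.dilution)
    q2 = quantify(m2.cq, curve, m2.dilution)
    if q1.value is None or q2.value is None or q1.below_loq or q2.below_loq:
        return InhibitionResult(verdict="unevaluable", ratio=None)
    ratio = q2.value / q1.value
    verdict = "inhibited" if abs(ratio - 1.0) > tolerance else "ok"
    return InhibitionResult(verdict=verdict, ratio=ratio)


def normalize_expression(
    target_copies: float, ref_copies: Sequence[Optional[float]]
) -> float:
    """Target copies over the geometric mean of reference-gene copies."""
    if target_copies <= 0:
        raise ValueError("target copies must be > 0")
    if not ref_copies:
        raise ValueError("reference unquantifiable")
    for r in ref_copies:
        if r is None or r <= 0:
            raise ValueError("reference unquantifiable")
    return target_copies / float(stats.gmean(np.asarray(ref_copies, dtype=float)))


def knockdown_percent(
    treated: Sequence[float], control: Sequence[float]
) -> float:
    """100 * (1 - mean(treated)/mean(control)) on normalized expression."""
    if not len(treated) or not len(control):
        raise ValueError("both groups must be non-empty")
    mc = float(np.mean(control))
    if mc <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (1.0 - float(np.mean(treated)) / mc)


def read_cq_csv(path: Union[str, Path]) -> list[QpcrMeasurement]:
    """Read the fixed Cq dialect: sample_id,group,gene,dilution,replicate,cq
    with ``ND`` marking non-detected wells."""
    df = pd.read_csv(
        path, dtype={"sample_id": str, "group": str, "gene": str, "cq": str}
    )
    missing = [c for c in CQ_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq CSV missing columns: {missing}")
    out = []
    for row in df.itertuples():
        raw = str(row.cq).strip()
        cq = None if raw.upper() == ND else float(raw)
        out.append(
            QpcrMeasurement(
                sample_id=row.sample_id,
                group=row.group,
                gene=row.gene,
                dilution=float(row.dilution),
                replicate=int(row.replicate),
                cq=cq,
            )
        )
    return out


def fit_curves_from_standards(
    standards: Sequence[QpcrMeasurement], loq_residual: float = 0.5
) -> dict[str, StandardCurve]:
    """One StandardCurve per gene from a standards table."""
    curves = {}
    for gene in sorted({m.gene for m in standards}):
        pts = [(m.dilution, m.cq) for m in standards if m.gene == gene]
        curves[gene] = fit_standard_curve(pts, gene=gene, loq_residual=loq_residual)
    return curves


def sample_copy_number(
    measurements: Sequence[QpcrMeasurement],
    curve: StandardCurve,
    loq_impute: Optional[str] = None,
) -> Optional[float]:
    """Mean dilution-corrected copy number over a sample's wells for one gene.

    Below-LOQ and non-detected wells are excluded by default;
    ``loq_impute="half"`` substitutes LOQ/2 for them instead. Returns None
    when no well is usable.
    """
    values = []
    for m in measurements:
        q = quantify(m.cq, curve, m.dilution)
        if q.value is not None and not q.below_loq:
            values.append(q.value)
        elif loq_impute == "half" and curve.loq is not None:
            values.append(curve.loq / 2.0 / m.dilution)
    return float(np.mean(values)) if values else None


def expression_table(
    samples: Sequence[QpcrMeasurement],
    curves: dict[str, StandardCurve],
    target_gene: str,
    ref_genes: Sequence[str],
    loq_impute: Optional[str] = None,
) -> pd.DataFrame:
    """Per-sample normalized target expression.

    Columns: sample_id, group, target_copies, ref_geomean, normalized.
    Samples with an unquantifiable target or any unquantifiable reference
    are dropped.
    """
    rows = []
    for sid in sorted({m.sample_id for m in samples}):
        sub = [m for m in samples if m.sample_id == sid]
        group = sub[0].group
        tgt = sample_copy_number(
            [m for m in sub if m.gene == target_gene], curves[target_gene], loq_impute
        )
        refs = [
            sample_copy_number(
                [m for m in sub if m.gene == g], curves[g], loq_impute
            )
            for g in ref_genes
        ]
        if tgt is None or any(r is None for r in refs):
            continue
        norm = normalize_expression(tgt, refs)
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "target_copies": tgt,
                "ref_geomean": float(stats.gmean(refs)),
                "normalized": norm,
            }
        )
    return pd.DataFrame(rows)


def group_knockdown(
    table: pd.DataFrame, treated_group: str, control_group: str
) -> dict:
    """Knockdown percent plus a descriptive Welch t statistic."""
    treated = table.loc[table["group"] == treated_group, "normalized"].to_numpy()
    control = table.loc[table["group"] == control_group, "normalized"].to_numpy()
    kd = knockdown_percent(treated, control)
    if len(treated) > 1 and len(control) > 1:
        t_stat, t_p = stats.ttest_ind(treated, control, equal_var=False)
    else:
        t_stat, t_p = float("nan"), float("nan")
    return {
        "knockdown_pct": kd,
        "n_treated": int(len(treated)),
        "n_control": int(len(control)),
        "welch_t": float(t_stat),
        "welch_p": float(t_p),
    }
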