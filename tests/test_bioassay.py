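"""Survival and field-efficacy statistics: KM, Cox PH, Henderson-Tilton."""

import numpy as np
import pandas as pd
import pytest

from dsrna_forge.bioassay import (
    FieldAssessment,
    SurvivalRecord,
    cox_fit,
    emergence_rate,
    henderson_tilton,
    henderson_tilton_summary,
    km_curve,
    leaf_damage_increase,
    read_field_csv,
    read_survival_csv,
)
from oracle_utils import brute_cox_beta, naive_cox_loglik


def _rec(i, arm, t, e, trial=""):
    return SurvivalRecord(subject_id=f"s{i}", arm=arm, time=t, event=e, trial=trial)


def _two_arm_records(rng, n, rate0, rate1, max_day=None, round_days=False):
    records = []
    i = 0
    for arm, rate in (("ctrl", rate0), ("trt", rate1)):
        for _ in range(n):
            t = float(rng.exponential(1.0 / rate))
            if round_days:
                t = float(np.ceil(t))
            ev = 1
            if max_day is not None and t > max_day:
                t, ev = float(max_day), 0
            records.append(_rec(i, arm, t, ev))
            i += 1
    return records


class TestKaplanMeier:
    def test_hand_computed_four_subject_example(self):
        records = [
            _rec(1, "a", 1.0, 1),
            _rec(2, "a", 2.0, 1),
            _rec(3, "a", 2.0, 0),
            _rec(4, "a", 3.0, 0),
        ]
        curve = km_curve(records, "a")
        assert curve.survival_at(1.0) == pytest.approx(0.75)
        assert curve.survival_at(2.0) == pytest.approx(0.50)
        assert list(curve.at_risk) == [4, 3]
        assert list(curve.deaths) == [1, 1]

    def test_all_censored_gives_flat_one(self):
        records = [_rec(i, "a", 14.0, 0) for i in range(10)]
        curve = km_curve(records, "a")
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_no_censoring_reduces_to_one_minus_ecdf(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            times = np.ceil(rng.exponential(5.0, size=n))
            records = [_rec(i, "a", float(t), 1) for i, t in enumerate(times)]
            curve = km_curve(records, "a")
            for t in np.unique(times):
                assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(1)
        records = _two_arm_records(rng, 60, 0.05, 0.2, max_day=14, round_days=True)
        curve = km_curve(records, "trt")
        sub = [r for r in records if r.arm == "trt"]
        kmf = lifelines.KaplanMeierFitter().fit(
            [r.time for r in sub], [r.event for r in sub]
        )
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            km_curve([_rec(1, "a", 1.0, 1)], "b")


class TestCox:
    def test_symmetric_arms_give_zero_beta(self):
        records = []
        for i, t in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
            records.append(_rec(f"a{i}", "a", t, 1))
            records.append(_rec(f"b{i}", "b", t, 1))
        fit = cox_fit(records, "a")
        assert abs(fit.beta[0]) < 1e-6
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-8)

    def test_matches_bruteforce_partial_likelihood_maximizer(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            records = _two_arm_records(rng, 10, 0.05, 0.2)  # distinct times
            fit = cox_fit(records, "ctrl")
            times = np.array([r.time for r in records])
            events = np.array([r.event for r in records])
            x = np.array([1.0 if r.arm == "trt" else 0.0 for r in records])
            brute = brute_cox_beta(times, events, x)
            assert fit.beta[0] == pytest.approx(brute, abs=1e-4)
            # fitted log-likelihood agrees with the naive evaluation
            assert fit.loglik_fit == pytest.approx(
                naive_cox_loglik(fit.beta[0], times, events, x), abs=1e-8
            )
            assert fit.loglik_null == pytest.approx(
                naive_cox_loglik(0.0, times, events, x), abs=1e-8
            )

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(3)
        records = _two_arm_records(rng, 15, 0.05, 0.25)
        fe = cox_fit(records, "ctrl", ties="efron")
        fb = cox_fit(records, "ctrl", ties="breslow")
        assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-9)
        assert fe.loglik_fit == pytest.approx(fb.loglik_fit, abs=1e-9)

    def test_efron_matches_lifelines_with_heavy_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        records = _two_arm_records(rng, 80, 0.05, 0.25, max_day=14, round_days=True)
        fit = cox_fit(records, "ctrl")
        df = pd.DataFrame(
            {
                "t": [r.time for r in records],
                "e": [r.event for r in records],
                "x": [1.0 if r.arm == "trt" else 0.0 for r in records],
            }
        )
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert fit.beta[0] == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
        assert fit.se[0] == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-6
        )

    def test_three_arm_fit_with_strata(self):
        rng = np.random.default_rng(5)
        records = []
        for trial in ("t1", "t2"):
            for arm, rate in (("water", 0.04), ("dsEGFP", 0.05), ("dsMESH", 0.3)):
                for i in range(30):
                    t = float(np.ceil(rng.exponential(1.0 / rate)))
                    ev = 1
                    if t > 14:
                        t, ev = 14.0, 0
                    records.append(_rec(f"{trial}{arm}{i}", arm, t, ev, trial=trial))
        fit = cox_fit(records, "water", strata="trial")
        assert fit.converged
        assert fit.terms == ["dsEGFP", "dsMESH"]
        assert fit.beta[fit.terms.index("dsMESH")] > 1.0

    def test_complete_separation_flagged_not_raised(self):
        records = [_rec(i, "a", float(i % 5 + 1), 1) for i in range(10)]
        records += [_rec(10 + i, "b", 14.0, 0) for i in range(10)]
        fit = cox_fit(records, "b")
        assert fit.monotone_likelihood
        assert not fit.converged

    def test_error_cases(self):
        with pytest.raises(ValueError, match="no events"):
            cox_fit([_rec(1, "a", 1.0, 0), _rec(2, "b", 2.0, 0)], "a")
        with pytest.raises(ValueError, match="two arms"):
            cox_fit([_rec(1, "a", 1.0, 1), _rec(2, "a", 2.0, 1)], "a")
        with pytest.raises(ValueError, match="not present"):
            cox_fit([_rec(1, "a", 1.0, 1), _rec(2, "b", 2.0, 1)], "z")


class TestFieldMetrics:
    def test_henderson_tilton_worked_examples(self):
        treated = FieldAssessment("L", "p1", "dsMESH", 20, 2, 7)
        control = FieldAssessment("L", "c1", "control", 20, 20, 7)
        assert henderson_tilton(treated, control) == pytest.approx(90.0)
        # proportional decline -> zero corrected mortality
        t2 = FieldAssessment("L", "p2", "dsMESH", 30, 15, 7)
        c2 = FieldAssessment("L", "c2", "control", 20, 10, 7)
        assert henderson_tilton(t2, c2) == pytest.approx(0.0)
        t3 = FieldAssessment("L", "p3", "dsMESH", 18, 0, 7)
        assert henderson_tilton(t3, control) == pytest.approx(100.0)

    def test_henderson_tilton_scale_invariant(self):
        a = FieldAssessment("L", "p", "dsMESH", 20, 6, 7)
        c = FieldAssessment("L", "c", "control", 25, 21, 7)
        a3 = FieldAssessment("L", "p", "dsMESH", 60, 18, 7)
        c3 = FieldAssessment("L", "c", "control", 75, 63, 7)
        assert henderson_tilton(a, c) == pytest.approx(henderson_tilton(a3, c3))

    def test_control_collapse_rejected(self):
        a = FieldAssessment("L", "p", "dsMESH", 20, 5, 7)
        c = FieldAssessment("L", "c", "control", 20, 0, 7)
        with pytest.raises(ValueError, match="control collapsed"):
            henderson_tilton(a, c)

    def test_summary_pairs_within_location(self):
        assessments = [
            FieldAssessment("A", "a_c1", "control", 20, 18, 7),
            FieldAssessment("A", "a_c2", "control", 20, 18, 7),
            FieldAssessment("A", "a_t1", "dsMESH", 20, 2, 7),
            FieldAssessment("B", "b_c1", "control", 30, 15, 7),
            FieldAssessment("B", "b_t1", "dsMESH", 30, 15, 7),
        ]
        summary = henderson_tilton_summary(assessments, "dsMESH", "control")
        assert summary["per_location"]["A"] == pytest.approx(
            100 * (1 - (2 * 20) / (20 * 18))
        )
        assert summary["per_location"]["B"] == pytest.approx(0.0)
        assert summary["pooled"] == pytest.approx(
            (summary["per_location"]["A"] + 0.0) / 2
        )

    def test_leaf_damage_increase(self):
        a = FieldAssessment("L", "p", "dsMESH", 20, 5, 7,
                            damage_before=10.0, damage_after=35.0)
        assert leaf_damage_increase(a) == pytest.approx(25.0)
        b = FieldAssessment("L", "p", "dsMESH", 20, 5, 7,
                            damage_before=12.0, damage_after=12.0)
        assert leaf_damage_increase(b) == 0.0

    def test_emergence_rate(self):
        # 3 of 27 treated larvae emerging -> 11.1%
        assert emergence_rate(27, 3) == pytest.approx(100 * 3 / 27)
        assert emergence_rate(30, 0) == 0.0
        assert emergence_rate(30, 30) == 100.0
        with pytest.raises(ValueError, match="exceed"):
            emergence_rate(10, 11)
        with pytest.raises(ValueError):
            emergence_rate(0, 0)


class TestCsvDialects:
    def test_survival_roundtrip(self, tmp_path):
        p = tmp_path / "trial.csv"
        p.write_text(
            "subject_id,arm,trial,time_days,event\n"
            "s1,water,1,5,1\n"
            "s2,dsMESH,1,14,0\n"
        )
        records = read_survival_csv(p)
        assert records[0] == SurvivalRecord("s1", "water", 5.0, 1, "1")
        assert records[1].event == 0

    def test_survival_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("subject_id,arm,time_days\na,w,3\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_survival_csv(p)

    def test_field_roundtrip(self, tmp_path):
        p = tmp_path / "field.csv"
        p.write_text(
            "location,plot,arm,n_before,n_after,dpt,damage_before,damage_after\n"
            "A,p1,dsMESH,20,2,7,10,35\n"
        )
        a = read_field_csv(p)[0]
        assert (a.location, a.n_before, a.n_after) == ("A", 20, 2)
        assert leaf_damage_increase(a) == 25.0
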