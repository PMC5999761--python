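"""Behavioural event parsing, trial metrics, exclusions, and statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaidswitch import (COHERENT, TRANSPARENT, DesignError, TrialRecord,
                         apply_exclusions, clinical_correlation, cohort_table,
                         contrast_regression, epoch_statistics,
                         parse_event_log, trial_metrics, trial_to_epochs)
from plaidswitch.behavior import EventLogError


def make_trial(events, length=120.0, **meta):
    kw = dict(subject="s1", group="NTE", eye="binocular",
              direction="vertical", contrast=0.3, trial_length_s=length)
    kw.update(meta)
    return TrialRecord(events=events, **kw)


def event_rows(events, **meta):
    base = dict(subject="s1", group="NTE", eye="binocular",
                direction="vertical", contrast=0.3, trial_length_s=120.0)
    base.update(meta)
    return [dict(base, time_s=t, key=k) for t, k in events]


class TestParsing:
    def test_same_key_collapse(self):
        rows = event_rows([(0, COHERENT), (10, TRANSPARENT),
                           (10.5, TRANSPARENT), (30, COHERENT)])
        trials = parse_event_log(pd.DataFrame(rows))
        assert trials[0].events == [(0, COHERENT), (10, TRANSPARENT),
                                    (30, COHERENT)]

    def test_empty_trial_declared_with_blank_key(self):
        rows = event_rows([(np.nan, np.nan)])
        trials = parse_event_log(pd.DataFrame(rows))
        assert trials[0].events == []
        assert trial_metrics(trials[0]).n_switches == 0

    def test_duplicate_timestamp_rejected(self):
        rows = event_rows([(0, COHERENT), (10, TRANSPARENT),
                           (10, COHERENT)])
        with pytest.raises(EventLogError, match="10"):
            parse_event_log(pd.DataFrame(rows))

    def test_unknown_factor_level_rejected(self):
        rows = event_rows([(0, COHERENT)], eye="left")
        with pytest.raises(EventLogError, match="left"):
            parse_event_log(pd.DataFrame(rows))

    def test_missing_column_rejected(self):
        with pytest.raises(EventLogError, match="key"):
            parse_event_log(pd.DataFrame({"subject": ["a"]}))

    def test_full_crossed_design_trial_count(self):
        rows = []
        for eye in ("binocular", "weak", "strong"):
            for direction in ("vertical", "horizontal"):
                for contrast in (0.05, 0.30):
                    rows += event_rows([(0, COHERENT), (5, TRANSPARENT)],
                                       eye=eye, direction=direction,
                                       contrast=contrast)
        trials = parse_event_log(pd.DataFrame(rows))
        assert len(trials) == 12  # Experiment-2 design for one subject


class TestTrialMetrics:
    def test_worked_example(self):
        tr = make_trial([(0, COHERENT), (10, TRANSPARENT), (30, COHERENT),
                         (50, TRANSPARENT)])
        m = trial_metrics(tr)
        assert m.n_switches == 3
        assert m.coherent_durations_s == [10, 20]
        assert m.transparent_durations_s == [20]  # 50-120 s discarded
        assert m.mean_log10_coherent == pytest.approx(1.1505, abs=1e-4)
        assert m.mean_log10_transparent == pytest.approx(1.3010, abs=1e-4)

    def test_single_coherent_press(self):
        m = trial_metrics(make_trial([(0, COHERENT)]))
        assert m.n_switches == 0
        assert m.no_transparent
        assert m.coherent_durations_s == []

    def test_interrupted_transparent_not_measured(self):
        m = trial_metrics(make_trial([(0, COHERENT), (60, TRANSPARENT)]))
        assert m.n_switches == 1
        assert m.coherent_durations_s == [60]
        assert m.transparent_durations_s == []

    def test_late_first_press_epoch_starts_at_zero(self):
        m = trial_metrics(make_trial([(5, COHERENT), (20, TRANSPARENT),
                                      (40, COHERENT)]))
        assert m.coherent_durations_s == [20.0]  # 0-20 s, not 5-20 s
        assert m.transparent_durations_s == [20.0]

    def test_event_validation(self):
        with pytest.raises(EventLogError):
            make_trial([(0, COHERENT), (130, TRANSPARENT)])
        with pytest.raises(EventLogError):
            make_trial([(10, COHERENT), (5, TRANSPARENT)])
        with pytest.raises(EventLogError):
            make_trial([(0, "unsure")])

    @given(st.lists(st.floats(min_value=0.3, max_value=25), min_size=1,
                    max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_epoch_statistics(self, gaps):
        # shared-rule oracle: a coherent-first press sequence converted to
        # epochs must give identical metrics through either code path
        times = np.cumsum([0.0] + gaps)[:-1]
        keys = [COHERENT if i % 2 == 0 else TRANSPARENT
                for i in range(len(times))]
        tr = make_trial(list(zip(times, keys)), length=float(times[-1] + 30))
        direct = trial_metrics(tr)
        via_epochs = epoch_statistics(trial_to_epochs(tr))
        assert direct.n_switches == via_epochs.n_switches
        assert direct.coherent_durations_s == pytest.approx(
            via_epochs.coherent_durations_s)
        assert direct.transparent_durations_s == pytest.approx(
            via_epochs.transparent_durations_s)

    @given(st.lists(st.floats(min_value=0.3, max_value=25), min_size=1,
                    max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_time_conservation(self, gaps):
        times = np.cumsum([0.0] + gaps)[:-1]
        keys = [COHERENT if i % 2 == 0 else TRANSPARENT
                for i in range(len(times))]
        length = float(times[-1] + 30)
        tr = make_trial(list(zip(times, keys)), length=length)
        m = trial_metrics(tr)
        retained = sum(m.coherent_durations_s) + sum(m.transparent_durations_s)
        final_interval = length - (times[-1] if len(times) > 1 else 0.0)
        # retained durations + discarded final interval span the trial
        assert retained + final_interval == pytest.approx(length)


class TestExclusions:
    @staticmethod
    def base_cohort(n_subj=8, n_cond=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ("AMB", "NTE"):
            for s in range(n_subj):
                for c in range(n_cond):
                    rows.append({
                        "subject": f"{g}{s}", "group": g,
                        "eye": ["binocular", "weak", "strong"][c % 3],
                        "direction": ["vertical", "horizontal"][c % 2],
                        "contrast": [0.05, 0.3][c // 6],
                        "n_switches": 10,
                        "mean_log10_coh": rng.normal(0.7, 0.05),
                        "mean_log10_trans": rng.normal(0.5, 0.05),
                        "no_switch": False})
        return pd.DataFrame(rows)

    def test_clean_cohort_unchanged(self):
        cohort = self.base_cohort()
        kept, report = apply_exclusions(cohort)
        assert len(kept) == len(cohort)
        assert report.no_switch_subjects == []
        assert report.outlier_subjects == []

    def test_no_switch_subject_dropped(self):
        cohort = self.base_cohort()
        cohort.loc[cohort["subject"] == "AMB0", "no_switch"] = [True] + \
            [False] * 11
        kept, report = apply_exclusions(cohort)
        assert report.no_switch_subjects == ["AMB0"]
        assert "AMB0" not in set(kept["subject"])

    def test_outlier_in_many_conditions_dropped(self):
        cohort = self.base_cohort()
        # one subject far above the between-subject mean in 8 duration cells
        idx = cohort[cohort["subject"] == "NTE0"].index[:8]
        cohort.loc[idx, "mean_log10_coh"] += 3.0
        kept, report = apply_exclusions(cohort, outlier_condition_threshold=3)
        assert report.outlier_subjects == ["NTE0"]
        assert "NTE0" not in set(kept["subject"])

    def test_two_deviant_conditions_retained(self):
        cohort = self.base_cohort()
        idx = cohort[cohort["subject"] == "NTE0"].index[:2]
        cohort.loc[idx, "mean_log10_coh"] += 3.0
        kept, report = apply_exclusions(cohort, outlier_condition_threshold=3)
        assert report.outlier_subjects == []
        assert "NTE0" in set(kept["subject"])

    def test_deviation_below_mean_not_flagged(self):
        cohort = self.base_cohort()
        idx = cohort[cohort["subject"] == "NTE0"].index[:8]
        cohort.loc[idx, "mean_log10_coh"] -= 3.0  # 'above' rule is one-sided
        _, report = apply_exclusions(cohort)
        assert report.outlier_subjects == []

    def test_small_group_errors(self):
        cohort = self.base_cohort(n_subj=3)
        cohort.loc[cohort["subject"] == "AMB0", "no_switch"] = True
        with pytest.raises(DesignError, match="AMB"):
            apply_exclusions(cohort)


class TestContrastRegression:
    @staticmethod
    def cohort_from_slopes(slope_amb, slope_nte, noise=0.0, seed=0,
                           n_subj=6):
        rng = np.random.default_rng(seed)
        levels = [0.03, 0.05, 0.1, 0.15, 0.35, 0.5]
        rows = []
        for g, slope in (("AMB", slope_amb), ("NTE", slope_nte)):
            for s in range(n_subj):
                for c in levels:
                    rows.append({"subject": f"{g}{s}", "group": g,
                                 "eye": "binocular", "direction": "vertical",
                                 "contrast": c,
                                 "n_switches": 20 + slope * c
                                 + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_noiseless_linear_slope_recovered(self):
        cohort = self.cohort_from_slopes(slope_amb=-18.0, slope_nte=-18.0)
        out = contrast_regression(cohort, "n_switches")
        for g in ("AMB", "NTE"):
            assert out["groups"][g]["slope"] == pytest.approx(-18.0)
            assert out["groups"][g]["r_squared"] == pytest.approx(1.0)

    def test_flat_noiseless_slope_zero(self):
        cohort = self.cohort_from_slopes(0.0, 0.0)
        out = contrast_regression(cohort, "n_switches")
        assert out["groups"]["NTE"]["slope"] == pytest.approx(0.0, abs=1e-10)

    def test_interaction_detects_group_difference(self):
        cohort = self.cohort_from_slopes(0.0, -30.0, noise=2.0, seed=4)
        out = contrast_regression(cohort, "n_switches")
        assert out["interaction"]["p"] < 0.01
        assert out["interaction"]["df1"] == 1

    def test_log_contrast_option(self):
        cohort = self.cohort_from_slopes(0.0, -30.0, noise=2.0, seed=4)
        out = contrast_regression(cohort, "n_switches", log_contrast=True)
        assert out["log_contrast"] is True
        assert np.isfinite(out["groups"]["NTE"]["slope"])

    def test_too_few_levels_rejected(self):
        cohort = self.cohort_from_slopes(0, 0)
        cohort = cohort[cohort["contrast"].isin([0.03, 0.05, 0.1])]
        with pytest.raises(DesignError):
            contrast_regression(cohort, "n_switches")


class TestClinicalCorrelation:
    @staticmethod
    def cohort_with_switches(values):
        rows = []
        for s, v in values.items():
            for eye in ("weak", "strong", "binocular"):
                rows.append({"subject": s, "group": "AMB", "eye": eye,
                             "direction": "vertical", "contrast": 0.3,
                             "n_switches": v, "mean_log10_coh": 0.7,
                             "mean_log10_trans": 0.5, "no_switch": False})
        return pd.DataFrame(rows)

    def test_perfect_correlation(self):
        values = {f"a{i}": float(i) for i in range(1, 9)}
        cohort = self.cohort_with_switches(values)
        clinical = pd.DataFrame(
            {"subject": list(values), "log_SA": list(values.values()),
             "log_VA_weak": list(values.values()),
             "log_VA_strong": [-v for v in values.values()]})
        out = clinical_correlation(cohort, clinical)
        by = out.set_index("clinical")["pearson_r"]
        assert by["log_SA"] == pytest.approx(1.0)
        assert by["log_VA_weak"] == pytest.approx(1.0)
        assert by["log_VA_strong"] == pytest.approx(-1.0)
        assert (out["n"] == 8).all()

    def test_independent_values_mostly_uncorrelated(self):
        rng = np.random.default_rng(8)
        values = {f"a{i}": float(v)
                  for i, v in enumerate(rng.poisson(20, size=100))}
        cohort = self.cohort_with_switches(values)
        clinical = pd.DataFrame({"subject": list(values),
                                 "log_SA": rng.normal(2, 0.5, 100),
                                 "log_VA_weak": rng.normal(0.4, 0.3, 100),
                                 "log_VA_strong": rng.normal(0, 0.1, 100)})
        out = clinical_correlation(cohort, clinical)
        assert (out["pearson_r"].abs() < 0.3).all()
        assert (out["p"] > 0.05).all()

    def test_too_few_matches_rejected(self):
        cohort = self.cohort_with_switches({"a1": 10.0, "a2": 12.0})
        clinical = pd.DataFrame({"subject": ["a1", "a2"], "log_SA": [1, 2],
                                 "log_VA_weak": [1, 2],
                                 "log_VA_strong": [1, 2]})
        with pytest.raises(DesignError):
            clinical_correlation(cohort, clinical)


def test_cohort_table_shape():
    trials = [make_trial([(0, COHERENT), (10, TRANSPARENT)],
                         subject=f"s{i}") for i in range(4)]
    table = cohort_table(trials)
    assert len(table) == 4
    assert {"n_switches", "mean_log10_coh", "mean_log10_trans",
            "no_switch"} <= set(table.columns)
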