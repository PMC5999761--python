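"""Behavioural key-press analysis for 120-s bistable plaid trials.

Observers hold down nothing; they press one of two keys at every perceived
change, one key per percept (coherent / transparent).  Per trial, the two
dependent variables are:

* number of switches — key events counted from the first *transparent*
  report (inclusive; the change into it is the first genuine switch, since
  the first percept is always coherent) to the end of the trial;
* dominance durations — intervals between successive presses, with the
  final interrupted interval discarded, log10-transformed before averaging.

The first percept is assumed present from trial start, so the first
duration runs from t = 0 to the second press even when the first press is
registered late.

Event logs are delimited tables with one row per press: columns
``subject, group, eye, direction, contrast, trial_length_s, time_s, key``.
A row with an empty ``key`` declares a trial with no presses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .anova import DesignError
from .percepts import (COHERENT, TRANSPARENT, EpochStatistics, PerceptEpoch,
                       PerceptEpochSequence)

__all__ = [
    "GROUPS", "EYES", "DIRECTIONS", "KEYS",
    "TrialRecord", "EventLogError",
    "parse_event_log", "trial_metrics", "trial_to_epochs", "cohort_table",
    "apply_exclusions", "contrast_regression", "clinical_correlation",
]

GROUPS = ("AMB", "NTE")
EYES = ("binocular", "weak", "strong")
DIRECTIONS = ("vertical", "horizontal")
KEYS = (COHERENT, TRANSPARENT)

CONDITION_COLS = ["eye", "direction", "contrast"]


class EventLogError(ValueError):
    """Raised for malformed behavioural event logs."""


@dataclass
class TrialRecord:
    """One behavioural trial: metadata plus its (collapsed) key events."""

    subject: str
    group: str
    eye: str
    direction: str
    contrast: float
    trial_length_s: float = 120.0
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise EventLogError(f"unknown group {self.group!r}")
        if self.eye not in EYES:
            raise EventLogError(f"unknown eye condition {self.eye!r}")
        if self.direction not in DIRECTIONS:
            raise EventLogError(f"unknown direction {self.direction!r}")
        if self.trial_length_s <= 0:
            raise EventLogError("trial length must be positive")
        prev = -np.inf
        for t, key in self.events:
            if key not in KEYS:
                raise EventLogError(f"unknown percept key {key!r}")
            if not 0 <= t <= self.trial_length_s:
                raise EventLogError(
                    f"event time {t} outside [0, {self.trial_length_s}]")
            if t <= prev:
                raise EventLogError(
                    f"event times must be strictly increasing (at t = {t})")
            prev = t

    @property
    def condition(self) -> tuple:
        return (self.eye, self.direction, self.contrast)


REQUIRED_COLUMNS = ["subject", "group", "eye", "direction", "contrast",
                    "trial_length_s", "time_s", "key"]


def parse_event_log(table: pd.DataFrame | str) -> list[TrialRecord]:
    """Parse an event log into trial records.

    Events are grouped per trial and sorted by time; consecutive presses
    of the same key collapse to the first (a repeated key signals no
    percept change).  Duplicate timestamps within a trial are an error.
    """
    if isinstance(table, str):
        table = pd.read_csv(table)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise EventLogError(f"missing column(s): {missing}")
    trials = []
    meta_cols = ["subject", "group", "eye", "direction", "contrast",
                 "trial_length_s"]
    for meta, rows in table.groupby(meta_cols, sort=True):
        meta = dict(zip(meta_cols, meta))
        rows = rows.dropna(subset=["key"])
        rows = rows[rows["key"].astype(str).str.len() > 0]
        rows = rows.sort_values("time_s", kind="stable")
        times = rows["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            t_bad = times[np.flatnonzero(np.diff(times) <= 0)[0] + 1]
            raise EventLogError(
                f"duplicate/unsorted timestamp {t_bad} in trial "
                f"{tuple(meta.values())}")
        events = []
        for t, key in zip(times, rows["key"]):
            if events and events[-1][1] == key:
                continue  # repeated key: no percept change
            events.append((float(t), str(key)))
        trials.append(TrialRecord(
            subject=str(meta["subject"]), group=str(meta["group"]),
            eye=str(meta["eye"]), direction=str(meta["direction"]),
            contrast=float(meta["contrast"]),
            trial_length_s=float(meta["trial_length_s"]), events=events))
    return trials


def trial_to_epochs(trial: TrialRecord) -> PerceptEpochSequence | None:
    """Convert key events to percept epochs (first epoch starts at t = 0)."""
    if not trial.events:
        return None
    times = [0.0] + [t for t, _ in trial.events[1:]] + [trial.trial_length_s]
    epochs = [PerceptEpoch(key, times[i], times[i + 1])
              for i, (_, key) in enumerate(trial.events)]
    return PerceptEpochSequence(epochs=epochs,
                                total_time_s=trial.trial_length_s,
                                source="behavior")


def trial_metrics(trial: TrialRecord) -> EpochStatistics:
    """Switch count and dominance durations of one behavioural trial.

    The switch count is the number of key events from the first transparent
    report (inclusive) to trial end.  Durations are intervals between
    successive presses, the first percept being present from t = 0 and the
    final interrupted interval discarded.  When the first event is coherent
    — the behavioural norm, since the first percept always is — the result
    is identical to :func:`plaidswitch.percepts.epoch_statistics` applied
    to :func:`trial_to_epochs`.
    """
    events = trial.events
    keys = [k for _, k in events]
    if TRANSPARENT not in keys:
        return EpochStatistics(n_switches=0, no_transparent=True)
    first_t = keys.index(TRANSPARENT)
    n_switches = len(events) - first_t
    times = [0.0] + [t for t, _ in events[1:]] + [trial.trial_length_s]
    durations = np.diff(times)[:-1]  # final interrupted interval discarded
    coh = [float(d) for d, k in zip(durations, keys) if k == COHERENT]
    tra = [float(d) for d, k in zip(durations, keys) if k == TRANSPARENT]
    return EpochStatistics(n_switches=n_switches, coherent_durations_s=coh,
                           transparent_durations_s=tra)


def cohort_table(trials: list[TrialRecord]) -> pd.DataFrame:
    """Tidy per-subject-per-condition table of the dependent variables."""
    rows = []
    for tr in trials:
        m = trial_metrics(tr)
        rows.append({
            "subject": tr.subject, "group": tr.group, "eye": tr.eye,
            "direction": tr.direction, "contrast": tr.contrast,
            "n_switches": m.n_switches,
            "mean_log10_coh": m.mean_log10_coherent,
            "mean_log10_trans": m.mean_log10_transparent,
            "no_switch": m.no_transparent,
        })
    return pd.DataFrame(rows)


def tidy_durations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Long format with ``percept`` as an explicit within factor."""
    long = cohort.melt(
        id_vars=["subject", "group"] + CONDITION_COLS,
        value_vars=["mean_log10_coh", "mean_log10_trans"],
        var_name="percept", value_name="mean_log10_duration")
    long["percept"] = long["percept"].map(
        {"mean_log10_coh": COHERENT, "mean_log10_trans": TRANSPARENT})
    return long


@dataclass
class ExclusionReport:
    no_switch_subjects: list[str]
    outlier_subjects: list[str]
    outlier_cell_counts: dict[str, int]
    n_cells: int


def apply_exclusions(cohort: pd.DataFrame, outlier_condition_threshold: int = 3,
                     sd_bound: float = 2.0,
                     min_group_size: int = 3) -> tuple[pd.DataFrame, ExclusionReport]:
    """Exclusion rules for the duration analysis.

    Subjects with no perceptual switch in at least one condition lack the
    duration variable there and are dropped.  Then, per condition x percept
    cell, duration values more than ``sd_bound`` SD *above* the
    between-subject mean of the cell (computed within group) are flagged;
    subjects flagged in at least ``outlier_condition_threshold`` cells are
    dropped.  The returned table serves duration analyses only —
    switch-count analyses keep every subject.
    """
    no_switch = sorted(cohort.loc[cohort["no_switch"], "subject"].unique())
    kept = cohort[~cohort["subject"].isin(no_switch)].copy()

    counts: dict[str, int] = {}
    n_cells = 0
    for dv in ("mean_log10_coh", "mean_log10_trans"):
        grouped = kept.groupby(["group"] + CONDITION_COLS)[dv]
        mean = grouped.transform("mean")
        sd = grouped.transform("std")
        flagged = kept.loc[kept[dv] > mean + sd_bound * sd, "subject"]
        n_cells += kept.groupby(["group"] + CONDITION_COLS).ngroups
        for s in flagged:
            counts[s] = counts.get(s, 0) + 1
    outliers = sorted(s for s, c in counts.items()
                      if c >= outlier_condition_threshold)
    kept = kept[~kept["subject"].isin(outliers)]

    for g, sub in kept.groupby("group"):
        if sub["subject"].nunique() < min_group_size:
            raise DesignError(
                f"fewer than {min_group_size} subjects left in group {g!r} "
                "after exclusions; duration statistics undefined")
    report = ExclusionReport(no_switch_subjects=no_switch,
                             outlier_subjects=outliers,
                             outlier_cell_counts=counts, n_cells=n_cells)
    return kept, report


# ---------------------------------------------------------------------------
# contrast regressions and clinical correlations
# ---------------------------------------------------------------------------

def contrast_regression(cohort: pd.DataFrame, dv: str = "n_switches",
                        log_contrast: bool = False) -> dict:
    """Per-group linear fit of the response against contrast.

    Group fits use the across-subject condition means (one point per
    contrast level) and report slope, 95% CI, and R^2.  The
    group x contrast interaction F compares the groups' per-subject
    linear-trend slopes (one OLS slope per subject) with a one-way ANOVA.
    """
    levels = np.sort(cohort["contrast"].unique())
    if levels.size < 4:
        raise DesignError("at least 4 contrast levels required")
    xcol = np.log10(levels) if log_contrast else levels

    per_subj = (cohort.groupby(["group", "subject", "contrast"])[dv]
                .mean().reset_index())
    out: dict = {"dv": dv, "log_contrast": log_contrast, "groups": {}}
    subj_slopes = []
    for g, sub in per_subj.groupby("group"):
        if sub["contrast"].nunique() < 3:
            raise DesignError(f"group {g!r} has < 3 contrast points")
        cond_means = sub.groupby("contrast")[dv].mean().reindex(levels)
        x = sm.add_constant(xcol)
        fit = sm.OLS(cond_means.to_numpy(), x).fit()
        ci = fit.conf_int()[1]
        out["groups"][g] = {
            "slope": float(fit.params[1]),
            "ci_low": float(ci[0]), "ci_high": float(ci[1]),
            "r_squared": float(fit.rsquared),
            "p": float(fit.pvalues[1]), "n_levels": int(levels.size)}
        for s, ssub in sub.groupby("subject"):
            xs = np.log10(ssub["contrast"]) if log_contrast else ssub["contrast"]
            slope = np.polyfit(xs, ssub[dv], 1)[0]
            subj_slopes.append({"group": g, "slope": slope})
    slopes = pd.DataFrame(subj_slopes)
    groups = [d["slope"].to_numpy() for _, d in slopes.groupby("group")]
    if len(groups) == 2:
        f, p = stats.f_oneway(*groups)
        out["interaction"] = {"F": float(f),
                              "df1": 1, "df2": int(len(slopes) - 2),
                              "p": float(p)}
    return out


def clinical_correlation(cohort: pd.DataFrame,
                         clinical: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between monocular switch counts and acuities.

    ``clinical`` columns: ``subject, log_SA, log_VA_weak, log_VA_strong``.
    Pairings mirror the standard report: weak-eye and strong-eye switch
    counts against the matching visual acuity, and mean monocular switch
    count against stereo acuity.
    """
    mono = cohort[cohort["eye"].isin(["weak", "strong"])]
    per_eye = (mono.groupby(["subject", "eye"])["n_switches"]
               .mean().unstack("eye"))
    both = per_eye.mean(axis=1).rename("monocular")
    merged = clinical.set_index("subject").join(per_eye).join(both)
    pairings = [("monocular", "log_SA"), ("weak", "log_VA_weak"),
                ("strong", "log_VA_strong")]
    rows = []
    for sw_col, cl_col in pairings:
        sub = merged[[sw_col, cl_col]].dropna()
        if len(sub) < 3:
            raise DesignError(
                f"fewer than 3 matched subjects for {sw_col} vs {cl_col}")
        r, p = stats.pearsonr(sub[sw_col], sub[cl_col])
        rows.append({"switches": sw_col, "clinical": cl_col,
                     "pearson_r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)
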