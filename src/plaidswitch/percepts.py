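"""Percept epoch extraction and dominance statistics.

A simulated sample is labelled *coherent* when the coherent population's
rate strictly exceeds both transparent rates, and *transparent* otherwise
(T_R and T_L collapse to a single transparent label; ties are transparent).
Runs of equal labels form epochs; the two dependent variables of a trial
are the number of switches — counted from the first transparent epoch to
the end of the trial, the convention used for behavioural key presses —
and the dominance durations, excluding the final interrupted epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COHERENT",
    "TRANSPARENT",
    "PerceptEpoch",
    "PerceptEpochSequence",
    "EpochStatistics",
    "classify_trajectory",
    "epoch_statistics",
    "summarize_repeats",
]

COHERENT = "coherent"
TRANSPARENT = "transparent"


@dataclass(frozen=True)
class PerceptEpoch:
    label: str
    onset_s: float
    offset_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class PerceptEpochSequence:
    """Ordered, contiguous, label-alternating percept epochs of one trial."""

    epochs: list[PerceptEpoch]
    total_time_s: float
    source: str = "simulation"

    def __post_init__(self) -> None:
        prev = None
        for ep in self.epochs:
            if ep.offset_s <= ep.onset_s:
                raise ValueError(f"empty or inverted epoch {ep}")
            if prev is not None:
                if ep.onset_s != prev.offset_s:
                    raise ValueError("epochs must be contiguous")
                if ep.label == prev.label:
                    raise ValueError("consecutive epochs must alternate labels")
            prev = ep

    def labels(self) -> list[str]:
        return [ep.label for ep in self.epochs]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [ep.label for ep in self.epochs],
                "onset_s": [ep.onset_s for ep in self.epochs],
                "offset_s": [ep.offset_s for ep in self.epochs],
            }
        )


def classify_trajectory(traj, min_epoch_s: float = 0.0,
                        source: str = "simulation") -> PerceptEpochSequence:
    """Label every sample of a trajectory and run-length encode into epochs.

    Parameters
    ----------
    traj : NetworkTrajectory
        Simulated trial (rates in population order C, T_R, T_L).
    min_epoch_s : float
        Optional minimum epoch length; epochs shorter than this merge into
        their predecessor (default 0 = off).  Sub-perceptual flickers near
        the classification boundary are artifacts of per-sample labelling,
        so the filter exists, but the default reports the raw labels.
    """
    rates = np.asarray(traj.rates)
    if rates.shape[0] == 0:
        raise ValueError("empty trajectory")
    t_s = np.asarray(traj.times_ms, dtype=float) / 1000.0
    coherent = (rates[:, 0] > rates[:, 1]) & (rates[:, 0] > rates[:, 2])
    total = float(t_s[-1])

    # run boundaries: first sample of each new label
    change = np.flatnonzero(np.diff(coherent.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    onsets = t_s[starts]
    offsets = np.concatenate((onsets[1:], [total]))
    labels = [COHERENT if coherent[i] else TRANSPARENT for i in starts]

    if min_epoch_s > 0 and len(labels) > 1:
        labels, onsets, offsets = _merge_short(labels, list(onsets),
                                               list(offsets), min_epoch_s)
    epochs = [PerceptEpoch(lab, float(on), float(off))
              for lab, on, off in zip(labels, onsets, offsets)]
    return PerceptEpochSequence(epochs=epochs, total_time_s=total, source=source)


def _merge_short(labels, onsets, offsets, min_epoch_s):
    """Merge epochs shorter than the bound into their predecessor.

    A short leading epoch has no predecessor and is absorbed forward into
    its successor instead (the startup transient, where all rates are tied
    at zero, otherwise survives as a spurious transparent flicker).
    """
    labels, onsets, offsets = list(labels), list(onsets), list(offsets)
    while len(labels) > 1 and offsets[0] - onsets[0] < min_epoch_s:
        onsets[1] = onsets[0]
        del labels[0], onsets[0], offsets[0]
    out_l, out_on, out_off = [labels[0]], [onsets[0]], [offsets[0]]
    for lab, on, off in zip(labels[1:], onsets[1:], offsets[1:]):
        if off - on < min_epoch_s:
            out_off[-1] = off  # absorbed by predecessor
        elif lab == out_l[-1]:
            out_off[-1] = off  # re-merge runs joined by an absorption
        else:
            out_l.append(lab)
            out_on.append(on)
            out_off.append(off)
    return out_l, out_on, out_off


@dataclass
class EpochStatistics:
    """Switch count and dominance durations of one trial.

    ``n_switches`` counts label changes from the first transparent epoch
    (inclusive — the change into it is the first switch) to trial end.
    Duration lists exclude the final interrupted epoch.  ``no_transparent``
    flags trials that never left the coherent percept.
    """

    n_switches: int
    coherent_durations_s: list[float] = field(default_factory=list)
    transparent_durations_s: list[float] = field(default_factory=list)
    no_transparent: bool = False

    @property
    def log10_coherent(self) -> list[float]:
        return [np.log10(d) for d in self.coherent_durations_s]

    @property
    def log10_transparent(self) -> list[float]:
        return [np.log10(d) for d in self.transparent_durations_s]

    @property
    def mean_log10_coherent(self) -> float:
        vals = self.log10_coherent
        return float(np.mean(vals)) if vals else np.nan

    @property
    def mean_log10_transparent(self) -> float:
        vals = self.log10_transparent
        return float(np.mean(vals)) if vals else np.nan


def epoch_statistics(seq: PerceptEpochSequence) -> EpochStatistics:
    """Compute the trial's switch count and per-label duration lists."""
    if not seq.epochs:
        raise ValueError("at least one epoch required")
    labels = seq.labels()
    if TRANSPARENT not in labels:
        return EpochStatistics(n_switches=0, no_transparent=True)
    first_t = labels.index(TRANSPARENT)
    # each epoch at or after the first transparent one begins with a switch,
    # except a transparent epoch that opens the trial (no change precedes it)
    n_switches = len(labels) - first_t
    if first_t == 0:
        n_switches -= 1
    retained = seq.epochs[:-1]
    coh = [ep.duration_s for ep in retained if ep.label == COHERENT]
    tra = [ep.duration_s for ep in retained if ep.label == TRANSPARENT]
    return EpochStatistics(n_switches=n_switches, coherent_durations_s=coh,
                           transparent_durations_s=tra)


def summarize_repeats(stats: list[EpochStatistics]) -> dict:
    """Mean and sample SD (n-1) of the per-trial variables across repeats.

    Trials flagged ``no_transparent`` are excluded from duration summaries
    and counted separately; if every trial is flagged the duration
    summaries are reported as NaN.
    """
    if len(stats) < 2:
        raise ValueError("at least two trials required")
    switches = np.array([s.n_switches for s in stats], dtype=float)
    ok = [s for s in stats if not s.no_transparent]
    out = {
        "n_trials": len(stats),
        "n_no_transparent": len(stats) - len(ok),
        "switches_mean": float(np.mean(switches)),
        "switches_sd": float(np.std(switches, ddof=1)),
    }
    for key, attr in (("log10_coh", "mean_log10_coherent"),
                      ("log10_trans", "mean_log10_transparent")):
        vals = np.array([getattr(s, attr) for s in ok], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size >= 2:
            out[f"{key}_mean"] = float(np.mean(vals))
            out[f"{key}_sd"] = float(np.std(vals, ddof=1))
        else:
            out[f"{key}_mean"] = float(vals[0]) if vals.size == 1 else np.nan
            out[f"{key}_sd"] = np.nan
    return out
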