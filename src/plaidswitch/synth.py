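"""Seeded generator of synthetic behavioural event logs.

Emulates the statistical structure the analysis pipeline assumes: each
trial is an alternating renewal process starting with a coherent percept at
t = 0, with dominance durations drawn from a log-normal law (the family
consistent with log10-transforming durations before averaging; a
moment-matched gamma alternative is available).  Between-subject
heterogeneity enters as normal random intercepts on the log10 duration
means, and stimulus contrast enters as a per-group linear trend on the
log10 means — by default positive for the control group (NTE: durations
shorten, switches accelerate, as contrast drops) and zero for the
amblyopic group (AMB: flat), the effect structure the contrast experiments
probe.

No attempt is made to emulate reaction-time lags, misreports, or eye
movements; generated logs are idealised percept reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .percepts import COHERENT, TRANSPARENT

__all__ = ["CohortDesign", "sample_trial_events", "generate_cohort"]


@dataclass
class CohortDesign:
    """Design of a synthetic cohort.

    ``log10_mean_coh`` / ``log10_mean_trans`` are the population log10
    dominance-duration means (seconds) at the reference contrast;
    ``log10_sd_within`` is the epoch-to-epoch spread within a trial and
    ``subject_sd`` the SD of the per-subject random intercept, all in
    log10 units.  ``contrast_slope`` maps group -> change of the log10
    means per unit contrast relative to ``contrast_ref``.
    """

    n_amb: int = 10
    n_nte: int = 11
    eyes: tuple[str, ...] = ("binocular", "weak", "strong")
    directions: tuple[str, ...] = ("vertical", "horizontal")
    contrasts: tuple[float, ...] = (0.05, 0.30)
    trial_length_s: float = 120.0
    log10_mean_coh: float = 0.75
    log10_mean_trans: float = 0.55
    log10_sd_within: float = 0.25
    subject_sd: float = 0.15
    contrast_slope: dict = field(
        default_factory=lambda: {"NTE": 0.5, "AMB": 0.0})
    contrast_ref: float = 0.30
    duration_family: str = "lognormal"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.log10_sd_within < 0 or self.subject_sd < 0:
            raise ValueError("spreads must be non-negative")
        if self.n_amb < 1 or self.n_nte < 1:
            raise ValueError("need at least one subject per group")
        if self.duration_family not in ("lognormal", "gamma"):
            raise ValueError("duration_family must be 'lognormal' or 'gamma'")
        if self.trial_length_s <= 0:
            raise ValueError("trial length must be positive")

    @classmethod
    def experiment1(cls, **kw) -> "CohortDesign":
        """Single high contrast, three eyes, two directions."""
        return cls(n_amb=10, n_nte=10, contrasts=(0.30,), **kw)

    @classmethod
    def experiment2(cls, **kw) -> "CohortDesign":
        """High and low contrast crossed with eyes and directions."""
        return cls(n_amb=10, n_nte=11, contrasts=(0.05, 0.30), **kw)

    @classmethod
    def experiment3(cls, **kw) -> "CohortDesign":
        """Six contrast levels, vertical motion, binocular viewing."""
        return cls(n_amb=5, n_nte=6, eyes=("binocular",),
                   directions=("vertical",),
                   contrasts=(0.03, 0.05, 0.1, 0.15, 0.35, 0.5), **kw)

    @property
    def conditions(self) -> list[tuple[str, str, float]]:
        return [(e, d, c) for e in self.eyes for d in self.directions
                for c in self.contrasts]

    def null(self) -> "CohortDesign":
        """Copy with every group effect removed (type-I calibration)."""
        import dataclasses
        return dataclasses.replace(
            self, contrast_slope={g: 0.0 for g in self.contrast_slope})


def _draw_duration(rng: np.random.Generator, mean_log10: float,
                   sd_log10: float, family: str) -> float:
    if family == "lognormal":
        return float(10.0 ** rng.normal(mean_log10, sd_log10))
    # gamma with the same raw-scale mean and variance as the log-normal
    ln10 = np.log(10.0)
    mu = np.exp(ln10 * mean_log10 + 0.5 * (ln10 * sd_log10) ** 2)
    var = (np.exp((ln10 * sd_log10) ** 2) - 1.0) * mu ** 2
    if var <= 0:
        return float(mu)
    shape = mu ** 2 / var
    return float(rng.gamma(shape, var / mu))


def sample_trial_events(mean_log10_coh: float, mean_log10_trans: float,
                        sd_log10: float, trial_length_s: float,
                        rng: np.random.Generator | int,
                        family: str = "lognormal") -> list[tuple[float, str]]:
    """Sample one trial's key events (alternating renewal process).

    The first percept is coherent and starts at t = 0; epoch lengths are
    drawn per percept and the trial truncates at ``trial_length_s`` (the
    epoch in progress at the end is the interrupted one the analysis
    discards).  Events are emitted at epoch onsets.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    events = []
    t, label = 0.0, COHERENT
    while t < trial_length_s:
        events.append((t, label))
        mean = mean_log10_coh if label == COHERENT else mean_log10_trans
        t += _draw_duration(rng, mean, sd_log10, family)
        label = TRANSPARENT if label == COHERENT else COHERENT
    return events


def generate_cohort(design: CohortDesign, clinical: str | None = None,
                    clinical_r: float = 0.7
                    ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate a full event log (and optionally a clinical table).

    One trial per subject x condition.  ``clinical`` may be ``None`` (no
    table), ``"null"`` (acuities independent of behaviour) or ``"linked"``
    (acuities correlated, with coefficient ``clinical_r``, to the subject's
    duration intercept).  Returns ``(events, clinical_table)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(design.base_seed))
    rows = []
    subj_offsets: dict[str, float] = {}
    for group, n_subj in (("AMB", design.n_amb), ("NTE", design.n_nte)):
        slope = design.contrast_slope.get(group, 0.0)
        for i in range(n_subj):
            subject = f"{group.lower()}{i + 1:02d}"
            offset = rng.normal(0.0, design.subject_sd)
            subj_offsets[subject] = offset
            for eye, direction, contrast in design.conditions:
                shift = offset + slope * (contrast - design.contrast_ref)
                events = sample_trial_events(
                    design.log10_mean_coh + shift,
                    design.log10_mean_trans + shift,
                    design.log10_sd_within, design.trial_length_s, rng,
                    design.duration_family)
                for t, key in events:
                    rows.append({"subject": subject, "group": group,
                                 "eye": eye, "direction": direction,
                                 "contrast": contrast,
                                 "trial_length_s": design.trial_length_s,
                                 "time_s": round(t, 4), "key": key})
    events_df = pd.DataFrame(rows)

    clinical_df = None
    if clinical is not None:
        if clinical not in ("null", "linked"):
            raise ValueError("clinical must be None, 'null' or 'linked'")
        crows = []
        for subject, offset in subj_offsets.items():
            if not subject.startswith("amb"):
                continue
            if clinical == "null":
                zs = rng.standard_normal(3)
            else:
                # acuity worsens with the subject's duration intercept
                scale = np.sqrt(max(0.0, 1.0 - clinical_r ** 2))
                zs = (clinical_r * (offset / max(design.subject_sd, 1e-12))
                      + scale * rng.standard_normal(3))
            crows.append({"subject": subject,
                          "log_SA": 2.0 + 0.45 * zs[0],
                          "log_VA_weak": 0.4 + 0.30 * zs[1],
                          "log_VA_strong": 0.0 + 0.10 * zs[2]})
        clinical_df = pd.DataFrame(crows)
    return events_df, clinical_df
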