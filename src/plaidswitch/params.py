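"""Model parameters for the three-population plaid-motion competition model.

The network has three firing-rate populations — coherent (C) and the two
depth-ordered transparent percepts (T_R, T_L) — coupled by mutual inhibition,
each with slow spike-frequency adaptation and an Ornstein-Uhlenbeck noise
input.  The literature reuses the symbol ``tau`` for three distinct time
constants; this container disambiguates them (``tau_r``, ``tau_a``,
``tau_s``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = ["ModelParameters", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """All constants of the competition model.

    Time constants and ``dt`` are in milliseconds; ``duration`` is in
    seconds (user-facing trial lengths are quoted in seconds).

    Parameters
    ----------
    tau_r : float
        Firing-rate relaxation time constant, ms.
    tau_a : float
        Spike-frequency adaptation time constant, ms.
    tau_s : float
        Ornstein-Uhlenbeck noise correlation time, ms.
    beta1 : float
        Cross-inhibition strength between C and each transparent population.
    beta2 : float
        Inhibition strength between T_R and T_L.
    gamma : float
        Adaptation strength; the adaptation variable saturates at
        ``gamma * r`` for a clamped rate ``r``.
    sigma : float
        Noise strength; equals the stationary standard deviation of the
        OU process.
    theta : float
        Transducer threshold (half-activation input).
    k : float
        Transducer slope parameter.
    I_C, I_TR, I_TL : float
        Deterministic external inputs to the three populations.
    dt : float
        Euler integration step, ms.
    duration : float
        Simulated trial length, s.
    transducer_base : float
        Base of the exponential in the sigmoidal transducer.  The default
        ``e`` gives the standard logistic gain used throughout the rivalry
        modelling literature; other bases are exposed only for fidelity
        experiments with non-standard printed forms.
    """

    tau_r: float = 10.0
    tau_a: float = 2500.0
    tau_s: float = 200.0
    beta1: float = 0.9
    beta2: float = 0.7
    gamma: float = 0.25
    sigma: float = 0.08
    theta: float = 0.2
    k: float = 0.1
    I_C: float = 1.0
    I_TR: float = 0.9
    I_TL: float = 0.9
    dt: float = 1.0
    duration: float = 120.0
    transducer_base: float = field(default=math.e)

    def __post_init__(self) -> None:
        for name in ("tau_r", "tau_a", "tau_s", "dt", "duration", "k"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("sigma", "gamma", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.dt > self.tau_r / 5.0:
            raise InvalidParameterError(
                f"dt = {self.dt} ms too coarse; require dt <= tau_r/5 = "
                f"{self.tau_r / 5.0} ms"
            )
        if self.transducer_base <= 0 or self.transducer_base == 1.0:
            raise InvalidParameterError("transducer_base must be positive and != 1")

    # -- convenience -----------------------------------------------------

    @property
    def n_steps(self) -> int:
        """Number of Euler steps in one trial."""
        return int(math.floor(self.duration * 1000.0 / self.dt))

    @property
    def n_samples(self) -> int:
        """Number of stored samples (steps + initial state)."""
        return self.n_steps + 1

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    @classmethod
    def sweep_base(cls) -> "ModelParameters":
        """Reference point of the simulation battery.

        beta1 = 0.9, beta2 = 0.7, sigma = 0.06, gamma = 0.2, I_C = 1 and
        I_T = 0.9 I_C — the representative operating point at which noise,
        adaptation, input strength and relative input are varied one at a
        time.
        """
        return cls(sigma=0.06, gamma=0.2, I_C=1.0, I_TR=0.9, I_TL=0.9)

    # -- config I/O ------------------------------------------------------

    @classmethod
    def from_config(cls, path: str) -> "ModelParameters":
        """Load parameters from a flat YAML mapping of field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidParameterError(f"config {path!r} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s) in {path!r}: {sorted(unknown)}"
            )
        return cls(**{key: float(val) for key, val in raw.items()})

    def to_config(self, path: str) -> None:
        """Write parameters as a flat YAML mapping."""
        data = {f.name: float(getattr(self, f.name)) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
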