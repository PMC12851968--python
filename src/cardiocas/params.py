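"""Core parameter containers for the cardiac autonomic signature (CAS).

The CAS describes a subject's beat-to-beat R-R interval (RRi) trajectory
across a rest-exercise-recovery protocol with seven parameters: a baseline
level ``alpha`` (ms), an exercise-induced drop of magnitude ``beta`` (ms),
a recovery of magnitude ``c * beta`` (``c`` dimensionless), logistic rate
constants ``lam`` and ``phi`` (min^-1) for the drop and recovery
transitions, the drop onset time ``tau`` (min) and the lag ``delta`` (min)
from drop onset to recovery onset.  ``sigma`` (ms) is the standard
deviation of the Gaussian beat-to-beat observation noise around the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "CASParameters",
    "ProtocolTiming",
    "ParameterBounds",
    "CAS_PARAM_NAMES",
]

#: Canonical ordering of the seven CAS parameters.
CAS_PARAM_NAMES = ("alpha", "beta", "c", "lam", "phi", "tau", "delta")


@dataclass(frozen=True)
class CASParameters:
    """The 7-parameter CAS vector plus observation-noise SD.

    Parameters
    ----------
    alpha : float
        Baseline (resting) RRi level in ms.
    beta : float
        Magnitude of the exercise-induced RRi drop in ms (>= 0).
    c : float
        Recovery proportion relative to ``beta`` (dimensionless); the
        post-recovery asymptote is ``alpha - beta * (1 - c)``.
    lam : float
        Steepness of the drop transition in min^-1 (> 0).
    phi : float
        Steepness of the recovery transition in min^-1 (> 0).
    tau : float
        Drop onset time in minutes.
    delta : float
        Lag from drop onset to recovery onset in minutes (>= 0).
    sigma : float
        Beat-to-beat Gaussian noise SD in ms (>= 0).
    """

    alpha: float
    beta: float
    c: float
    lam: float
    phi: float
    tau: float
    delta: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if self.phi <= 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.alpha - self.beta <= 0:
            raise ValueError(
                "alpha - beta must be > 0 so RRi stays positive at the "
                f"exercise nadir (alpha={self.alpha}, beta={self.beta})"
            )

    def as_array(self) -> np.ndarray:
        """Return the 7-vector (alpha, beta, c, lam, phi, tau, delta)."""
        return np.array([getattr(self, k) for k in CAS_PARAM_NAMES], float)

    @classmethod
    def from_array(cls, theta: np.ndarray, sigma: float = 0.0) -> "CASParameters":
        theta = np.asarray(theta, float)
        if theta.shape != (7,):
            raise ValueError(f"expected a 7-vector, got shape {theta.shape}")
        return cls(*theta, sigma=sigma)

    @staticmethod
    def is_valid_vector(theta: np.ndarray) -> bool:
        """Check the CAS invariants on a raw 7-vector without raising."""
        alpha, beta, c, lam, phi, tau, delta = np.asarray(theta, float)
        return bool(
            beta >= 0 and lam > 0 and phi > 0 and delta >= 0 and alpha - beta > 0
        )


@dataclass(frozen=True)
class ProtocolTiming:
    """Durations (min) of the rest, exercise and recovery segments."""

    rest_duration: float = 7.0
    exercise_duration: float = 2.0
    recovery_duration: float = 5.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {v}")

    @property
    def total_duration(self) -> float:
        return self.rest_duration + self.exercise_duration + self.recovery_duration

    @property
    def exercise_onset(self) -> float:
        return self.rest_duration

    @property
    def recovery_onset(self) -> float:
        return self.rest_duration + self.exercise_duration


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the 7 CAS parameters, as (lower, upper) pairs.

    Defaults enclose physiologic ranges for adult exercise testing; ``tau``
    defaults to the full span of the 14-min default protocol.
    """

    alpha: tuple = (300.0, 1500.0)
    beta: tuple = (0.0, 1000.0)
    c: tuple = (0.0, 2.0)
    lam: tuple = (0.1, 20.0)
    phi: tuple = (0.1, 20.0)
    tau: tuple = (0.0, 14.0)
    delta: tuple = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in CAS_PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    @classmethod
    def for_protocol(cls, protocol: ProtocolTiming, **overrides) -> "ParameterBounds":
        """Default bounds with ``tau`` capped at the protocol span."""
        kw = {"tau": (0.0, protocol.total_duration)}
        kw.update(overrides)
        return cls(**kw)

    def as_arrays(self) -> tuple:
        lo = np.array([getattr(self, k)[0] for k in CAS_PARAM_NAMES])
        hi = np.array([getattr(self, k)[1] for k in CAS_PARAM_NAMES])
        return lo, hi

    def clip(self, theta: np.ndarray) -> np.ndarray:
        lo, hi = self.as_arrays()
        return np.clip(np.asarray(theta, float), lo, hi)

    def contains(self, theta: np.ndarray) -> bool:
        lo, hi = self.as_arrays()
        theta = np.asarray(theta, float)
        return bool(np.all(theta >= lo) and np.all(theta <= hi))
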