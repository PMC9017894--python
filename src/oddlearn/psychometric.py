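"""Psychometric function and learning-trajectory mathematics.

The task is two-alternative texture-oddball detection: on each trial the
observer reports whether a briefly presented grid of oriented lines contains
a single offset element.  Accuracy as a function of stimulus onset asynchrony
(SOA, the time between stimulus and mask) follows a chance-floored Quick
(base-2 Weibull) psychometric function,

    p(x) = gamma + (1 - gamma - eps) * (1 - 2**(-(x / theta)**beta)),

with guessing floor ``gamma = 0.5``, lapse rate ``eps`` and shape ``beta``.
At ``x = theta`` with ``eps = 0`` the function passes through 0.75 exactly,
so ``theta`` is the 75%-correct threshold.

Learning is expressed as an exponentially saturating decay of the
log-threshold over trials:

    log theta(t) = A + (S - A) * 2**(-(t - 1) / 10**R),

where ``S`` is the log starting threshold (trial 1), ``A`` the log
asymptotic threshold, and ``10**R`` the number of trials after which half of
the log-threshold change has occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PsychometricParams",
    "LearningTrajectory",
    "pf_probability",
    "threshold_at",
    "solve_threshold75",
    "learning_magnitude",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the chance-floored Quick psychometric function.

    Parameters
    ----------
    threshold_s : float
        SOA threshold in seconds (midpoint parameter; the 75%-correct SOA
        when the lapse rate is zero). Must be positive.
    shape : float
        Weibull/Quick shape (slope) parameter beta. Must be positive.
    lapse : float
        Lapse rate eps in [0, 0.5): probability of a stimulus-independent
        error, capping accuracy at ``1 - lapse``.
    chance : float
        Guessing floor; fixed at 0.5 for this two-alternative task.
    """

    threshold_s: float
    shape: float
    lapse: float = 0.0
    chance: float = 0.5

    def __post_init__(self) -> None:
        if not (np.isfinite(self.threshold_s) and self.threshold_s > 0):
            raise ValueError(f"threshold_s must be finite and > 0, got {self.threshold_s}")
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"shape must be finite and > 0, got {self.shape}")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")
        if self.chance != 0.5:
            raise ValueError("chance floor is fixed at 0.5 for the two-alternative task")


@dataclass(frozen=True)
class LearningTrajectory:
    """Components of change of the log-threshold over trials.

    ``log_start`` (S) and ``log_asym`` (A) are natural-log thresholds in
    log-seconds; ``log10_rate`` (R) is the base-10 log of the half-change
    time constant in trials.  The trajectory starts exactly at ``exp(S)``
    on trial 1 and saturates monotonically at ``exp(A)``.
    """

    log_start: float
    log_asym: float
    log10_rate: float

    def __post_init__(self) -> None:
        for name in ("log_start", "log_asym", "log10_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def pf_probability(soa_s, params: PsychometricParams):
    """Probability of a correct response at a given SOA.

    Parameters
    ----------
    soa_s : float or array_like
        Stimulus onset asynchrony in seconds; must be finite and >= 0.
    params : PsychometricParams

    Returns
    -------
    float or ndarray
        ``gamma + (1 - gamma - eps) * (1 - 2**(-(soa/theta)**beta))``,
        bounded in ``[gamma, 1 - eps]`` and strictly increasing in SOA.
    """
    soa = np.asarray(soa_s, dtype=float)
    if not np.all(np.isfinite(soa)):
        raise ValueError("soa_s must be finite")
    if np.any(soa < 0):
        raise ValueError("soa_s must be >= 0")
    g, e = params.chance, params.lapse
    with np.errstate(divide="ignore"):
        w = np.exp(params.shape * (np.log(soa, where=soa > 0, out=np.full_like(soa, -np.inf)) - math.log(params.threshold_s)))
    p = g + (1.0 - g - e) * (1.0 - np.exp(-_LN2 * w))
    return float(p) if np.isscalar(soa_s) else p


def threshold_at(t, traj: LearningTrajectory):
    """Threshold (seconds) on trial ``t`` of the saturating learning curve.

    ``t`` is 1-based and may be real; ``t = 1`` returns ``exp(log_start)``
    exactly, and ``t = 1 + 10**log10_rate`` returns the log-midpoint
    ``exp((S + A) / 2)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)) or np.any(t_arr < 1):
        raise ValueError("trial index t must be finite and >= 1")
    S, A, R = traj.log_start, traj.log_asym, traj.log10_rate
    decay = np.exp2(-(t_arr - 1.0) / (10.0 ** R))
    out = np.exp(A + (S - A) * decay)
    return float(out) if np.isscalar(t) else out


def solve_threshold75(params: PsychometricParams) -> float:
    """SOA (seconds) at which accuracy equals 75%.

    With a nonzero lapse rate the 75% point sits slightly above the midpoint
    parameter; the closed form is
    ``theta * (-log2(1 - 0.25 / (0.5 - eps)))**(1/beta)``.  Requires
    ``lapse < 0.25`` so that 75% accuracy is attainable.
    """
    e = params.lapse
    if e >= 0.25:
        raise ValueError(f"75% accuracy is unattainable with lapse {e} >= 0.25")
    inner = 1.0 - 0.25 / (0.5 - e)
    x = params.threshold_s * (-math.log2(inner)) ** (1.0 / params.shape)
    return x


def learning_magnitude(
    traj: LearningTrajectory,
    shape: float,
    lapse: float,
    mean_soa_s: float,
    t_start: float = 1.0,
    t_end: float = 200.0,
) -> float:
    """Magnitude of learning: accuracy gain at the mean SOA.

    Difference between predicted accuracy at trial ``t_end`` and trial
    ``t_start``, both evaluated at ``mean_soa_s`` with the participant's
    shape and lapse.  Positive iff the threshold improved (decreased) at
    that SOA.
    """
    if not (t_end > t_start >= 1):
        raise ValueError("require t_end > t_start >= 1")
    if not mean_soa_s > 0:
        raise ValueError("mean_soa_s must be > 0")
    p_end = pf_probability(
        mean_soa_s,
        PsychometricParams(threshold_at(t_end, traj), shape, lapse),
    )
    p_start = pf_probability(
        mean_soa_s,
        PsychometricParams(threshold_at(t_start, traj), shape, lapse),
    )
    return p_end - p_start
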