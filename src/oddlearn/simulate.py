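"""Synthetic texture-oddball experiments with known ground truth.

Emulates the design of the behavioural study the models are built for:
2 age groups (child, adult) x 3 mood conditions (control, positive, stress),
two blocks of 210 trials per participant, SOAs drawn from seven fixed levels
between 15 and 500 ms, an oddball target on half of the trials, and Bernoulli
correctness generated from the chance-floored Quick psychometric function
whose threshold decays exponentially with trial number.  A configurable
minority of participants respond at chance on every trial, to exercise the
at-chance exclusion filter downstream.

Both trial types (oddball present / absent) share the same accuracy model;
the simulator draws the trial type only to reproduce the record schema.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "CONDITIONS",
    "DesignSpec",
    "GroundTruth",
    "simulate_experiment",
    "smooth_accuracy",
    "save_simulation",
]

AGE_GROUPS = ("child", "adult")
CONDITIONS = ("control", "positive", "stress")

#: ordinal valence levels: stress < control < positive
VALENCE_LEVEL = {"stress": 0, "control": 1, "positive": 2}

TRIAL_COLUMNS = [
    "participant_id",
    "age_group",
    "condition",
    "block",
    "trial",
    "soa_ms",
    "oddball_present",
    "correct",
]


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the simulated experiment (defaults follow the study design)."""

    n_per_cell: int = 24
    n_blocks: int = 2
    trials_per_block: int = 210
    soa_levels_ms: tuple = (15, 30, 60, 90, 120, 300, 500)
    oddball_fraction: float = 0.5
    balanced_soa: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1 or self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("n_per_cell, n_blocks and trials_per_block must be >= 1")
        levels = tuple(self.soa_levels_ms)
        if not levels or any(s <= 0 for s in levels) or list(levels) != sorted(levels):
            raise ValueError("soa_levels_ms must be positive and sorted ascending")
        if not (0.0 < self.oddball_fraction < 1.0):
            raise ValueError("oddball_fraction must lie in (0, 1)")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class GroundTruth:
    """True population parameters of the simulated learners.

    Fixed effects act on the link scales: log-seconds for the asymptotic
    (``asym_*``) and starting (``start_*``) thresholds, log10-trials for the
    half-change rate (``rate_*``), log units for the PF shape.  Age is coded
    -0.5 (child) / +0.5 (adult), arousal -0.5 (control) / +0.5 (positive,
    stress), and valence acts monotonically through cumulative simplex
    weights (0 for stress, ``zeta1`` for control, 1 for positive).

    Defaults are round values on the scales seen in comparable texture-
    learning datasets (asymptote near 90 ms for adults, start thresholds
    around half a second, half-change time of a few dozen trials); condition
    effects are zero, matching the study's null result.  The magnitudes are
    calibrated so that nearly all simulated learners pass the at-chance
    screen, leaving exclusions to the at-chance subpopulation, which is the
    pattern the screening rule is meant to capture.
    """

    asym_intercept: float = -2.4
    asym_age: float = -0.6
    asym_arousal: float = 0.0
    asym_valence: float = 0.0
    start_intercept: float = -0.5
    start_age: float = 0.5
    start_arousal: float = 0.0
    start_valence: float = 0.0
    rate_intercept: float = 1.8
    rate_age: float = 0.3
    rate_arousal: float = 0.0
    rate_valence: float = 0.0
    sd_asym: float = 0.5
    sd_start: float = 0.5
    sd_rate: float = 0.5
    sd_shape: float = 0.2
    shape_intercept: float = 1.1
    lapse: float = 0.01
    zeta1: float = 0.5
    fraction_at_chance: float = 0.1
    block2_asym_offset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sd_asym, self.sd_start, self.sd_rate, self.sd_shape) < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not (0.0 <= self.zeta1 <= 1.0):
            raise ValueError("zeta1 must lie in [0, 1]")
        if not (0.0 <= self.fraction_at_chance < 1.0):
            raise ValueError("fraction_at_chance must lie in [0, 1)")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")


def _linear_predictor(truth: GroundTruth, component: str, age_c: float, ar_c: float, cumv: float) -> float:
    b0 = getattr(truth, f"{component}_intercept")
    b_age = getattr(truth, f"{component}_age")
    b_ar = getattr(truth, f"{component}_arousal")
    b_v = getattr(truth, f"{component}_valence")
    return b0 + b_age * age_c + b_ar * ar_c + b_v * cumv


def simulate_experiment(design: DesignSpec, truth: GroundTruth | None = None):
    """Simulate one full experiment.

    Returns
    -------
    records : pandas.DataFrame
        One row per trial with columns ``participant_id, age_group,
        condition, block, trial, soa_ms, oddball_present, correct``; trial
        indices run 1..n_trials continuously across blocks.
    participants : pandas.DataFrame
        Per-participant ground truth: realised log thresholds (``log_start``,
        ``log_asym``), ``log10_rate``, PF ``shape``, ``lapse`` and the
        ``at_chance`` flag.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(design.seed)
    n_t = design.n_trials
    soa_levels = np.asarray(design.soa_levels_ms, dtype=float)

    part_rows = []
    rec_frames = []
    ln2 = np.log(2.0)
    for age in AGE_GROUPS:
        age_c = -0.5 if age == "child" else 0.5
        for cond in CONDITIONS:
            ar_c = -0.5 if cond == "control" else 0.5
            cumv = (0.0, truth.zeta1, 1.0)[VALENCE_LEVEL[cond]]
            for i in range(design.n_per_cell):
                pid = f"{age}_{cond}_{i + 1:03d}"
                at_chance = bool(rng.random() < truth.fraction_at_chance)
                A = _linear_predictor(truth, "asym", age_c, ar_c, cumv) + truth.sd_asym * rng.standard_normal()
                S = _linear_predictor(truth, "start", age_c, ar_c, cumv) + truth.sd_start * rng.standard_normal()
                R = _linear_predictor(truth, "rate", age_c, ar_c, cumv) + truth.sd_rate * rng.standard_normal()
                shape = np.exp(truth.shape_intercept + truth.sd_shape * rng.standard_normal())

                t = np.arange(1, n_t + 1, dtype=float)
                block = np.where(t <= design.trials_per_block, 1, 2)
                if design.balanced_soa:
                    soa = np.concatenate([
                        rng.permutation(np.resize(soa_levels, design.trials_per_block))
                        for _ in range(design.n_blocks)
                    ])
                else:
                    soa = rng.choice(soa_levels, size=n_t)
                oddball = rng.random(n_t) < design.oddball_fraction

                if at_chance:
                    p = np.full(n_t, 0.5)
                else:
                    A_t = A + np.where(block == 2, truth.block2_asym_offset, 0.0)
                    decay = np.exp2(-(t - 1.0) / (10.0 ** R))
                    log_theta = A_t + (S - A_t) * decay
                    w = np.exp(shape * (np.log(soa / 1000.0) - log_theta))
                    p = (1.0 - truth.lapse) - (0.5 - truth.lapse) * np.exp(-ln2 * w)
                correct = rng.random(n_t) < p

                rec_frames.append(pd.DataFrame({
                    "participant_id": pid,
                    "age_group": age,
                    "condition": cond,
                    "block": block,
                    "trial": t.astype(int),
                    "soa_ms": soa,
                    "oddball_present": oddball,
                    "correct": correct,
                }))
                part_rows.append({
                    "participant_id": pid,
                    "age_group": age,
                    "condition": cond,
                    "at_chance": at_chance,
                    "log_asym": A,
                    "log_start": S,
                    "log10_rate": R,
                    "shape": shape,
                    "lapse": truth.lapse,
                })

    records = pd.concat(rec_frames, ignore_index=True)[TRIAL_COLUMNS]
    participants = pd.DataFrame(part_rows)
    return records, participants


def smooth_accuracy(records: pd.DataFrame, window: int = 21, by=("age_group", "condition")) -> pd.DataFrame:
    """Centred moving proportion correct per trial index within each group.

    A block-free descriptive smoother for raw learning curves: for every
    trial index the proportion correct is pooled over participants in the
    group and smoothed with a centred window of ``window`` trial indices
    (truncated at the edges).  ``window = 1`` returns the raw per-trial
    proportions.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if records.empty:
        warnings.warn("smooth_accuracy received no records; returning empty frame")
        return pd.DataFrame(columns=[*by, "trial", "accuracy"])
    out = []
    for keys, grp in records.groupby(list(by)):
        agg = grp.groupby("trial")["correct"].agg(n_correct="sum", n="count").sort_index()
        roll_c = agg["n_correct"].rolling(window, center=True, min_periods=1).sum()
        roll_n = agg["n"].rolling(window, center=True, min_periods=1).sum()
        frame = pd.DataFrame({"trial": agg.index, "accuracy": (roll_c / roll_n).to_numpy()})
        if not isinstance(keys, tuple):
            keys = (keys,)
        for name, val in zip(by, keys):
            frame[name] = val
        out.append(frame[[*by, "trial", "accuracy"]])
    return pd.concat(out, ignore_index=True)


def save_simulation(records: pd.DataFrame, participants: pd.DataFrame, outdir, design: DesignSpec, truth: GroundTruth) -> dict:
    """Write trials.csv, ground_truth.csv and a run-manifest JSON; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials_path = outdir / "trials.csv"
    truth_path = outdir / "ground_truth.csv"
    records.to_csv(trials_path, index=False)
    participants.to_csv(truth_path, index=False)
    manifest = {
        "seed": design.seed,
        "design": asdict(design),
        "ground_truth": asdict(truth),
        "n_participants": int(participants.shape[0]),
        "n_trials": int(records.shape[0]),
        "trials_csv": str(trials_path),
        "ground_truth_csv": str(truth_path),
    }
    with open(outdir / "simulation_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
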