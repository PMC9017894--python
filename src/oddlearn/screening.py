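"""Participant screening and analysis-window truncation.

Participants who cannot do the task respond at the 50% guessing floor; they
are identified with a one-tailed exact binomial test of overall accuracy
against 0.5 (upper tail, over ALL trials) and excluded when p >= .05.
Screening always precedes truncation: the learning models are then fitted
to only the first 200 trials of the included participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningResult",
    "binomial_upper_p",
    "exclude_at_chance",
    "apply_screening",
    "truncate_trials",
    "screening_summary",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_TRIAL = 200


@dataclass(frozen=True)
class ScreeningResult:
    participant_id: str
    n_trials: int
    n_correct: int
    one_tailed_p: float
    included: bool


def binomial_upper_p(k: int, n: int) -> float:
    """Exact one-tailed binomial p-value P(X >= k) for X ~ Binomial(n, 1/2)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    # survival function is P(X > k-1) = P(X >= k); exact, no normal approximation
    return float(stats.binom.sf(k - 1, n, 0.5))


def exclude_at_chance(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Screen every participant for above-chance performance over all trials.

    Returns a DataFrame with one row per participant: ``n_trials``,
    ``n_correct``, the exact upper-tail binomial p-value against 0.5, and
    ``included = (p < alpha)`` (strict inequality).  Participants with zero
    usable trials are excluded with a warning and NaN p.
    """
    rows = []
    counts = records.dropna(subset=["correct"]).groupby("participant_id")["correct"].agg(["sum", "count"])
    for pid in records["participant_id"].unique():
        if pid not in counts.index or counts.loc[pid, "count"] == 0:
            warnings.warn(f"participant {pid} has no trials with recorded correctness; excluded")
            rows.append(ScreeningResult(pid, 0, 0, float("nan"), False))
            continue
        n = int(counts.loc[pid, "count"])
        k = int(counts.loc[pid, "sum"])
        p = binomial_upper_p(k, n)
        rows.append(ScreeningResult(pid, n, k, p, bool(p < alpha)))
    return pd.DataFrame([r.__dict__ for r in rows])


def truncate_trials(records: pd.DataFrame, max_trial: int | None = DEFAULT_MAX_TRIAL) -> pd.DataFrame:
    """Retain only trials with index <= ``max_trial`` (per-participant indices unchanged).

    ``max_trial=None`` keeps all trials (the sensitivity-analysis mode).
    """
    if max_trial is None:
        return records.copy()
    if max_trial < 1:
        raise ValueError("max_trial must be >= 1")
    return records[records["trial"] <= max_trial].copy()


def apply_screening(records: pd.DataFrame, screening: pd.DataFrame) -> pd.DataFrame:
    """Drop trials of participants whose screening row has ``included = False``."""
    keep = set(screening.loc[screening["included"], "participant_id"])
    return records[records["participant_id"].isin(keep)].copy()


def screening_summary(screening: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Included-participant counts per age group x condition (sample-size table)."""
    meta = records[["participant_id", "age_group", "condition"]].drop_duplicates()
    merged = screening.merge(meta, on="participant_id", how="left")
    table = (
        merged[merged["included"]]
        .pivot_table(index="age_group", columns="condition", values="participant_id", aggfunc="count", fill_value=0)
    )
    return table.reindex(index=["adult", "child"],
                         columns=["control", "positive", "stress"], fill_value=0)
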