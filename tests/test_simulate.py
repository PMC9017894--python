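"""Synthetic-experiment generator: determinism, design shape, accuracy behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from oddlearn import (
    DesignSpec,
    GroundTruth,
    simulate_experiment,
    smooth_accuracy,
    pf_probability,
    PsychometricParams,
)


def test_record_counts_and_schema(tiny_experiment):
    records, participants = tiny_experiment
    n_part = 2 * 3 * 2  # cells x n_per_cell
    assert len(participants) == n_part
    assert len(records) == n_part * 60
    per = records.groupby("participant_id")["trial"].agg(["min", "max", "count", "nunique"])
    assert (per["min"] == 1).all()
    assert (per["max"] == 60).all()
    assert (per["count"] == per["nunique"]).all()  # no gaps or duplicates
    assert set(records["soa_ms"].unique()) <= {15, 30, 60, 90, 120, 300, 500}
    assert set(records["age_group"]) == {"child", "adult"}
    assert set(records["condition"]) == {"control", "positive", "stress"}


def test_same_seed_reproduces_byte_identical_output():
    design = DesignSpec(n_per_cell=2, n_blocks=1, trials_per_block=50, seed=99)
    r1, p1 = simulate_experiment(design, GroundTruth())
    r2, p2 = simulate_experiment(design, GroundTruth())
    pd.testing.assert_frame_equal(r1, r2)
    pd.testing.assert_frame_equal(p1, p2)
    r3, _ = simulate_experiment(DesignSpec(n_per_cell=2, n_blocks=1, trials_per_block=50, seed=100),
                                GroundTruth())
    assert not r3["correct"].equals(r1["correct"])


def test_floor_behavior_threshold_far_above_soas():
    # threshold held at 10 s, far beyond the 500 ms maximum SOA: accuracy ~ 0.5
    truth = GroundTruth(
        asym_intercept=math.log(10.0), start_intercept=math.log(10.0),
        asym_age=0, start_age=0, rate_age=0,
        sd_asym=0.0, sd_start=0.0, sd_rate=0.0, sd_shape=0.0,
        lapse=0.0, fraction_at_chance=0.0,
    )
    records, _ = simulate_experiment(DesignSpec(n_per_cell=5, seed=1), truth)
    acc = records["correct"].mean()
    se = math.sqrt(0.25 / len(records))
    assert abs(acc - 0.5) < 4 * se


def test_ceiling_behavior_threshold_below_min_soa():
    truth = GroundTruth(
        asym_intercept=math.log(0.001), start_intercept=math.log(0.001),
        asym_age=0, start_age=0, rate_age=0,
        sd_asym=0.0, sd_start=0.0, sd_rate=0.0, sd_shape=0.0,
        lapse=0.02, fraction_at_chance=0.0,
    )
    records, _ = simulate_experiment(DesignSpec(n_per_cell=5, seed=2), truth)
    acc = records["correct"].mean()
    se = math.sqrt(acc * (1 - acc) / len(records))
    assert acc > 1 - 0.02 - 3 * se


def test_empirical_accuracy_matches_pf_at_fixed_trial():
    """With a flat trajectory, accuracy at each SOA converges to the PF."""
    truth = GroundTruth(
        asym_intercept=-2.3, start_intercept=-2.3,
        asym_age=0, start_age=0, rate_age=0,
        sd_asym=0.0, sd_start=0.0, sd_rate=0.0, sd_shape=0.0,
        shape_intercept=math.log(3.0), lapse=0.01, fraction_at_chance=0.0,
    )
    records, _ = simulate_experiment(
        DesignSpec(n_per_cell=15, n_blocks=1, trials_per_block=210, seed=5), truth
    )
    params = PsychometricParams(math.exp(-2.3), 3.0, 0.01)
    for soa_ms, grp in records.groupby("soa_ms"):
        expected = pf_probability(soa_ms / 1000.0, params)
        n = len(grp)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(grp["correct"].mean() - expected) < 4 * se, f"SOA {soa_ms}"


def test_injected_asymptote_effect_shows_in_late_accuracy():
    """A strong arousal benefit on the asymptote raises late-trial accuracy."""
    truth = GroundTruth(asym_arousal=-1.5, rate_intercept=1.0,
                        sd_asym=0.2, fraction_at_chance=0.0)
    records, _ = simulate_experiment(DesignSpec(n_per_cell=20, seed=8), truth)
    late = records[records["trial"] > 300]
    acc = late.groupby(late["condition"] == "control")["correct"].mean()
    assert acc[False] > acc[True]  # stress/positive (+0.5 coded) outperform control


def test_at_chance_participants_are_pure_guessers():
    truth = GroundTruth(fraction_at_chance=0.5)
    records, participants = simulate_experiment(DesignSpec(n_per_cell=10, seed=3), truth)
    chance_ids = participants.loc[participants["at_chance"], "participant_id"]
    assert len(chance_ids) > 0
    sub = records[records["participant_id"].isin(chance_ids)]
    acc = sub["correct"].mean()
    assert abs(acc - 0.5) < 4 * math.sqrt(0.25 / len(sub))


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        DesignSpec(n_per_cell=0)
    with pytest.raises(ValueError):
        DesignSpec(soa_levels_ms=(30, 15))
    with pytest.raises(ValueError):
        DesignSpec(oddball_fraction=1.0)


# --------------------------------------------------------------------- #

def _toy_records(correct_seq):
    return pd.DataFrame({
        "participant_id": "p1",
        "age_group": "adult",
        "condition": "control",
        "trial": np.arange(1, len(correct_seq) + 1),
        "correct": correct_seq,
    })


def test_smooth_accuracy_constant_input():
    rec = _toy_records([True] * 10)
    out = smooth_accuracy(rec, window=3)
    assert np.allclose(out["accuracy"], 1.0)


def test_smooth_accuracy_window_one_is_identity():
    seq = [True, False, True, True, False]
    out = smooth_accuracy(_toy_records(seq), window=1)
    assert out["accuracy"].tolist() == [1.0, 0.0, 1.0, 1.0, 0.0]


def test_smooth_accuracy_alternating_matches_enumeration():
    # alternating 1,0,1,0,... with window 2 (centred, truncated edges):
    # pandas centres a length-2 window on [t-1, t], so position 0 keeps its raw
    # value and every interior position averages the previous and current trial
    seq = [bool(i % 2 == 0) for i in range(6)]  # 1,0,1,0,1,0
    out = smooth_accuracy(_toy_records(seq), window=2)
    expected = [1.0] + [0.5] * 5
    assert out["accuracy"].tolist() == pytest.approx(expected)


def test_smooth_accuracy_empty_warns():
    with pytest.warns(UserWarning):
        out = smooth_accuracy(pd.DataFrame(columns=["age_group", "condition", "trial", "correct"]))
    assert out.empty
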