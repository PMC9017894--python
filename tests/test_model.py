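"""Hierarchical model: likelihood oracle, gradients, structure, recovery contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from oddlearn import DesignSpec, GroundTruth, simulate_experiment
from oddlearn.model import LearningModel, ModelSpec, PriorConfig

LN2 = math.log(2.0)


def enumerate_loglik(records, A, S, R, shape, lapse):
    """Independent per-trial oracle: plain Python Bernoulli sum through the PF."""
    total = 0.0
    pid_map = {pid: i for i, pid in enumerate(sorted(records["participant_id"].unique()))}
    for _, row in records.iterrows():
        i = pid_map[row["participant_id"]]
        t = row["trial"]
        decay = 2.0 ** (-(t - 1.0) / 10.0 ** R[i])
        theta = math.exp(A[i] + (S[i] - A[i]) * decay)
        soa = row["soa_ms"] / 1000.0
        p = (1 - lapse) - (0.5 - lapse) * 2.0 ** (-((soa / theta) ** shape[i]))
        total += math.log(p) if row["correct"] else math.log(1 - p)
    return total


def _randomized_instance(rng, n_part, n_trials):
    records = pd.DataFrame({
        "participant_id": np.repeat([f"p{i}" for i in range(n_part)], n_trials),
        "age_group": "adult",
        "condition": rng.choice(["control", "positive", "stress"], n_part * n_trials)
        if n_part > 1 else "control",
        "trial": np.tile(np.arange(1, n_trials + 1), n_part),
        "soa_ms": rng.choice([15, 30, 60, 90, 120, 300, 500], n_part * n_trials),
        "correct": rng.random(n_part * n_trials) < 0.7,
    })
    return records


@pytest.mark.parametrize("instance_seed", range(5))
def test_loglikelihood_matches_per_trial_enumeration(instance_seed):
    rng = np.random.default_rng(instance_seed)
    n_part, n_trials = int(rng.integers(2, 4)), int(rng.integers(20, 51))
    records = _randomized_instance(rng, n_part, n_trials)
    model = LearningModel(records, ModelSpec.per_age("adult", "none", lapse=0.01))
    x = rng.standard_normal(model.n_params) * 0.5
    A, S, R, LB, eps = model.participant_params(x)
    oracle = enumerate_loglik(records, A, S, R, np.exp(LB), eps)
    assert model.loglikelihood(x) == pytest.approx(oracle, abs=1e-8)


def test_loglikelihood_invariant_to_trial_order(rng):
    records = _randomized_instance(rng, 3, 40)
    model = LearningModel(records, ModelSpec.per_age("adult", "none"))
    x = rng.standard_normal(model.n_params) * 0.3
    shuffled = records.sample(frac=1.0, random_state=1)
    model2 = LearningModel(shuffled, ModelSpec.per_age("adult", "none"))
    assert model.loglikelihood(x) == pytest.approx(model2.loglikelihood(x), abs=1e-10)


def test_all_correct_saturated_pf_limit():
    """theta -> 0 makes every trial's accuracy 1 - eps."""
    n = 60
    records = pd.DataFrame({
        "participant_id": np.repeat(["a", "b"], n // 2),
        "age_group": "adult", "condition": "control",
        "trial": np.tile(np.arange(1, n // 2 + 1), 2),
        "soa_ms": 120, "correct": True,
    })
    spec = ModelSpec.per_age("adult", "none", lapse=0.01)
    model = LearningModel(records, spec)
    x = np.zeros(model.n_params)
    # push both participants' thresholds far below the smallest SOA
    x[model._sl_b][0] = -12.0  # asym intercept
    x[model._sl_b][model._k] = -12.0  # start intercept
    assert model.loglikelihood(x) == pytest.approx(n * math.log(1 - 0.01), abs=1e-6)


@pytest.mark.parametrize("spec", [
    ModelSpec.full(),
    ModelSpec.full(include_interactions=False),
    ModelSpec.full(lapse_mode="estimated"),
    ModelSpec.full(parameterization="noncentered"),
    ModelSpec.per_age("child", "arousal"),
    ModelSpec.per_age("adult", "valence"),
    ModelSpec.per_age("adult", "valence").null_partner(),
], ids=lambda s: f"{s.label}-{s.lapse_mode}-{s.parameterization}")
def test_gradient_matches_finite_differences(tiny_experiment, spec):
    records, _ = tiny_experiment
    model = LearningModel(records, spec)
    rng = np.random.default_rng(0)
    x = model.initial_point(rng) + 0.2 * rng.standard_normal(model.n_params)
    lp, grad = model.logpost_and_grad(x)
    assert np.isfinite(lp) and np.all(np.isfinite(grad))
    for i in rng.choice(model.n_params, size=min(20, model.n_params), replace=False):
        xp, xm = x.copy(), x.copy()
        xp[i] += 1e-6
        xm[i] -= 1e-6
        fd = (model.logpost_and_grad(xp)[0] - model.logpost_and_grad(xm)[0]) / 2e-6
        assert grad[i] == pytest.approx(fd, rel=2e-4, abs=1e-5)


def test_parameterizations_agree_on_posterior_density():
    """Centred and non-centred forms describe the same posterior: the density of
    corresponding points differs only by the (constant-free) transform."""
    rng = np.random.default_rng(1)
    records = _randomized_instance(rng, 3, 30)
    m_c = LearningModel(records, ModelSpec.per_age("adult", "none", parameterization="centered"))
    m_nc = LearningModel(records, ModelSpec.per_age("adult", "none", parameterization="noncentered"))
    x = rng.standard_normal(m_c.n_params) * 0.3
    # map the non-centred vector to its centred counterpart: u = sd * z
    x_c = x.copy()
    sd = np.exp(x[m_nc._sl_logsd])
    z = x[m_nc._sl_z].reshape(4, -1)
    x_c[m_c._sl_z] = (sd[:, None] * z).ravel()
    a = m_nc.participant_params(x)
    b = m_c.participant_params(x_c)
    for u, v in zip(a, b):
        assert np.allclose(u, v, atol=1e-12)
    # density ratio equals the log Jacobian of u = sd*z, which is P * sum(log sd)
    lp_nc = m_nc.logpost_and_grad(x)[0]
    lp_c = m_c.logpost_and_grad(x_c)[0]
    P = m_c.n_participants
    assert lp_nc == pytest.approx(lp_c + P * np.sum(np.log(sd)), abs=1e-8)


def test_structural_errors():
    one = pd.DataFrame({
        "participant_id": "solo", "age_group": "adult", "condition": "control",
        "trial": np.arange(1, 30), "soa_ms": 60, "correct": True,
    })
    with pytest.raises(ValueError, match="2 participants"):
        LearningModel(one, ModelSpec.per_age("adult", "none"))
    bad_soa = pd.concat([one.assign(participant_id="a"), one.assign(participant_id="b")])
    bad_soa.loc[bad_soa.index[3], "soa_ms"] = -5
    with pytest.raises(ValueError, match="soa_ms"):
        LearningModel(bad_soa, ModelSpec.per_age("adult", "none"))
    missing = pd.concat([one.assign(participant_id="a"), one.assign(participant_id="b")])
    missing["correct"] = missing["correct"].astype(object)
    missing.loc[missing.index[0], "correct"] = None
    with pytest.raises(ValueError, match="correct"):
        LearningModel(missing, ModelSpec.per_age("adult", "none"))


def test_valence_models_use_only_stress_and_positive(tiny_experiment):
    records, _ = tiny_experiment
    model = LearningModel(records, ModelSpec.per_age("adult", "valence"))
    assert set(model.data["condition"]) == {"stress", "positive"}
    null = LearningModel(records, ModelSpec.per_age("adult", "valence").null_partner())
    assert set(null.data["condition"]) == {"stress", "positive"}


def test_prior_predictive_accuracies_within_pf_bounds(rng):
    """Participant parameters drawn from the priors give accuracies in [0.5, 1 - eps]."""
    records = _randomized_instance(rng, 3, 30)
    model = LearningModel(records, ModelSpec.per_age("adult", "none"))
    pr = model.spec.priors
    for _ in range(200):
        A = rng.normal(*pr.asym_intercept)
        S = rng.normal(*pr.start_intercept)
        beta = math.exp(rng.normal(*pr.shape_intercept))
        theta = math.exp(A + (S - A) * 0.5)
        for soa in (0.015, 0.12, 0.5):
            p = (1 - 0.01) - (0.5 - 0.01) * 2 ** (-((soa / theta) ** beta))
            assert 0.5 - 1e-12 <= p <= 1 - 0.01 + 1e-12


# ------------------------------------------------------------------ #
# fitted-results contracts (shared small fit)

def test_full_model_summary_has_19_labelled_rows(small_full_fit):
    table = small_full_fit.summary()
    assert len(table) == 19
    assert list(table.index[:6]) == [
        "Asym: Intercept", "Asym: age", "Asym: arousal",
        "Asym: age × arousal", "Asym: valence", "Asym: age × valence",
    ]
    assert table.index[-1] == "PF shape: Intercept"
    assert list(table.columns) == ["Estimate", "lower 95% CI", "upper 95% CI", "reliable"]
    assert (table["lower 95% CI"] <= table["Estimate"]).all()
    assert (table["Estimate"] <= table["upper 95% CI"]).all()


def test_per_age_summary_has_7_rows(small_modelled_records):
    model = LearningModel(small_modelled_records, ModelSpec.per_age("adult", "valence"))
    fit = model.fit(draws=50, warmup=80, chains=1, seed=0)
    table = fit.summary()
    assert len(table) == 7
    assert list(table.index) == [
        "Asym: Intercept", "Asym: valence", "Start: Intercept", "Start: valence",
        "Rate: Intercept", "Rate: valence", "PF shape: Intercept",
    ]


def test_reliability_flag_semantics():
    from oddlearn.model import LearningModelResults
    # synthetic draws: one coefficient pinned at 0.5, another symmetric about 0
    d = pd.DataFrame({"pinned": np.full(100, 0.5), "sym": np.linspace(-1, 1, 100)})
    lo, hi = d.quantile(0.025), d.quantile(0.975)
    reliable = (lo > 0) | (hi < 0)
    assert bool(reliable["pinned"]) and not bool(reliable["sym"])


def test_fit_is_deterministic_given_seed(small_modelled_records):
    model = LearningModel(small_modelled_records, ModelSpec.per_age("adult", "none"))
    f1 = model.fit(draws=30, warmup=50, chains=2, seed=11)
    f2 = model.fit(draws=30, warmup=50, chains=2, seed=11)
    assert np.array_equal(f1.draws, f2.draws)
    f3 = model.fit(draws=30, warmup=50, chains=2, seed=12)
    assert not np.array_equal(f3.draws, f1.draws)


def test_monotonic_valence_contract(small_full_fit):
    """Fitted valence contributions are ordered stress<=control<=positive or the
    reverse in every posterior draw (cumulative-simplex parameterisation)."""
    model = small_full_fit.model
    flat = small_full_fit.draws.reshape(-1, small_full_fit.draws.shape[-1])
    k = model._k
    b_v = flat[:, model._sl_b][:, model.coef_names.index("valence")]  # asym component
    zeta1 = 1.0 / (1.0 + np.exp(-flat[:, model._i_zeta]))
    contrib = np.stack([np.zeros_like(b_v), b_v * zeta1, b_v], axis=1)  # stress, control, positive
    diffs = np.diff(contrib, axis=1)
    monotone = np.all(diffs >= -1e-12, axis=1) | np.all(diffs <= 1e-12, axis=1)
    assert monotone.all()


def test_learning_magnitude_posterior(small_full_fit):
    out = small_full_fit.learning_magnitude()
    per = out["per_participant"]
    assert len(per) == small_full_fit.model.n_participants
    assert (per["lower 95% CI"] <= per["mean"]).all()
    contrasts = out["contrasts"]
    assert len(contrasts) == 3  # three condition pairs
    # self-contrast is identically zero
    same = small_full_fit.learning_magnitude(t_start=1, t_end=1)
    assert np.allclose(same["per_participant"]["mean"], 0.0, atol=1e-12)


def test_degenerate_flat_trajectory_gives_zero_magnitude(small_modelled_records):
    model = LearningModel(small_modelled_records, ModelSpec.per_age("adult", "none"))
    x = model.initial_point(np.random.default_rng(0))
    # force S = A for every participant by equating the start and asymptote
    # fixed effects, random-effect draws, and random-effect scales
    k = model._k
    x[model._sl_b][k:2 * k] = x[model._sl_b][:k]          # start fe = asym fe
    x[model._sl_logsd][1] = x[model._sl_logsd][0]
    z = x[model._sl_z].reshape(4, -1)
    z[1] = z[0]                                           # start u = asym u
    x[model._sl_z] = z.ravel()
    A, S, R, LB, eps = model.participant_params(x)
    assert np.allclose(A, S)


def test_plot_learning_curves_renders(small_full_fit):
    import matplotlib
    matplotlib.use("Agg")
    ax = small_full_fit.plot_learning_curves()
    assert len(ax.lines) == 3  # one posterior-mean curve per condition
    assert ax.get_ylim()[1] <= 1.0
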