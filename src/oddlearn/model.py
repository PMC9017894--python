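"""Hierarchical Bayesian model of trial-by-trial perceptual learning.

The observation model is Bernoulli correctness through a chance-floored
Quick psychometric function whose log-threshold decays exponentially with
trial number.  Each participant p has learning components

    A_p (log asymptotic threshold), S_p (log starting threshold),
    R_p (log10 half-change time in trials), log beta_p (PF shape),

each decomposed into group fixed effects and a by-participant Gaussian
random effect (non-centred).  Conditions are coded as in the study design:
age -0.5 (child) / +0.5 (adult); arousal -0.5 (control) / +0.5 (positive or
stress); valence as a monotonic ordinal effect (stress < control < positive)
through cumulative Dirichlet-simplex weights in the full model, or as a
binary +/-0.5 contrast (stress vs positive) in the per-age valence models.

Usage follows the Model/Results pattern::

    model = LearningModel(records, ModelSpec.full())
    res = model.fit(draws=500, warmup=500, chains=2, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._likelihood import loglik_grad
from .sampling import sample_nuts
from .simulate import VALENCE_LEVEL

__all__ = ["PriorConfig", "ModelSpec", "LearningModel", "LearningModelResults"]

_COMPONENTS = ("asym", "start", "rate")
_COMPONENT_LABEL = {"asym": "Asym", "start": "Start", "rate": "Rate"}


@dataclass(frozen=True)
class PriorConfig:
    """Normal (location, scale) priors on the link scales; all proper.

    Intercept priors are scaled to the task: thresholds of order 100 ms
    (log-seconds near -2.5), starting thresholds up to a few seconds,
    half-change times of order tens of trials (log10 near 1.7), and a PF
    shape near 3.  The rate prior doubles as a soft bound keeping 10**R
    within roughly [1, 5 x n_trials] trials, which prevents start/asymptote
    aliasing when a participant shows no learning.
    """

    asym_intercept: tuple = (-2.5, 1.0)
    start_intercept: tuple = (0.0, 1.5)
    rate_intercept: tuple = (math.log10(50.0), 0.7)
    coefficient: tuple = (0.0, 1.0)
    sd_scale: float = 1.0                      # half-Normal scale for random-effect SDs
    shape_intercept: tuple = (math.log(3.0), 0.5)
    lapse_beta: tuple = (2.0, 60.0)            # Beta prior on lapse/0.5 when estimated

    def intercept_prior(self, component: str) -> tuple:
        return getattr(self, f"{component}_intercept")


@dataclass(frozen=True)
class ModelSpec:
    """Which effects the model estimates and on which data subset.

    ``scope='full'`` fits both age groups and both affective dimensions
    (arousal contrast + monotonic valence, with age interactions by
    default).  ``scope='per_age'`` fits a single age group with one
    dimension (``effect``) or none (the null partner used in Bayes-factor
    comparisons); per-age valence models use only the stress and positive
    conditions.
    """

    scope: str = "full"                       # 'full' | 'per_age'
    age_group: str | None = None              # required when scope='per_age'
    effect: str = "both"                      # 'both' | 'arousal' | 'valence' | 'none'
    include_interactions: bool = True
    conditions: tuple | None = None           # None = dictated by scope/effect
    lapse: float = 0.01
    lapse_mode: str = "fixed"                 # 'fixed' | 'estimated'
    parameterization: str = "noncentered"     # 'noncentered' | 'centered'
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.scope not in ("full", "per_age"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "full":
            if self.effect != "both":
                raise ValueError("the full model always includes both dimensions")
        else:
            if self.age_group not in ("child", "adult"):
                raise ValueError("per-age models require age_group 'child' or 'adult'")
            if self.effect not in ("arousal", "valence", "none"):
                raise ValueError(f"per-age effect must be arousal/valence/none, got {self.effect!r}")
        if self.lapse_mode not in ("fixed", "estimated"):
            raise ValueError("lapse_mode must be 'fixed' or 'estimated'")
        if self.parameterization not in ("centered", "noncentered"):
            raise ValueError("parameterization must be 'centered' or 'noncentered'")
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must lie in [0, 0.5)")

    @classmethod
    def full(cls, **kw) -> "ModelSpec":
        return cls(scope="full", effect="both", **kw)

    @classmethod
    def per_age(cls, age_group: str, effect: str, **kw) -> "ModelSpec":
        return cls(scope="per_age", age_group=age_group, effect=effect, **kw)

    def null_partner(self) -> "ModelSpec":
        """The matched no-effect model on the same data subset (for Bayes factors)."""
        if self.scope != "per_age" or self.effect == "none":
            raise ValueError("null partners are defined for per-age effect models")
        return replace(self, effect="none", conditions=self.data_conditions())

    def data_conditions(self) -> tuple:
        if self.conditions is not None:
            return tuple(self.conditions)
        if self.scope == "per_age" and self.effect == "valence":
            return ("stress", "positive")
        return ("control", "positive", "stress")

    @property
    def label(self) -> str:
        if self.scope == "full":
            return "full"
        return f"{self.age_group}-{self.effect}"


class LearningModel:
    """Hierarchical learning model bound to a screened, truncated trial table.

    Parameters
    ----------
    records : pandas.DataFrame
        Long-format trials with columns ``participant_id, age_group,
        condition, trial, soa_ms, correct`` (already screened and truncated;
        see :mod:`oddlearn.screening`).
    spec : ModelSpec
    """

    def __init__(self, records: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        data = records
        if spec.scope == "per_age":
            data = data[data["age_group"] == spec.age_group]
        data = data[data["condition"].isin(spec.data_conditions())]
        self._validate(data)
        data = data.sort_values(["participant_id", "trial"]).reset_index(drop=True)
        self.data = data

        pids = data["participant_id"].unique()
        if len(pids) < 2:
            raise ValueError("random effects require at least 2 participants per modelled group")
        self.participants = pd.Index(pids, name="participant_id")
        self.n_participants = len(pids)
        pid_codes = pd.Categorical(data["participant_id"], categories=pids).codes

        # per-trial arrays
        self._y = data["correct"].to_numpy(dtype=np.int8)
        self._log_soa = np.log(data["soa_ms"].to_numpy(dtype=float) / 1000.0)
        self._tm1 = data["trial"].to_numpy(dtype=float) - 1.0
        self._pidx = pid_codes.astype(np.int32)
        self.mean_soa_s = float(data["soa_ms"].mean() / 1000.0)
        self.max_trial = int(data["trial"].max())

        # per-participant covariates
        meta = data.drop_duplicates("participant_id").set_index("participant_id").loc[pids]
        self.participant_meta = meta[["age_group", "condition"]].copy()
        age_c = np.where(meta["age_group"].to_numpy() == "adult", 0.5, -0.5)
        ar_c = np.where(meta["condition"].to_numpy() == "control", -0.5, 0.5)
        vlevel = meta["condition"].map(VALENCE_LEVEL).to_numpy()
        self._age_c = age_c
        self._vlevel = vlevel

        if spec.scope == "full":
            cols = [np.ones(self.n_participants), age_c, ar_c]
            names = ["Intercept", "age", "arousal"]
            if spec.include_interactions:
                cols.append(age_c * ar_c)
                names.append("age × arousal")
            self._X_lin = np.column_stack(cols)
            self._mono_names = ["valence"] + (["age × valence"] if spec.include_interactions else [])
        elif spec.effect == "arousal":
            self._X_lin = np.column_stack([np.ones(self.n_participants), ar_c])
            names = ["Intercept", "arousal"]
            self._mono_names = []
        elif spec.effect == "valence":
            vbin = np.where(meta["condition"].to_numpy() == "positive", 0.5, -0.5)
            self._X_lin = np.column_stack([np.ones(self.n_participants), vbin])
            names = ["Intercept", "valence"]
            self._mono_names = []
        else:  # null
            self._X_lin = np.ones((self.n_participants, 1))
            names = ["Intercept"]
            self._mono_names = []
        self.coef_names = names + self._mono_names
        self.has_mono = bool(self._mono_names)
        self._k_lin = self._X_lin.shape[1]
        self._k = self._k_lin + len(self._mono_names)

        # parameter-vector layout
        P, k = self.n_participants, self._k
        idx = 0
        self._sl_b = slice(idx, idx + 3 * k); idx += 3 * k
        self._i_shape = idx; idx += 1
        self._sl_logsd = slice(idx, idx + 4); idx += 4
        self._i_zeta = idx if self.has_mono else None
        idx += int(self.has_mono)
        self._i_lapse = idx if spec.lapse_mode == "estimated" else None
        idx += int(spec.lapse_mode == "estimated")
        self._sl_z = slice(idx, idx + 4 * P); idx += 4 * P
        self.n_params = idx

        # prior locations/scales for the fixed-effect block
        pr = spec.priors
        loc = np.zeros(3 * k)
        scale = np.zeros(3 * k)
        for ci, comp in enumerate(_COMPONENTS):
            mu0, sd0 = pr.intercept_prior(comp)
            loc[ci * k] = mu0
            scale[ci * k] = sd0
            loc[ci * k + 1: (ci + 1) * k] = pr.coefficient[0]
            scale[ci * k + 1: (ci + 1) * k] = pr.coefficient[1]
        self._b_loc, self._b_scale = loc, scale

        # full normalising constants of the (proper) priors: required so the
        # unnormalised posterior integrates to the marginal likelihood, which
        # bridge sampling compares across models of different dimension
        l2pi = math.log(2.0 * math.pi)
        const = float(np.sum(-0.5 * l2pi - np.log(scale)))
        const += -0.5 * l2pi - math.log(pr.shape_intercept[1])
        const += 4.0 * (math.log(2.0) - math.log(pr.sd_scale) - 0.5 * l2pi)
        const += 4 * P * (-0.5 * l2pi)
        if spec.lapse_mode == "estimated":
            a_l, b_l = pr.lapse_beta
            const += math.lgamma(a_l + b_l) - math.lgamma(a_l) - math.lgamma(b_l)
        self._log_prior_const = const

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        required = {"participant_id", "age_group", "condition", "trial", "soa_ms", "correct"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"records are missing columns: {sorted(missing)}")
        if data.empty:
            raise ValueError("no trials remain after subsetting; check spec vs data")
        soa = data["soa_ms"].to_numpy(dtype=float)
        if np.any(~np.isfinite(soa)) or np.any(soa <= 0):
            raise ValueError("soa_ms must be finite and > 0 for every modelled trial")
        if data["correct"].isna().any():
            raise ValueError("correct must be non-missing for every modelled trial")
        if np.any(data["trial"].to_numpy() < 1):
            raise ValueError("trial indices must be >= 1")

    # ------------------------------------------------------------------ #
    # parameter handling

    def unpack(self, x: np.ndarray) -> dict:
        """Split a flat unconstrained vector into named blocks."""
        P, k = self.n_participants, self._k
        out = {
            "b": x[self._sl_b].reshape(3, k),
            "shape_intercept": x[self._i_shape],
            "log_sd": x[self._sl_logsd],
            "z": x[self._sl_z].reshape(4, P),
        }
        out["zeta1"] = _sigmoid(x[self._i_zeta]) if self._i_zeta is not None else None
        if self._i_lapse is not None:
            out["lapse"] = 0.5 * _sigmoid(x[self._i_lapse])
        else:
            out["lapse"] = self.spec.lapse
        return out

    def _design(self, zeta1):
        if not self.has_mono:
            return self._X_lin
        cum = np.array([0.0, zeta1, 1.0])[self._vlevel]
        cols = [self._X_lin, cum[:, None]]
        if "age × valence" in self._mono_names:
            cols.append((self._age_c * cum)[:, None])
        return np.column_stack(cols)

    def participant_params(self, x: np.ndarray):
        """Per-participant (A, S, R, log beta) implied by an unconstrained vector."""
        p = self.unpack(x)
        X = self._design(p["zeta1"])
        if self.spec.parameterization == "centered":
            ASR = p["b"] @ X.T + p["z"][:3]             # (3, P); z holds u directly
            LB = p["shape_intercept"] + p["z"][3]
        else:
            sd = np.exp(p["log_sd"])
            ASR = p["b"] @ X.T + sd[:3, None] * p["z"][:3]
            LB = p["shape_intercept"] + sd[3] * p["z"][3]
        return ASR[0], ASR[1], ASR[2], LB, p["lapse"]

    def loglikelihood(self, x: np.ndarray) -> float:
        """Bernoulli log-likelihood of the data at an unconstrained vector."""
        A, S, R, LB, eps = self.participant_params(x)
        ll, *_ = loglik_grad(self._y, self._log_soa, self._tm1, self._pidx,
                             np.vstack([A, S, R]), LB, eps)
        return ll

    def logpost_and_grad(self, x: np.ndarray):
        """Unnormalised log posterior (with transform Jacobians) and its gradient."""
        p = self.unpack(x)
        b, z, log_sd = p["b"], p["z"], p["log_sd"]
        sd = np.exp(log_sd)
        X = self._design(p["zeta1"])
        centered = self.spec.parameterization == "centered"
        if centered:
            ASR = b @ X.T + z[:3]
            LB = p["shape_intercept"] + z[3]
        else:
            ASR = b @ X.T + sd[:3, None] * z[:3]
            LB = p["shape_intercept"] + sd[3] * z[3]
        eps = p["lapse"]

        ll, g3, gLB, g_eps = loglik_grad(
            self._y, self._log_soa, self._tm1, self._pidx, ASR, LB, eps
        )

        grad = np.empty_like(x)
        pr = self.spec.priors

        # fixed effects
        bflat = b.ravel()
        grad[self._sl_b] = (g3 @ X).ravel()
        grad[self._sl_b] -= (bflat - self._b_loc) / self._b_scale ** 2
        lp = ll + self._log_prior_const - 0.5 * float(
            (((bflat - self._b_loc) / self._b_scale) ** 2).sum())

        # shape intercept
        mu_s, sd_s = pr.shape_intercept
        grad[self._i_shape] = gLB.sum() - (p["shape_intercept"] - mu_s) / sd_s ** 2
        lp += -0.5 * ((p["shape_intercept"] - mu_s) / sd_s) ** 2

        # by-participant random effects and their SDs
        # (half-Normal(0, sd_scale) prior on each SD, sampled as log sd)
        tau = pr.sd_scale
        P = self.n_participants
        gz = grad[self._sl_z].reshape(4, P)            # view into grad
        if centered:
            # z holds the effects u themselves; prior u ~ N(0, sd)
            z_over_sd2 = z / sd[:, None] ** 2
            gz[:3] = g3
            gz[3] = gLB
            gz -= z_over_sd2
            zs2 = (z * z_over_sd2).sum(axis=1)         # sum (u/sd)^2 per component
            lp += -0.5 * float(zs2.sum()) - P * float(log_sd.sum())
            grad[self._sl_logsd] = zs2 - P - sd ** 2 / tau ** 2 + 1.0
        else:
            # non-centred: u = sd * z with z ~ N(0, 1)
            gz[:3] = sd[:3, None] * g3
            gz[3] = sd[3] * gLB
            zg = (z[:3] * g3).sum(axis=1)
            grad[self._sl_logsd][:3] = sd[:3] * zg
            grad[self._sl_logsd.start + 3] = sd[3] * float(z[3] @ gLB)
            grad[self._sl_logsd] -= sd ** 2 / tau ** 2 - 1.0
            gz -= z
            lp += -0.5 * float((z * z).sum())
        lp += float((-0.5 * (sd / tau) ** 2 + log_sd).sum())

        # monotonic-valence simplex: Dirichlet(1,1) => uniform zeta1, logit transform
        if self._i_zeta is not None:
            z1 = p["zeta1"]
            is_mid = (self._vlevel == 1).astype(float)
            coef_v = b[:, self._k_lin]                  # valence coefficient per component
            dcum = coef_v @ g3                          # d logpost / d cum weight, per participant
            if "age × valence" in self._mono_names:
                dcum = dcum + (b[:, self._k_lin + 1] @ g3) * self._age_c
            g_zeta1 = float(np.dot(dcum, is_mid))
            jac = z1 * (1.0 - z1)
            grad[self._i_zeta] = g_zeta1 * jac + (1.0 - 2.0 * z1)
            lp += math.log(max(jac, 1e-300))

        # estimated lapse: lapse = 0.5 * sigmoid(lam), Beta prior on lapse/0.5
        if self._i_lapse is not None:
            a_l, b_l = pr.lapse_beta
            u = 2.0 * eps                     # sigmoid(lam)
            lp += (a_l - 1.0) * math.log(max(u, 1e-300)) + (b_l - 1.0) * math.log(max(1 - u, 1e-300))
            lp += math.log(max(u * (1 - u), 1e-300))
            dlp_du = (a_l - 1.0) / max(u, 1e-300) - (b_l - 1.0) / max(1 - u, 1e-300)
            du_dlam = u * (1 - u)
            grad[self._i_lapse] = (g_eps * 0.5 + dlp_du) * du_dlam + (1.0 - 2.0 * u)
        return lp, grad

    # ------------------------------------------------------------------ #

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = np.zeros(self.n_params)
        k = self._k
        for ci, comp in enumerate(_COMPONENTS):
            x[self._sl_b.start + ci * k] = self.spec.priors.intercept_prior(comp)[0]
        x[self._i_shape] = self.spec.priors.shape_intercept[0]
        x[self._sl_logsd] = math.log(0.3)
        x += 0.1 * rng.standard_normal(self.n_params)
        return x

    def posterior_mode(self, rng: np.random.Generator, maxiter: int = 200) -> np.ndarray:
        """Approximate posterior mode by L-BFGS; used to seed the sampler."""
        from scipy.optimize import minimize

        def neg(x):
            lp, g = self.logpost_and_grad(x)
            if not np.isfinite(lp):
                return 1e30, np.zeros_like(x)
            return -lp, -g

        opt = minimize(neg, self.initial_point(rng), jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        return opt.x

    def mode_hessian_covariance(self, mode: np.ndarray, h: float = 1e-4,
                                max_var: float = 10.0) -> np.ndarray:
        """Dense posterior-covariance estimate from the Hessian at the mode.

        Central finite differences of the analytic gradient give the full
        Hessian of the negative log posterior; its (eigenvalue-regularised)
        inverse approximates the posterior covariance, including the strong
        within-participant correlations between learning components.  Used
        as the sampler's fixed dense inverse metric.
        """
        n = self.n_params
        H = np.empty((n, n))
        for i in range(n):
            xp = mode.copy(); xp[i] += h
            xm = mode.copy(); xm[i] -= h
            H[:, i] = -(self.logpost_and_grad(xp)[1] - self.logpost_and_grad(xm)[1]) / (2 * h)
        H = 0.5 * (H + H.T)
        lam, vecs = np.linalg.eigh(H)
        # flat or negative directions get prior-scale variance, not infinity
        var = 1.0 / np.maximum(lam, 1.0 / max_var)
        var = np.minimum(var, max_var)
        return (vecs * var) @ vecs.T

    def mode_curvature(self, mode: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Diagonal posterior variances estimated from curvature at the mode.

        Central finite differences of the gradient give the Hessian diagonal
        of the negative log posterior; its inverse seeds the sampler's
        diagonal mass matrix, which warmup then refines.
        """
        diag = np.empty(self.n_params)
        for i in range(self.n_params):
            xp = mode.copy(); xp[i] += h
            xm = mode.copy(); xm[i] -= h
            gp = self.logpost_and_grad(xp)[1][i]
            gm = self.logpost_and_grad(xm)[1][i]
            diag[i] = -(gp - gm) / (2 * h)
        var = np.where(diag > 1e-8, 1.0 / np.maximum(diag, 1e-8), 1.0)
        return np.clip(var, 1e-6, 1e3)

    def fit(
        self,
        draws: int = 500,
        warmup: int = 500,
        chains: int = 2,
        seed: int = 0,
        target_accept: float = 0.8,
        max_treedepth: int = 8,
        init: str = "mode",
        metric: str = "diag",
        max_retries: int = 1,
    ) -> "LearningModelResults":
        """Sample the posterior with NUTS; returns a results object.

        ``init='mode'`` seeds every chain near an L-BFGS approximation of the
        posterior mode (with per-chain jitter), which shortens warmup
        considerably; ``init='random'`` starts from jittered prior locations.
        When adaptation visibly failed (split R-hat above 1.2 or more than
        2% divergent transitions) the fit is retried once, deterministically,
        with doubled warmup and a higher acceptance target.  Emits a
        ``UserWarning`` (not an error) when max split R-hat exceeds 1.01 or
        any divergent transitions occurred.
        """
        seqs = np.random.SeedSequence(seed).spawn(chains + 1)
        mode = self.posterior_mode(np.random.default_rng(seqs[-1])) if init == "mode" else None
        dense_inv_mass = None
        inv_mass0 = None
        if mode is not None and metric == "dense":
            dense_inv_mass = self.mode_hessian_covariance(mode)
        elif mode is not None:
            inv_mass0 = self.mode_curvature(mode)
        chain_draws, chain_logp, divergences, depths = [], [], 0, []
        step_sizes = []
        for cs in seqs[:chains]:
            rng = np.random.default_rng(cs)
            x0 = None
            for _ in range(100):
                if mode is not None:
                    cand = mode + 0.05 * rng.standard_normal(self.n_params)
                else:
                    cand = self.initial_point(rng)
                lp, _ = self.logpost_and_grad(cand)
                if np.isfinite(lp):
                    x0 = cand
                    break
            if x0 is None:
                raise RuntimeError("could not find a finite initial density in 100 draws")
            res = sample_nuts(
                self.logpost_and_grad, x0, warmup, draws, rng,
                target_accept=target_accept, max_treedepth=max_treedepth,
                inv_mass0=inv_mass0, dense_inv_mass=dense_inv_mass,
            )
            chain_draws.append(res.draws)
            chain_logp.append(res.logp)
            divergences += res.divergences
            depths.append(res.treedepths)
            step_sizes.append(res.step_size)
        out = LearningModelResults(
            model=self,
            draws=np.stack(chain_draws),
            logp=np.stack(chain_logp),
            divergences=divergences,
            step_sizes=step_sizes,
            seed=seed,
        )
        max_rhat = out.max_rhat()
        adaptation_failed = max_rhat > 1.3 or divergences > 0.05 * draws * chains
        if adaptation_failed and max_retries > 0:
            return self.fit(
                draws=draws, warmup=warmup + 200, chains=chains, seed=seed + 7919,
                target_accept=min(0.95, target_accept + 0.1),
                max_treedepth=max_treedepth, init=init, metric=metric,
                max_retries=max_retries - 1,
            )
        if max_rhat > 1.01 or divergences > 0:
            warnings.warn(
                f"sampling quality warning for model {self.spec.label!r}: "
                f"max split R-hat {max_rhat:.3f}, {divergences} divergences",
                UserWarning,
            )
        return out


def _sigmoid(v: float) -> float:
    if v >= 0:
        return 1.0 / (1.0 + math.exp(-v))
    e = math.exp(v)
    return e / (1.0 + e)


class LearningModelResults:
    """Posterior draws plus the summaries the analysis reports.

    ``draws`` has shape (chains, draws, n_params) on the unconstrained
    scale; every summary is computed from these stored draws.
    """

    def __init__(self, model, draws, logp, divergences, step_sizes, seed):
        self.model = model
        self.spec = model.spec
        self.draws = draws
        self.logp = logp
        self.divergences = int(divergences)
        self.step_sizes = step_sizes
        self.seed = seed
        self.n_chains, self.n_draws, _ = draws.shape

    # -------------------------------------------------------------- #

    @property
    def fixed_effect_labels(self) -> list:
        labels = []
        for comp in _COMPONENTS:
            for name in self.model.coef_names:
                labels.append(f"{_COMPONENT_LABEL[comp]}: {name}")
        labels.append("PF shape: Intercept")
        return labels

    def fixed_effect_draws(self) -> pd.DataFrame:
        """Flattened posterior draws of all fixed effects (columns = labels)."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        k = self.model._k
        cols = {}
        b = flat[:, self.model._sl_b]
        for ci, comp in enumerate(_COMPONENTS):
            for j, name in enumerate(self.model.coef_names):
                cols[f"{_COMPONENT_LABEL[comp]}: {name}"] = b[:, ci * k + j]
        cols["PF shape: Intercept"] = flat[:, self.model._i_shape]
        return pd.DataFrame(cols)

    def summary(self, ci_prob: float = 0.95) -> pd.DataFrame:
        """Coefficient table: posterior mean, equal-tailed CI, reliability flag.

        A coefficient is flagged reliable when its CI excludes zero (the
        intercept rows carry the flag too, but it is only meaningful for
        contrasts).
        """
        d = self.fixed_effect_draws()
        lo_q, hi_q = (1 - ci_prob) / 2, 1 - (1 - ci_prob) / 2
        est = d.mean()
        lo = d.quantile(lo_q)
        hi = d.quantile(hi_q)
        reliable = (lo > 0) | (hi < 0)
        return pd.DataFrame({
            "Estimate": est,
            "lower 95% CI": lo,
            "upper 95% CI": hi,
            "reliable": reliable,
        })

    def _diagnostic_draws(self) -> np.ndarray:
        """Draws reshaped for diagnostics: a single chain is split in half so
        that split R-hat and ESS remain defined (arviz needs >= 2 chains)."""
        c, n, d = self.draws.shape
        if c == 1:
            half = n // 2
            return self.draws[:, : 2 * half].reshape(2, half, d)
        return self.draws

    def min_ess_bulk(self) -> float:
        """Worst bulk effective sample size over all parameters (cached)."""
        if not hasattr(self, "_min_ess_bulk"):
            import arviz as az
            ds = az.convert_to_dataset(self._diagnostic_draws(), group="posterior")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._min_ess_bulk = float(np.nanmin(az.ess(ds, method="bulk")["x"].to_numpy()))
        return self._min_ess_bulk

    def max_rhat(self) -> float:
        """Worst split R-hat over all parameters (cached)."""
        if not hasattr(self, "_max_rhat"):
            import arviz as az
            ds = az.convert_to_dataset(self._diagnostic_draws(), group="posterior")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._max_rhat = float(np.nanmax(az.rhat(ds)["x"].to_numpy()))
        return self._max_rhat

    def diagnostics(self) -> dict:
        """Split R-hat, bulk/tail ESS (worst case over parameters), divergences (cached)."""
        if not hasattr(self, "_diagnostics"):
            import arviz as az
            ds = az.convert_to_dataset(self._diagnostic_draws(), group="posterior")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess_bulk = az.ess(ds, method="bulk")["x"].to_numpy()
                ess_tail = az.ess(ds, method="tail")["x"].to_numpy()
            self._diagnostics = {
                "max_rhat": self.max_rhat(),
                "min_ess_bulk": float(np.nanmin(ess_bulk)),
                "min_ess_tail": float(np.nanmin(ess_tail)),
                "divergences": self.divergences,
            }
        return self._diagnostics

    # -------------------------------------------------------------- #

    def participant_param_draws(self):
        """Per-draw per-participant (A, S, R, log beta); arrays of shape (n_total, P)."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        n_total = flat.shape[0]
        P = self.model.n_participants
        A = np.empty((n_total, P)); S = np.empty((n_total, P))
        R = np.empty((n_total, P)); LB = np.empty((n_total, P))
        eps = np.empty(n_total)
        for i, x in enumerate(flat):
            A[i], S[i], R[i], LB[i], eps[i] = self.model.participant_params(x)
        return A, S, R, LB, eps

    def learning_magnitude(self, t_start: float = 1.0, t_end: float | None = None,
                           mean_soa_s: float | None = None) -> dict:
        """Posterior learning magnitudes and condition contrasts.

        The magnitude of learning is each participant's difference between
        ending and starting accuracy, evaluated at the mean SOA of the
        modelled trials.  Returns per-participant posterior summaries and
        per-condition contrasts with equal-tailed 95% CIs, all computed
        draw-by-draw from the stored posterior.
        """
        t_end = float(t_end if t_end is not None else self.model.max_trial)
        soa = mean_soa_s if mean_soa_s is not None else self.model.mean_soa_s
        A, S, R, LB, eps = self.participant_param_draws()
        ln2 = math.log(2.0)

        def acc(logth, beta, eps_v):
            w = np.exp(beta * (math.log(soa) - logth))
            return (1.0 - eps_v) - (0.5 - eps_v) * np.exp(-ln2 * w)

        beta = np.exp(LB)
        eps_col = eps[:, None]
        d_end = np.exp2(-(t_end - 1.0) / 10.0 ** R)
        d_start = np.exp2(-(t_start - 1.0) / 10.0 ** R)
        mag = acc(A + (S - A) * d_end, beta, eps_col) - acc(A + (S - A) * d_start, beta, eps_col)

        per_part = pd.DataFrame({
            "participant_id": self.model.participants,
            "condition": self.model.participant_meta["condition"].to_numpy(),
            "age_group": self.model.participant_meta["age_group"].to_numpy(),
            "mean": mag.mean(axis=0),
            "lower 95% CI": np.quantile(mag, 0.025, axis=0),
            "upper 95% CI": np.quantile(mag, 0.975, axis=0),
        })
        conds = list(dict.fromkeys(self.model.participant_meta["condition"]))
        cond_draws = {c: mag[:, self.model.participant_meta["condition"].to_numpy() == c].mean(axis=1)
                      for c in conds}
        rows = []
        for i, c1 in enumerate(conds):
            for c2 in conds[i + 1:]:
                diff = cond_draws[c2] - cond_draws[c1]
                rows.append({
                    "contrast": f"{c2} - {c1}",
                    "mean": diff.mean(),
                    "lower 95% CI": np.quantile(diff, 0.025),
                    "upper 95% CI": np.quantile(diff, 0.975),
                })
        return {"per_participant": per_part, "contrasts": pd.DataFrame(rows)}

    # -------------------------------------------------------------- #

    def plot_learning_curves(self, ax=None, n_draws: int = 100):
        """Posterior-mean predicted accuracy at the mean SOA over trials, per condition."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        A, S, R, LB, eps = self.participant_param_draws()
        t = np.arange(1, self.model.max_trial + 1, dtype=float)
        ln2 = math.log(2.0)
        soa = self.model.mean_soa_s
        cond = self.model.participant_meta["condition"].to_numpy()
        for c in dict.fromkeys(cond):
            sel = cond == c
            Am, Sm, Rm = A[:, sel].mean(), S[:, sel].mean(), R[:, sel].mean()
            betam, epsm = np.exp(LB[:, sel]).mean(), eps.mean()
            logth = Am + (Sm - Am) * np.exp2(-(t - 1.0) / 10.0 ** Rm)
            w = np.exp(betam * (np.log(soa) - logth))
            acc = (1 - epsm) - (0.5 - epsm) * np.exp(-ln2 * w)
            ax.plot(t, acc, label=c)
        ax.set_xlabel("trial")
        ax.set_ylabel(f"P(correct) at mean SOA ({1000 * soa:.0f} ms)")
        ax.set_ylim(0.45, 1.0)
        ax.legend(title="condition")
        return ax
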