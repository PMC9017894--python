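"""Numba kernel for the per-trial Bernoulli likelihood and its gradient.

Each trial contributes ``Bernoulli(p_i)`` with

    p_i = (1 - eps) - (0.5 - eps) * 2**(-(soa_i / theta_p(t_i))**beta_p)
    log theta_p(t) = A_p + (S_p - A_p) * 2**(-(t - 1) / 10**R_p)

The kernel returns the total log-likelihood together with its partial
derivatives with respect to each participant's (A, S, R) — stacked as a
(3, P) array — plus the shape (log beta) gradient and the shared-lapse
gradient; the chain rule to fixed effects, random-effect SDs and the
simplex is applied by the caller.
"""

import math

import numpy as np
from numba import njit

_LN2 = math.log(2.0)
_LN10 = math.log(10.0)


@njit(cache=True, fastmath=True, error_model="numpy")
def loglik_grad(y, log_soa, tm1, pidx, ASR, LB, eps):  # pragma: no cover - exercised via wrapper
    n_part = LB.shape[0]
    n = y.shape[0]
    A = ASR[0].copy()
    S = ASR[1].copy()
    R = ASR[2].copy()
    beta = np.empty(n_part)
    cdecay = np.empty(n_part)   # ln2 / 10**R
    rho = np.empty(n_part)      # per-trial decay factor 2**(-1/10**R)
    for p in range(n_part):
        beta[p] = math.exp(LB[p])
        cdecay[p] = _LN2 * 10.0 ** (-R[p])
        rho[p] = math.exp(-cdecay[p])
    g = np.zeros((3, n_part))
    gA = g[0]
    gS = g[1]
    gR = g[2]
    gLB = np.zeros(n_part)
    g_eps = 0.0
    ll = 0.0
    prev_p = -1
    prev_t = -1.0
    d = 1.0
    for i in range(n):
        p = pidx[i]
        # 2**(-(t-1)/10**R) via a per-participant recurrence on consecutive trials
        if p == prev_p and tm1[i] == prev_t + 1.0:
            d *= rho[p]
        else:
            d = math.exp(-tm1[i] * cdecay[p])
        prev_p = p
        prev_t = tm1[i]
        logth = A[p] + (S[p] - A[p]) * d
        arg = beta[p] * (log_soa[i] - logth)
        saturated = arg > 690.0  # w would overflow; prob saturates at 1 - eps
        if saturated:
            w = 0.0
            q = 0.0
        else:
            w = math.exp(arg)
            q = math.exp(-_LN2 * w)
        prob = (1.0 - eps) - (0.5 - eps) * q
        if y[i] == 1:
            ll += math.log(prob)
            dldp = 1.0 / prob
        else:
            om = 1.0 - prob
            if om < 1e-300:
                om = 1e-300
            ll += math.log(om)
            dldp = -1.0 / om
        if saturated:
            # gradient through q vanishes
            g_eps += dldp * (q - 1.0)
            continue
        dldw = dldp * (0.5 - eps) * _LN2 * q
        dldlogth = dldw * (-beta[p]) * w
        gA[p] += dldlogth * (1.0 - d)
        gS[p] += dldlogth * d
        gR[p] += dldlogth * (S[p] - A[p]) * d * tm1[i] * _LN10 * cdecay[p]
        gLB[p] += dldw * w * arg
        g_eps += dldp * (q - 1.0)
    return ll, g, gLB, g_eps
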