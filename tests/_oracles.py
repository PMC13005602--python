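"""Independent brute-force transcriptions of the estimator and variance
formulas, written as explicit double loops over records and baseline jump
times. Used only as test oracles; deliberately shares no code with the
production implementation beyond the fitted model parameters."""

import math

import numpy as np
from scipy import stats

FLOOR = 1e-8


def _cum_baseline(model, t, left=False):
    total = 0.0
    for u, dl in zip(model.jump_times, model.jump_increments):
        if (u < t) if left else (u <= t):
            total += dl
    return total


def _k(cens, t, x, left=False):
    lin = sum(b * v for b, v in zip(cens.beta, x)) if len(cens.beta) else 0.0
    return math.exp(-_cum_baseline(cens, t, left) * math.exp(lin))


def _h(out, t, x):
    if out.family == "cox":
        lin = sum(b * v for b, v in zip(out.cox.beta, x)) if len(out.cox.beta) else 0.0
        return math.exp(-_cum_baseline(out.cox, t) * math.exp(lin))
    mu = out.gamma0 + sum(g * v for g, v in zip(out.gamma1, x))
    if t <= 0:
        return 1.0
    z = (math.log(t) - mu) / out.sigma
    dist = {"lognormal": stats.norm, "weibull": stats.gumbel_l, "loglogistic": stats.logistic}
    return float(dist[out.family].sf(z))


def _tau(omega_i):
    w = max(omega_i, FLOOR)
    return (1.0 - w) / w


def _xrow(sample, i, names):
    return [float(sample.X.iloc[i][c]) for c in names]


def naive_aug(sample, i, cens, out, t):
    """Augmentation integral for record i by explicit jump-time loop."""
    u, d = sample.U[i], sample.delta[i]
    xc = _xrow(sample, i, cens.covariate_names)
    xo = _xrow(sample, i, out.covariate_names)
    h_t = _h(out, t, xo)
    val = 0.0
    if d == 0 and u <= t:
        val += h_t / (max(_h(out, u, xo), FLOOR) * max(_k(cens, u, xc, left=True), FLOOR))
    lin = sum(b * v for b, v in zip(cens.beta, xc)) if len(cens.beta) else 0.0
    for uk, dl in zip(cens.jump_times, cens.jump_increments):
        if uk <= min(u, t):
            val -= (
                dl * math.exp(lin) * h_t
                / (max(_h(out, uk, xo), FLOOR) * max(_k(cens, uk, xc, left=True), FLOOR))
            )
    return val


def _pi_a(sample, a):
    return sample.pi if a == 1 else 1.0 - sample.pi


def _ipw_num_i(sample, omega, cens, a, i, t):
    if sample.S[i] != 1 or sample.A[i] != a:
        return 0.0
    xc = _xrow(sample, i, cens[a].covariate_names)
    k = max(_k(cens[a], sample.U[i], xc, left=True), FLOOR)
    return _tau(omega[i]) * sample.delta[i] * (sample.U[i] >= t) / k


def naive_ipw1(sample, omega, cens, a, t):
    W = sum(sample.w_survey[i] for i in range(len(sample.S)) if sample.S[i] == 0)
    num = sum(_ipw_num_i(sample, omega, cens, a, i, t) for i in range(len(sample.S)))
    return num / (_pi_a(sample, a) * W)


def naive_ipw2(sample, omega, cens, a, t):
    num = sum(_ipw_num_i(sample, omega, cens, a, i, t) for i in range(len(sample.S)))
    den = sum(
        _tau(omega[i])
        for i in range(len(sample.S))
        if sample.S[i] == 1 and sample.A[i] == a
    )
    return num / den


def naive_om(sample, out, a, t):
    num = den = 0.0
    for i in range(len(sample.S)):
        if sample.S[i] == 0:
            w = sample.w_survey[i]
            num += w * _h(out[a], t, _xrow(sample, i, out[a].covariate_names))
            den += w
    return num / den


def _dr_trial_i(sample, omega, cens, out, a, i, t):
    """tau_i * (residual + augmentation) for trial record i in arm a, else 0."""
    if sample.S[i] != 1 or sample.A[i] != a:
        return 0.0
    xc = _xrow(sample, i, cens[a].covariate_names)
    xo = _xrow(sample, i, out[a].covariate_names)
    k_t = max(_k(cens[a], t, xc), FLOOR)
    h_t = _h(out[a], t, xo)
    resid = ((sample.U[i] >= t) - k_t * h_t) / k_t
    return _tau(omega[i]) * (resid + naive_aug(sample, i, cens[a], out[a], t))


def naive_dr1(sample, omega, cens, out, a, t):
    W = sum(sample.w_survey[i] for i in range(len(sample.S)) if sample.S[i] == 0)
    total = 0.0
    for i in range(len(sample.S)):
        total += _dr_trial_i(sample, omega, cens, out, a, i, t) / _pi_a(sample, a)
        if sample.S[i] == 0:
            total += sample.w_survey[i] * _h(out[a], t, _xrow(sample, i, out[a].covariate_names))
    return total / W


def naive_dr2_parts(sample, omega, cens, out, a, t):
    tau_sum = sum(
        _tau(omega[i])
        for i in range(len(sample.S))
        if sample.S[i] == 1 and sample.A[i] == a
    )
    nu1 = sum(
        _dr_trial_i(sample, omega, cens, out, a, i, t) for i in range(len(sample.S))
    ) / tau_sum
    nu2 = naive_om(sample, out, a, t)
    return nu1, nu2


def naive_dr2(sample, omega, cens, out, a, t):
    nu1, nu2 = naive_dr2_parts(sample, omega, cens, out, a, t)
    return nu1 + nu2


# -- variance transcriptions -------------------------------------------------

def naive_var_ipw1(sample, omega, cens, t):
    W = sum(sample.w_survey[i] for i in range(len(sample.S)) if sample.S[i] == 0)
    S = {a: naive_ipw1(sample, omega, cens, a, t) for a in (0, 1)}
    delta = S[1] - S[0]
    total = 0.0
    for i in range(len(sample.S)):
        I = {}
        for a in (0, 1):
            val = _ipw_num_i(sample, omega, cens, a, i, t) / _pi_a(sample, a)
            if sample.S[i] == 0:
                val -= sample.w_survey[i] * S[a]
            I[a] = val
        total += (I[1] - I[0] - delta) ** 2
    return total / W**2


def naive_var_ipw2(sample, omega, cens, t):
    total = 0.0
    for a in (0, 1):
        S_a = naive_ipw2(sample, omega, cens, a, t)
        den = sum(
            _tau(omega[i])
            for i in range(len(sample.S))
            if sample.S[i] == 1 and sample.A[i] == a
        )
        for i in range(len(sample.S)):
            if sample.S[i] == 1 and sample.A[i] == a:
                xc = _xrow(sample, i, cens[a].covariate_names)
                k = max(_k(cens[a], sample.U[i], xc, left=True), FLOOR)
                ipcw = sample.delta[i] * (sample.U[i] >= t) / k
                total += (_tau(omega[i]) * (ipcw - S_a) / den) ** 2
    return total


def naive_var_dr1(sample, omega, cens, out, t):
    W = sum(sample.w_survey[i] for i in range(len(sample.S)) if sample.S[i] == 0)
    S = {a: naive_dr1(sample, omega, cens, out, a, t) for a in (0, 1)}
    delta = S[1] - S[0]
    total = 0.0
    for i in range(len(sample.S)):
        I = {}
        for a in (0, 1):
            val = _dr_trial_i(sample, omega, cens, out, a, i, t) / _pi_a(sample, a)
            if sample.S[i] == 0:
                h = _h(out[a], t, _xrow(sample, i, out[a].covariate_names))
                val += sample.w_survey[i] * (h - S[a])
            I[a] = val
        total += (I[1] - I[0] - delta) ** 2
    return total / W**2


def naive_var_dr2(sample, omega, cens, out, t):
    W = sum(sample.w_survey[i] for i in range(len(sample.S)) if sample.S[i] == 0)
    total = 0.0
    for a in (0, 1):
        nu1, nu2 = naive_dr2_parts(sample, omega, cens, out, a, t)
        den = sum(
            _tau(omega[i])
            for i in range(len(sample.S))
            if sample.S[i] == 1 and sample.A[i] == a
        )
        for i in range(len(sample.S)):
            val = 0.0
            if sample.S[i] == 1 and sample.A[i] == a:
                val += (
                    _dr_trial_i(sample, omega, cens, out, a, i, t) - _tau(omega[i]) * nu1
                ) / den
            if sample.S[i] == 0:
                h = _h(out[a], t, _xrow(sample, i, out[a].covariate_names))
                val += sample.w_survey[i] * (h - nu2) / W
            total += val**2
    return total


def naive_wkm(U, d, w, t):
    """Weighted product-limit estimate of P(T >= t) by explicit loop."""
    surv = 1.0
    for u in sorted(set(U[d == 1])):
        if u < t:
            y = sum(wi for ui, wi in zip(U, w) if ui >= u)
            dn = sum(wi for ui, di, wi in zip(U, d, w) if ui == u and di == 1)
            surv *= 1.0 - dn / y
    return surv
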