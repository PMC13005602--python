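"""Approximate influence-function variance estimators and Wald intervals.

Variances deliberately ignore the uncertainty from fitting the sampling
score, censoring and outcome models: each estimator's residual influence
contributions are squared and summed with the nuisances held fixed. This is
conservative for the weighting estimators and close to nominal for the doubly
robust ones.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .dataio import CombinedSample
from .estimators import (
    NuisanceSet,
    SurvivalCurveEstimate,
    _dr_trial_term,
    _ipcw_term,
    _pi_a,
    _survey_weight_total,
    _tau_arm,
    dr2_decomposition,
)


def wald_ci(delta_hat: float, variance: float, level: float = 0.95):
    """Normal-approximation interval delta-hat +/- z * sqrt(variance)."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance)
    return float(delta_hat - half), float(delta_hat + half)


def _point(est: SurvivalCurveEstimate, t: float):
    i = est._index_of(t)
    return float(est.S1[i]), float(est.S0[i]), float(est.delta[i])


def var_ipw1(
    sample: CombinedSample, estimate: SurvivalCurveEstimate, nuisances: NuisanceSet, t: float
) -> float:
    """Variance of the IPW1 TASTE: squared centered influence contributions
    scaled by the inverse squared survey-weight total."""
    S1, S0, delta = _point(estimate, t)
    W = _survey_weight_total(sample)
    k = sample.S.size
    I = {a: np.zeros(k) for a in (0, 1)}
    for a, S_a in ((1, S1), (0, S0)):
        mask = sample.arm(a)
        tau = _tau_arm(sample, nuisances.omega, a)
        ipcw = _ipcw_term(sample, nuisances.censoring[a], a, t)
        I[a][mask] = tau * ipcw / _pi_a(sample, a)
        I[a][sample.survey] = -sample.w_survey[sample.survey] * S_a
    return float(np.sum((I[1] - I[0] - delta) ** 2) / W**2)


def var_ipw2(
    sample: CombinedSample, estimate: SurvivalCurveEstimate, nuisances: NuisanceSet, t: float
) -> float:
    """Variance of the IPW2 TASTE: per-arm self-normalized influence
    contributions centered at the arm estimate."""
    S1, S0, _ = _point(estimate, t)
    total = 0.0
    for a, S_a in ((1, S1), (0, S0)):
        tau = _tau_arm(sample, nuisances.omega, a)
        ipcw = _ipcw_term(sample, nuisances.censoring[a], a, t)
        contrib = tau * (ipcw - S_a) / tau.sum()
        total += float(np.sum(contrib**2))
    return total


def var_dr1(
    sample: CombinedSample, estimate: SurvivalCurveEstimate, nuisances: NuisanceSet, t: float
) -> float:
    """Variance of the DR1 TASTE combining the residual, martingale and
    outcome-regression influence pieces."""
    S1, S0, delta = _point(estimate, t)
    W = _survey_weight_total(sample)
    k = sample.S.size
    surv = sample.survey
    w = sample.w_survey[surv]
    I = {a: np.zeros(k) for a in (0, 1)}
    for a, S_a in ((1, S1), (0, S0)):
        mask = sample.arm(a)
        tau = _tau_arm(sample, nuisances.omega, a)
        trial_term = _dr_trial_term(sample, nuisances.censoring[a], nuisances.outcome[a], a, t)
        I[a][mask] = tau * trial_term / _pi_a(sample, a)
        out = nuisances.outcome[a]
        Xs = sample.design_matrix(out.covariate_names)[surv]
        I[a][surv] = w * (out.survival(t, Xs) - S_a)
    return float(np.sum((I[1] - I[0] - delta) ** 2) / W**2)


def var_dr2(
    sample: CombinedSample, estimate: SurvivalCurveEstimate, nuisances: NuisanceSet, t: float
) -> float:
    """Variance of the DR2 TASTE from its two-part influence function: the
    weighting part centered at nu1 and the outcome part centered at nu2."""
    W = _survey_weight_total(sample)
    surv = sample.survey
    w = sample.w_survey[surv]
    k = sample.S.size
    total = 0.0
    for a in (0, 1):
        nu1, nu2 = dr2_decomposition(
            sample, nuisances.omega, nuisances.censoring, nuisances.outcome, a, t
        )
        mask = sample.arm(a)
        tau = _tau_arm(sample, nuisances.omega, a)
        trial_term = _dr_trial_term(sample, nuisances.censoring[a], nuisances.outcome[a], a, t)
        out = nuisances.outcome[a]
        Xs = sample.design_matrix(out.covariate_names)[surv]
        I = np.zeros(k)
        I[mask] = tau * (trial_term - nu1) / tau.sum()
        I[surv] = w * (out.survival(t, Xs) - nu2) / W
        total += float(np.sum(I**2))
    return total


VARIANCE_FUNCTIONS = {
    "IPW1": var_ipw1,
    "IPW2": var_ipw2,
    "DR1": var_dr1,
    "DR2": var_dr2,
}
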