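"""Counterfactual survival estimators for the target population.

Implements the outcome-model (OM), Horvitz-Thompson-type (IPW1),
self-normalized (IPW2) weighting estimators, their augmented doubly robust
counterparts (DR1, DR2), and an inverse-odds-weighted Kaplan-Meier reference
(WKM), together with the treatment-effect curve delta(t) = S1(t) - S0(t).

All estimators take survey weights into account: IPW1/DR1 normalize by the
survey-weight total, IPW2/DR2 self-normalize their trial terms by the summed
inverse odds (so the randomization probability pi cancels), and every
estimator relies on a sampling score fitted by survey-weighted logistic
regression. Survival indicators are closed at t, i.e. I(U >= t); the censoring
survival is evaluated at the subject's own time via its left limit K(U-|X) and
at fixed analysis times via its right-continuous value K(t|X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CombinedSample
from .exceptions import EstimationError
from .nuisance import SURV_FLOOR, CensoringModel, OutcomeModel

ESTIMATOR_TAGS = ("OM", "IPW1", "IPW2", "DR1", "DR2", "WKM")


def _floor(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, SURV_FLOOR)


@dataclass
class NuisanceSet:
    """Bundle of fitted nuisances consumed by estimators and variance formulas.

    ``omega`` is the per-record fitted sampling score for the full combined
    sample; ``censoring`` and ``outcome`` map arm -> fitted model.
    """

    omega: np.ndarray | None = None
    censoring: dict[int, CensoringModel] | None = None
    outcome: dict[int, OutcomeModel] | None = None


@dataclass
class SurvivalCurveEstimate:
    """Estimated counterfactual survival curves and TASTE on a time grid."""

    estimator: str
    times: np.ndarray
    S1: np.ndarray
    S0: np.ndarray
    delta: np.ndarray
    se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    out_of_range: np.ndarray
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times, "S1": self.S1, "S0": self.S0,
                "delta": self.delta, "se": self.se,
                "ci_lo": self.ci_lo, "ci_hi": self.ci_hi,
            }
        )

    def _index_of(self, t: float) -> int:
        hits = np.flatnonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-12))
        if hits.size == 0:
            raise EstimationError(
                f"t={t} is not on the estimation grid; step estimates are not interpolated"
            )
        return int(hits[0])


def taste(est: SurvivalCurveEstimate, t: float):
    """delta-hat(t) with its SE and Wald CI at a grid time."""
    i = est._index_of(t)
    return float(est.delta[i]), float(est.se[i]), (float(est.ci_lo[i]), float(est.ci_hi[i]))


# ---------------------------------------------------------------------------
# shared per-arm ingredients
# ---------------------------------------------------------------------------

def _pi_a(sample: CombinedSample, a: int) -> float:
    return sample.pi if a == 1 else 1.0 - sample.pi


def _tau_arm(sample: CombinedSample, omega_hat: np.ndarray, a: int) -> np.ndarray:
    """Inverse odds (1-omega)/omega for trial records in arm a."""
    omega = _floor(np.asarray(omega_hat, dtype=float)[sample.arm(a)])
    return (1.0 - omega) / omega


def _ipcw_term(sample: CombinedSample, cens: CensoringModel, a: int, t: float) -> np.ndarray:
    """Delta_i I(U_i >= t) / K_a(U_i-|X_i) for trial records in arm a."""
    mask = sample.arm(a)
    U, d = sample.U[mask], sample.delta[mask]
    Xc = sample.design_matrix(cens.covariate_names)[mask]
    k_left = _floor(cens.survival(U, Xc, side="left"))
    return d * (U >= t) / k_left


def martingale_augmentation(u, delta, x, cens: CensoringModel, out: OutcomeModel, t: float) -> float:
    """Censoring-martingale augmentation integral for a single trial subject.

    Returns int_0^t H(t|x)/H(s|x) dM(s|x)/K(s|x): the counting-process jump
    (when the subject is censored at or before t) minus the compensator sum
    over the Breslow jump times of the censoring baseline up to min(u, t).
    ``x`` maps covariate names to values (dict or Series).
    """
    x = pd.Series(x)
    xc = x[cens.covariate_names].to_numpy(dtype=float)[None, :]
    xo = x[out.covariate_names].to_numpy(dtype=float)[None, :]
    return float(
        _augmentation(np.array([u]), np.array([delta], dtype=float), xc, xo, cens, out, t)[0]
    )


def _augmentation(
    U: np.ndarray, delta: np.ndarray, Xc: np.ndarray, Xo: np.ndarray,
    cens: CensoringModel, out: OutcomeModel, t: float,
) -> np.ndarray:
    """Vectorized augmentation integral for a set of trial subjects."""
    h_t = out.survival(t, Xo)
    jump = (delta == 0) & (U <= t)
    result = np.zeros(U.size)
    if jump.any():
        h_u_own = _floor(out.survival(U[jump], Xo[jump]))
        k_left_own = _floor(cens.survival(U[jump], Xc[jump], side="left"))
        result[jump] = h_t[jump] / (h_u_own * k_left_own)
    # compensator over the censoring-baseline jump set up to min(U_i, t)
    use = cens.jump_times <= t
    if use.any():
        jt = cens.jump_times[use]
        dlam = cens.jump_increments[use]
        ehat = np.exp(cens.linear_predictor(Xc))
        h_grid = _floor(out.survival_matrix(jt, Xo))
        k_grid = _floor(cens.survival_matrix(jt, Xc, side="left"))
        at_risk = U[:, None] >= jt[None, :]
        comp = (at_risk * (dlam[None, :] / (h_grid * k_grid))).sum(axis=1)
        result -= ehat * h_t * comp
    return result


def _dr_trial_term(
    sample: CombinedSample,
    cens: CensoringModel,
    out: OutcomeModel,
    a: int,
    t: float,
) -> np.ndarray:
    """Per-subject residual + augmentation term for arm-a trial records:
    {I(U>=t) - K(t|X)H(t|X)}/K(t|X) + int H(t)/H(u) dM(u)/K(u)."""
    mask = sample.arm(a)
    U, d = sample.U[mask], sample.delta[mask]
    Xc = sample.design_matrix(cens.covariate_names)[mask]
    Xo = sample.design_matrix(out.covariate_names)[mask]
    k_t = _floor(cens.survival(t, Xc))
    h_t = out.survival(t, Xo)
    resid = ((U >= t) - k_t * h_t) / k_t
    aug = _augmentation(U, d, Xc, Xo, cens, out, t)
    return resid + aug


def _survey_weight_total(sample: CombinedSample) -> float:
    total = float(sample.w_survey[sample.survey].sum())
    if total <= 0:
        raise EstimationError("survey-weight total is zero")
    return total


def _finalize(
    estimator: str,
    sample: CombinedSample,
    times: np.ndarray,
    S1: np.ndarray,
    S0: np.ndarray,
    nuisances: NuisanceSet,
    level: float,
    var_fn=None,
    provenance: dict | None = None,
) -> SurvivalCurveEstimate:
    from . import inference  # local import to avoid a cycle

    delta = S1 - S0
    se = np.full(times.size, np.nan)
    lo = np.full(times.size, np.nan)
    hi = np.full(times.size, np.nan)
    est = SurvivalCurveEstimate(
        estimator=estimator, times=times, S1=S1, S0=S0, delta=delta,
        se=se, ci_lo=lo, ci_hi=hi,
        out_of_range=(S1 < 0) | (S1 > 1) | (S0 < 0) | (S0 > 1),
        provenance=provenance or {},
    )
    if var_fn is not None:
        for j, t in enumerate(times):
            v = var_fn(sample, est, nuisances, float(t))
            se[j] = np.sqrt(v)
            lo[j], hi[j] = inference.wald_ci(delta[j], v, level)
    return est


def _as_times(times) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise EstimationError("analysis times must be nonnegative")
    return times


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def estimate_ipw1(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    censoring_models: dict[int, CensoringModel],
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Horvitz-Thompson-type weighting estimator (unnormalized trial weights,
    normalized by the survey-weight total)."""
    from .inference import var_ipw1

    times = _as_times(times)
    W = _survey_weight_total(sample)
    S = {a: np.empty(times.size) for a in (0, 1)}
    for a in (0, 1):
        tau = _tau_arm(sample, omega_hat, a)
        for j, t in enumerate(times):
            ipcw = _ipcw_term(sample, censoring_models[a], a, float(t))
            S[a][j] = np.sum(tau * ipcw) / (_pi_a(sample, a) * W)
    nu = NuisanceSet(omega=np.asarray(omega_hat, dtype=float), censoring=dict(censoring_models))
    return _finalize("IPW1", sample, times, S[1], S[0], nu, level, var_ipw1)


def estimate_ipw2(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    censoring_models: dict[int, CensoringModel],
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Self-normalized (Hajek-type) weighting estimator; free of pi and of the
    survey weights except through the fitted sampling score."""
    from .inference import var_ipw2

    times = _as_times(times)
    S = {a: np.empty(times.size) for a in (0, 1)}
    for a in (0, 1):
        tau = _tau_arm(sample, omega_hat, a)
        tau_sum = tau.sum()
        if tau_sum <= 0:
            raise EstimationError(f"arm {a} has zero total inverse-odds weight")
        for j, t in enumerate(times):
            ipcw = _ipcw_term(sample, censoring_models[a], a, float(t))
            S[a][j] = np.sum(tau * ipcw) / tau_sum
    nu = NuisanceSet(omega=np.asarray(omega_hat, dtype=float), censoring=dict(censoring_models))
    return _finalize("IPW2", sample, times, S[1], S[0], nu, level, var_ipw2)


def estimate_om(
    sample: CombinedSample,
    outcome_models: dict[int, OutcomeModel],
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Outcome-regression estimator: survey-weighted mean of H_a(t|X) over the
    target-population sample. No variance formula is attached (SE is NaN)."""
    times = _as_times(times)
    W = _survey_weight_total(sample)
    surv = sample.survey
    w = sample.w_survey[surv]
    S = {}
    for a in (0, 1):
        out = outcome_models[a]
        Xs = sample.design_matrix(out.covariate_names)[surv]
        H = out.survival_matrix(times, Xs)
        S[a] = (w[:, None] * H).sum(axis=0) / W
    nu = NuisanceSet(outcome=dict(outcome_models))
    return _finalize("OM", sample, times, S[1], S[0], nu, level, None)


def estimate_dr1(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    censoring_models: dict[int, CensoringModel],
    outcome_models: dict[int, OutcomeModel],
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Augmented (doubly robust) estimator normalized by the survey-weight
    total; survey weights enter the score fit, the normalization and the
    outcome-regression term."""
    from .inference import var_dr1

    times = _as_times(times)
    W = _survey_weight_total(sample)
    surv = sample.survey
    w = sample.w_survey[surv]
    S = {a: np.empty(times.size) for a in (0, 1)}
    for a in (0, 1):
        tau = _tau_arm(sample, omega_hat, a)
        out = outcome_models[a]
        Xs = sample.design_matrix(out.covariate_names)[surv]
        for j, t in enumerate(times):
            trial_term = _dr_trial_term(sample, censoring_models[a], out, a, float(t))
            om_term = np.sum(w * out.survival(float(t), Xs))
            S[a][j] = (np.sum(tau * trial_term) / _pi_a(sample, a) + om_term) / W
    nu = NuisanceSet(
        omega=np.asarray(omega_hat, dtype=float),
        censoring=dict(censoring_models), outcome=dict(outcome_models),
    )
    return _finalize("DR1", sample, times, S[1], S[0], nu, level, var_dr1)


def dr2_decomposition(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    censoring_models: dict[int, CensoringModel],
    outcome_models: dict[int, OutcomeModel],
    a: int,
    t: float,
) -> tuple[float, float]:
    """The (nu1, nu2) split of the DR2 estimator for arm ``a`` at time ``t``:
    nu1 is the self-normalized weighting part, nu2 the survey-weighted
    outcome-regression part; their sum is the DR2 point estimate."""
    tau = _tau_arm(sample, omega_hat, a)
    tau_sum = tau.sum()
    if tau_sum <= 0:
        raise EstimationError(f"arm {a} has zero total inverse-odds weight")
    trial_term = _dr_trial_term(sample, censoring_models[a], outcome_models[a], a, t)
    nu1 = float(np.sum(tau * trial_term) / tau_sum)
    surv = sample.survey
    w = sample.w_survey[surv]
    Xs = sample.design_matrix(outcome_models[a].covariate_names)[surv]
    nu2 = float(np.sum(w * outcome_models[a].survival(t, Xs)) / w.sum())
    return nu1, nu2


def estimate_dr2(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    censoring_models: dict[int, CensoringModel],
    outcome_models: dict[int, OutcomeModel],
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Self-normalized doubly robust estimator (pi cancels); survey weights
    enter the score fit and the outcome-regression term only."""
    from .inference import var_dr2

    times = _as_times(times)
    S = {a: np.empty(times.size) for a in (0, 1)}
    for a in (0, 1):
        for j, t in enumerate(times):
            nu1, nu2 = dr2_decomposition(
                sample, omega_hat, censoring_models, outcome_models, a, float(t)
            )
            S[a][j] = nu1 + nu2
    nu = NuisanceSet(
        omega=np.asarray(omega_hat, dtype=float),
        censoring=dict(censoring_models), outcome=dict(outcome_models),
    )
    return _finalize("DR2", sample, times, S[1], S[0], nu, level, var_dr2)


# ---------------------------------------------------------------------------
# weighted Kaplan-Meier reference
# ---------------------------------------------------------------------------

def _wkm_arm(U, d, w, times):
    """Weighted Kaplan-Meier curve S(t-) (product over event times u < t) and
    its influence-function variance with weights treated as known."""
    order = np.argsort(U, kind="stable")
    Us, ds, ws = U[order], d[order], w[order]
    ev_times = np.unique(Us[ds == 1])
    # weighted risk set and event mass at each event time
    Yw = np.array([ws[Us >= u].sum() for u in ev_times])
    dNw = np.array([ws[(Us == u) & (ds == 1)].sum() for u in ev_times])
    haz = dNw / Yw
    surv_steps = np.cumprod(1.0 - haz)

    S_out = np.empty(len(times))
    var_out = np.empty(len(times))
    # per-subject compensator lookup: G(x) = sum_{u <= x} dLambda(u)/Yw(u)
    cum_dl_over_y = np.cumsum(haz / Yw)

    for j, t in enumerate(times):
        k = np.searchsorted(ev_times, t, side="left")  # events strictly before t
        S = surv_steps[k - 1] if k > 0 else 1.0
        S_out[j] = S
        if k == 0:
            var_out[j] = 0.0
            continue
        # influence of each subject on the cumulative hazard before t
        own_event = (ds == 1) & (Us < t)
        pos_own = np.searchsorted(ev_times, Us, side="right") - 1
        term1 = np.where(own_event, ws / Yw[np.clip(pos_own, 0, None)], 0.0)
        # compensator: sum over u < t with u <= U_i
        upto = np.minimum(np.searchsorted(ev_times[:k], Us, side="right"), k)
        comp = ws * np.where(upto > 0, cum_dl_over_y[np.clip(upto - 1, 0, None)], 0.0)
        psi = term1 - comp
        var_out[j] = S**2 * np.sum(psi**2)
    return S_out, var_out


def estimate_wkm(
    sample: CombinedSample,
    omega_hat: np.ndarray,
    times,
    level: float = 0.95,
) -> SurvivalCurveEstimate:
    """Inverse-odds-weighted Kaplan-Meier per arm (no censoring-model
    adjustment), with a sandwich variance treating the weights as known."""
    from .inference import wald_ci

    times = _as_times(times)
    S = {}
    V = {}
    for a in (0, 1):
        mask = sample.arm(a)
        if not mask.any():
            raise EstimationError(f"no trial records in arm {a}")
        tau = _tau_arm(sample, omega_hat, a)
        S[a], V[a] = _wkm_arm(sample.U[mask], sample.delta[mask].astype(int), tau, times)
    delta = S[1] - S[0]
    var = V[1] + V[0]
    se = np.sqrt(var)
    lo = np.empty(times.size)
    hi = np.empty(times.size)
    for j in range(times.size):
        lo[j], hi[j] = wald_ci(delta[j], var[j], level)
    return SurvivalCurveEstimate(
        estimator="WKM", times=times, S1=S[1], S0=S[0], delta=delta,
        se=se, ci_lo=lo, ci_hi=hi,
        out_of_range=np.zeros(times.size, dtype=bool),
        provenance={"weights": "inverse odds of sampling"},
    )
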