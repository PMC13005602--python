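"""Per-arm censoring and failure-time models on trial data.

Censoring is modeled with an arm-specific Cox proportional-hazards model
(censoring treated as the event) whose baseline cumulative hazard is the
Breslow step estimator; the outcome can be modeled with a Cox model or a
parametric accelerated failure time (AFT) family. Both expose the conditional
survival functions K_a(t|X) and H_a(t|X) that every estimator consumes.

Conventions: Breslow handling of ties; evaluation at a subject's own observed
time uses the left-continuous version (side="left"); the baseline is carried
flat beyond its largest jump.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dataio import CombinedSample
from .exceptions import FittingError

logger = logging.getLogger(__name__)

#: floor for conditional survival values entering denominators
SURV_FLOOR = 1e-8

AFT_FAMILIES = {
    "lognormal": stats.norm,       # log T = mu + sigma * N(0,1)
    "weibull": stats.gumbel_l,     # standard minimum extreme value residual
    "loglogistic": stats.logistic,
}


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties) + Breslow baseline
# ---------------------------------------------------------------------------

def _cox_newton(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 100,
):
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Returns (beta, jump_times, jump_increments, cov): the Breslow baseline
    cumulative-hazard jumps at the unique event times and the inverse observed
    information at beta-hat.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    t, d, Xs = time[order], event[order].astype(bool), X[order]
    ev = np.flatnonzero(d)
    if ev.size == 0:
        raise FittingError("no events to fit a Cox model on")
    # first index of the risk set {j : t_j >= t_i} for each event
    start = np.searchsorted(t, t[ev], side="left")

    beta = np.zeros(p)
    loglik = -np.inf
    grad_tol = tol * max(1.0, ev.size)  # score components scale with events
    for _ in range(max_iter):
        eta = Xs @ beta
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1]
        s0 = S0[start]
        new_loglik = float(np.sum(eta[ev] - np.log(s0)))
        if p == 0:
            break
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        XX = Xs[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1]
        xbar = S1[start] / s0[:, None]
        grad = (Xs[ev] - xbar).sum(axis=0)
        if np.max(np.abs(grad)) < grad_tol and new_loglik >= loglik - 1e-12:
            loglik = new_loglik
            break
        hess = (S2[start] / s0[:, None, None]).sum(axis=0) - xbar.T @ xbar
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise FittingError(f"singular Cox information matrix: {err}") from err
        # step-halving to guarantee ascent
        shrink = 1.0
        for _ in range(30):
            cand = beta + shrink * step
            eta_c = Xs @ cand
            S0_c = np.cumsum(np.exp(eta_c)[::-1])[::-1]
            ll_c = float(np.sum(eta_c[ev] - np.log(S0_c[start])))
            if np.isfinite(ll_c) and ll_c >= new_loglik - 1e-12:
                break
            shrink *= 0.5
        else:
            raise FittingError("Cox step-halving failed; partial likelihood not increasing")
        beta = cand
        loglik = ll_c
        if not np.isfinite(beta).all() or np.max(np.abs(beta)) > 1e3:
            raise FittingError("divergent Cox coefficients; possible monotone likelihood")
        if np.max(np.abs(shrink * step)) < 1e-12:
            break  # parameter change below float resolution
    else:
        raise FittingError(f"Cox fit did not converge in {max_iter} iterations")

    # Breslow baseline at beta-hat: jump d_u / S0(u) at each unique event time
    eta = Xs @ beta
    w = np.exp(eta)
    S0 = np.cumsum(w[::-1])[::-1]
    ev_times = t[ev]
    uniq, first = np.unique(ev_times, return_index=True)
    counts = np.diff(np.append(first, ev_times.size))
    s0_u = S0[np.searchsorted(t, uniq, side="left")]
    increments = counts / s0_u

    if p:
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        XX = Xs[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum((w[:, None, None] * XX)[::-1], axis=0)[::-1]
        xbar = S1[start] / S0[start][:, None]
        info = (S2[start] / S0[start][:, None, None]).sum(axis=0) - xbar.T @ xbar
        cov = np.linalg.inv(info)
    else:
        cov = np.zeros((0, 0))
    return beta, uniq, increments, cov


@dataclass
class _CoxSurvival:
    """Conditional survival from a Cox fit: exp(-Lambda0(t) * exp(X beta))."""

    beta: np.ndarray
    jump_times: np.ndarray
    jump_increments: np.ndarray
    covariate_names: list[str]
    cov: np.ndarray | None = None
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._cum = np.concatenate([[0.0], np.cumsum(self.jump_increments)])

    def cumulative_baseline(self, t, side: str = "right") -> np.ndarray:
        """Lambda0 at t (right-continuous) or t- (left). Flat beyond last jump."""
        kind = "left" if side == "left" else "right"
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side=kind)
        return self._cum[idx]

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.beta.size == 0:
            return np.zeros(X.shape[0])
        return X @ self.beta

    def survival(self, t, X, side: str = "right") -> np.ndarray:
        """S(t|X); scalar t broadcasts over rows of X, vector t is elementwise."""
        lam0 = self.cumulative_baseline(t, side)
        return np.exp(-np.atleast_1d(lam0) * np.exp(self.linear_predictor(X)))

    def survival_matrix(self, times, X, side: str = "right") -> np.ndarray:
        """S(t|X) on the grid ``times`` for every row of X; shape (len(X), len(times))."""
        lam0 = self.cumulative_baseline(np.asarray(times, dtype=float), side)
        return np.exp(-np.outer(np.exp(self.linear_predictor(X)), lam0))


@dataclass
class CensoringModel(_CoxSurvival):
    """Arm-specific Cox model for the censoring time with Breslow baseline."""

    arm: int = 0
    degenerate: bool = False  # no censoring events: K identically 1


def fit_censoring_model(
    sample: CombinedSample, arm: int, covariates: list[str] | None = None
) -> CensoringModel:
    """Fit the censoring Cox model in trial arm ``arm`` (censoring is the event).

    With no censoring events the model degenerates to K = 1 with a warning.
    """
    if covariates is None:
        covariates = sample.covariate_names
    covariates = list(covariates)
    mask = sample.arm(arm)
    time = sample.U[mask]
    cens_event = 1.0 - sample.delta[mask]
    X = sample.design_matrix(covariates)[mask] if covariates else np.empty((mask.sum(), 0))
    if cens_event.sum() == 0:
        logger.warning("arm %d has no censoring events; censoring survival fixed at 1", arm)
        return CensoringModel(
            beta=np.zeros(len(covariates)), jump_times=np.empty(0),
            jump_increments=np.empty(0), covariate_names=covariates,
            arm=arm, degenerate=True,
        )
    beta, jumps, incr, cov = _cox_newton(time, cens_event, X)
    return CensoringModel(
        beta=beta, jump_times=jumps, jump_increments=incr,
        covariate_names=covariates, arm=arm, cov=cov,
    )


def censoring_survival(model: CensoringModel, t, X, side: str = "right") -> np.ndarray:
    """K_a(t|X) (side="right") or its left limit K_a(t-|X) (side="left")."""
    return model.survival(t, X, side=side)


@dataclass
class OutcomeModel:
    """Arm-specific failure-time model: Cox (Breslow baseline) or parametric AFT."""

    arm: int
    family: str  # "cox", "lognormal", "weibull", "loglogistic"
    covariate_names: list[str]
    cox: _CoxSurvival | None = None
    gamma0: float | None = None
    gamma1: np.ndarray | None = None
    sigma: float | None = None

    def _aft_z(self, logt, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        mu = self.gamma0 + (X @ self.gamma1 if self.gamma1.size else 0.0)
        return (logt - mu) / self.sigma

    def survival(self, t, X, side: str = "right") -> np.ndarray:
        """H_a(t|X). ``side`` only matters for the step-function Cox family."""
        if self.family == "cox":
            return self.cox.survival(t, X, side=side)
        t = np.atleast_1d(np.asarray(t, dtype=float))
        with np.errstate(divide="ignore"):
            logt = np.log(t)
        return AFT_FAMILIES[self.family].sf(self._aft_z(logt, X))

    def survival_matrix(self, times, X, side: str = "right") -> np.ndarray:
        if self.family == "cox":
            return self.cox.survival_matrix(times, X, side=side)
        times = np.asarray(times, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        mu = self.gamma0 + (X @ self.gamma1 if self.gamma1.size else np.zeros(X.shape[0]))
        with np.errstate(divide="ignore"):
            z = (np.log(times)[None, :] - mu[:, None]) / self.sigma
        return AFT_FAMILIES[self.family].sf(z)


def _fit_aft(time, event, X, family: str):
    """Right-censored maximum likelihood for a location-scale AFT family."""
    dist = AFT_FAMILIES[family]
    n, p = X.shape
    logt = np.log(time)
    ev = event.astype(bool)
    design = np.column_stack([np.ones(n), X])
    # least-squares warm start on the events
    coef0, *_ = np.linalg.lstsq(design[ev], logt[ev], rcond=None)
    resid = logt[ev] - design[ev] @ coef0
    sigma0 = max(float(np.std(resid)), 1e-2)
    x0 = np.concatenate([coef0, [np.log(sigma0)]])

    def negloglik(par):
        mu = design @ par[:-1]
        sigma = np.exp(par[-1])
        z = (logt - mu) / sigma
        ll = np.sum(dist.logpdf(z[ev]) - par[-1]) + np.sum(dist.logsf(z[~ev]))
        return -ll

    bounds = [(None, None)] * (p + 1) + [(np.log(1e-4), np.log(1e4))]
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
    if not res.success and res.status != 2:  # status 2: precision loss, usually converged
        raise FittingError(f"{family} AFT fit failed: {res.message}")
    par = res.x
    return float(par[0]), par[1:-1].copy(), float(np.exp(par[-1]))


def fit_outcome_model(
    sample: CombinedSample,
    arm: int,
    covariates: list[str] | None = None,
    family: str = "cox",
) -> OutcomeModel:
    """Fit the failure-time model for arm ``arm`` on trial data.

    ``family`` selects the Cox partial likelihood (with Breslow baseline on the
    failure events) or a parametric AFT maximum-likelihood fit with right
    censoring (lognormal / weibull / loglogistic residual laws).
    """
    if family != "cox" and family not in AFT_FAMILIES:
        raise ValueError(f"unknown outcome family {family!r}")
    if covariates is None:
        covariates = sample.covariate_names
    covariates = list(covariates)
    mask = sample.arm(arm)
    time = sample.U[mask]
    event = sample.delta[mask]
    if event.sum() == 0:
        raise FittingError(f"arm {arm} has no failure events")
    X = sample.design_matrix(covariates)[mask] if covariates else np.empty((int(mask.sum()), 0))
    if family == "cox":
        beta, jumps, incr, cov = _cox_newton(time, event, X)
        cox = _CoxSurvival(
            beta=beta, jump_times=jumps, jump_increments=incr,
            covariate_names=covariates, cov=cov,
        )
        return OutcomeModel(arm=arm, family="cox", covariate_names=covariates, cox=cox)
    g0, g1, sigma = _fit_aft(time, event, X, family)
    return OutcomeModel(
        arm=arm, family=family, covariate_names=covariates,
        gamma0=g0, gamma1=g1, sigma=sigma,
    )
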