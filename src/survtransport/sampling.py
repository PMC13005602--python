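"""Survey-weighted logistic sampling-score model, inverse-odds weights and
covariate-balance diagnostics.

The sampling score omega(X) = P(S=1|X) is fit by weighted logistic regression
with case weight ``w_survey`` for survey records and 1 for trial records. Trial
records are reweighted toward the target population with the inverse odds
tau = (1 - omega)/omega, and the fit is diagnosed with survey-weighted
standardized mean differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import CombinedSample
from .exceptions import EstimationError, FittingError

logger = logging.getLogger(__name__)

#: floor applied to fitted sampling scores before forming odds
OMEGA_FLOOR = 1e-8


@dataclass
class SamplingScoreModel:
    """Fitted weighted-logistic sampling-score model.

    ``theta`` stacks the intercept first, then one slope per entry of
    ``covariate_names``.
    """

    theta: np.ndarray
    covariate_names: list[str]
    converged: bool
    max_abs_score: float
    n_iter: int = 0

    def predict(self, X) -> np.ndarray:
        """Sampling score omega(X) in (0,1) for a covariate matrix/frame."""
        if isinstance(X, pd.DataFrame):
            X = X[self.covariate_names].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = self.theta[0] + X @ self.theta[1:]
        return expit(eta)

    def predict_sample(self, sample: CombinedSample) -> np.ndarray:
        return self.predict(sample.X)


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(design.shape[1]):
            rest = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(rest) == r:
                collinear.append(names[j])
        raise FittingError(f"design matrix rank-deficient; collinear columns: {collinear}")


def fit_sampling_score(
    sample: CombinedSample,
    covariates: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> SamplingScoreModel:
    """Fit omega(X) by iteratively reweighted least squares.

    The pseudo log-likelihood uses case weight w_survey for S=0 records and 1
    for S=1 records; convergence requires the largest absolute component of the
    weighted score to fall below ``tol``.
    """
    if covariates is None:
        covariates = sample.covariate_names
    covariates = list(covariates)
    y = sample.S.astype(float)
    w = np.where(sample.trial, 1.0, sample.w_survey)
    Xc = sample.design_matrix(covariates) if covariates else np.empty((y.size, 0))
    design = np.column_stack([np.ones(y.size), Xc])
    names = ["(intercept)", *covariates]
    _check_rank(design, names)

    theta = np.zeros(design.shape[1])
    converged = False
    it = 0
    score_max = np.inf
    for it in range(1, max_iter + 1):
        p = expit(design @ theta)
        score = design.T @ (w * (y - p))
        score_max = float(np.max(np.abs(score)))
        if score_max < tol:
            converged = True
            break
        wt = w * p * (1.0 - p)
        hess = design.T @ (design * wt[:, None])
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate
            raise FittingError(f"singular IRLS system at iteration {it}: {err}") from err
        if not np.isfinite(step).all():
            raise FittingError("non-finite IRLS step; possible separation")
        theta = theta + step
        if np.max(np.abs(theta)) > 1e3:
            raise FittingError(
                f"divergent coefficients (max |theta| > 1e3) at iteration {it}; "
                "likely complete separation"
            )
    if not converged:
        raise FittingError(
            f"weighted logistic fit did not converge in {max_iter} iterations "
            f"(max |score| = {score_max:.3g})"
        )
    p = expit(design @ theta)
    boundary = (p[y == 1].min() >= 1 - 1e-8) and (p[y == 0].max() <= 1e-8)
    if boundary or np.max(np.abs(theta)) > 30:
        raise FittingError(
            "fitted probabilities at the boundary; likely complete separation"
        )
    return SamplingScoreModel(
        theta=theta, covariate_names=covariates, converged=True,
        max_abs_score=score_max, n_iter=it,
    )


def inverse_odds_weights(
    model: SamplingScoreModel,
    sample: CombinedSample,
    truncate_pct: float | None = None,
) -> np.ndarray:
    """Inverse-odds-of-sampling weights tau_i = (1-omega_i)/omega_i for trial records.

    When ``truncate_pct`` is given, trial sampling scores below that percentile
    of the trial score distribution are floored at the percentile value before
    forming odds. Returns an array aligned with the trial (S=1) records.
    """
    omega = model.predict_sample(sample)[sample.trial]
    return inverse_odds_from_scores(omega, truncate_pct)


def inverse_odds_from_scores(
    omega: np.ndarray, truncate_pct: float | None = None
) -> np.ndarray:
    """Form tau = (1-omega)/omega from trial sampling scores, with optional
    percentile truncation of the scores."""
    omega = np.asarray(omega, dtype=float).copy()
    if truncate_pct is not None:
        if not (0 <= truncate_pct <= 50):
            raise ValueError("truncate_pct must lie in [0, 50]")
        # 'higher' keeps the floor on an observed score value
        floor = np.percentile(omega, truncate_pct, method="higher")
        omega = np.maximum(omega, floor)
    if np.any(omega <= OMEGA_FLOOR):
        logger.warning(
            "%d sampling score(s) at or below %.0e floored before forming odds",
            int((omega <= OMEGA_FLOOR).sum()), OMEGA_FLOOR,
        )
        omega = np.maximum(omega, OMEGA_FLOOR)
    return (1.0 - omega) / omega


@dataclass
class BalanceTable:
    """Per-covariate standardized mean differences before/after weighting."""

    table: pd.DataFrame  # columns: covariate, smd_unweighted, smd_weighted, target_sd, flag_0.1, flag_0.2

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _weighted_target_sd(x: np.ndarray, w: np.ndarray) -> float:
    """Survey-weighted SD of a covariate in the target population.

    Uses the design-weighted variance with denominator
    sum(w) - sum(w^2)/sum(w); reduces to the ordinary (n-1) sample SD when all
    weights are equal.
    """
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    denom = sw - np.sum(w**2) / sw
    if denom <= 0:
        return np.nan
    return float(np.sqrt(np.sum(w * (x - xbar) ** 2) / denom))


def smd_table(
    sample: CombinedSample,
    tau: np.ndarray | None = None,
    covariates: list[str] | None = None,
) -> BalanceTable:
    """Standardized mean differences between the (tau-weighted) trial and the
    survey-weighted target population.

    SMD_k = |weighted trial mean - survey-weighted target mean| / s_k, with s_k
    the survey-weighted target-population standard deviation. ``tau`` must be
    aligned with the S=1 records; ``None`` compares the unweighted trial.
    """
    if covariates is None:
        covariates = sample.covariate_names
    trial = sample.trial
    n = sample.n
    if tau is None:
        tau = np.ones(n)
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (n,):
        raise EstimationError(f"tau has shape {tau.shape}, expected ({n},)")
    w_t = sample.w_survey[sample.survey]

    rows = []
    for name in covariates:
        x = sample.X[name].to_numpy(dtype=float)
        x_trial, x_target = x[trial], x[sample.survey]
        target_mean = np.sum(w_t * x_target) / w_t.sum()
        s = _weighted_target_sd(x_target, w_t)
        if not np.isfinite(s) or s <= 0:
            logger.warning("covariate %s has zero target-population variance; SMD undefined", name)
            rows.append((name, np.nan, np.nan, np.nan, False, False))
            continue
        smd_unw = abs(x_trial.mean() - target_mean) / s
        smd_w = abs(np.sum(tau * x_trial) / tau.sum() - target_mean) / s
        rows.append((name, smd_unw, smd_w, s, smd_w > 0.1, smd_w > 0.2))
    table = pd.DataFrame(
        rows,
        columns=["covariate", "smd_unweighted", "smd_weighted", "target_sd", "flag_0.1", "flag_0.2"],
    )
    return BalanceTable(table=table)
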