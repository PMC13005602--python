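"""Synthetic combined-sample generator and oracle truth.

The generator draws a population of covariates X1,X2 ~ N(0,1),
X3 ~ Bernoulli(0.5), selects trial participants through a logistic model in X,
selects a survey of the nonparticipants through a second logistic model
(records carry the true inverse inclusion probability as survey weight),
randomizes treatment within the trial, and produces right-censored
exponential-baseline Cox failure times under two censoring mechanisms
(covariate-dependent Cox, or Uniform(0, b)). The oracle computes the true
counterfactual survival functions in the target population by Monte Carlo
integration over the covariate law weighted by P(S=0|X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dataio import CombinedSample

#: weak/strong trial-selection coefficient presets
THETA_WEAK = (-6.5, -0.2, -0.1, -0.5)
THETA_STRONG = (-6.7, -0.8, -0.4, -1.0)
#: survey-inclusion coefficients
XI = (-7.0, 0.3, 0.4, 0.2)
#: per-arm log-hazard coefficients on (X1, X2, X3), unit exponential baseline
OUTCOME_LOGHAZ = {1: (0.2, -0.6, 0.6), 0: (0.2, 0.6, -0.6)}
#: covariate-dependent censoring log-hazard coefficients
CENSORING_LOGHAZ = (0.1, 0.4, -0.6)
#: upper bound of the random (uniform) censoring mechanism
UNIFORM_BOUND = 2.1


@dataclass(frozen=True)
class Scenario:
    """Data-generating-process parameters for one simulation scenario."""

    theta: tuple[float, ...]
    xi: tuple[float, ...] = XI
    outcome_loghaz: tuple[tuple[float, ...], tuple[float, ...]] = (
        OUTCOME_LOGHAZ[0],
        OUTCOME_LOGHAZ[1],
    )  # indexed by arm
    censoring_kind: str = "cox"  # "cox" or "uniform"
    censoring_loghaz: tuple[float, ...] = CENSORING_LOGHAZ
    uniform_bound: float = UNIFORM_BOUND
    population_size: int = 1_000_000
    pi: float = 0.5
    seed: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValueError("pi must lie in (0,1)")
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.censoring_kind not in ("cox", "uniform"):
            raise ValueError(f"unknown censoring mechanism {self.censoring_kind!r}")
        if self.censoring_kind == "uniform" and self.uniform_bound <= 0:
            raise ValueError("uniform censoring bound must be positive")


def preset_scenario(sampling: str = "weak", censoring: str = "cox", **overrides) -> Scenario:
    """Named scenario presets: sampling in {weak, strong}, censoring in
    {cox, uniform}; population 1e6 and pi = 0.5."""
    thetas = {"weak": THETA_WEAK, "strong": THETA_STRONG}
    if sampling not in thetas:
        raise ValueError(f"unknown sampling preset {sampling!r}; expected weak|strong")
    if censoring not in ("cox", "uniform"):
        raise ValueError(f"unknown censoring preset {censoring!r}; expected cox|uniform")
    kwargs = dict(
        theta=thetas[sampling],
        censoring_kind=censoring,
        name=f"{sampling}-{censoring}",
    )
    kwargs.update(overrides)
    return Scenario(**kwargs)


def _draw_covariates(rng: np.random.Generator, size: int) -> np.ndarray:
    X = np.empty((size, 3))
    X[:, 0] = rng.standard_normal(size)
    X[:, 1] = rng.standard_normal(size)
    X[:, 2] = rng.random(size) < 0.5
    return X


def _logistic_prob(coefs, X) -> np.ndarray:
    c = np.asarray(coefs, dtype=float)
    return expit(c[0] + X @ c[1:])


def generate(scenario: Scenario, seed: int | None = None) -> CombinedSample:
    """Draw one combined trial + survey sample from the scenario.

    The master seed spawns independent substreams for the population
    covariates, trial/survey selection, treatment assignment, failure times
    and censoring times, so replications are coupled across scenarios sharing
    a seed.
    """
    if seed is None:
        seed = scenario.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(5)]
    rng_pop, rng_sel, rng_trt, rng_fail, rng_cens = streams

    N = scenario.population_size
    X = _draw_covariates(rng_pop, N)
    pS = _logistic_prob(scenario.theta, X)
    S = rng_sel.random(N) < pS

    # survey selection among nonparticipants; weight = true 1/P(D=1|X)
    pD = _logistic_prob(scenario.xi, X)
    D = (~S) & (rng_sel.random(N) < pD)

    keep = S | D
    Xk = X[keep]
    Sk = S[keep].astype(int)
    w = np.where(Sk == 1, 1.0, 1.0 / pD[keep])

    n = int(Sk.sum())
    trial = Sk == 1
    A = np.full(keep.sum(), np.nan)
    U = np.full(keep.sum(), np.nan)
    delta = np.full(keep.sum(), np.nan)

    A_tr = (rng_trt.random(n) < scenario.pi).astype(float)
    Xt = Xk[trial]
    loghaz = np.where(
        A_tr[:, None] == 1,
        np.asarray(scenario.outcome_loghaz[1]),
        np.asarray(scenario.outcome_loghaz[0]),
    )
    lam = np.exp((Xt * loghaz).sum(axis=1))
    T = rng_fail.exponential(1.0, n) / lam
    if scenario.censoring_kind == "cox":
        lam_c = np.exp(Xt @ np.asarray(scenario.censoring_loghaz))
        C = rng_cens.exponential(1.0, n) / lam_c
    else:
        C = rng_cens.uniform(0.0, scenario.uniform_bound, n)

    A[trial] = A_tr
    U[trial] = np.minimum(T, C)
    delta[trial] = (T <= C).astype(float)

    return CombinedSample(
        S=Sk,
        X=pd.DataFrame(Xk, columns=["X1", "X2", "X3"]),
        A=A,
        U=U,
        delta=delta,
        w_survey=w,
        pi=scenario.pi,
    )


@dataclass
class TrueTaste:
    """Oracle counterfactual survival functions and TASTE in the target
    population, with Monte Carlo standard errors."""

    times: np.ndarray
    S1: np.ndarray
    S0: np.ndarray
    delta: np.ndarray
    mc_draws: int
    mc_se: np.ndarray


def true_taste(
    scenario: Scenario,
    times,
    mc_draws: int = 1_000_000,
    seed: int | None = None,
) -> TrueTaste:
    """Monte Carlo integration of the closed-form conditional survival over the
    covariate law, importance-weighted by P(S=0|X).

    With the unit exponential baseline, S_a(t|X) = exp(-t exp(coef_a' X)); the
    target estimand conditions on S=0 through the weight 1 - P(S=1|X).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    rng = np.random.default_rng(seed)
    X = _draw_covariates(rng, int(mc_draws))
    wq = 1.0 - _logistic_prob(scenario.theta, X)
    lam1 = np.exp(X @ np.asarray(scenario.outcome_loghaz[1]))
    lam0 = np.exp(X @ np.asarray(scenario.outcome_loghaz[0]))
    wsum = wq.sum()

    S1 = np.empty(times.size)
    S0 = np.empty(times.size)
    mc_se = np.empty(times.size)
    for j, t in enumerate(times):
        d = np.exp(-t * lam1) - np.exp(-t * lam0)
        S1[j] = np.sum(wq * np.exp(-t * lam1)) / wsum
        S0[j] = np.sum(wq * np.exp(-t * lam0)) / wsum
        dm = np.sum(wq * d) / wsum
        mc_se[j] = np.sqrt(np.sum(wq**2 * (d - dm) ** 2)) / wsum
    return TrueTaste(
        times=times, S1=S1, S0=S0, delta=S1 - S0, mc_draws=int(mc_draws), mc_se=mc_se
    )
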