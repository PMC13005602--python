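import numpy as np
import pandas as pd
import pytest

from survtransport import CombinedSample
from survtransport.nuisance import CensoringModel, OutcomeModel, _CoxSurvival


def make_sample(S, A, U, delta, X, w=None, pi=0.5):
    S = np.asarray(S)
    if w is None:
        w = np.ones(S.size)
    return CombinedSample(
        S=S, A=np.asarray(A, dtype=float), U=np.asarray(U, dtype=float),
        delta=np.asarray(delta, dtype=float), X=pd.DataFrame(X),
        w_survey=np.asarray(w, dtype=float), pi=pi,
    )


def degenerate_censoring(arm, covariates):
    """A censoring model with K identically 1."""
    return CensoringModel(
        beta=np.zeros(len(covariates)), jump_times=np.empty(0),
        jump_increments=np.empty(0), covariate_names=list(covariates),
        arm=arm, degenerate=True,
    )


def cox_outcome(arm, covariates, beta, jump_times, jump_increments):
    cox = _CoxSurvival(
        beta=np.asarray(beta, dtype=float),
        jump_times=np.asarray(jump_times, dtype=float),
        jump_increments=np.asarray(jump_increments, dtype=float),
        covariate_names=list(covariates),
    )
    return OutcomeModel(arm=arm, family="cox", covariate_names=list(covariates), cox=cox)


def cox_censoring(arm, covariates, beta, jump_times, jump_increments):
    return CensoringModel(
        beta=np.asarray(beta, dtype=float),
        jump_times=np.asarray(jump_times, dtype=float),
        jump_increments=np.asarray(jump_increments, dtype=float),
        covariate_names=list(covariates), arm=arm,
    )


@pytest.fixture
def four_row_csv(tmp_path):
    path = tmp_path / "sample.csv"
    path.write_text(
        "id,S,A,U,delta,w_survey,X1,X2\n"
        "1,1,1,2.0,1,1,0.5,-0.2\n"
        "2,1,0,1.5,0,1,-0.1,0.3\n"
        "3,0,,,,2.5,0.2,0.1\n"
        "4,0,,,,4.0,-0.4,0.6\n"
    )
    return path


@pytest.fixture
def saturated_sample():
    """Single binary covariate with cell counts (S=1,x=1)=2, (S=0,x=1)=2,
    (S=1,x=0)=1, (S=0,x=0)=3; all survey weights 1."""
    return make_sample(
        S=[1, 1, 1, 0, 0, 0, 0, 0],
        A=[1, 0, 1, *([np.nan] * 5)],
        U=[1.0, 2.0, 3.0, *([np.nan] * 5)],
        delta=[1, 1, 1, *([np.nan] * 5)],
        X={"x": [1, 1, 0, 1, 1, 0, 0, 0]},
    )


@pytest.fixture
def ten_record_sample():
    """Deterministic 10-record fixture with non-uniform survey weights,
    censoring, two covariates, and an asymmetric pi."""
    rng = np.random.default_rng(123)
    X = pd.DataFrame(
        {"X1": rng.normal(size=10).round(3), "X2": rng.normal(size=10).round(3)}
    )
    return CombinedSample(
        S=np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0]),
        A=np.array([1, 1, 1, 0, 0, 0, *([np.nan] * 4)]),
        U=np.array([0.4, 1.1, 2.3, 0.7, 1.6, 2.9, *([np.nan] * 4)]),
        delta=np.array([1, 0, 1, 0, 1, 1, *([np.nan] * 4)], dtype=float),
        X=X,
        w_survey=np.array([1, 1, 1, 1, 1, 1, 1.5, 2.0, 3.5, 5.0]),
        pi=0.4,
    )


@pytest.fixture
def ten_record_nuisances(ten_record_sample):
    """Hand-built fitted nuisances for the 10-record fixture: prescribed
    sampling scores, per-arm Cox censoring baselines and Cox outcome models."""
    rng = np.random.default_rng(7)
    omega = rng.uniform(0.15, 0.6, size=10)
    cens = {
        1: cox_censoring(1, ["X1", "X2"], [0.2, -0.1], [0.9, 1.8], [0.15, 0.3]),
        0: cox_censoring(0, ["X1", "X2"], [-0.3, 0.25], [0.5, 2.0], [0.2, 0.25]),
    }
    out = {
        1: cox_outcome(1, ["X1", "X2"], [0.3, -0.4], [0.4, 1.2, 2.2], [0.2, 0.25, 0.3]),
        0: cox_outcome(0, ["X1", "X2"], [-0.2, 0.35], [0.6, 1.5], [0.3, 0.35]),
    }
    return omega, cens, out


@pytest.fixture(scope="session")
def weak_cox_sample():
    """One simulated weak-sampling, Cox-censoring draw (shared, read-only)."""
    from survtransport import generate, preset_scenario

    return generate(preset_scenario("weak", "cox"), seed=42)


@pytest.fixture(scope="session")
def weak_cox_fits(weak_cox_sample):
    """Correctly specified nuisance fits on the shared simulated draw."""
    from survtransport import fit_censoring_model, fit_outcome_model, fit_sampling_score

    s = weak_cox_sample
    model = fit_sampling_score(s, ["X1", "X2", "X3"])
    omega = model.predict_sample(s)
    cens = {a: fit_censoring_model(s, a, ["X1", "X2", "X3"]) for a in (0, 1)}
    out = {a: fit_outcome_model(s, a, ["X1", "X2", "X3"], family="cox") for a in (0, 1)}
    return omega, cens, out
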