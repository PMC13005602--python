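"""Monte Carlo harness: run estimators across scenarios and
model-specification grids, summarizing Bias, ESD, ASE and coverage.

Each specification cell states whether the outcome, sampling-score and
censoring working models are correctly specified. Misspecification follows
the standard recipe: the incorrect sampling and censoring models drop X2 and
X3, and the incorrect outcome model swaps the Cox fit for a lognormal AFT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimators as est
from .dataio import CombinedSample
from .exceptions import EstimationError, FittingError
from .nuisance import fit_censoring_model, fit_outcome_model
from .sampling import fit_sampling_score
from .simulate import Scenario, generate, true_taste

logger = logging.getLogger(__name__)

ALL_COVARS = ["X1", "X2", "X3"]
SAMPLING_COVARS = {"correct": ALL_COVARS, "incorrect": ["X1"]}
CENSORING_COVARS = {"correct": ALL_COVARS, "incorrect": ["X1"]}
OUTCOME_FAMILY = {"correct": "cox", "incorrect": "lognormal"}


@dataclass(frozen=True)
class SpecGrid:
    """One model-specification cell: 'correct' / 'incorrect' per working model.

    ``None`` marks a model the estimator does not use (e.g. the outcome model
    for IPW estimators).
    """

    outcome_spec: str | None = "correct"
    sampling_spec: str | None = "correct"
    censoring_spec: str | None = "correct"

    def __post_init__(self) -> None:
        for name in ("outcome_spec", "sampling_spec", "censoring_spec"):
            v = getattr(self, name)
            if v is not None and v not in ("correct", "incorrect"):
                raise ValueError(f"{name} must be correct|incorrect|None, got {v!r}")

    def label(self, which: str) -> str:
        v = getattr(self, which)
        return {"correct": "T", "incorrect": "F", None: ""}[v]


def default_grid(estimator: str) -> list[SpecGrid]:
    """The specification cells reported for each estimator in the reference
    Monte Carlo tables."""
    tag = estimator.upper()
    if tag == "WKM":
        return [
            SpecGrid(outcome_spec=None, sampling_spec=s, censoring_spec=None)
            for s in ("correct", "incorrect")
        ]
    if tag in ("IPW1", "IPW2"):
        return [
            SpecGrid(outcome_spec=None, sampling_spec=s, censoring_spec=c)
            for s in ("correct", "incorrect")
            for c in ("correct", "incorrect")
        ]
    if tag in ("DR1", "DR2"):
        return [
            SpecGrid("correct", "correct", "correct"),
            SpecGrid("correct", "incorrect", "incorrect"),
            SpecGrid("incorrect", "correct", "correct"),
            SpecGrid("incorrect", "incorrect", "incorrect"),
        ]
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class SimulationSummary:
    """Per-(estimator, spec cell, time) Monte Carlo summary."""

    table: pd.DataFrame  # estimator, T_spec, S_spec, C_spec, t, bias, esd, ase, cp, n_reps, n_failed
    delta_true: dict[float, float]
    n_reps: int
    n_failed: int

    def lookup(self, estimator: str, t: float, **spec) -> pd.Series:
        """Fetch one summary row, e.g. lookup('DR1', 0.712, S_spec='T')."""
        q = (self.table["estimator"] == estimator) & np.isclose(self.table["t"], t)
        for k, v in spec.items():
            q &= self.table[k] == v
        rows = self.table[q]
        if len(rows) != 1:
            raise KeyError(f"expected 1 row for {estimator}, t={t}, {spec}; got {len(rows)}")
        return rows.iloc[0]


def _fit_cell_nuisances(sample: CombinedSample, needs: dict):
    """Fit each distinct nuisance specification once per replicate."""
    fits: dict = {"omega": {}, "cens": {}, "out": {}}
    for sspec in needs["sampling"]:
        model = fit_sampling_score(sample, SAMPLING_COVARS[sspec])
        fits["omega"][sspec] = model.predict_sample(sample)
    for cspec in needs["censoring"]:
        fits["cens"][cspec] = {
            a: fit_censoring_model(sample, a, CENSORING_COVARS[cspec]) for a in (0, 1)
        }
    for ospec in needs["outcome"]:
        fits["out"][ospec] = {
            a: fit_outcome_model(sample, a, ALL_COVARS, family=OUTCOME_FAMILY[ospec])
            for a in (0, 1)
        }
    return fits


def _evaluate(tag: str, cell: SpecGrid, sample: CombinedSample, fits: dict, times):
    omega = fits["omega"].get(cell.sampling_spec)
    cens = fits["cens"].get(cell.censoring_spec)
    outm = fits["out"].get(cell.outcome_spec)
    if tag == "WKM":
        e = est.estimate_wkm(sample, omega, times)
    elif tag == "IPW1":
        e = est.estimate_ipw1(sample, omega, cens, times)
    elif tag == "IPW2":
        e = est.estimate_ipw2(sample, omega, cens, times)
    elif tag == "DR1":
        e = est.estimate_dr1(sample, omega, cens, outm, times)
    elif tag == "DR2":
        e = est.estimate_dr2(sample, omega, cens, outm, times)
    else:
        raise ValueError(f"unknown estimator {tag!r}")
    return e.delta, e.se


def run_mc(
    scenario: Scenario,
    grid: list[SpecGrid] | None,
    estimators: list[str],
    times,
    n_reps: int = 500,
    master_seed: int = 0,
    delta_true: dict[float, float] | None = None,
    truth_draws: int = 1_000_000,
) -> SimulationSummary:
    """Run the Monte Carlo study.

    ``grid`` may be None, in which case each estimator uses its default cells;
    otherwise every estimator is run for every applicable cell. Replicates
    where any fit fails are dropped and counted. Summaries are on the raw
    scale; ``write_summary`` applies the x100 convention.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    tags = [t.upper() for t in estimators]

    tasks: list[tuple[str, SpecGrid]] = []
    for tag in tags:
        cells = default_grid(tag) if grid is None else _applicable_cells(tag, grid)
        tasks.extend((tag, cell) for cell in cells)

    needs = {
        "sampling": {c.sampling_spec for _, c in tasks if c.sampling_spec},
        "censoring": {c.censoring_spec for _, c in tasks if c.censoring_spec},
        "outcome": {c.outcome_spec for _, c in tasks if c.outcome_spec},
    }

    if delta_true is None:
        truth = true_taste(scenario, times, mc_draws=truth_draws, seed=master_seed + 10_007)
        delta_true = {float(t): float(d) for t, d in zip(times, truth.delta)}

    seeds = np.random.SeedSequence(master_seed).spawn(n_reps)
    deltas = np.full((n_reps, len(tasks), times.size), np.nan)
    ses = np.full_like(deltas, np.nan)
    ok = np.zeros(n_reps, dtype=bool)
    n_failed = 0
    for r in range(n_reps):
        try:
            sample = generate(scenario, seed=seeds[r])
            fits = _fit_cell_nuisances(sample, needs)
            for k, (tag, cell) in enumerate(tasks):
                deltas[r, k], ses[r, k] = _evaluate(tag, cell, sample, fits, times)
            ok[r] = True
        except (FittingError, EstimationError) as err:
            n_failed += 1
            logger.warning("replicate %d dropped: %s", r, err)

    if not ok.any():
        raise EstimationError("all Monte Carlo replicates failed")

    z = 1.959963984540054  # 97.5% normal quantile
    rows = []
    used = int(ok.sum())
    for k, (tag, cell) in enumerate(tasks):
        for j, t in enumerate(times):
            d = deltas[ok, k, j]
            s = ses[ok, k, j]
            dt = delta_true[float(t)]
            covers = (d - z * s <= dt) & (dt <= d + z * s)
            rows.append(
                {
                    "estimator": tag,
                    "T_spec": cell.label("outcome_spec"),
                    "S_spec": cell.label("sampling_spec"),
                    "C_spec": cell.label("censoring_spec"),
                    "t": float(t),
                    "bias": float(d.mean() - dt),
                    "esd": float(d.std(ddof=1)),
                    "ase": float(s.mean()),
                    "cp": float(covers.mean()),
                    "n_reps": used,
                    "n_failed": n_failed,
                }
            )
    columns = [
        "estimator", "T_spec", "S_spec", "C_spec", "t",
        "bias", "esd", "ase", "cp", "n_reps", "n_failed",
    ]
    return SimulationSummary(
        table=pd.DataFrame(rows, columns=columns),
        delta_true=delta_true, n_reps=used, n_failed=n_failed,
    )


def _applicable_cells(tag: str, grid: list[SpecGrid]) -> list[SpecGrid]:
    """Project user-supplied cells onto the models the estimator uses."""
    out = []
    for cell in grid:
        if tag == "WKM":
            cell = SpecGrid(None, cell.sampling_spec, None)
        elif tag in ("IPW1", "IPW2"):
            cell = SpecGrid(None, cell.sampling_spec, cell.censoring_spec)
        if cell not in out:
            out.append(cell)
    return out


def write_summary(summary: SimulationSummary, path, scale100: bool = True) -> None:
    """Write the summary as a delimited table; bias/esd/ase/cp are multiplied
    by 100 when ``scale100`` (the convention of the reference tables)."""
    table = summary.table.copy()
    if scale100:
        for col in ("bias", "esd", "ase", "cp"):
            table[col] = table[col] * 100.0
    table.to_csv(path, index=False)
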