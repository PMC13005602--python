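"""Combined trial + survey sample container, validation, and tabular/config I/O.

The combined sample is the union of a randomized trial (S=1, with treatment A,
observed time U, event indicator delta) and a survey sample of the external
target population (S=0, covariates only, design weight ``w_survey`` = inverse
inclusion probability). All downstream modules consume :class:`CombinedSample`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names, in canonical order
CANONICAL_COLUMNS = ("id", "S", "D", "A", "U", "delta", "w_survey")


@dataclass
class CombinedSample:
    """Per-individual records for the union of trial and survey samples.

    Parameters
    ----------
    S : (n+m,) array of {0,1}
        Trial-participation indicator.
    X : DataFrame, shape (n+m, p)
        Real-valued baseline covariates, one named column per covariate.
    A, U, delta : arrays
        Treatment, observed time and event indicator; defined (non-NaN) iff
        S=1. For S=0 records these are NaN.
    w_survey : (n+m,) array
        Design weight 1/p_i for S=0 records, exactly 1 for S=1 records.
    pi : float
        Known randomization probability P(A=1|S=1), sample-level metadata.
    ids : array or None
        Optional record identifiers (defaults to 0..n+m-1).
    """

    S: np.ndarray
    X: pd.DataFrame
    A: np.ndarray
    U: np.ndarray
    delta: np.ndarray
    w_survey: np.ndarray
    pi: float = 0.5
    ids: np.ndarray | None = None
    D: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=int)
        k = self.S.size
        self.A = np.asarray(self.A, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.w_survey = np.asarray(self.w_survey, dtype=float)
        if self.ids is None:
            self.ids = np.arange(k)
        else:
            self.ids = np.asarray(self.ids)
        if self.D is None:
            self.D = np.ones(k, dtype=int)
        else:
            self.D = np.asarray(self.D, dtype=int)
        self.X = pd.DataFrame(self.X).reset_index(drop=True)
        self._validate()

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        k = self.S.size
        for name in ("A", "U", "delta", "w_survey", "D"):
            arr = getattr(self, name)
            if arr.shape != (k,):
                raise ValidationError(f"column {name!r} has length {arr.shape}, expected {k}")
        if len(self.X) != k:
            raise ValidationError("covariate table length does not match indicator columns")
        if not np.isin(self.S, (0, 1)).all():
            raise ValidationError("S must be binary")
        if not (0.0 < self.pi < 1.0):
            raise ValidationError(f"pi must lie in (0,1), got {self.pi}")
        trial = self.S == 1
        if np.any(self.D[trial] != 1):
            bad = self.ids[trial][self.D[trial] != 1]
            raise ValidationError(f"trial records must have D=1 (ids {bad[:5].tolist()})")
        for name, arr in (("A", self.A), ("U", self.U), ("delta", self.delta)):
            miss = trial & ~np.isfinite(arr)
            if miss.any():
                raise ValidationError(
                    f"S=1 record(s) missing {name}: ids {self.ids[miss][:5].tolist()}"
                )
            extra = ~trial & np.isfinite(arr)
            if extra.any():
                raise ValidationError(
                    f"{name} defined for S=0 record(s): ids {self.ids[extra][:5].tolist()}"
                )
        if not np.isin(self.A[trial], (0, 1)).all():
            raise ValidationError("A must be binary for trial records")
        if not np.isin(self.delta[trial], (0, 1)).all():
            raise ValidationError("delta must be binary for trial records")
        if np.any(self.U[trial] <= 0):
            bad = self.ids[trial][self.U[trial] <= 0]
            raise ValidationError(f"nonpositive observed time U: ids {bad[:5].tolist()}")
        if np.any(~np.isfinite(self.w_survey)) or np.any(self.w_survey <= 0):
            raise ValidationError("w_survey must be positive and finite for every record")
        if np.any(self.w_survey[trial] != 1.0):
            raise ValidationError("w_survey must equal 1 for every S=1 record")
        if not trial.any() or trial.all():
            raise ValidationError("need at least one trial record and one survey record")
        for a in (0, 1):
            if not np.any(trial & (self.A == a)):
                raise ValidationError(f"no trial record in arm A={a}")
        if not np.isfinite(self.X.to_numpy(dtype=float)).all():
            raise ValidationError("covariates must be finite real values")

    # -- convenience ---------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of trial records."""
        return int(self.S.sum())

    @property
    def m(self) -> int:
        """Number of survey records."""
        return int((1 - self.S).sum())

    @property
    def trial(self) -> np.ndarray:
        return self.S == 1

    @property
    def survey(self) -> np.ndarray:
        return self.S == 0

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)

    def arm(self, a: int) -> np.ndarray:
        """Boolean mask for trial records with A = a."""
        return (self.S == 1) & (self.A == a)

    def design_matrix(self, covariates: list[str]) -> np.ndarray:
        missing = [c for c in covariates if c not in self.X.columns]
        if missing:
            raise SchemaError(f"unknown covariate column(s): {missing}")
        return self.X[list(covariates)].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabular representation in canonical column order."""
        df = pd.DataFrame(
            {
                "id": self.ids,
                "S": self.S,
                "D": self.D,
                "A": self.A,
                "U": self.U,
                "delta": self.delta,
                "w_survey": self.w_survey,
            }
        )
        return pd.concat([df, self.X.reset_index(drop=True)], axis=1)


def read_sample(
    path,
    schema: dict[str, str] | None = None,
    covariates: list[str] | None = None,
    pi: float = 0.5,
    delimiter: str | None = None,
) -> CombinedSample:
    """Read a delimited-text combined sample.

    Parameters
    ----------
    schema : dict, optional
        Map from canonical names (``S``, ``A``, ``U``, ``delta``, ...) to the
        column names used in the file.
    covariates : list of str, optional
        Covariate columns; defaults to every non-reserved column.
    delimiter : str, optional
        Field delimiter; sniffed between comma and tab when omitted.
    """
    schema = dict(schema or {})
    if delimiter is None:
        with open(path) as fh:
            header = fh.readline()
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delimiter)
    colmap = {canon: schema.get(canon, canon) for canon in CANONICAL_COLUMNS}

    if colmap["S"] not in df.columns:
        raise SchemaError(f"missing mandatory column {colmap['S']!r} (S)")
    S = df[colmap["S"]].to_numpy()
    has_trial = (S == 1).any()
    for canon in ("A", "U", "delta"):
        if colmap[canon] not in df.columns:
            if has_trial:
                raise SchemaError(f"missing mandatory column {colmap[canon]!r} ({canon})")
            df[colmap[canon]] = np.nan

    reserved = {colmap[c] for c in CANONICAL_COLUMNS}
    if covariates is None:
        covariates = [c for c in df.columns if c not in reserved]
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise SchemaError(f"missing covariate column(s): {missing}")
    if not covariates:
        raise SchemaError("no covariate columns found")

    k = len(df)
    if colmap["w_survey"] in df.columns:
        w = df[colmap["w_survey"]].to_numpy(dtype=float)
    else:
        logger.info("no %r column: defaulting every survey weight to 1 (m = N case)", colmap["w_survey"])
        w = np.ones(k)
    ids = df[colmap["id"]].to_numpy() if colmap["id"] in df.columns else None
    D = df[colmap["D"]].to_numpy(dtype=int) if colmap["D"] in df.columns else None

    sample = CombinedSample(
        S=S,
        X=df[covariates],
        A=df[colmap["A"]].to_numpy(dtype=float),
        U=df[colmap["U"]].to_numpy(dtype=float),
        delta=df[colmap["delta"]].to_numpy(dtype=float),
        w_survey=w,
        pi=pi,
        ids=ids,
        D=D,
    )
    logger.info("read %d records (%d trial, %d survey) from %s", k, sample.n, sample.m, path)
    return sample


def write_sample(sample: CombinedSample, path, delimiter: str = ",") -> None:
    """Write the sample as delimited text in canonical column order."""
    sample.to_frame().to_csv(path, sep=delimiter, index=False)


def summarize_sample(sample: CombinedSample) -> dict:
    """Record counts, per-arm sizes, censoring fraction and survey-weight total."""
    trial = sample.trial
    n = sample.n
    return {
        "n": n,
        "m": sample.m,
        "n_arm1": int(sample.arm(1).sum()),
        "n_arm0": int(sample.arm(0).sum()),
        "censoring_fraction": float((1.0 - sample.delta[trial]).sum() / n),
        "weight_total": float(sample.w_survey[sample.survey].sum()),
        "pi": sample.pi,
    }


def load_config(path) -> dict:
    """Load a YAML key-value configuration (schema map, pi, covariate lists,
    time grid, truncation percentile, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("configuration file must hold a key-value mapping")
    return cfg
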