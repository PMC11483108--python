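"""Data model for a randomized two-arm trial.

A :class:`TrialDataset` holds, per patient, the biomarker matrix ``X``, the
treatment arm ``A`` coded in {+1, -1}, the endpoint data (a continuous
outcome, a binary 0/1 outcome, or an observed time plus event indicator),
and a propensity score ``pi`` in (0, 1).  :class:`ColumnRoles` maps columns
of a flat CSV/TSV table onto those roles; :func:`load_trial` performs the
mapping with validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Endpoint",
    "CONTINUOUS",
    "BINARY",
    "SURVIVAL",
    "ColumnRoles",
    "TrialDataset",
    "TrialValidationError",
    "RoleMappingError",
    "load_trial",
    "validate",
    "write_trial",
    "estimate_propensity",
]


class TrialValidationError(ValueError):
    """A dataset violates a TrialDataset invariant."""


class RoleMappingError(KeyError):
    """Column roles do not match the table being loaded."""


@dataclass(frozen=True)
class Endpoint:
    """Endpoint taxonomy: exactly one of continuous, binary, survival.

    The single-letter codes ``"c"``, ``"b"``, ``"s"`` are accepted as
    aliases in :meth:`from_code` because they are the conventional
    shorthand for endpoint type in clinical biomarker analysis.
    """

    kind: str

    _KINDS = ("continuous", "binary", "survival")
    _CODES = {"c": "continuous", "b": "binary", "s": "survival"}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(
                f"endpoint kind must be one of {self._KINDS}, got {self.kind!r}"
            )

    @classmethod
    def from_code(cls, code: str) -> "Endpoint":
        kind = cls._CODES.get(code, code)
        return cls(kind)

    @property
    def is_survival(self) -> bool:
        return self.kind == "survival"


CONTINUOUS = Endpoint("continuous")
BINARY = Endpoint("binary")
SURVIVAL = Endpoint("survival")


@dataclass(frozen=True)
class ColumnRoles:
    """Assignment of table columns to trial roles.

    Parameters
    ----------
    biomarker_cols
        Names of biomarker columns (numeric or categorical).
    trt_col
        Treatment-arm column; must contain exactly two distinct values.
    trt_positive_label
        The arm label mapped to +1 (treatment); the other maps to -1.
    outcome_col
        Outcome column for continuous/binary endpoints.
    time_col, event_col
        Observed time and event indicator (1 = event, 0 = censored) for
        survival endpoints.
    propensity_col
        Optional column with propensity scores in (0, 1).
    default_propensity
        Value used when no propensity column is given; 0.5 corresponds to
        a 1:1 randomized trial.
    patient_id_col
        Optional identifier column; row numbers are used otherwise.
    """

    biomarker_cols: tuple[str, ...]
    trt_col: str
    trt_positive_label: Any
    outcome_col: str | None = None
    time_col: str | None = None
    event_col: str | None = None
    propensity_col: str | None = None
    default_propensity: float = 0.5
    patient_id_col: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "biomarker_cols", tuple(self.biomarker_cols))
        if len(set(self.biomarker_cols)) != len(self.biomarker_cols):
            raise ValueError("biomarker names must be unique")
        if not 0.0 < self.default_propensity < 1.0:
            raise ValueError("default_propensity must lie in (0, 1)")

    def outcome_columns(self, endpoint: Endpoint) -> tuple[str, ...]:
        if endpoint.is_survival:
            if self.time_col is None or self.event_col is None:
                raise RoleMappingError(
                    "survival endpoint requires time_col and event_col"
                )
            return (self.time_col, self.event_col)
        if self.outcome_col is None:
            raise RoleMappingError(f"{endpoint.kind} endpoint requires outcome_col")
        return (self.outcome_col,)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnRoles":
        return cls(
            biomarker_cols=tuple(d["biomarker_cols"]),
            trt_col=d["trt_col"],
            trt_positive_label=d.get("trt_positive_label", 1),
            outcome_col=d.get("outcome_col"),
            time_col=d.get("time_col"),
            event_col=d.get("event_col"),
            propensity_col=d.get("propensity_col"),
            default_propensity=d.get("default_propensity", 0.5),
            patient_id_col=d.get("patient_id_col"),
        )


@dataclass
class TrialDataset:
    """Patient-level two-arm trial data in canonical coding.

    Attributes
    ----------
    patient_id : list of str
    X : pandas.DataFrame
        Biomarker matrix, one named column per biomarker; numeric or
        categorical.  Missing values are legal (the tree learner handles
        them via default directions).
    A : ndarray
        Treatment arm, +1 = treatment, -1 = placebo/control.
    y : ndarray or None
        Continuous or binary (0/1) outcome; None for survival.
    time, event : ndarray or None
        Observed time (> 0) and event indicator (1 = event observed,
        0 = censored); None unless survival.
    pi : ndarray
        Propensity score per patient, elementwise in (0, 1).
    endpoint : Endpoint
    arm_labels : mapping of {+1, -1} to the original arm labels.
    """

    patient_id: list[str]
    X: pd.DataFrame
    A: np.ndarray
    pi: np.ndarray
    endpoint: Endpoint
    y: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    arm_labels: dict[int, Any] = field(default_factory=lambda: {1: 1, -1: -1})

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
        if self.event is not None:
            self.event = np.asarray(self.event, dtype=float)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def biomarker_names(self) -> list[str]:
        return list(self.X.columns)

    def original_arm_labels(self) -> np.ndarray:
        """Map the canonical +1/-1 coding back to the input labels."""
        return np.asarray([self.arm_labels[int(a)] for a in self.A])

    def to_frame(self) -> pd.DataFrame:
        """Flat table with canonical column names (arm coded +1/-1)."""
        out = self.X.copy()
        out.insert(0, "patient_id", self.patient_id)
        out["trt"] = self.A
        if self.endpoint.is_survival:
            out["time"] = self.time
            out["event"] = self.event
        else:
            out["y"] = self.y
        out["pi"] = self.pi
        return out


def validate(dataset: TrialDataset) -> list[str]:
    """Report every TrialDataset invariant violation (empty list = valid).

    Each message names the offending rows or column; this function never
    raises, so it can be used to audit a dataset constructed by hand.
    """
    report: list[str] = []
    n = len(dataset.X)
    if n < 1:
        report.append("dataset has no rows")
        return report
    names = list(dataset.X.columns)
    if len(set(names)) != len(names):
        dup = sorted({c for c in names if names.count(c) > 1})
        report.append(f"duplicate biomarker names: {dup}")

    def _check_len(vec, label):
        if vec is not None and len(vec) != n:
            report.append(f"{label} has length {len(vec)}, expected {n}")
            return False
        return vec is not None

    if _check_len(dataset.A, "A"):
        bad = np.flatnonzero(~np.isin(dataset.A, (1, -1)))
        if bad.size:
            report.append(f"A not in {{+1,-1}} at rows {bad[:10].tolist()}")
    if _check_len(dataset.pi, "pi"):
        bad = np.flatnonzero(~((dataset.pi > 0) & (dataset.pi < 1)))
        if bad.size:
            report.append(f"pi outside (0,1) at rows {bad[:10].tolist()}")
    if len(dataset.patient_id) != n:
        report.append(f"patient_id has length {len(dataset.patient_id)}, expected {n}")

    if dataset.endpoint.is_survival:
        if dataset.time is None or dataset.event is None:
            report.append("survival endpoint requires time and event vectors")
        else:
            if _check_len(dataset.time, "time"):
                bad = np.flatnonzero(~(dataset.time > 0))
                if bad.size:
                    report.append(f"time not > 0 at rows {bad[:10].tolist()}")
            if _check_len(dataset.event, "event"):
                bad = np.flatnonzero(~np.isin(dataset.event, (0.0, 1.0)))
                if bad.size:
                    report.append(f"event not in {{0,1}} at rows {bad[:10].tolist()}")
    else:
        if dataset.y is None:
            report.append(f"{dataset.endpoint.kind} endpoint requires y")
        elif _check_len(dataset.y, "y"):
            if np.any(~np.isfinite(dataset.y)):
                bad = np.flatnonzero(~np.isfinite(dataset.y))
                report.append(f"y missing/non-finite at rows {bad[:10].tolist()}")
            elif dataset.endpoint.kind == "binary":
                bad = np.flatnonzero(~np.isin(dataset.y, (0.0, 1.0)))
                if bad.size:
                    report.append(f"binary y not in {{0,1}} at rows {bad[:10].tolist()}")
    return report


def _map_treatment(raw: pd.Series, positive_label: Any) -> tuple[np.ndarray, dict]:
    levels = pd.unique(raw.dropna())
    if len(levels) != 2:
        raise RoleMappingError(
            f"treatment column {raw.name!r} must have exactly 2 levels, "
            f"found {len(levels)}: {list(levels)[:5]}"
        )
    if positive_label not in levels:
        # {0,1}-coded arms: map 1 -> +1, 0 -> -1 with a warning.
        lv = set(levels.tolist())
        if lv == {0, 1}:
            warnings.warn(
                "treatment coded {0,1}; mapping 1 -> +1 (treatment), 0 -> -1",
                stacklevel=3,
            )
            positive_label = 1
        else:
            raise RoleMappingError(
                f"positive label {positive_label!r} not among treatment levels {list(levels)}"
            )
    negative_label = next(l for l in levels if l != positive_label)
    A = np.where(raw.to_numpy() == positive_label, 1, -1)
    return A, {1: positive_label, -1: negative_label}


def load_trial(
    path: str | Path | pd.DataFrame,
    roles: ColumnRoles,
    endpoint: Endpoint,
) -> TrialDataset:
    """Load a delimited patient table and map it onto trial roles.

    Rows with a missing outcome or treatment are rejected (dropped with a
    warning reporting the count); missing biomarker values are preserved.
    A missing propensity column is filled with ``roles.default_propensity``.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        # round_trip parser: numeric values survive write/load bit-for-bit
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")

    required = list(roles.biomarker_cols) + [roles.trt_col]
    required += list(roles.outcome_columns(endpoint))
    if roles.propensity_col is not None:
        required.append(roles.propensity_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RoleMappingError(f"columns not found in table: {missing}")

    essential = [roles.trt_col, *roles.outcome_columns(endpoint)]
    bad = df[essential].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} rows with missing treatment/outcome",
            stacklevel=2,
        )
        df = df.loc[~bad].reset_index(drop=True)

    A, arm_labels = _map_treatment(df[roles.trt_col], roles.trt_positive_label)

    if roles.propensity_col is not None:
        pi = df[roles.propensity_col].to_numpy(dtype=float)
    else:
        pi = np.full(len(df), roles.default_propensity)

    if roles.patient_id_col is not None:
        pid = df[roles.patient_id_col].astype(str).tolist()
    else:
        pid = [str(i) for i in range(len(df))]

    X = df[list(roles.biomarker_cols)].copy()
    kwargs: dict[str, Any] = {}
    if endpoint.is_survival:
        kwargs["time"] = df[roles.time_col].to_numpy(dtype=float)
        kwargs["event"] = df[roles.event_col].to_numpy(dtype=float)
    else:
        kwargs["y"] = df[roles.outcome_col].to_numpy(dtype=float)

    ds = TrialDataset(
        patient_id=pid,
        X=X,
        A=A,
        pi=pi,
        endpoint=endpoint,
        arm_labels=arm_labels,
        **kwargs,
    )
    report = validate(ds)
    if report:
        raise TrialValidationError("; ".join(report))
    return ds


def write_trial(dataset: TrialDataset, path: str | Path) -> None:
    """Write the canonical flat-table form (round-trips via load_trial)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def canonical_roles(dataset: TrialDataset) -> ColumnRoles:
    """Roles matching :func:`write_trial` output, for round-trip loading."""
    return ColumnRoles(
        biomarker_cols=tuple(dataset.biomarker_names),
        trt_col="trt",
        trt_positive_label=1,
        outcome_col=None if dataset.endpoint.is_survival else "y",
        time_col="time" if dataset.endpoint.is_survival else None,
        event_col="event" if dataset.endpoint.is_survival else None,
        propensity_col="pi",
        patient_id_col="patient_id",
    )


def estimate_propensity(dataset: TrialDataset) -> np.ndarray:
    """Estimate pi(X) by logistic regression of arm on (one-hot) biomarkers.

    Never applied silently: callers must assign the result to a dataset
    copy themselves.  Rows with missing biomarkers use the arm frequency.
    """
    from sklearn.linear_model import LogisticRegression

    Xd = pd.get_dummies(dataset.X, dummy_na=False, dtype=float)
    target = (dataset.A == 1).astype(int)
    ok = ~Xd.isna().any(axis=1).to_numpy()
    pi = np.full(dataset.n, target.mean(), dtype=float)
    if ok.sum() >= 2 and len(np.unique(target[ok])) == 2:
        lr = LogisticRegression(max_iter=1000)
        lr.fit(Xd.to_numpy()[ok], target[ok])
        pi[ok] = lr.predict_proba(Xd.to_numpy()[ok])[:, 1]
    return np.clip(pi, 1e-6, 1 - 1e-6)


def load_roles_config(path: str | Path) -> tuple[ColumnRoles, Endpoint]:
    """Read a JSON or YAML config declaring ColumnRoles and Endpoint."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    endpoint = Endpoint.from_code(d["endpoint"])
    roles = ColumnRoles.from_dict(d["roles"])
    return roles, endpoint
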