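"""Synthetic randomized two-arm trials with known treatment heterogeneity.

Data are drawn from the generative model

    E(Y | A, X) = z(X) * A + h(X)

on the endpoint's natural scale: identity for continuous outcomes (Gaussian
noise), logit for binary outcomes, and log-hazard for exponential survival
times with independent exponential censoring tuned to a target censoring
fraction.  h(X) is the prognostic main effect (generated here, never
estimated by the modelling code); z(X) is the treatment contrast that
defines the true benefit subgroup.

Because the survival scale is log-hazard, a *negative* z means treatment
benefit there; the endpoint-aware benefit sign is centralised in
:func:`true_benefit_sign` so the generator and the subgroup model can
never disagree about the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .trial_data import BINARY, CONTINUOUS, SURVIVAL, Endpoint, TrialDataset

__all__ = [
    "LinearEffect",
    "ThresholdEffect",
    "ConstantEffect",
    "effect_from_dict",
    "EffectSpec",
    "simulate_trial",
    "true_benefit_sign",
    "tutorial_fixture",
]


@dataclass(frozen=True)
class ConstantEffect:
    """h(X) or z(X) identically equal to ``value``."""

    value: float = 0.0

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        return np.full(len(X), float(self.value))

    def to_dict(self) -> dict:
        return {"type": "constant", "value": self.value}


@dataclass(frozen=True)
class LinearEffect:
    """Linear form: intercept + sum_j coefs[j] * X[j]."""

    coefs: Mapping[str, float]
    intercept: float = 0.0

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), float(self.intercept))
        for name, beta in self.coefs.items():
            out = out + beta * X[name].to_numpy(dtype=float)
        return out

    def to_dict(self) -> dict:
        return {"type": "linear", "coefs": dict(self.coefs), "intercept": self.intercept}


@dataclass(frozen=True)
class ThresholdEffect:
    """Step form: ``above`` where X[var] > threshold, else ``below``."""

    var: str
    threshold: float
    below: float
    above: float

    def __call__(self, X: pd.DataFrame) -> np.ndarray:
        x = X[self.var].to_numpy(dtype=float)
        return np.where(x > self.threshold, float(self.above), float(self.below))

    def to_dict(self) -> dict:
        return {
            "type": "threshold",
            "var": self.var,
            "threshold": self.threshold,
            "below": self.below,
            "above": self.above,
        }


def effect_from_dict(d: Mapping[str, Any]):
    """Rebuild an effect from its serialised form (see each ``to_dict``)."""
    kind = d["type"]
    if kind == "constant":
        return ConstantEffect(d.get("value", 0.0))
    if kind == "linear":
        return LinearEffect(coefs=d["coefs"], intercept=d.get("intercept", 0.0))
    if kind == "threshold":
        return ThresholdEffect(
            var=d["var"], threshold=d["threshold"], below=d["below"], above=d["above"]
        )
    raise ValueError(f"unknown effect type {kind!r}")


Effect = Callable[[pd.DataFrame], np.ndarray]


@dataclass(frozen=True)
class EffectSpec:
    """Full generative specification of a synthetic two-arm trial.

    Parameters
    ----------
    n, p
        Patients and numeric biomarkers (columns ``x1..xp``, iid standard
        normal, optionally exchangeably correlated with coefficient rho).
    h, z
        Prognostic main effect and treatment contrast on the endpoint's
        natural scale.
    propensity
        P(A = +1); arms are Bernoulli, emulating randomization.
    noise_sd
        Gaussian noise SD for the continuous endpoint.
    baseline_hazard, censoring_rate
        Survival: event times are exponential with rate
        baseline_hazard * exp(h + z A); censoring is an independent
        exponential whose rate is solved numerically so the expected
        censored fraction equals ``censoring_rate``.
    categorical_levels
        Optional extra categorical biomarkers, e.g. {"sex": ["M", "F"]},
        sampled uniformly (pure noise unless referenced by h or z).
    """

    n: int
    p: int = 10
    h: Effect = field(default_factory=ConstantEffect)
    z: Effect = field(default_factory=ConstantEffect)
    endpoint: Endpoint = CONTINUOUS
    propensity: float = 0.5
    noise_sd: float = 1.0
    baseline_hazard: float = 1.0
    censoring_rate: float = 0.0
    rho: float = 0.0
    categorical_levels: Mapping[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.n < 1:
            raise ValueError("need n >= 1 and p >= 1")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 < self.propensity < 1:
            raise ValueError("propensity must lie in (0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


def true_benefit_sign(z: np.ndarray, endpoint: Endpoint) -> np.ndarray:
    """True optimal arm per patient: +1 iff treatment is beneficial.

    Benefit means higher outcome for continuous/binary endpoints (z > 0)
    and lower hazard for survival (z < 0); z = 0 carries no benefit and
    maps to -1, matching the ITR tie-break.
    """
    if endpoint.is_survival:
        return np.where(z < 0, 1, -1)
    return np.where(z > 0, 1, -1)


def _censoring_rate_for(lam: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+lam_i) = target."""

    def frac(c: float) -> float:
        return float(np.mean(c / (c + lam))) - target

    lo, hi = 1e-12, 1e12
    if frac(lo) > 0 or frac(hi) < 0:
        raise RuntimeError(f"cannot tune censoring to {target}")
    return brentq(frac, lo, hi, xtol=1e-14)


def simulate_trial(spec: EffectSpec) -> tuple[TrialDataset, np.ndarray, np.ndarray]:
    """Draw one trial; returns (dataset, true_z, true_subgroup).

    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.rho > 0:
        shared = rng.standard_normal((spec.n, 1))
        indep = rng.standard_normal((spec.n, spec.p))
        Xmat = np.sqrt(spec.rho) * shared + np.sqrt(1 - spec.rho) * indep
    else:
        Xmat = rng.standard_normal((spec.n, spec.p))
    X = pd.DataFrame(Xmat, columns=[f"x{j + 1}" for j in range(spec.p)])
    for name, levels in spec.categorical_levels.items():
        X[name] = rng.choice(levels, size=spec.n)

    A = np.where(rng.random(spec.n) < spec.propensity, 1, -1)
    hv = np.asarray(spec.h(X), dtype=float)
    zv = np.asarray(spec.z(X), dtype=float)
    lin = hv + zv * A

    pid = [f"P{i:05d}" for i in range(spec.n)]
    pi = np.full(spec.n, spec.propensity)
    kind = spec.endpoint.kind
    if kind == "continuous":
        y = lin + rng.normal(0.0, spec.noise_sd, size=spec.n)
        ds = TrialDataset(patient_id=pid, X=X, A=A, pi=pi, endpoint=CONTINUOUS, y=y)
    elif kind == "binary":
        y = (rng.random(spec.n) < expit(lin)).astype(float)
        ds = TrialDataset(patient_id=pid, X=X, A=A, pi=pi, endpoint=BINARY, y=y)
    else:
        lam = spec.baseline_hazard * np.exp(lin)
        t_event = rng.exponential(1.0 / lam)
        if spec.censoring_rate > 0:
            c_rate = _censoring_rate_for(lam, spec.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate, size=spec.n)
        else:
            t_cens = np.full(spec.n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(float)
        ds = TrialDataset(
            patient_id=pid, X=X, A=A, pi=pi, endpoint=SURVIVAL, time=time, event=event
        )
    return ds, zv, true_benefit_sign(zv, spec.endpoint)


TUTORIAL_SEED = 20240731
TUTORIAL_N = 600


def tutorial_fixture(endpoint: str | Endpoint = BINARY) -> TrialDataset:
    """Deterministic 10-biomarker demonstration trial.

    x1 is uniform on (0, 1) and drives a threshold-predictive effect at
    x1 = 0.5 (treatment helps only biomarker-positive patients, with a
    prognostic bump on the same threshold); x2..x10 are standard-normal
    noise.  Both a binary response and a survival (time/event, ~30%
    censoring) outcome are generated on the same patients; ``endpoint``
    selects which one the returned dataset exposes, with the other kept
    in the extra fields so downstream summaries can use either.

    This is a synthetic emulation for demonstrations and tests; it does
    not reproduce any real trial's rows.
    """
    if isinstance(endpoint, str):
        endpoint = Endpoint.from_code(endpoint)
    rng = np.random.default_rng(TUTORIAL_SEED)
    n = TUTORIAL_N
    X = pd.DataFrame(rng.standard_normal((n, 10)), columns=[f"x{j}" for j in range(1, 11)])
    X["x1"] = rng.random(n)
    A = np.where(rng.random(n) < 0.5, 1, -1)
    pos = (X["x1"].to_numpy() > 0.5).astype(float)

    # binary response: prognostic + predictive step at x1 = 0.5
    h_b = -0.5 + 0.8 * pos
    z_b = -0.2 + 1.7 * pos
    y = (rng.random(n) < expit(h_b + z_b * A)).astype(float)

    # survival: treatment lowers hazard only above the threshold
    h_s = 0.3 * pos
    z_s = 0.1 - 1.1 * pos
    lam = 0.5 * np.exp(h_s + z_s * A)
    t_event = rng.exponential(1.0 / lam)
    c_rate = _censoring_rate_for(lam, 0.30)
    t_cens = rng.exponential(1.0 / c_rate, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)

    pid = [f"T{i:04d}" for i in range(n)]
    pi = np.full(n, 0.5)
    return TrialDataset(
        patient_id=pid,
        X=X,
        A=A,
        pi=pi,
        endpoint=endpoint,
        y=y,
        time=time,
        event=event,
        arm_labels={1: "Treatment", -1: "Placebo"},
    )
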