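"""Modified-loss family for individualized treatment rule estimation.

The contrast function Z(X) = [E(Y|A=+1,X) - E(Y|A=-1,X)] / 2 of a two-arm
trial can be estimated without modelling the prognostic main effect H(X):
for any per-patient loss kernel M(y, v) that is convex in v and whose
v-derivative at 0 is monotone in y, the population minimizer of either

* the A-learning loss   L_A(f) = mean_i M(y_i, c_i f(x_i)),
  with c_i = (A_i + 1)/2 - pi_i,  or
* the weight-learning loss  L_W(f) = mean_i w_i M(y_i, A_i f(x_i)),
  with inverse-propensity weights w_i = 1 / (A_i pi_i + (1 - A_i)/2)
  (1/pi on the treated arm, 1/(1-pi) on controls),

recovers the sign of Z(X) — the optimal treatment rule — where pi_i is the
propensity score P(A=+1 | X_i).

Kernels implemented, one per endpoint:

==========  =====================================================
continuous  M(y, v) = (v - y)^2
binary      M(y, v) = log(1 + e^v) - y v   (Bernoulli deviance)
survival    M contribution  -delta 1(Z <= tau) (v - log Ê[e^v 1(Z >= u)])
            integrated over the counting process, i.e. a modified
            Cox partial likelihood with Breslow tie handling
==========  =====================================================

This module exposes the composite losses and their exact per-patient
first/second derivatives, which drive the boosting engine in
:mod:`itrboost.subgroup_model`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import expit, log1p

from .trial_data import Endpoint, TrialDataset

__all__ = [
    "LossConfig",
    "ModifiedSignal",
    "GradHess",
    "A_LEARNING",
    "WEIGHT_LEARNING",
    "HESSIAN_FLOOR",
    "m_value",
    "modified_signal",
    "composite_loss",
    "loss_gradient",
]

A_LEARNING = "A_learning"
WEIGHT_LEARNING = "weight_learning"

# keeps the Newton boosting step defined when the curvature vanishes
HESSIAN_FLOOR = 1e-16


class DegenerateLossError(ValueError):
    """The loss is undefined on this data (e.g. no events at or before tau)."""


@dataclass(frozen=True)
class LossConfig:
    """Endpoint + loss-type + survival horizon tau.

    tau is the fixed horizon up to which events contribute to the partial
    likelihood; it must satisfy P(Z >= tau) > 0, i.e. tau <= max observed
    time.  ``weight_inside_risk_set`` controls whether weight-learning
    weights also enter the risk-set expectation (default: outer-only).
    """

    endpoint: Endpoint
    loss_type: Literal["A_learning", "weight_learning"] = A_LEARNING
    tau: float | None = None
    weight_inside_risk_set: bool = False

    def __post_init__(self) -> None:
        if self.loss_type not in (A_LEARNING, WEIGHT_LEARNING):
            raise ValueError(f"unknown loss_type {self.loss_type!r}")
        if self.endpoint.is_survival:
            if self.tau is not None and self.tau <= 0:
                raise ValueError("tau must be positive")
        elif self.tau is not None:
            raise ValueError("tau applies to survival endpoints only")

    def resolve_tau(self, time: np.ndarray, event: np.ndarray) -> float:
        """tau, defaulting to the largest observed event time."""
        if self.tau is not None:
            if self.tau > float(np.max(time)):
                raise ValueError("tau exceeds the largest observed time")
            return float(self.tau)
        if not np.any(event > 0):
            raise DegenerateLossError("no events observed; cannot default tau")
        return float(np.max(time[event > 0]))


@dataclass(frozen=True)
class ModifiedSignal:
    """Per-patient treatment-centering multiplier and IPW weight.

    c_i = (A_i + 1)/2 - pi_i in (-1, 1);  w_i = 1/(A_i pi_i + (1-A_i)/2) > 1.
    """

    c: np.ndarray
    w: np.ndarray


@dataclass(frozen=True)
class GradHess:
    """Per-patient gradient and (floored) diagonal Hessian of a loss."""

    g: np.ndarray
    h: np.ndarray


def modified_signal(A: np.ndarray, pi: np.ndarray) -> ModifiedSignal:
    """Compute the A-learning multiplier c and the IPW weight w."""
    A = np.asarray(A, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if not np.all(np.isin(A, (1.0, -1.0))):
        raise ValueError("A must be coded in {+1, -1}")
    if not np.all((pi > 0) & (pi < 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    c = (A + 1.0) / 2.0 - pi
    w = 1.0 / (A * pi + (1.0 - A) / 2.0)
    return ModifiedSignal(c=c, w=w)


def m_value(
    endpoint: Endpoint,
    y: float,
    v: float,
    risk_log_mean: float | None = None,
) -> float:
    """Per-patient loss kernel M(y, v).

    For the survival endpoint ``y`` is the event indicator already
    restricted to the horizon (delta * 1(Z <= tau)) and ``risk_log_mean``
    is the precomputed log of the empirical risk-set mean of e^v at the
    patient's event time.
    """
    if not np.isfinite(v):
        raise ValueError("score v must be finite")
    if endpoint.kind == "continuous":
        return float((v - y) ** 2)
    if endpoint.kind == "binary":
        # log(1 + e^v) - y v, stabilized: log1p(e^-|v|) + max(v, 0)
        return float(log1p(np.exp(-abs(v))) + max(v, 0.0) - y * v)
    if risk_log_mean is None:
        raise ValueError("survival m_value requires risk_log_mean")
    return float(-y * (v - risk_log_mean))


def _scores(dataset: TrialDataset, f: np.ndarray, config: LossConfig):
    """Per-patient transformed scores v, chain multipliers m, outer weights u."""
    f = np.asarray(f, dtype=float)
    if len(f) != dataset.n:
        raise ValueError(f"f has length {len(f)}, expected {dataset.n}")
    if config.endpoint != dataset.endpoint:
        raise ValueError(
            f"loss endpoint {config.endpoint.kind} != dataset {dataset.endpoint.kind}"
        )
    sig = modified_signal(dataset.A, dataset.pi)
    if config.loss_type == A_LEARNING:
        mult = sig.c
        u = np.ones(dataset.n)
    else:
        mult = dataset.A.astype(float)
        u = sig.w
    return f, mult * f, mult, u


def _survival_terms(dataset: TrialDataset, v: np.ndarray, u: np.ndarray, config: LossConfig):
    """Sorted-prefix machinery shared by the survival loss and gradient.

    Returns (d, log_mean, order, ...) where for each patient i with
    d_i = delta_i 1(Z_i <= tau) > 0, log_mean_i is the log of the empirical
    mean over all patients j of e^{v_j} 1(Z_j >= Z_i) (Breslow: ties share
    the common risk set {j : Z_j >= Z_i}).
    """
    time, event = dataset.time, dataset.event
    tau = config.resolve_tau(time, event)
    d = event * (time <= tau)
    if config.weight_inside_risk_set and config.loss_type == WEIGHT_LEARNING:
        rw = u
    else:
        rw = np.ones_like(v)
    if not np.any(d > 0):
        raise DegenerateLossError("no events at or before tau")
    n = len(v)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    shift = float(np.max(v))
    ev = rw[order] * np.exp(v[order] - shift)
    # suffix sums: risk-set sum for threshold t = sum of ev over Z >= t
    suffix = np.cumsum(ev[::-1])[::-1]
    # risk set of patient i: first sorted index with Z >= Z_i
    idx = np.searchsorted(t_sorted, time, side="left")
    risk_sum = suffix[idx]  # idx < n always since Z_i is in the sample
    log_mean = shift + np.log(risk_sum) - np.log(n)
    return d, log_mean, order, t_sorted, ev, suffix, idx, shift, n


def composite_loss(dataset: TrialDataset, f: np.ndarray, config: LossConfig) -> float:
    """Mean modified loss over patients at scores f.

    A-learning averages M(y_i, c_i f_i); weight-learning averages
    w_i M(y_i, A_i f_i).  For survival endpoints events are counted only
    up to tau and tied event times share a Breslow risk set.
    """
    f, v, _, u = _scores(dataset, f, config)
    kind = config.endpoint.kind
    if kind == "continuous":
        return float(np.mean(u * (v - dataset.y) ** 2))
    if kind == "binary":
        m = log1p(np.exp(-np.abs(v))) + np.maximum(v, 0.0) - dataset.y * v
        return float(np.mean(u * m))
    d, log_mean, *_ = _survival_terms(dataset, v, u, config)
    return float(-np.mean(u * d * (v - log_mean)))


def loss_gradient(dataset: TrialDataset, f: np.ndarray, config: LossConfig) -> GradHess:
    """Exact gradient and diagonal second derivative of :func:`composite_loss`.

    The returned g is d composite_loss / d f_i (mean scale, so it matches
    finite differences of :func:`composite_loss` directly); h is a
    positive diagonal curvature, floored at ``HESSIAN_FLOOR``.  For the
    survival loss h uses the diagonal approximation
    sum_i d_i p_ik (1 - p_ik) with p_ik the risk-set softmax weight.
    """
    f, v, mult, u = _scores(dataset, f, config)
    n = dataset.n
    kind = config.endpoint.kind
    if kind == "continuous":
        g = u * mult * 2.0 * (v - dataset.y) / n
        h = u * mult**2 * 2.0 / n
    elif kind == "binary":
        p = expit(v)
        g = u * mult * (p - dataset.y) / n
        h = u * mult**2 * p * (1.0 - p) / n
    else:
        d, log_mean, order, t_sorted, ev, suffix, idx, shift, _ = _survival_terms(
            dataset, v, u, config
        )
        # dL/dv_k = -(1/n) [u_k d_k - sum_i u_i d_i p_ik],
        # p_ik = rw_k e^{v_k} 1(Z_k >= Z_i) / risk_sum_i.
        # Accumulate a_k = sum_{i: Z_i <= Z_k} u_i d_i / risk_sum_i and
        # b_k = sum u_i d_i / risk_sum_i^2 by prefix sums over sorted times.
        risk_sum = suffix[idx]
        term1 = (u * d) / risk_sum
        term2 = (u * d) / risk_sum**2
        t1_sorted = np.cumsum(term1[order])
        t2_sorted = np.cumsum(term2[order])
        # events with Z_i <= Z_k: last sorted index with Z <= Z_k
        pos = np.searchsorted(t_sorted, dataset.time, side="right") - 1
        a = t1_sorted[pos]
        b = t2_sorted[pos]
        if config.weight_inside_risk_set and config.loss_type == WEIGHT_LEARNING:
            e_k = u * np.exp(v - shift)
        else:
            e_k = np.exp(v - shift)
        grad_v = -(u * d - e_k * a) / n
        hess_v = (e_k * a - e_k**2 * b) / n
        g = mult * grad_v
        h = mult**2 * hess_v
    h = np.maximum(h, HESSIAN_FLOOR)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(h))):
        raise FloatingPointError("non-finite gradient/Hessian")
    return GradHess(g=g, h=h)
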