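"""Biomarker-outcome association diagnostics.

* :func:`roc_curve_biomarker` — ROC of a biomarker against a binary
  response, with automatic direction orientation (AUC >= 0.5).
* :func:`ecdf_curve` — empirical CDF of a biomarker per subgroup, with
  fraction-below/above queries at arbitrary cutoffs.
* :func:`smooth_outcome_curve` — penalized-spline smooth of the outcome on
  a biomarker on the endpoint's natural link scale (identity / logit /
  martingale residuals of a null survival model).
* :func:`smooth_treatment_contrast` — per-arm smooths and their
  difference, the graphical check of whether a biomarker is predictive:
  a contrast curve that departs from zero where the biomarker is high
  (or low) indicates treatment-effect modification.

Every plotting helper first returns the plotted numbers; figures are
separate artifacts.

The smoother is a cubic B-spline basis of user-chosen dimension k with a
second-difference (curvature) penalty whose weight is selected by
generalized cross-validation; the logit link is fitted by penalized IRLS.
It is encapsulated in :class:`PenalizedSpline` so the backend can be
swapped without touching the calling code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit

from .trial_data import Endpoint, TrialDataset

__all__ = [
    "ROCResult",
    "ECDFResult",
    "SmoothContrast",
    "PenalizedSpline",
    "roc_curve_biomarker",
    "ecdf_curve",
    "smooth_outcome_curve",
    "smooth_treatment_contrast",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class ROCResult:
    """ROC points (threshold sweep), trapezoidal AUC, chosen orientation."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    direction: str  # ">" if larger biomarker values predict response
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ECDFResult:
    """Right-continuous eCDF step points per group."""

    groups: dict  # label -> (sorted x, cumulative fraction)

    def fraction_at(self, cutoff: float, group=None) -> tuple[float, float]:
        """(fraction <= cutoff, fraction > cutoff); they sum to 1 exactly."""
        if group is None:
            if len(self.groups) != 1:
                raise ValueError("specify a group when several are present")
            group = next(iter(self.groups))
        x, _ = self.groups[group]
        below = float(np.searchsorted(x, cutoff, side="right")) / len(x)
        return below, 1.0 - below


@dataclass
class SmoothContrast:
    """A fitted smooth (or smooth difference) on an evaluation grid."""

    grid: np.ndarray
    fit: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    k: int
    scale: str  # "link" or "response"
    notes: list[str] = field(default_factory=list)


def roc_curve_biomarker(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    outcome_col: str = "y",
    direction: str = "auto",
) -> ROCResult:
    """ROC of a biomarker for a binary response, all thresholds swept.

    direction ">" treats larger biomarker values as predicting response;
    "auto" picks the orientation whose AUC is >= 0.5.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    frame = data.to_frame() if isinstance(data, TrialDataset) else data
    x = frame[biomarker].to_numpy(float)
    y = frame[outcome_col].to_numpy(float)
    keep = np.isfinite(x)
    x, y = x[keep], y[keep]
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ROC requires both outcome classes present")

    def _one(score):
        fpr, tpr, thr = _sk_roc(y, score)
        return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))

    if direction == "auto":
        fpr, tpr, thr, auc = _one(x)
        chosen = ">"
        if auc < 0.5:
            fpr, tpr, thr, auc = _one(-x)
            chosen = "<"
    elif direction in (">", "greater"):
        fpr, tpr, thr, auc = _one(x)
        chosen = ">"
    elif direction in ("<", "less"):
        fpr, tpr, thr, auc = _one(-x)
        chosen = "<"
    else:
        raise ValueError(f"direction must be '>', '<' or 'auto', got {direction!r}")
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc=auc,
        direction=chosen,
        n_pos=int(np.sum(y == 1)),
        n_neg=int(np.sum(y == 0)),
    )


def ecdf_curve(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    by: Sequence | None = None,
) -> ECDFResult:
    """Empirical CDF of a biomarker, overall or per subgroup."""
    frame = data.to_frame() if isinstance(data, TrialDataset) else data
    x = frame[biomarker].to_numpy(float)
    labels = np.asarray(by) if by is not None else np.full(len(x), "all")
    groups = {}
    for g in pd.unique(labels):
        xs = np.sort(x[(labels == g) & np.isfinite(x)])
        if len(xs) == 0:
            warnings.warn(f"group {g!r} empty after dropping missing; skipped")
            continue
        groups[g] = (xs, np.arange(1, len(xs) + 1) / len(xs))
    if not groups:
        raise ValueError("no finite biomarker values")
    return ECDFResult(groups=groups)


class PenalizedSpline:
    """Cubic B-spline smoother with curvature penalty and GCV.

    The basis has exactly ``k`` functions (clamped cubic B-splines with
    interior knots at sample quantiles); the penalty is the squared
    second difference of the coefficient vector, so constants and linear
    trends are unpenalized.  The penalty weight is chosen by minimizing
    GCV(lambda) = n * deviance / (n - edf)^2 over a log-spaced grid.
    Optional linear adjuster columns enter the design unpenalized.
    """

    LAMBDA_GRID = np.logspace(-4.0, 8.0, 25)

    def __init__(self, k: int = 5, degree: int = 3, family: str = "gaussian"):
        if family not in ("gaussian", "binomial"):
            raise ValueError(f"unsupported family {family!r}")
        self.k = int(k)
        self.degree = degree
        self.family = family

    # -- basis -----------------------------------------------------------
    def _make_knots(self, x: np.ndarray) -> None:
        uniq = np.unique(x)
        k = self.k
        if k < self.degree + 1:
            raise ValueError(f"k must be >= {self.degree + 1} for a cubic basis")
        if len(uniq) < 2 * k:
            k_new = max(self.degree + 1, len(uniq) // 2)
            warnings.warn(
                f"only {len(uniq)} distinct values: reducing basis dimension "
                f"{k} -> {k_new}"
            )
            k = k_new
        self.k_used = k
        inner = np.quantile(uniq, np.linspace(0, 1, k - self.degree + 1))
        inner = np.unique(inner)
        while len(inner) < 2:  # pathological: nearly constant x
            inner = np.r_[inner, inner[-1] + 1.0]
        self.k_used = len(inner) + self.degree - 1
        self._lo, self._hi = float(inner[0]), float(inner[-1])
        self.knots = np.r_[[inner[0]] * self.degree, inner, [inner[-1]] * self.degree]

    def _basis(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self._lo, self._hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    # -- fitting ---------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        keep = np.isfinite(x) & np.isfinite(y)
        if Z is not None:
            keep &= np.all(np.isfinite(Z), axis=1)
            Z = np.asarray(Z, float)[keep]
        x, y = x[keep], y[keep]
        self._make_knots(x)
        B = self._basis(x)
        if Z is not None:
            self._zmean = Z.mean(axis=0)
            B = np.column_stack([B, Z - self._zmean])  # centered adjusters
            nz = Z.shape[1]
        else:
            self._zmean = None
            nz = 0
        kb = self.k_used
        D = np.diff(np.eye(kb), n=2, axis=0)
        P = np.zeros((B.shape[1], B.shape[1]))
        P[:kb, :kb] = D.T @ D
        n = len(y)

        best = None
        for lam in self.LAMBDA_GRID:
            beta, edf, dev, cov = self._fit_one(B, y, P, lam)
            gcv = n * dev / max(n - edf, 1e-8) ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, edf, dev, cov)
        _, self.lambda_, self.beta_, self.edf_, dev, self.cov_ = best
        if self.family == "gaussian":
            self.scale_ = dev / max(n - self.edf_, 1e-8)
            self.cov_ = self.cov_ * self.scale_
        self.n_adjust_ = nz
        return self

    def _fit_one(self, B, y, P, lam):
        n = len(y)
        if self.family == "gaussian":
            BtB = B.T @ B
            A = BtB + lam * P
            Ainv = np.linalg.inv(A)
            beta = Ainv @ (B.T @ y)
            H_trace = float(np.trace(Ainv @ BtB))
            resid = y - B @ beta
            dev = float(resid @ resid)
            cov = Ainv @ BtB @ Ainv  # sandwich; scaled by phi after GCV
            return beta, H_trace, dev, cov
        # binomial: penalized IRLS on the logit link
        beta = np.zeros(B.shape[1])
        for _ in range(50):
            eta = B @ beta
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-8, None)
            z = eta + (y - mu) / w
            BtWB = (B * w[:, None]).T @ B
            A = BtWB + lam * P
            Ainv = np.linalg.inv(A)
            beta_new = Ainv @ ((B * w[:, None]).T @ z)
            if np.max(np.abs(beta_new - beta)) < 1e-9:
                beta = beta_new
                break
            beta = beta_new
        eta = B @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        dev = float(-2 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        w = np.clip(mu * (1 - mu), 1e-8, None)
        BtWB = (B * w[:, None]).T @ B
        Ainv = np.linalg.inv(BtWB + lam * P)
        edf = float(np.trace(Ainv @ BtWB))
        cov = Ainv @ BtWB @ Ainv
        return beta, edf, dev, cov

    def predict(self, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(fit, pointwise SE) on the link scale at grid points."""
        Bg = self._basis(np.asarray(grid, float))
        if self._zmean is not None:
            # adjusters held at their sample means (centered -> zeros)
            Bg = np.column_stack([Bg, np.zeros((len(Bg), self.n_adjust_))])
        fit = Bg @ self.beta_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Bg, self.cov_, Bg), 0.0))
        return fit, se


def _martingale_residuals(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """delta_i - cumulative null hazard at t_i (Nelson-Aalen)."""
    from lifelines import NelsonAalenFitter

    naf = NelsonAalenFitter()
    naf.fit(time, event)
    cumhaz = naf.cumulative_hazard_at_times(time).to_numpy()
    return event - cumhaz


def _link_data(frame: pd.DataFrame, endpoint: Endpoint):
    """(pseudo-outcome, family) for smoothing on the natural link."""
    if endpoint.kind == "continuous":
        return frame["y"].to_numpy(float), "gaussian"
    if endpoint.kind == "binary":
        return frame["y"].to_numpy(float), "binomial"
    resid = _martingale_residuals(
        frame["time"].to_numpy(float), frame["event"].to_numpy(float)
    )
    return resid, "gaussian"


def _grid_for(x: np.ndarray, num: int = 100) -> np.ndarray:
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    return np.linspace(lo, hi, num)


def smooth_outcome_curve(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    endpoint: Endpoint,
    k: int = 5,
    adjust_covariates: Sequence[str] | None = None,
    trim_outliers: bool = False,
    grid_size: int = 100,
) -> SmoothContrast:
    """Penalized-spline smooth of the outcome on a biomarker.

    The smooth is on the endpoint's natural link: identity for continuous,
    logit for binary, and a martingale-residual smooth against a null
    survival model for time-to-event data (the standard functional-form
    diagnostic).  ``trim_outliers`` drops biomarker values outside 1.5 IQR
    beyond the quartiles before fitting.
    """
    frame = data.to_frame() if isinstance(data, TrialDataset) else data
    x = frame[biomarker].to_numpy(float)
    yv, family = _link_data(frame, endpoint)
    keep = np.isfinite(x)
    notes: list[str] = []
    if trim_outliers:
        q1, q3 = np.nanpercentile(x, [25, 75])
        iqr = q3 - q1
        out = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        notes.append(f"trimmed {int(np.sum(out & keep))} outlying biomarker values")
        keep &= ~out
    Z = (
        frame.loc[keep, list(adjust_covariates)].to_numpy(float)
        if adjust_covariates
        else None
    )
    sp = PenalizedSpline(k=k, family=family)
    sp.fit(x[keep], yv[keep], Z=Z)
    grid = _grid_for(x[keep], grid_size)
    fit, se = sp.predict(grid)
    if sp.k_used != k:
        notes.append(f"basis dimension reduced to {sp.k_used}")
    return SmoothContrast(
        grid=grid,
        fit=fit,
        band_lo=fit - _Z975 * se,
        band_hi=fit + _Z975 * se,
        k=sp.k_used,
        scale="link",
        notes=notes,
    )


def smooth_treatment_contrast(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    endpoint: Endpoint | None = None,
    arm: Sequence | None = None,
    k: int = 5,
    adjust_covariates: Sequence[str] | None = None,
    grid_size: int = 100,
) -> SmoothContrast:
    """Smoothed treatment-contrast curve: arm(+1) smooth minus arm(-1) smooth.

    Both per-arm smooths are fitted on the link scale over a common grid
    spanning the biomarker range; the pointwise band combines both arms'
    sampling uncertainty (variances add).  A curve inconsistent with zero
    over part of the range indicates a predictive biomarker.  Swapping
    arm labels negates the curve exactly.
    """
    if isinstance(data, TrialDataset):
        endpoint = endpoint or data.endpoint
        arm = data.A if arm is None else arm
    if endpoint is None or arm is None:
        raise ValueError("plain-table input requires explicit endpoint and arm")
    frame = data.to_frame() if isinstance(data, TrialDataset) else data
    arm = np.asarray(arm)
    if not (np.any(arm == 1) and np.any(arm == -1)):
        raise ValueError("both arms must be present")
    x = frame[biomarker].to_numpy(float)
    yv, family = _link_data(frame, endpoint)
    grid = _grid_for(x[np.isfinite(x)], grid_size)

    fits, ses, notes = {}, {}, []
    for a in (1, -1):
        mask = arm == a
        Z = (
            frame.loc[mask, list(adjust_covariates)].to_numpy(float)
            if adjust_covariates
            else None
        )
        sp = PenalizedSpline(k=k, family=family)
        sp.fit(x[mask], yv[mask], Z=Z)
        fits[a], ses[a] = sp.predict(grid)
        if sp.k_used != k:
            notes.append(f"arm {a:+d}: basis dimension reduced to {sp.k_used}")
    contrast = fits[1] - fits[-1]
    se = np.sqrt(ses[1] ** 2 + ses[-1] ** 2)
    return SmoothContrast(
        grid=grid,
        fit=contrast,
        band_lo=contrast - _Z975 * se,
        band_hi=contrast + _Z975 * se,
        k=k,
        scale="link",
        notes=notes,
    )


# -- plotting artifacts --------------------------------------------------

def _agg_axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_roc(result: ROCResult, path, label: str = "biomarker") -> None:
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.fpr, result.tpr, label=f"{label} (AUC={result.auc:.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ecdf(result: ECDFResult, path, biomarker: str = "biomarker") -> None:
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, (xs, fr) in result.groups.items():
        ax.step(xs, fr, where="post", label=str(g))
    ax.set_xlabel(biomarker)
    ax.set_ylabel("empirical CDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_contrast(result: SmoothContrast, path, title: str = "Group contrast") -> None:
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.grid, result.fit, color="#c44e52")
    ax.fill_between(result.grid, result.band_lo, result.band_hi, alpha=0.25, color="#c44e52")
    ax.axhline(0.0, ls="--", color="grey")
    ax.set_xlabel("biomarker")
    ax.set_ylabel(f"treatment contrast ({result.scale} scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_smooth(
    result: SmoothContrast,
    path,
    scatter: tuple[np.ndarray, np.ndarray] | None = None,
    title: str = "Outcome smooth",
) -> None:
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    if scatter is not None:
        ax.plot(scatter[0], scatter[1], ".", alpha=0.3, color="grey")
    ax.plot(result.grid, result.fit, color="#4878d0")
    ax.fill_between(result.grid, result.band_lo, result.band_hi, alpha=0.25, color="#4878d0")
    ax.set_xlabel("biomarker")
    ax.set_ylabel("outcome (link scale)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
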