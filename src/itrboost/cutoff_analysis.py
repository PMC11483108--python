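"""Candidate-cutoff evaluation and fixed-cutoff performance summaries.

Companion-diagnostic (CDx) development typically restricts a continuous
biomarker to a handful of technically feasible cutoffs (e.g. IHC scoring
levels).  :func:`evaluate_cutoffs` scores each candidate against the
outcome — classification agreement (sensitivity/specificity/Youden/kappa)
and association tests (Fisher exact, two-sample t, log-rank) — and selects
the best candidate under the requested criterion.  :func:`cutoff_performance`
then summarizes the biomarker-positive and -negative groups at one chosen
cutoff, with an endpoint-appropriate between-group comparison.

Convention: "biomarker-positive" means the value strictly meets the
direction (x > c for ">", x < c for "<"); values equal to the cutoff are
negative under ">".  Rows with a missing value of the analyzed biomarker
are dropped and the count reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import Endpoint, TrialDataset

__all__ = [
    "CutoffResult",
    "CutoffPerformance",
    "evaluate_cutoffs",
    "cutoff_performance",
    "dichotomize",
    "cohens_kappa",
]

_METHOD_ENDPOINT = {
    "fisher": "binary",
    "youden": "binary",
    "kappa": "binary",
    "two_sample": "continuous",
    "logrank": "survival",
}


@dataclass
class CutoffResult:
    """Metrics for one candidate cutoff."""

    cutoff: float
    direction: str
    n_positive: int
    n_negative: int
    metrics: dict[str, float] = field(default_factory=dict)


@dataclass
class CutoffPerformance:
    """Endpoint summaries of the two groups at a fixed cutoff."""

    cutoff: float
    direction: str
    n_dropped_missing: int
    groups: pd.DataFrame  # one row per group with endpoint summaries
    test_name: str
    statistic: float | None
    p_value: float | None
    notes: list[str] = field(default_factory=list)


def dichotomize(x: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    """Boolean biomarker-positive indicator under the strict convention."""
    x = np.asarray(x, dtype=float)
    if direction == ">":
        return x > cutoff
    if direction == "<":
        return x < cutoff
    raise ValueError(f"direction must be '>' or '<', got {direction!r}")


def cohens_kappa(pos: np.ndarray, y: np.ndarray) -> float:
    """Chance-corrected agreement between a binary marker and outcome."""
    pos = np.asarray(pos, dtype=bool)
    y = np.asarray(y, dtype=float)
    n = len(y)
    po = float(np.mean(pos == (y == 1)))
    pe = (np.mean(pos) * np.mean(y == 1)) + (np.mean(~pos) * np.mean(y == 0))
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def _extract(
    data,
    biomarker: str,
    endpoint: Endpoint,
    outcome_col: str = "y",
    time_col: str = "time",
    event_col: str = "event",
):
    """Pull (x, outcome columns) from a TrialDataset or a flat DataFrame.

    Plain tables use the canonical column names by default; override the
    ``*_col`` arguments for other layouts.
    """
    if isinstance(data, TrialDataset):
        frame = data.to_frame()
        outcome_col, time_col, event_col = "y", "time", "event"
    else:
        frame = data
    if biomarker not in frame.columns:
        raise KeyError(f"biomarker {biomarker!r} not found")
    x = frame[biomarker].to_numpy(dtype=float)
    if endpoint.is_survival:
        out = (
            frame[time_col].to_numpy(dtype=float),
            frame[event_col].to_numpy(dtype=float),
        )
    else:
        out = (frame[outcome_col].to_numpy(dtype=float),)
    return frame, x, out


def _binary_cell_metrics(pos: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """2x2 classification + association metrics (y = 1 is the response)."""
    tp = int(np.sum(pos & (y == 1)))
    fn = int(np.sum(~pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    tn = int(np.sum(~pos & (y == 0)))
    m: dict[str, float] = {"tp": tp, "fn": fn, "fp": fp, "tn": tn}
    m["sensitivity"] = tp / (tp + fn) if tp + fn else np.nan
    m["specificity"] = tn / (tn + fp) if tn + fp else np.nan
    m["youden"] = m["sensitivity"] + m["specificity"] - 1.0
    m["ppv"] = tp / (tp + fp) if tp + fp else np.nan
    m["npv"] = tn / (tn + fn) if tn + fn else np.nan
    m["kappa"] = cohens_kappa(pos, y)
    # two-sided probability-mass Fisher exact; defined for zero cells
    m["p_value"] = float(stats.fisher_exact([[tp, fn], [fp, tn]]).pvalue)
    if min(tp, fn, fp, tn) > 0:
        m["odds_ratio"] = (tp * tn) / (fp * fn)
    else:
        m["odds_ratio"] = np.nan
    return m


def _continuous_metrics(pos: np.ndarray, y: np.ndarray) -> dict[str, float]:
    ypos, yneg = y[pos], y[~pos]
    m: dict[str, float] = {}
    if len(ypos) >= 2 and len(yneg) >= 2:
        t = stats.ttest_ind(ypos, yneg, equal_var=False)
        m["p_value"] = float(t.pvalue)
        m["statistic"] = float(t.statistic)
    else:
        m["p_value"] = np.nan
        m["statistic"] = np.nan
    m["mean_difference"] = (
        float(np.mean(ypos) - np.mean(yneg)) if len(ypos) and len(yneg) else np.nan
    )
    return m


def _survival_metrics(pos: np.ndarray, time: np.ndarray, event: np.ndarray) -> dict[str, float]:
    from lifelines.statistics import logrank_test

    m: dict[str, float] = {}
    if pos.all() or (~pos).all() or event.sum() == 0:
        m["p_value"] = np.nan
        m["hazard_ratio"] = np.nan
        return m
    lr = logrank_test(time[pos], time[~pos], event[pos], event[~pos])
    m["p_value"] = float(lr.p_value)
    m["statistic"] = float(lr.test_statistic)
    m["hazard_ratio"] = _cox_hr(pos.astype(float), time, event)
    return m


def _cox_hr(indicator: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    from lifelines import CoxPHFitter

    df = pd.DataFrame({"g": indicator, "time": time, "event": event})
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        return float(np.exp(cph.params_["g"]))
    except Exception:
        return np.nan


def evaluate_cutoffs(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    endpoint: Endpoint,
    cutoffs: Sequence[float],
    direction: str = ">",
    method: str = "fisher",
    outcome_col: str = "y",
    time_col: str = "time",
    event_col: str = "event",
) -> tuple[list[CutoffResult], float]:
    """Score candidate cutoffs and select the best under ``method``.

    youden / kappa select the maximizing candidate; fisher / two_sample /
    logrank select the smallest p-value (ties broken toward the larger
    biomarker-positive group, the enrichment-friendly choice).  Candidates
    outside the observed biomarker range are evaluated with a warning.
    """
    if method not in _METHOD_ENDPOINT:
        raise ValueError(f"unknown method {method!r}")
    if _METHOD_ENDPOINT[method] != endpoint.kind:
        raise ValueError(f"method {method!r} is for {_METHOD_ENDPOINT[method]} endpoints")
    cutoffs = [float(c) for c in cutoffs]
    if not cutoffs or not all(np.isfinite(cutoffs)):
        raise ValueError("need at least one finite candidate cutoff")

    _, x, out = _extract(data, biomarker, endpoint, outcome_col, time_col, event_col)
    keep = np.isfinite(x)
    n_missing = int(np.sum(~keep))
    x = x[keep]
    out = tuple(o[keep] for o in out)
    lo, hi = float(np.min(x)), float(np.max(x))

    results: list[CutoffResult] = []
    for c in cutoffs:
        if not lo <= c <= hi:
            warnings.warn(
                f"cutoff {c} outside observed range [{lo:.4g}, {hi:.4g}]", stacklevel=2
            )
        pos = dichotomize(x, c, direction)
        res = CutoffResult(
            cutoff=c,
            direction=direction,
            n_positive=int(pos.sum()),
            n_negative=int((~pos).sum()),
        )
        res.metrics["n_dropped_missing"] = n_missing
        if pos.all() or (~pos).all():
            res.metrics["degenerate"] = 1.0
        if endpoint.kind == "binary":
            res.metrics.update(_binary_cell_metrics(pos, out[0]))
        elif endpoint.kind == "continuous":
            res.metrics.update(_continuous_metrics(pos, out[0]))
        else:
            res.metrics.update(_survival_metrics(pos, out[0], out[1]))
        results.append(res)

    selected = _select(results, method)
    return results, selected


def _select(results: list[CutoffResult], method: str) -> float:
    if method in ("youden", "kappa"):
        key = "youden" if method == "youden" else "kappa"
        vals = [(r.metrics.get(key, np.nan), r) for r in results]
        finite = [(v, r) for v, r in vals if np.isfinite(v)]
        if not finite:
            return results[0].cutoff
        best = max(v for v, _ in finite)
        cands = [r for v, r in finite if v == best]
    else:
        vals = [(r.metrics.get("p_value", np.nan), r) for r in results]
        finite = [(v, r) for v, r in vals if np.isfinite(v)]
        if not finite:
            return results[0].cutoff
        best = min(v for v, _ in finite)
        cands = [r for v, r in finite if v == best]
    # tie-break: larger biomarker-positive group
    cands.sort(key=lambda r: (-r.n_positive, r.cutoff))
    return cands[0].cutoff


def _km_median_ci(time: np.ndarray, event: np.ndarray) -> tuple[float, float, float]:
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    km = KaplanMeierFitter()
    km.fit(time, event)
    med = float(km.median_survival_time_)
    ci = median_survival_times(km.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return med, lo, hi


def cutoff_performance(
    data: TrialDataset | pd.DataFrame,
    biomarker: str,
    cutoff: float,
    direction: str,
    endpoint: Endpoint,
    adjust_covariates: Sequence[str] | None = None,
    outcome_col: str = "y",
    time_col: str = "time",
    event_col: str = "event",
) -> CutoffPerformance:
    """Summarize the two biomarker groups at one fixed cutoff.

    Continuous: group mean +/- sd, Welch t-test (covariate-adjusted linear
    model when adjusters are given).  Binary: response rates, rate
    difference, Fisher exact.  Survival: Kaplan-Meier medians with 95% CI,
    log-rank test and Cox hazard ratio.  Empty groups produce a flagged
    degenerate result, never a crash.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    frame, x, out = _extract(data, biomarker, endpoint, outcome_col, time_col, event_col)
    keep = np.isfinite(x)
    n_missing = int(np.sum(~keep))
    frame = frame.loc[keep].reset_index(drop=True)
    x = x[keep]
    out = tuple(o[keep] for o in out)
    pos = dichotomize(x, cutoff, direction)
    notes: list[str] = []
    if n_missing:
        notes.append(f"{n_missing} rows dropped for missing {biomarker}")

    rows = []
    for label, mask in (("biomarker_positive", pos), ("biomarker_negative", ~pos)):
        row: dict[str, Any] = {"group": label, "n": int(mask.sum())}
        if mask.sum() == 0:
            rows.append(row)
            continue
        if endpoint.kind == "continuous":
            row["mean"] = float(np.mean(out[0][mask]))
            row["sd"] = float(np.std(out[0][mask], ddof=1)) if mask.sum() > 1 else np.nan
        elif endpoint.kind == "binary":
            row["responders"] = int(np.sum(out[0][mask] == 1))
            row["rate"] = float(np.mean(out[0][mask] == 1))
        else:
            t, e = out[0][mask], out[1][mask]
            row["events"] = int(e.sum())
            if e.sum() == 0:
                row["km_median"] = np.nan
                notes.append(f"{label}: all censored; median undefined")
            else:
                med, lo, hi = _km_median_ci(t, e)
                row["km_median"], row["km_median_lo"], row["km_median_hi"] = med, lo, hi
                if not np.isfinite(med):
                    notes.append(f"{label}: KM median not reached")
        rows.append(row)
    groups = pd.DataFrame(rows)

    stat: float | None = None
    pval: float | None = None
    if pos.sum() == 0 or (~pos).sum() == 0:
        notes.append("one biomarker group is empty; between-group test skipped")
        test_name = "none"
    elif endpoint.kind == "continuous":
        if adjust_covariates:
            import statsmodels.api as sm

            Xd = sm.add_constant(
                pd.concat(
                    [pd.Series(pos.astype(float), name="pos"), frame[list(adjust_covariates)]],
                    axis=1,
                ).astype(float)
            )
            fit = sm.OLS(out[0], Xd).fit()
            test_name = "adjusted_linear_model"
            stat, pval = float(fit.tvalues["pos"]), float(fit.pvalues["pos"])
        else:
            t = stats.ttest_ind(out[0][pos], out[0][~pos], equal_var=False)
            test_name = "welch_t"
            stat, pval = float(t.statistic), float(t.pvalue)
    elif endpoint.kind == "binary":
        m = _binary_cell_metrics(pos, out[0])
        test_name = "fisher_exact"
        pval = m["p_value"]
        groups.attrs["rate_difference"] = (
            float(np.mean(out[0][pos] == 1) - np.mean(out[0][~pos] == 1))
        )
    else:
        if out[1].sum() == 0:
            notes.append("no events; log-rank test skipped")
            test_name = "none"
        else:
            m = _survival_metrics(pos, out[0], out[1])
            test_name = "logrank"
            stat = m.get("statistic")
            pval = m["p_value"]
            groups.attrs["hazard_ratio"] = m["hazard_ratio"]

    return CutoffPerformance(
        cutoff=float(cutoff),
        direction=direction,
        n_dropped_missing=n_missing,
        groups=groups,
        test_name=test_name,
        statistic=stat,
        p_value=pval,
        notes=notes,
    )


def results_frame(results: Sequence[CutoffResult]) -> pd.DataFrame:
    """Flatten CutoffResults into one row per candidate for CSV export."""
    rows = []
    for r in results:
        row = {
            "cutoff": r.cutoff,
            "direction": r.direction,
            "n_positive": r.n_positive,
            "n_negative": r.n_negative,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_cutoff_metrics(results: Sequence[CutoffResult], path) -> None:
    """Sensitivity/specificity (or p-value) versus candidate cutoff."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results_frame(results).sort_values("cutoff")
    fig, ax = plt.subplots(figsize=(6, 4))
    if "sensitivity" in df:
        ax.plot(df["cutoff"], df["sensitivity"], "o-", label="sensitivity")
        ax.plot(df["cutoff"], df["specificity"], "s-", label="specificity")
        ax.plot(df["cutoff"], df["youden"], "^--", label="Youden")
        ax.set_ylabel("metric")
    else:
        ax.plot(df["cutoff"], df["p_value"], "o-", label="p-value")
        ax.set_yscale("log")
        ax.set_ylabel("association p-value")
    ax.set_xlabel("candidate cutoff")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
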