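"""Arm-by-biomarker-group performance tables.

:func:`subgroup_treatment_summary` produces the four-cell predictive
layout (treatment/placebo x biomarker-positive/negative): per-cell endpoint
summaries, within-group treatment contrasts (mean difference / rate
difference + odds ratio / hazard ratio, with CI and test p-value), and a
treatment-by-group interaction p-value from a single endpoint-appropriate
regression model (linear, logistic, or proportional hazards) with a
group x arm term — the standard clinical test of whether a biomarker is
predictive rather than merely prognostic.

:func:`subgroup_summary` gives per-group summaries with a global
across-group test, and :func:`categorical_summary` tabulates categorical
biomarkers with optional cross-tabulation against arm or group.
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
    "SubgroupPerformanceTable",
    "subgroup_summary",
    "subgroup_treatment_summary",
    "categorical_summary",
]

MIN_GROUP_FOR_CONTRAST = 2  # cells smaller than this are summarized only


@dataclass
class SubgroupPerformanceTable:
    """Cell summaries, per-group treatment contrasts, interaction test."""

    cells: pd.DataFrame        # one row per (group, arm)
    contrasts: pd.DataFrame    # one row per group
    interaction_p: float | None
    interaction_model: str
    notes: list[str] = field(default_factory=list)


def _outcome_arrays(data, endpoint: Endpoint):
    if isinstance(data, TrialDataset):
        frame = data.to_frame()
    else:
        frame = data
    if endpoint.is_survival:
        return frame, frame["time"].to_numpy(float), frame["event"].to_numpy(float)
    return frame, frame["y"].to_numpy(float), None


def _km_summary(time: np.ndarray, event: np.ndarray) -> dict[str, float]:
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    out: dict[str, float] = {"events": int(event.sum())}
    if event.sum() == 0:
        out["km_median"] = np.nan
        return out
    km = KaplanMeierFitter()
    # log(-log) CI is the lifelines default for survival curves
    km.fit(time, event)
    out["km_median"] = float(km.median_survival_time_)
    ci = median_survival_times(km.confidence_interval_)
    out["km_median_lo"] = float(ci.iloc[0, 0])
    out["km_median_hi"] = float(ci.iloc[0, 1])
    return out


def _cell_summary(endpoint: Endpoint, y, time, event, mask) -> dict[str, Any]:
    row: dict[str, Any] = {"n": int(mask.sum())}
    if mask.sum() == 0:
        return row
    if endpoint.kind == "continuous":
        row["mean"] = float(np.mean(y[mask]))
        row["sd"] = float(np.std(y[mask], ddof=1)) if mask.sum() > 1 else np.nan
    elif endpoint.kind == "binary":
        row["responders"] = int(np.sum(y[mask] == 1))
        row["rate"] = float(np.mean(y[mask] == 1))
    else:
        row.update(_km_summary(time[mask], event[mask]))
    return row


def subgroup_summary(
    data: TrialDataset | pd.DataFrame,
    group: Sequence,
    endpoint: Endpoint,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Per-group endpoint summaries with a global across-group test.

    Continuous: one-way ANOVA; binary: chi-square (Fisher exact for a
    2x2 with any expected cell < 5); survival: multivariate log-rank.
    A single group yields summaries only, with a notice.
    """
    frame, y_or_t, event = _outcome_arrays(data, endpoint)
    group = np.asarray(group)
    if len(group) != len(frame):
        raise ValueError("group labels must match the number of rows")
    levels = pd.unique(group)
    rows = []
    for g in levels:
        mask = group == g
        row = {"group": g}
        if endpoint.is_survival:
            row.update(_cell_summary(endpoint, None, y_or_t, event, mask))
        else:
            row.update(_cell_summary(endpoint, y_or_t, None, None, mask))
        rows.append(row)
    table = pd.DataFrame(rows)

    test: dict[str, Any] = {"test": None, "p_value": None, "note": None}
    if len(levels) < 2:
        test["note"] = "single group: no across-group test"
        return table, test
    if endpoint.kind == "continuous":
        samples = [y_or_t[group == g] for g in levels]
        f = stats.f_oneway(*samples)
        test.update(test="anova", statistic=float(f.statistic), p_value=float(f.pvalue))
    elif endpoint.kind == "binary":
        ct = pd.crosstab(pd.Series(group), pd.Series(y_or_t)).to_numpy()
        if ct.shape == (2, 2) and (stats.contingency.expected_freq(ct) < 5).any():
            test.update(test="fisher_exact", p_value=float(stats.fisher_exact(ct).pvalue))
        else:
            chi = stats.chi2_contingency(ct)
            test.update(
                test="chi_square", statistic=float(chi.statistic), p_value=float(chi.pvalue)
            )
    else:
        from lifelines.statistics import multivariate_logrank_test

        lr = multivariate_logrank_test(y_or_t, group, event)
        test.update(
            test="logrank", statistic=float(lr.test_statistic), p_value=float(lr.p_value)
        )
    return table, test


def _contrast_continuous(y1, y0) -> dict[str, float]:
    d = float(np.mean(y1) - np.mean(y0))
    t = stats.ttest_ind(y1, y0, equal_var=False)
    se = np.sqrt(np.var(y1, ddof=1) / len(y1) + np.var(y0, ddof=1) / len(y0))
    return {
        "mean_difference": d,
        "ci_lo": d - 1.959963984540054 * se,
        "ci_hi": d + 1.959963984540054 * se,
        "p_value": float(t.pvalue),
    }


def _contrast_binary(y1, y0) -> dict[str, float]:
    n1, n0 = len(y1), len(y0)
    p1, p0 = float(np.mean(y1 == 1)), float(np.mean(y0 == 1))
    d = p1 - p0
    se = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    a, b = int(np.sum(y1 == 1)), int(np.sum(y1 == 0))
    c, e = int(np.sum(y0 == 1)), int(np.sum(y0 == 0))
    out = {
        "rate_difference": d,
        "ci_lo": d - 1.959963984540054 * se,
        "ci_hi": d + 1.959963984540054 * se,
        "p_value": float(stats.fisher_exact([[a, b], [c, e]]).pvalue),
    }
    out["odds_ratio"] = (a * e) / (b * c) if min(a, b, c, e) > 0 else np.nan
    return out


def _contrast_survival(t1, e1, t0, e0) -> dict[str, float]:
    from lifelines import CoxPHFitter
    from lifelines.statistics import logrank_test

    out: dict[str, float] = {}
    if e1.sum() + e0.sum() == 0:
        return {"hazard_ratio": np.nan, "p_value": np.nan}
    lr = logrank_test(t1, t0, e1, e0)
    out["p_value"] = float(lr.p_value)
    df = pd.DataFrame(
        {
            "trt": np.r_[np.ones(len(t1)), np.zeros(len(t0))],
            "time": np.r_[t1, t0],
            "event": np.r_[e1, e0],
        }
    )
    try:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = float(cph.params_["trt"])
        se = float(cph.standard_errors_["trt"])
        out["hazard_ratio"] = np.exp(beta)
        out["ci_lo"] = np.exp(beta - 1.959963984540054 * se)  # Wald on log-HR
        out["ci_hi"] = np.exp(beta + 1.959963984540054 * se)
    except Exception:
        out["hazard_ratio"] = np.nan
    return out


def _interaction_p(
    frame: pd.DataFrame,
    group: np.ndarray,
    arm: np.ndarray,
    endpoint: Endpoint,
    y,
    time,
    event,
    adjust: Sequence[str] | None,
) -> tuple[float | None, str, str | None]:
    """Wald p for the group x arm term in a single regression model."""
    import statsmodels.api as sm

    levels = pd.unique(group)
    if len(levels) < 2:
        return None, "none", "single group: interaction test skipped"
    g01 = (group == levels[0]).astype(float)  # reference coding
    a01 = (arm == 1).astype(float)
    cols = {"group": g01, "arm": a01, "inter": g01 * a01}
    if adjust:
        for c in adjust:
            cols[c] = frame[c].to_numpy(float)
    D = pd.DataFrame(cols)
    try:
        if endpoint.kind == "continuous":
            fit = sm.OLS(y, sm.add_constant(D)).fit()
            return float(fit.pvalues["inter"]), "linear", None
        if endpoint.kind == "binary":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, sm.add_constant(D)).fit(disp=0)
            return float(fit.pvalues["inter"]), "logistic", None
        from lifelines import CoxPHFitter

        D["time"] = time
        D["event"] = event
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(D, duration_col="time", event_col="event")
        return float(cph.summary.loc["inter", "p"]), "cox", None
    except Exception as exc:  # separation, non-convergence, empty cells
        return None, "failed", f"interaction model failed: {exc}"


def subgroup_treatment_summary(
    data: TrialDataset | pd.DataFrame,
    group: Sequence,
    arm: Sequence | None = None,
    endpoint: Endpoint | None = None,
    adjust_covariates: Sequence[str] | None = None,
) -> SubgroupPerformanceTable:
    """Group x arm cell summaries, per-group contrasts, interaction test.

    ``arm`` defaults to the dataset's +1/-1 treatment coding when ``data``
    is a TrialDataset.  Cells with n below ``MIN_GROUP_FOR_CONTRAST`` are
    summarized but excluded from model-based contrasts.
    """
    if isinstance(data, TrialDataset):
        if endpoint is None:
            endpoint = data.endpoint
        if arm is None:
            arm = data.A
    if endpoint is None or arm is None:
        raise ValueError("plain-table input requires explicit endpoint and arm")
    frame, y_or_t, event = _outcome_arrays(data, endpoint)
    group = np.asarray(group)
    arm = np.asarray(arm)
    if not {int(a) for a in np.unique(arm)} <= {1, -1}:
        raise ValueError("arm must be coded in {+1, -1}")
    if len(np.unique(arm)) < 2:
        raise ValueError("both arms must be present")

    if endpoint.is_survival:
        y, time = None, y_or_t
    else:
        y, time = y_or_t, None

    notes: list[str] = []
    levels = list(pd.unique(group))
    cell_rows = []
    for g in levels:
        for a, a_name in ((1, "treatment"), (-1, "control")):
            mask = (group == g) & (arm == a)
            row = {"group": g, "arm": a_name}
            row.update(_cell_summary(endpoint, y, time, event, mask))
            cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)

    contrast_rows = []
    for g in levels:
        m1 = (group == g) & (arm == 1)
        m0 = (group == g) & (arm == -1)
        row: dict[str, Any] = {"group": g, "n_treatment": int(m1.sum()), "n_control": int(m0.sum())}
        if m1.sum() < MIN_GROUP_FOR_CONTRAST or m0.sum() < MIN_GROUP_FOR_CONTRAST:
            notes.append(f"group {g!r}: a cell has n < {MIN_GROUP_FOR_CONTRAST}; contrast NA")
        elif endpoint.kind == "continuous":
            row.update(_contrast_continuous(y[m1], y[m0]))
        elif endpoint.kind == "binary":
            row.update(_contrast_binary(y[m1], y[m0]))
        else:
            row.update(_contrast_survival(time[m1], event[m1], time[m0], event[m0]))
        contrast_rows.append(row)
    contrasts = pd.DataFrame(contrast_rows)

    empty_cell = any(
        ((group == g) & (arm == a)).sum() == 0 for g in levels for a in (1, -1)
    )
    if empty_cell:
        notes.append("empty group x arm cell: interaction test skipped")
        ip, model, note = None, "none", None
    else:
        ip, model, note = _interaction_p(
            frame, group, arm, endpoint, y, time, event, adjust_covariates
        )
    if note:
        notes.append(note)
    return SubgroupPerformanceTable(
        cells=cells, contrasts=contrasts, interaction_p=ip,
        interaction_model=model, notes=notes,
    )


def categorical_summary(
    data: TrialDataset | pd.DataFrame,
    variable: str,
    by: Sequence | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Level counts and percentages, optionally cross-tabulated.

    With ``by`` given, adds a level x group contingency table and a
    chi-square test of independence (Fisher exact for sparse 2x2).
    """
    frame = data.to_frame() if isinstance(data, TrialDataset) else data
    if variable not in frame.columns:
        raise KeyError(f"variable {variable!r} not found")
    v = frame[variable]
    counts = v.value_counts(dropna=False).rename_axis("level").reset_index(name="count")
    counts["percent"] = 100.0 * counts["count"] / counts["count"].sum()
    result: dict[str, Any] = {"n": int(len(v))}
    if by is not None:
        by = np.asarray(by)
        ct = pd.crosstab(v, pd.Series(by, index=v.index, name="by"))
        result["crosstab"] = ct
        arr = ct.to_numpy()
        if arr.shape == (2, 2) and (stats.contingency.expected_freq(arr) < 5).any():
            result["test"] = "fisher_exact"
            result["p_value"] = float(stats.fisher_exact(arr).pvalue)
        elif arr.shape[0] > 1 and arr.shape[1] > 1:
            chi = stats.chi2_contingency(arr)
            result["test"] = "chi_square"
            result["p_value"] = float(chi.pvalue)
    return counts, result


def plot_forest(table: SubgroupPerformanceTable, path) -> None:
    """Forest-style plot of per-group treatment contrasts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.contrasts
    eff_col = next(
        (c for c in ("mean_difference", "rate_difference", "hazard_ratio") if c in df),
        None,
    )
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(df) + 1.5))
    ypos = np.arange(len(df))[::-1]
    if eff_col is not None:
        ax.errorbar(
            df[eff_col],
            ypos,
            xerr=(
                (df[eff_col] - df.get("ci_lo", df[eff_col])).abs(),
                (df.get("ci_hi", df[eff_col]) - df[eff_col]).abs(),
            ),
            fmt="s",
            color="black",
            capsize=3,
        )
        ax.axvline(1.0 if eff_col == "hazard_ratio" else 0.0, ls="--", color="grey")
        ax.set_xlabel(eff_col.replace("_", " "))
    ax.set_yticks(ypos)
    ax.set_yticklabels(df["group"].astype(str))
    ax.set_title("Per-group treatment contrast")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
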