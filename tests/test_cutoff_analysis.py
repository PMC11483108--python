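"""Cutoff evaluation against definitional arithmetic and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from itrboost.cutoff_analysis import (
    cohens_kappa,
    cutoff_performance,
    dichotomize,
    evaluate_cutoffs,
    results_frame,
)
from itrboost.synthetic_trial import EffectSpec, ThresholdEffect, simulate_trial
from itrboost.trial_data import BINARY, CONTINUOUS, SURVIVAL


def fisher_oracle(tp, fn, fp, tn):
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums P(table) over all tables with the observed margins whose
    probability does not exceed the observed table's (probability-mass
    definition).
    """
    n = tp + fn + fp + tn
    r1 = tp + fn
    c1 = tp + fp
    p_obs = hypergeom.pmf(tp, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = hypergeom.pmf(k, n, r1, c1)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def kappa_oracle(tp, fn, fp, tn):
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    return (po - pe) / (1 - pe) if pe != 1 else (1.0 if po == 1 else 0.0)


def table_to_columns(tp, fn, fp, tn):
    """Expand 2x2 cell counts into (biomarker value, outcome) columns."""
    x = np.r_[np.ones(tp + fp), np.zeros(fn + tn)]
    y = np.r_[np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
    return pd.DataFrame({"x1": x, "y": y})


def eval_one(tp, fn, fp, tn):
    df = table_to_columns(tp, fn, fp, tn)
    results, _ = evaluate_cutoffs(df, "x1", BINARY, cutoffs=[0.5], method="fisher")
    return results[0]


class TestBinaryCutoffMetrics:
    def test_toy_table_definitional_arithmetic(self):
        r = eval_one(tp=8, fn=2, fp=3, tn=7)
        assert r.metrics["sensitivity"] == pytest.approx(0.8)
        assert r.metrics["specificity"] == pytest.approx(0.7)
        assert r.metrics["youden"] == pytest.approx(0.5)
        assert r.n_positive == 11 and r.n_negative == 9

    def test_fisher_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        tables = [(8, 2, 3, 7), (1, 0, 0, 1), (0, 5, 5, 0), (3, 3, 3, 3)]
        tables += [tuple(rng.integers(0, 7, 4)) for _ in range(40)]
        for tp, fn, fp, tn in tables:
            if tp + fn == 0 or fp + tn == 0 or tp + fp == 0 or fn + tn == 0:
                continue
            r = eval_one(tp, fn, fp, tn)
            assert r.metrics["p_value"] == pytest.approx(
                fisher_oracle(tp, fn, fp, tn), abs=1e-12
            ), (tp, fn, fp, tn)

    def test_kappa_matches_closed_form_on_all_small_tables(self):
        for tp, fn, fp, tn in itertools.product(range(4), repeat=4):
            if tp + fp == 0 or fn + tn == 0 or tp + fn + fp + tn == 0:
                continue
            df = table_to_columns(tp, fn, fp, tn)
            k = cohens_kappa(df["x1"].to_numpy() == 1, df["y"].to_numpy())
            assert k == pytest.approx(kappa_oracle(tp, fn, fp, tn), abs=1e-12)

    def test_perfect_agreement_kappa_one(self):
        r = eval_one(tp=10, fn=0, fp=0, tn=10)
        assert r.metrics["kappa"] == pytest.approx(1.0)

    def test_independent_columns_kappa_near_zero(self):
        rng = np.random.default_rng(1)
        n = 10_000
        df = pd.DataFrame(
            {"x1": rng.integers(0, 2, n).astype(float), "y": rng.integers(0, 2, n).astype(float)}
        )
        results, _ = evaluate_cutoffs(df, "x1", BINARY, [0.5], method="kappa")
        assert abs(results[0].metrics["kappa"]) < 0.1

    def test_youden_identity_every_row(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.normal(size=200), "y": rng.integers(0, 2, 200).astype(float)})
        results, _ = evaluate_cutoffs(df, "x1", BINARY, [-1, 0, 1], method="youden")
        for r in results:
            assert r.metrics["youden"] == pytest.approx(
                r.metrics["sensitivity"] + r.metrics["specificity"] - 1.0, abs=1e-15
            )

    def test_direction_flip_preserves_fisher_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=150), "y": rng.integers(0, 2, 150).astype(float)})
        # no observation equals the cutoff, so the two directions give
        # exactly complementary groups and the same exact test
        a, _ = evaluate_cutoffs(df, "x1", BINARY, [0.2], direction=">", method="fisher")
        b, _ = evaluate_cutoffs(df, "x1", BINARY, [0.2], direction="<", method="fisher")
        assert a[0].metrics["p_value"] == pytest.approx(b[0].metrics["p_value"], abs=1e-12)
        assert a[0].metrics["sensitivity"] == pytest.approx(
            1.0 - b[0].metrics["sensitivity"], abs=1e-12
        )

    def test_strict_inequality_convention(self):
        assert dichotomize(np.array([0.5, 0.6]), 0.5, ">").tolist() == [False, True]
        assert dichotomize(np.array([0.5, 0.4]), 0.5, "<").tolist() == [False, True]


class TestSelection:
    def test_threshold_flip_selects_true_cutoff(self):
        """Response rate flips at x1 = 0.5: candidate 0.5 wins by Fisher p."""
        spec = EffectSpec(
            n=600,
            p=2,
            h=ThresholdEffect("x1", 0.5, below=-1.2, above=1.2),
            endpoint=BINARY,
            seed=4,
        )
        ds, _, _ = simulate_trial(spec)
        df = ds.to_frame()
        df["x1"] = (df["x1"] - df["x1"].min()) / (df["x1"].max() - df["x1"].min())
        # rescale so the flip sits near 0.5 on the unit interval
        flip = (0.5 - ds.X["x1"].min()) / (ds.X["x1"].max() - ds.X["x1"].min())
        cands = [0.1, 0.3, float(flip)]
        _, selected = evaluate_cutoffs(df, "x1", BINARY, cands, method="fisher")
        assert selected == pytest.approx(flip)

    def test_youden_selection_matches_brute_force_maximizer(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = (x + rng.normal(0, 1, 400) > 0).astype(float)
        df = pd.DataFrame({"x1": x, "y": y})
        cands = np.quantile(x, [0.2, 0.4, 0.5, 0.6, 0.8]).tolist()
        results, selected = evaluate_cutoffs(df, "x1", BINARY, cands, method="youden")
        best = max(results, key=lambda r: r.metrics["youden"])
        assert selected == best.cutoff

    def test_method_endpoint_compatibility_enforced(self):
        df = pd.DataFrame({"x1": [1.0, 2.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError, match="binary"):
            evaluate_cutoffs(df, "x1", CONTINUOUS, [1.5], method="fisher")

    def test_out_of_range_cutoff_warns(self):
        df = pd.DataFrame({"x1": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 1.0, 0.0, 1.0]})
        with pytest.warns(UserWarning, match="outside observed range"):
            results, _ = evaluate_cutoffs(df, "x1", BINARY, [10.0], method="fisher")
        assert results[0].metrics.get("degenerate") == 1.0

    def test_missing_biomarker_rows_dropped_and_counted(self):
        df = pd.DataFrame(
            {"x1": [0.1, np.nan, 0.7, 0.9, np.nan], "y": [0.0, 1.0, 1.0, 1.0, 0.0]}
        )
        results, _ = evaluate_cutoffs(df, "x1", BINARY, [0.5], method="fisher")
        assert results[0].metrics["n_dropped_missing"] == 2
        assert results[0].n_positive + results[0].n_negative == 3


class TestCutoffPerformance:
    def test_continuous_group_means_recovered(self):
        rng = np.random.default_rng(6)
        n = 500
        x = np.r_[np.ones(n), np.zeros(n)] + 0.01  # positives have x > 0.5
        y = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
        df = pd.DataFrame({"x1": x, "y": y})
        perf = cutoff_performance(df, "x1", 0.5, ">", CONTINUOUS)
        g = perf.groups.set_index("group")
        assert g.loc["biomarker_positive", "mean"] == pytest.approx(1.0, abs=0.15)
        assert g.loc["biomarker_negative", "mean"] == pytest.approx(0.0, abs=0.15)
        assert perf.p_value < 1e-3

    def test_all_censored_survival_flagged(self):
        df = pd.DataFrame(
            {"x1": [0.1, 0.9, 0.2, 0.8], "time": [1.0, 2.0, 3.0, 4.0], "event": [0.0] * 4}
        )
        perf = cutoff_performance(df, "x1", 0.5, ">", SURVIVAL)
        assert perf.p_value is None
        assert any("censored" in n or "no events" in n for n in perf.notes)

    def test_empty_group_degenerate_not_crash(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0], "y": [0.0, 1.0, 0.0]})
        perf = cutoff_performance(df, "x1", 10.0, ">", BINARY)
        assert perf.test_name == "none"
        assert perf.groups["n"].sum() == 3

    def test_null_type_one_error_controlled(self):
        """Identical group distributions: p > 0.01 in >= 95% of replicates."""
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            df = pd.DataFrame({"x1": rng.normal(size=120), "y": rng.normal(size=120)})
            perf = cutoff_performance(df, "x1", 0.0, ">", CONTINUOUS)
            if perf.p_value > 0.01:
                hits += 1
        assert hits >= int(0.95 * reps)


def test_results_frame_flattening():
    df = pd.DataFrame({"x1": [0.0, 1.0, 2.0, 3.0], "y": [0.0, 0.0, 1.0, 1.0]})
    results, _ = evaluate_cutoffs(df, "x1", BINARY, [0.5, 1.5, 2.5], method="youden")
    flat = results_frame(results)
    assert len(flat) == 3
    assert {"cutoff", "sensitivity", "specificity", "youden", "p_value"} <= set(flat.columns)
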