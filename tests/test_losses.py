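"""Oracle-backed tests of the modified-loss family and its derivatives."""

import numpy as np
import pytest

from itrboost.losses import (
    A_LEARNING,
    WEIGHT_LEARNING,
    DegenerateLossError,
    LossConfig,
    composite_loss,
    loss_gradient,
    m_value,
    modified_signal,
)
from itrboost.trial_data import BINARY, CONTINUOUS, SURVIVAL

from conftest import make_trial

ALL_COMBOS = [
    (kind, lt)
    for kind in ("continuous", "binary", "survival")
    for lt in (A_LEARNING, WEIGHT_LEARNING)
]


def null_survival_loss_oracle(time, event, tau):
    """Brute-force null (f=0) modified partial-likelihood mean.

    At v = 0 every patient contributes e^0 = 1 to each risk set, so the
    loss reduces to (1/N) sum over events before tau of log(risk_n / N),
    computed here by explicit risk-set loops.
    """
    n = len(time)
    total = 0.0
    for i in range(n):
        if event[i] == 1 and time[i] <= tau:
            risk = sum(1 for j in range(n) if time[j] >= time[i])
            total += -(0.0 - np.log(risk / n))
    return total / n


class TestMValue:
    @pytest.mark.parametrize(
        "endpoint,y,v,expected",
        [
            (CONTINUOUS, 2.0, 2.0, 0.0),
            (CONTINUOUS, 0.0, 3.0, 9.0),
            (BINARY, 0.0, 0.0, np.log(2.0)),
            (BINARY, 1.0, 0.0, np.log(2.0)),
        ],
    )
    def test_closed_forms(self, endpoint, y, v, expected):
        assert m_value(endpoint, y, v) == pytest.approx(expected, abs=1e-12)

    def test_survival_integrand_vanishes_at_risk_mean(self):
        assert m_value(SURVIVAL, 1.0, 0.7, risk_log_mean=0.7) == 0.0

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            m_value(CONTINUOUS, 0.0, np.inf)

    def test_convex_in_v(self):
        """Second differences along v are nonnegative for every kernel."""
        rng = np.random.default_rng(0)
        for endpoint in (CONTINUOUS, BINARY):
            for _ in range(20):
                y = float(rng.integers(0, 2)) if endpoint is BINARY else rng.normal()
                v = rng.normal(scale=2)
                h = 0.1
                vals = [m_value(endpoint, y, v + k * h) for k in (-1, 0, 1)]
                assert vals[0] - 2 * vals[1] + vals[2] >= -1e-9

    def test_derivative_at_zero_monotone_in_y(self):
        """dM/dv at v=0 decreases in y (continuous: -2y; binary: 1/2 - y)."""
        eps = 1e-6
        for endpoint, ys in ((CONTINUOUS, [-1.0, 0.0, 1.0, 2.0]), (BINARY, [0.0, 1.0])):
            derivs = [
                (m_value(endpoint, y, eps) - m_value(endpoint, y, -eps)) / (2 * eps)
                for y in ys
            ]
            assert all(d1 > d2 for d1, d2 in zip(derivs, derivs[1:]))


class TestModifiedSignal:
    @pytest.mark.parametrize(
        "A,pi,c,w",
        [(1, 0.5, 0.5, 2.0), (-1, 0.5, -0.5, 2.0), (1, 0.25, 0.75, 4.0)],
    )
    def test_examples(self, A, pi, c, w):
        sig = modified_signal(np.array([A]), np.array([pi]))
        assert sig.c[0] == pytest.approx(c)
        assert sig.w[0] == pytest.approx(w)

    def test_invariants_hold_on_random_inputs(self):
        rng = np.random.default_rng(1)
        A = np.where(rng.random(200) < 0.5, 1, -1)
        pi = rng.uniform(0.01, 0.99, 200)
        sig = modified_signal(A, pi)
        assert np.all((sig.c > -1) & (sig.c < 1))
        assert np.all(sig.w > 1)

    def test_degenerate_propensity_rejected(self):
        with pytest.raises(ValueError):
            modified_signal(np.array([1]), np.array([1.0]))


class TestCompositeLoss:
    def test_continuous_a_learning_at_zero_is_mean_y_squared(self):
        ds, _, _ = make_trial("continuous", n=50, seed=3)
        cfg = LossConfig(CONTINUOUS, A_LEARNING)
        loss = composite_loss(ds, np.zeros(50), cfg)
        assert loss == pytest.approx(np.mean(ds.y**2), rel=1e-12)

    @pytest.mark.parametrize("kind", ["continuous", "binary"])
    def test_weight_learning_equal_propensity_doubles_mean_m(self, kind):
        ds, _, _ = make_trial(kind, n=40, seed=4)
        cfg = LossConfig(ds.endpoint, WEIGHT_LEARNING)
        rng = np.random.default_rng(0)
        f = rng.normal(size=40)
        loss = composite_loss(ds, f, cfg)
        plain = np.mean([m_value(ds.endpoint, ds.y[i], ds.A[i] * f[i]) for i in range(40)])
        assert loss == pytest.approx(2.0 * plain, rel=1e-12)

    def test_equal_propensity_scale_identity_continuous(self):
        """With pi = 0.5, c = A/2, so L_A(f) = L_W(f/2) / 2 exactly."""
        ds, _, _ = make_trial("continuous", n=60, seed=6)
        rng = np.random.default_rng(2)
        f = rng.normal(size=60)
        la = composite_loss(ds, f, LossConfig(CONTINUOUS, A_LEARNING))
        lw = composite_loss(ds, f / 2.0, LossConfig(CONTINUOUS, WEIGHT_LEARNING))
        assert la == pytest.approx(lw / 2.0, rel=1e-12)

    def test_survival_null_matches_partial_likelihood_oracle(self):
        ds, _, _ = make_trial("survival", n=60, seed=7)
        cfg = LossConfig(SURVIVAL, A_LEARNING)
        tau = cfg.resolve_tau(ds.time, ds.event)
        expected = null_survival_loss_oracle(ds.time, ds.event, tau)
        assert composite_loss(ds, np.zeros(60), cfg) == pytest.approx(expected, abs=1e-9)

    def test_length_mismatch_rejected(self):
        ds, _, _ = make_trial("continuous", n=20, seed=0)
        with pytest.raises(ValueError, match="length"):
            composite_loss(ds, np.zeros(19), LossConfig(CONTINUOUS))

    def test_no_events_before_tau_degenerate(self):
        ds, _, _ = make_trial("survival", n=30, seed=8)
        cfg = LossConfig(SURVIVAL, A_LEARNING, tau=float(np.min(ds.time)) / 2)
        with pytest.raises(DegenerateLossError):
            composite_loss(ds, np.zeros(30), cfg)

    def test_tau_above_max_time_rejected(self):
        ds, _, _ = make_trial("survival", n=30, seed=8)
        cfg = LossConfig(SURVIVAL, A_LEARNING, tau=float(np.max(ds.time)) * 2)
        with pytest.raises(ValueError, match="tau"):
            composite_loss(ds, np.zeros(30), cfg)


class TestGradients:
    @pytest.mark.parametrize("kind,loss_type", ALL_COMBOS)
    @pytest.mark.parametrize("n", [10, 100])
    def test_matches_central_finite_differences(self, kind, loss_type, n):
        ds, _, _ = make_trial(kind, n=n, seed=9)
        cfg = LossConfig(ds.endpoint, loss_type)
        rng = np.random.default_rng(10)
        f = rng.normal(size=n)
        gh = loss_gradient(ds, f, cfg)
        eps = 1e-6
        idx = rng.choice(n, size=min(n, 20), replace=False)
        for i in idx:
            fp, fm = f.copy(), f.copy()
            fp[i] += eps
            fm[i] -= eps
            fd = (composite_loss(ds, fp, cfg) - composite_loss(ds, fm, cfg)) / (2 * eps)
            assert gh.g[i] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_continuous_a_learning_closed_form_at_zero(self):
        """At f = 0 the mean-scale derivatives are -2 c y / N and 2 c^2 / N."""
        ds, _, _ = make_trial("continuous", n=30, seed=11)
        cfg = LossConfig(CONTINUOUS, A_LEARNING)
        gh = loss_gradient(ds, np.zeros(30), cfg)
        from itrboost.losses import modified_signal

        c = modified_signal(ds.A, ds.pi).c
        np.testing.assert_allclose(gh.g, -2 * c * ds.y / 30, rtol=1e-12)
        np.testing.assert_allclose(gh.h, 2 * c**2 / 30, rtol=1e-12)

    def test_binary_saturated_gradient_vanishes(self):
        ds, _, _ = make_trial("binary", n=20, seed=12)
        ds.y[:] = 1.0
        ds.A[:] = 1
        cfg = LossConfig(BINARY, WEIGHT_LEARNING)
        gh = loss_gradient(ds, np.full(20, 40.0), cfg)
        assert np.all(np.abs(gh.g) < 1e-12)

    def test_hessian_positive(self):
        for kind, lt in ALL_COMBOS:
            ds, _, _ = make_trial(kind, n=40, seed=13)
            gh = loss_gradient(ds, np.zeros(40), LossConfig(ds.endpoint, lt))
            assert np.all(gh.h > 0)
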