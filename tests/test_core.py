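"""Unit and property tests for the model's mathematical core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgrisk import core
from bgrisk.params import AgentParams

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestPredictionErrors:
    @pytest.mark.parametrize(
        "reward,q,expected",
        [(1.0, 0.0, 1.0), (5.5, 5.5, 0.0), (-43.2, 0.0, -43.2)],
    )
    def test_immediate(self, reward, q, expected):
        assert core.td_error_immediate(reward, q) == pytest.approx(expected)

    def test_immediate_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            core.td_error_immediate(float("nan"), 0.0)
        with pytest.raises(ValueError):
            core.td_error_immediate(1.0, float("inf"))

    @pytest.mark.parametrize(
        "r,qn,qc,g,expected",
        [(0.0, 2.0, 1.0, 0.5, 0.0), (4.0, 0.0, 0.0, 0.7, 4.0)],
    )
    def test_discounted(self, r, qn, qc, g, expected):
        assert core.td_error_discounted(r, qn, qc, g) == pytest.approx(expected)

    @given(r=finite, qn=finite, qc=finite)
    @settings(max_examples=50)
    def test_gamma_zero_reduces_to_immediate(self, r, qn, qc):
        assert core.td_error_discounted(r, qn, qc, 0.0) == core.td_error_immediate(
            r, qc
        )

    def test_discounted_rejects_bad_gamma(self):
        for g in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                core.td_error_discounted(1.0, 0.0, 0.0, g)


class TestValueUpdate:
    def test_example(self):
        assert core.update_value(0.0, 1.0, 0.1) == pytest.approx(0.1)

    @given(q=finite, eta=st.floats(0.01, 0.99))
    @settings(max_examples=50)
    def test_zero_error_fixed_point(self, q, eta):
        assert core.update_value(q, 0.0, eta) == q

    def test_constant_reward_convergence_rate(self):
        # exponential smoothing: |q_n - r| = (1 - eta)^n |q_0 - r|
        r, eta, q = 2.0, 0.3, -1.0
        gap0 = abs(q - r)
        for n in range(1, 60):
            q = core.update_value(q, core.td_error_immediate(r, q), eta)
            assert abs(q - r) <= (1 - eta) ** n * gap0 + 1e-12
        assert q == pytest.approx(r, abs=1e-6)

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            core.update_value(0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            core.update_value(0.0, 1.0, 1.0)


class TestRiskUpdate:
    @pytest.mark.parametrize(
        "delta,h,expected", [(1.0, 0.0, 1.0), (-2.0, 1.0, 3.0), (0.0, 0.5, -0.5)]
    )
    def test_risk_error(self, delta, h, expected):
        assert core.risk_error(delta, h) == pytest.approx(expected)

    def test_risk_error_rejects_negative_h(self):
        with pytest.raises(ValueError):
            core.risk_error(1.0, -0.1)

    def test_example(self):
        assert core.update_risk(0.0, 1.0, 0.1) == pytest.approx(0.1)

    @given(
        h0=st.floats(0, 100),
        deltas=st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        eta=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100)
    def test_nonnegativity_invariant(self, h0, deltas, eta):
        """h stays >= 0 under any valid update sequence (convex combination)."""
        h = h0
        for d in deltas:
            h = core.update_risk(h, core.risk_error(d, h), eta)
            assert h >= 0

    def test_constant_delta_fixed_point(self):
        h = 0.0
        for _ in range(400):
            h = core.update_risk(h, core.risk_error(2.0, h), 0.1)
        assert h == pytest.approx(4.0, abs=1e-6)


class TestUtility:
    @pytest.mark.parametrize(
        "q,h,alpha,expected",
        [
            (1.0, 0.25, 1.5, 0.25),
            (-1.0, 0.25, 1.5, -0.25),
            (3.7, 9.0, 0.0, 3.7),
            (0.0, 5.0, 2.0, 0.0),
        ],
    )
    def test_examples(self, q, h, alpha, expected):
        assert core.utility(q, h, alpha) == pytest.approx(expected)

    def test_identity_transform(self):
        assert core.utility(1.0, 0.25, 1.5, risk_transform="identity") == pytest.approx(
            1 - 1.5 * 0.25
        )

    def test_sign_free_variant_always_penalises(self):
        assert core.utility(-1.0, 0.25, 1.5, sign_dependent=False) == pytest.approx(
            -1.0 - 0.75
        )

    def test_rejects_negative_h(self):
        with pytest.raises(ValueError):
            core.utility(1.0, -0.1, 1.0)

    @given(
        q=st.floats(0.01, 100),
        ha=st.floats(0, 50),
        hb=st.floats(0, 50),
        alpha=st.floats(0.01, 5),
    )
    @settings(max_examples=100)
    def test_gain_loss_risk_attitude(self, q, ha, hb, alpha):
        """Lower-risk option wins for gains; the preference flips for losses."""
        if abs(ha - hb) < 1e-9:
            return
        lo, hi = sorted((ha, hb))
        assert core.utility(q, lo, alpha) > core.utility(q, hi, alpha)
        assert core.utility(-q, lo, alpha) < core.utility(-q, hi, alpha)


class TestSoftmaxPolicy:
    def test_hand_computed_example(self):
        p = core.softmax_probs([1.0, 0.0], beta=1.0)
        assert p == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_beta_zero_uniform(self):
        p = core.softmax_probs([3.0, -1.0, 10.0], beta=0.0)
        assert p == pytest.approx([1 / 3] * 3)

    @given(
        u=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=6),
        beta=st.floats(0, 1e3),
    )
    @settings(max_examples=100)
    def test_normalises(self, u, beta):
        p = core.softmax_probs(u, beta)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_equal_utilities_equal_probs(self):
        p = core.softmax_probs([2.5, 2.5, 2.5], beta=7.0)
        assert p == pytest.approx([1 / 3] * 3)

    def test_large_beta_recovers_argmax(self):
        p = core.softmax_probs([0.0, 1.0, 0.5], beta=1e4)
        assert np.argmax(p) == 1
        assert p[1] > 0.999

    def test_overflow_safe(self):
        p = core.softmax_probs([1e5, 0.0], beta=100.0)
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            core.softmax_probs([], beta=1.0)


class TestSampleAction:
    def test_degenerate(self):
        rng = np.random.default_rng(0)
        assert all(core.sample_action([1.0, 0.0], rng) == 0 for _ in range(100))

    def test_empirical_frequencies(self):
        rng = np.random.default_rng(1)
        p = np.array([0.2, 0.5, 0.3])
        n = 100_000
        draws = np.array([core.sample_action(p, rng) for _ in range(n)])
        freqs = np.bincount(draws, minlength=3) / n
        bound = 3 * np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freqs - p) <= bound)

    def test_malformed_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            core.sample_action([0.5, 0.3], rng)
        with pytest.raises(ValueError):
            core.sample_action([1.2, -0.2], rng)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": -0.1},
            {"beta": -1.0},
            {"gamma": 1.0},
            {"gamma": -0.2},
            {"eta_q": 0.0},
            {"eta_q": 1.0},
            {"eta_h": 1.2},
            {"alpha": float("nan")},
            {"risk_transform": "cube"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AgentParams(**kwargs)

    def test_with_revalidates(self):
        p = AgentParams()
        with pytest.raises(ValueError):
            p.with_(alpha=-1)


class TestTables:
    def test_default_zero(self):
        t = core.ValueTable()
        assert t.get(("s", 0)) == 0.0

    def test_risk_table_rejects_negative(self):
        t = core.RiskTable()
        with pytest.raises(ValueError):
            t.set(("s", 0), -1.0)

    def test_trial_record_validates(self):
        with pytest.raises(ValueError):
            core.TrialRecord(0, "s", 0, 1.0, 1.0, 1.0, [0.0, 1.0], [0.6, 0.6])
        with pytest.raises(ValueError):
            core.TrialRecord(0, "s", 5, 1.0, 1.0, 1.0, [0.0, 1.0], [0.5, 0.5])


class TestStationaryOracle:
    def test_single_arm_convergence(self):
        """Running one arm with rewards {3 w.p. 1/3, 0 else}: Q -> mean 1,
        h -> E[delta^2] = Var(r) = 2, within Monte-Carlo tolerance."""
        eta = 0.01
        qs, hs = [], []
        for agent in range(5):
            rng = core.agent_rng(123, agent)
            q = h = 0.0
            for _ in range(100_000):
                r = 3.0 if rng.random() < 1 / 3 else 0.0
                d = core.td_error_immediate(r, q)
                xi = core.risk_error(d, h)
                q = core.update_value(q, d, eta)
                h = core.update_risk(h, xi, eta)
            qs.append(q)
            hs.append(h)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.05)
        assert np.mean(hs) == pytest.approx(2.0, abs=0.15)

    def test_agent_rng_reproducible_and_independent(self):
        a = core.agent_rng(7, 0).random(5)
        b = core.agent_rng(7, 0).random(5)
        c = core.agent_rng(7, 1).random(5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
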