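"""Unit and property tests for the three expectancy updaters."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from winlearn.learners import (
    DecayLearner,
    DecaySpec,
    DeltaLearner,
    DeltaSpec,
    WindowLearner,
    WindowSpec,
    decay_normalised_ev,
    decay_update,
    delta_update,
    make_learner,
    window_expectancy,
)

RELTOL = 1e-12

# outcome values drawn from the coding the tasks actually use (0/1 streams,
# +1/−1 choice outcomes, plus dyadic fractions) — all exactly summable in
# binary floating point, so summation order cannot change the result
dyadic_outcomes = st.sampled_from([0.0, 1.0, -1.0, 0.5, -0.5, 0.25, 0.75])
histories = st.lists(dyadic_outcomes, max_size=60)
widths = st.integers(min_value=1, max_value=40)


class TestWindowExpectancy:
    @pytest.mark.parametrize(
        "history, W, expected",
        [
            ([1, 0, 1, 1], 4, 0.75),
            ([1, 1, 0, 0, 0], 3, 0.0),
            ([1, 1, 1], 2, 1.0),  # only last two enter
            ([1], 4, 1.0),  # partial window: mean of available outcomes
            ([1, 0], 4, 0.5),
        ],
    )
    def test_examples(self, history, W, expected):
        assert window_expectancy(history, WindowSpec(W)) == expected

    def test_empty_history_returns_prior(self):
        assert window_expectancy([], WindowSpec(4)) == 0.0
        assert window_expectancy([], WindowSpec(4, prior_ev=0.3)) == 0.3

    @given(history=histories, W=widths)
    def test_matches_brute_force_slice_mean(self, history, W):
        """Exact agreement with an independent slice-and-average oracle."""
        if not history:
            return
        k = min(len(history), W)
        oracle = float(np.mean(history[-k:]))
        assert window_expectancy(history, WindowSpec(W)) == oracle

    @given(history=histories.filter(bool), W=widths)
    def test_bounded_by_window_contents(self, history, W):
        """The expectancy never leaves the convex hull of the averaged outcomes."""
        k = min(len(history), W)
        window = history[-k:]
        ev = window_expectancy(history, WindowSpec(W))
        assert min(window) <= ev <= max(window)

    @given(
        history=histories, W=widths,
        delta=st.sampled_from([0.5, -0.5, 1.0, 0.25]),
    )
    def test_recency_sensitivity_is_one_over_W(self, history, W, delta):
        """Perturbing the most recent outcome by δ moves a full window's
        expectancy by exactly δ/W — each event carries weight 1/W."""
        if len(history) < W:
            return
        spec = WindowSpec(W)
        bumped = history[:-1] + [history[-1] + delta]
        change = window_expectancy(bumped, spec) - window_expectancy(history, spec)
        assert math.isclose(change, delta / W, rel_tol=RELTOL, abs_tol=1e-15)

    def test_stationary_bernoulli_mean_near_base_rate(self):
        """On a stationary Bernoulli(0.5) stream the average expectancy sits at
        the base rate within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        outcomes = (rng.random(500) < 0.5).astype(float)
        spec = WindowSpec(32)
        evs = [
            window_expectancy(outcomes[:t], spec) for t in range(32, len(outcomes))
        ]
        se = math.sqrt(0.25 / len(evs))
        assert abs(np.mean(evs) - 0.5) < 3 * se

    @pytest.mark.parametrize("bad_W", [0, -1, 2.0])
    def test_invalid_width_rejected(self, bad_W):
        with pytest.raises((ValueError, TypeError)):
            WindowSpec(bad_W)


class TestDeltaRule:
    def test_single_step(self):
        assert delta_update(0.25, 1.0, DeltaSpec(L=0.5)) == 0.625

    @given(ev=st.floats(-5, 5), L=st.floats(0.01, 1.0))
    def test_zero_prediction_error_is_fixed_point(self, ev, L):
        assert delta_update(ev, ev, DeltaSpec(L=L)) == pytest.approx(ev, rel=RELTOL)

    def test_geometric_approach_matches_closed_form(self):
        """Repeated unit outcomes from ev=0: after k updates ev = 1 − (1−L)^k."""
        spec = DeltaSpec(L=0.05)
        ev = 0.0
        for k in range(1, 101):
            ev = delta_update(ev, 1.0, spec)
            assert math.isclose(ev, 1.0 - 0.95**k, rel_tol=RELTOL)

    @pytest.mark.parametrize("bad_L", [0.0, -0.1, 1.5])
    def test_invalid_rate_rejected(self, bad_L):
        with pytest.raises(ValueError):
            DeltaSpec(L=bad_L)


class TestDecayRule:
    def test_constant_input_fixed_point(self):
        # at D = 0.5 the fixed point (1−D)/D = 1
        assert decay_update(1.0, 1.0, DecaySpec(D=0.5)) == 1.0

    def test_zero_absorbing_under_null_input(self):
        for D in (0.05, 0.5, 0.95):
            assert decay_update(0.0, 0.0, DecaySpec(D=D)) == 0.0

    def test_accumulation_matches_closed_form(self):
        """Constant unit input from 0: strength after k steps is
        ((1−D)/D)·(1 − (1−D)^k)."""
        D = 0.05
        spec = DecaySpec(D=D)
        s = 0.0
        for k in range(1, 101):
            s = decay_update(s, 1.0, spec)
            expected = ((1 - D) / D) * (1.0 - (1 - D) ** k)
            assert math.isclose(s, expected, rel_tol=RELTOL)

    @pytest.mark.parametrize(
        "strength, D, expected",
        [(0.0, 0.3, 0.0), (9.5, 0.05, 0.5), (1.0, 0.5, 1.0)],
    )
    def test_normalisation(self, strength, D, expected):
        assert decay_normalised_ev(strength, DecaySpec(D=D)) == pytest.approx(
            expected, rel=RELTOL
        )

    @given(D=st.floats(0.01, 0.99))
    def test_asymptote_normalises_to_one(self, D):
        spec = DecaySpec(D=D)
        assert decay_normalised_ev((1 - D) / D, spec) == pytest.approx(1.0, rel=1e-9)

    @pytest.mark.parametrize("bad_D", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_decay_rejected(self, bad_D):
        with pytest.raises(ValueError):
            DecaySpec(D=bad_D)


class TestStatefulLearners:
    @given(history=histories, W=widths)
    def test_window_learner_tracks_functional_form(self, history, W):
        spec = WindowSpec(W, prior_ev=0.1)
        learner = WindowLearner(spec)
        for t, o in enumerate(history):
            assert learner.expectancy() == window_expectancy(history[:t], spec)
            learner.observe(o)
        assert learner.expectancy() == window_expectancy(history, spec)

    def test_factory_dispatch(self):
        assert isinstance(make_learner(WindowSpec(3)), WindowLearner)
        assert isinstance(make_learner(DeltaSpec(0.5)), DeltaLearner)
        assert isinstance(make_learner(DecaySpec(0.5)), DecayLearner)
        with pytest.raises(TypeError):
            make_learner(object())

    def test_decay_learner_expectancy_is_normalised(self):
        learner = DecayLearner(DecaySpec(D=0.5))
        learner.observe(1.0)  # strength = 0.5·(0+1) = 0.5
        assert learner.strength == 0.5
        assert learner.expectancy() == 0.5  # 0.5·(0.5/0.5)

    def test_all_learners_converge_on_stationary_stream(self):
        """Window, delta, and normalised decay expectancies all settle near
        the Bernoulli base rate on a long stationary stream."""
        rng = np.random.default_rng(7)
        p = 0.5
        outcomes = (rng.random(2000) < p).astype(float)
        for spec in (WindowSpec(32), DeltaSpec(0.05), DecaySpec(0.05)):
            learner = make_learner(spec)
            evs = []
            for o in outcomes:
                evs.append(learner.expectancy())
                learner.observe(o)
            tail = np.asarray(evs[200:])
            se = math.sqrt(p * (1 - p) / tail.size)
            assert abs(tail.mean() - p) < 3 * se, spec
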