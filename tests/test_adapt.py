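"""Entropy gate and adaptation-strategy tests with brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import driftadapt as da
from driftadapt.activities import Activity
from driftadapt.adapt import (
    AdaptationState,
    EntropyGate,
    backward_entropy_update,
    backward_relabel,
    entropy_select,
    maybe_retrain,
    perfect_update,
    threshold,
)
from driftadapt.dataset import EventSample
from driftadapt.errors import ConfigurationError, ValidationError


def hand_entropy(p):
    """Direct summation oracle for -sum p ln p."""
    return -sum(pk * math.log(pk) for pk in p if pk > 0)


def _sample(i=0, mode=Activity.WALK, label=Activity.WALK, with_stride=True, d=4):
    rng = np.random.default_rng(i)
    return EventSample(
        day=2, trial=i // 24, event=i % 24, mode=mode, label=label,
        forward=rng.normal(size=d),
        backward=rng.normal(size=d) if with_stride else None,
    )


class _StubBackward:
    """Backward predictor stub with a fixed posterior rule (test oracle)."""

    def __init__(self, classes, rule):
        self.classes = classes
        self._rule = rule

    def predict_posterior(self, x):
        return self._rule(x)


class TestEntropy:
    def test_one_hot_is_zero(self):
        assert da.entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    @pytest.mark.parametrize("n", [2, 3, 5, 7])
    def test_uniform_is_log_n(self, n):
        assert da.entropy(np.full(n, 1.0 / n)) == pytest.approx(math.log(n), abs=1e-12)

    def test_hand_summed_value(self):
        assert da.entropy(np.array([0.7, 0.2, 0.1])) == pytest.approx(0.801819, abs=1e-5)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            da.entropy(np.array([1.2, -0.2]))

    def test_bad_sum_rejected(self):
        with pytest.raises(ValidationError):
            da.entropy(np.array([0.5, 0.4]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=10))
    def test_matches_oracle_and_bounds(self, raw):
        p = np.array(raw) / np.sum(raw)
        e = da.entropy(p)
        assert e == pytest.approx(hand_entropy(p), abs=1e-9)
        assert 0.0 <= e <= math.log(len(p)) + 1e-12


class TestThreshold:
    def test_reference_five_classes_exact(self):
        assert threshold(5) == 0.6

    def test_single_class_is_zero(self):
        assert threshold(1) == 0.0

    def test_two_classes(self):
        assert threshold(2) == pytest.approx(0.258406, abs=1e-5)

    def test_monotone_in_class_count(self):
        values = [threshold(n) for n in range(1, 10)]
        assert values == sorted(values)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValidationError):
            threshold(0)


class TestEntropySelect:
    def _state(self):
        return AdaptationState(strategy="entropy")

    def test_one_hot_selected(self):
        state = self._state()
        classes = [Activity.WALK, Activity.SIT, Activity.STAND]
        entropy_select(_sample(), np.array([1.0, 0.0, 0.0]), classes,
                       EntropyGate(3), state, 0)
        assert len(state.forward_pool) == 1
        assert state.forward_pool[0].label is Activity.WALK  # predicted label

    def test_uniform_rejected(self):
        state = self._state()
        classes = [Activity.WALK, Activity.SIT, Activity.STAND]
        entropy_select(_sample(), np.full(3, 1 / 3), classes, EntropyGate(3), state, 0)
        assert state.forward_pool == []
        assert state.selection_log[-1]["decision"] is False

    def test_batch_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        classes = [Activity.WALK, Activity.SIT, Activity.STAIR_ASCENT]
        gate = EntropyGate(3)
        state = self._state()
        expected = 0
        for i in range(100):
            p = rng.dirichlet(np.ones(3) * 0.5)
            if hand_entropy(p) < 0.6 / math.log(5) * math.log(3):
                expected += 1
            entropy_select(_sample(i), p, classes, gate, state, 0)
        assert len(state.forward_pool) == expected

    def test_decision_invariant_to_class_permutation(self):
        rng = np.random.default_rng(1)
        gate = EntropyGate(4)
        classes = [Activity.WALK, Activity.SIT, Activity.STAND, Activity.RAMP_ASCENT]
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            perm = rng.permutation(4)
            s1, s2 = self._state(), self._state()
            entropy_select(_sample(), p, classes, gate, s1, 0)
            entropy_select(_sample(), p[perm], [classes[i] for i in perm], gate, s2, 0)
            assert len(s1.forward_pool) == len(s2.forward_pool)

    def test_single_class_mode_never_selected(self):
        """E = 0 and Thr(1) = 0: the strict inequality excludes the sample."""
        state = self._state()
        entropy_select(_sample(mode=Activity.SIT), np.array([1.0]),
                       [Activity.STAND], EntropyGate(1), state, 0)
        assert state.forward_pool == []


class TestBackwardStrategies:
    def test_perfect_backward_stub_reproduces_truth(self):
        classes = sorted(Activity, key=lambda a: a.value)

        def rule_from(label):
            p = np.full(len(classes), 0.0)
            p[classes.index(label)] = 1.0
            return p

        state = AdaptationState(strategy="backward")
        labels = [Activity.WALK, Activity.STAIR_ASCENT, Activity.SIT]
        for i, lab in enumerate(labels):
            stub = _StubBackward(classes, lambda x, lab=lab: rule_from(lab))
            backward_relabel(_sample(i, label=lab), stub, state, 0)
        assert [p.label for p in state.forward_pool] == labels

    def test_constant_predictor_floods_pool_with_walk(self):
        classes = sorted(Activity, key=lambda a: a.value)
        one_hot = np.zeros(len(classes))
        one_hot[classes.index(Activity.WALK)] = 1.0
        stub = _StubBackward(classes, lambda x: one_hot)
        state = AdaptationState(strategy="backward")
        for i in range(10):
            backward_relabel(_sample(i, label=Activity.SIT), stub, state, 0)
        assert all(p.label is Activity.WALK for p in state.forward_pool)

    def test_missing_strides_skipped_with_counting(self):
        classes = sorted(Activity, key=lambda a: a.value)
        stub = _StubBackward(classes, lambda x: np.full(len(classes), 1 / len(classes)))
        state = AdaptationState(strategy="backward")
        n, s = 20, 6
        for i in range(n):
            backward_relabel(_sample(i, with_stride=i >= s), stub, state, 0)
        assert len(state.forward_pool) == n - s
        skipped = [r for r in state.selection_log if r.get("skipped") == "missing_stride"]
        assert len(skipped) == s

    def test_backward_entropy_one_hot_enters_both_pools(self):
        classes = sorted(Activity, key=lambda a: a.value)
        one_hot = np.zeros(len(classes))
        one_hot[0] = 1.0
        stub = _StubBackward(classes, lambda x: one_hot)
        state = AdaptationState(strategy="backward_entropy")
        backward_entropy_update(_sample(), stub, EntropyGate(len(classes)), state, 0)
        assert len(state.forward_pool) == 1 and len(state.backward_pool) == 1

    def test_backward_entropy_uniform_forward_only(self):
        classes = sorted(Activity, key=lambda a: a.value)
        stub = _StubBackward(classes, lambda x: np.full(len(classes), 1 / len(classes)))
        state = AdaptationState(strategy="backward_entropy")
        backward_entropy_update(_sample(), stub, EntropyGate(len(classes)), state, 0)
        assert len(state.forward_pool) == 1 and state.backward_pool == []

    def test_backward_pool_growth_matches_brute_force(self):
        rng = np.random.default_rng(3)
        classes = sorted(Activity, key=lambda a: a.value)
        gate = EntropyGate(len(classes))
        state = AdaptationState(strategy="backward_entropy")
        expected = 0
        for i in range(100):
            p = rng.dirichlet(np.full(len(classes), 0.3))
            if hand_entropy(p) < gate.thr:
                expected += 1
            stub = _StubBackward(classes, lambda x, p=p: p)
            backward_entropy_update(_sample(i), stub, gate, state, 0)
        assert len(state.backward_pool) == expected
        assert len(state.forward_pool) == 100  # forward updates are ungated


class TestPerfectAndScheduler:
    def test_perfect_grows_by_n_with_true_labels(self):
        state = AdaptationState(strategy="perfect")
        labels = [Activity.WALK, Activity.SIT, Activity.RAMP_ASCENT] * 4
        for i, lab in enumerate(labels):
            perfect_update(_sample(i, label=lab), state, 0)
        assert [p.label for p in state.forward_pool] == labels

    def test_retrain_due_after_even_trials(self):
        state = AdaptationState(strategy="perfect", retrain_interval=2)
        due_at = [t for t in range(1, 41) if maybe_retrain(state).due]
        assert due_at == list(range(2, 41, 2))
        assert state.trials_since_retrain == 0

    def test_baseline_never_retrains(self):
        state = AdaptationState(strategy="baseline", retrain_interval=2)
        decisions = [maybe_retrain(state) for _ in range(40)]
        assert not any(d.retrain_forward or d.retrain_backward for d in decisions)

    def test_counter_stays_below_interval(self):
        state = AdaptationState(strategy="entropy", retrain_interval=3)
        for _ in range(20):
            maybe_retrain(state)
            assert 0 <= state.trials_since_retrain < 3

    def test_backward_entropy_schedules_both(self):
        state = AdaptationState(strategy="backward_entropy", retrain_interval=2)
        maybe_retrain(state)
        d = maybe_retrain(state)
        assert d.retrain_forward and d.retrain_backward

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ConfigurationError):
            AdaptationState(strategy="psychic")

    def test_pool_cap_is_fifo(self):
        state = AdaptationState(strategy="perfect", pool_cap=5)
        for i in range(8):
            perfect_update(_sample(i), state, 0)
        assert len(state.forward_pool) == 5
        assert state.forward_pool[0].uid == _sample(3).uid


class TestSelectionPurity:
    def test_selected_samples_purer_than_rejected(self, day1_session):
        """With a trained forward bank, entropy-selected pseudo-labels are
        wrong less often than rejected ones (averaged over 10 seeds)."""
        sel_wrong, rej_wrong = [], []
        for seed in range(10):
            drift = da.default_drift_config(
                seed=100 + seed, days=(1, 2), shift_magnitudes=(0.0, 2.5),
                cov_scales=(1.0, 0.9),
            )
            ds = da.simulate_feature_session(drift=drift, n_days=2, trials_per_day=8,
                                             days=(1, 2))
            bank = da.train_mode_specific(
                list(ds.iter_events(1)), da.NetConfig(seed=seed)
            )
            counts = {True: [0, 0], False: [0, 0]}  # selected -> [wrong, total]
            for ev in ds.iter_events(2):
                post, classes = bank.posterior(ev.mode, ev.forward)
                if len(classes) < 2:
                    continue
                gate = EntropyGate(len(classes))
                selected, _ = gate.admits(post)
                predicted = classes[int(np.argmax(post))]
                counts[selected][0] += int(predicted is not ev.label)
                counts[selected][1] += 1
            if counts[True][1] and counts[False][1]:
                sel_wrong.append(counts[True][0] / counts[True][1])
                rej_wrong.append(counts[False][0] / counts[False][1])
        assert np.mean(sel_wrong) < np.mean(rej_wrong)
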