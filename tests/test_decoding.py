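"""Losses, splits, evaluation and the logistic-regression baseline."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from eegexplain.decoding import (ArchitectureSpec, EEGNetClassifier,
                                 EvaluationResult, TrainedDecoder,
                                 categorical_accuracy, cross_entropy,
                                 evaluate_decoder, make_participant_splits,
                                 pointwise_logreg_baseline,
                                 subset_by_participants, train_decoder)
from eegexplain.simulate import simulate_dataset

from conftest import small_config


# -- cross-entropy ----------------------------------------------------------

def test_cross_entropy_closed_forms():
    assert cross_entropy([[0, 1]], [[0, 1]]) == 0.0
    p = np.full((1, 3), 1 / 3)
    assert np.isclose(cross_entropy([[1, 0, 0]], p), np.log(3))
    assert np.isclose(cross_entropy([[1, 0, 0]], [[0.7, 0.2, 0.1]]),
                      -np.log(0.7))


def test_cross_entropy_clamps_zero_probability_with_warning():
    with pytest.warns(RuntimeWarning, match="clamping"):
        val = cross_entropy([[1.0, 0.0]], [[0.0, 1.0]])
    assert np.isfinite(val) and val > 30  # -log(eps)


def test_cross_entropy_rejects_invalid_probabilities():
    with pytest.raises(ValueError):
        cross_entropy([[1, 0]], [[0.7, 0.7]])
    with pytest.raises(ValueError):
        cross_entropy([[1, 0]], [[-0.1, 1.1]])


# -- accuracy ---------------------------------------------------------------

def test_categorical_accuracy_exact_ratios():
    assert categorical_accuracy(np.arange(10), np.arange(10)) == 1.0
    assert categorical_accuracy(np.array([0, 1, 0, 1]),
                                np.array([0, 0, 0, 0])) == 0.5
    with pytest.raises(ValueError):
        categorical_accuracy(np.array([]), np.array([]))


def test_accuracy_of_permuted_labels_near_chance():
    rng = np.random.default_rng(0)
    labels = np.repeat(np.arange(3), 1000)
    perm = rng.permutation(labels)
    acc = categorical_accuracy(perm, labels)
    # 99% binomial interval around 1/3 at n=3000
    assert abs(acc - 1 / 3) < 2.576 * np.sqrt((1 / 3) * (2 / 3) / 3000)


# -- split plans ------------------------------------------------------------

def test_split_sizes_for_26_participants():
    """round(0.81*26), round(0.10*26), round(0.09*26) -> (21, 3, 2)."""
    plan = make_participant_splits(range(26), n_folds=5, seed=0)
    for train, val, test in plan.folds:
        assert (len(train), len(val), len(test)) == (21, 3, 2)
        assert set(train) | set(val) | set(test) == set(range(26))


def test_split_determinism_and_test_rotation():
    a = make_participant_splits(range(20), n_folds=5, seed=4)
    b = make_participant_splits(range(20), n_folds=5, seed=4)
    assert a == b
    tests = [frozenset(f[2]) for f in a.folds]
    assert len(set(tests)) == 5  # held-out participants vary across folds


def test_split_rejections():
    with pytest.raises(ValueError):
        make_participant_splits(range(2))
    with pytest.raises(ValueError):
        make_participant_splits(range(10), fractions=(0.5, 0.3, 0.1))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(min_value=5, max_value=40),
       folds=st.integers(min_value=2, max_value=6),
       seed=st.integers(min_value=0, max_value=1000))
def test_split_disjointness_property(n, folds, seed):
    plan = make_participant_splits(range(n), n_folds=folds, seed=seed)
    for train, val, test in plan.folds:
        assert not (set(train) & set(test))
        assert not (set(train) & set(val))
        assert not (set(val) & set(test))
        assert set(train) | set(val) | set(test) == set(range(n))


# -- evaluation -------------------------------------------------------------

class _ConstantDecoder:
    def __init__(self, cls):
        self._cls = cls

    def predict(self, X):
        return np.array([self._cls] * len(X))


def test_constant_decoder_scores_one_over_k(tiny_epochs):
    stub = TrainedDecoder(_ConstantDecoder("pre"), ArchitectureSpec(), None, 0,
                          ("post", "pre"))
    res = evaluate_decoder(stub, tiny_epochs)
    assert np.isclose(res.accuracy, 0.5)  # balanced 2-class set
    assert res.accuracy == np.mean(res.per_trial_correct)


def test_evaluation_result_consistency_enforced():
    with pytest.raises(ValueError):
        EvaluationResult(0.9, np.array(["a", "b"]), np.array([True, False]))


def test_unknown_test_class_rejected(tiny_epochs):
    stub = TrainedDecoder(_ConstantDecoder("pre"), ArchitectureSpec(), None, 0,
                          ("pre",))
    with pytest.raises(ValueError, match="unknown"):
        evaluate_decoder(stub, tiny_epochs)


def test_leakage_guard_rejects_participant_overlap(tiny_epochs):
    est = EEGNetClassifier(max_epochs=1, random_state=0)
    part = subset_by_participants(tiny_epochs, [0, 1])
    with pytest.raises(ValueError, match="leakage"):
        train_decoder(est, part, part)


# -- pointwise logistic baseline -------------------------------------------

@pytest.fixture(scope="module")
def logreg_curve():
    """Sharp, jitter-free component so the accuracy peak is identifiable."""
    from eegexplain.simulate import (ComponentSpec, SimConfig,
                                     fibonacci_montage, posterior_pattern)

    montage = fibonacci_montage(16)
    comp = ComponentSpec(0.15, 0.012, 5.0, posterior_pattern(montage, 2, 4),
                         ("post",))
    cfg = SimConfig(n_participants=4, trials_per_class_per_participant=40,
                    class_names=("pre", "post"), components=(comp,),
                    noise_sd=2.0, latency_jitter_sd=0.0, seed=0,
                    montage=montage)
    ep = simulate_dataset(cfg)
    train = subset_by_participants(ep, [0, 1, 2])
    test = subset_by_participants(ep, [3])
    curve, peak = pointwise_logreg_baseline(train, test)
    return cfg, curve, peak


def test_logreg_peaks_at_planted_latency(logreg_curve):
    cfg, curve, peak = logreg_curve
    t_peak = cfg.times[int(np.argmax(curve))]
    assert abs(t_peak - 0.15) <= 2 / cfg.sampling_rate


def test_logreg_chance_before_stimulus_response(logreg_curve):
    """Samples well before the component carry no class information."""
    cfg, curve, _ = logreg_curve
    early = curve[cfg.times < 0.05]
    n_test = 2 * 40  # one held-out participant, two classes
    assert np.all(np.abs(early - 0.5) < 3 * np.sqrt(0.25 / n_test) + 0.05)


def test_logreg_reported_max_is_curve_max(logreg_curve):
    _, curve, peak = logreg_curve
    assert peak == curve.max()
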