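"""Synthetic EEG generator: shapes, determinism, referencing, ground truth."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from eegexplain.simulate import (ComponentSpec, Montage, SimConfig,
                                 default_prepost_config, default_visual_config,
                                 fibonacci_montage, ground_truth_mask,
                                 noiseless_template, posterior_pattern,
                                 simulate_dataset, with_permuted_labels)

from conftest import small_config


def test_dimensional_bookkeeping():
    """3 classes x 4 participants x 50 trials at 256 Hz over 0.75 s."""
    cfg = default_visual_config(n_participants=4, trials_per_class=50)
    ep = simulate_dataset(cfg)
    assert ep.data.shape == (600, 32, 192)
    assert len(ep.labels) == len(ep.participants) == 600
    assert np.isclose(ep.times[1] - ep.times[0], 1 / 256)


def test_class_balance_and_trial_counts():
    ep = simulate_dataset(small_config(trials=8))
    for p in np.unique(ep.participants):
        for cls in np.unique(ep.labels):
            assert np.sum((ep.participants == p) & (ep.labels == cls)) == 8


def test_noise_free_limit_equals_template():
    """With all stochastic terms off, every trial equals the class template."""
    cfg = replace(small_config(), noise_sd=0.0, latency_jitter_sd=0.0,
                  participant_amplitude_sd=0.0, participant_topography_sd=0.0)
    ep = simulate_dataset(cfg)
    for cls in ("pre", "post"):
        tmpl = noiseless_template(cfg, cls)
        trials = ep.data[ep.labels == cls]
        assert np.allclose(trials, tmpl[None], atol=1e-12)


def test_seed_determinism_contract():
    cfg7 = small_config(seed=7)
    a = simulate_dataset(cfg7)
    b = simulate_dataset(small_config(seed=7))
    c = simulate_dataset(small_config(seed=8))
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_common_average_reference():
    ep = simulate_dataset(small_config())
    chan_mean = ep.data.mean(axis=1)
    assert np.max(np.abs(chan_mean)) <= 1e-9 * np.max(np.abs(ep.data))


def test_noise_sd_is_calibrated():
    """Band-limited 1/f background reaches the requested standard deviation."""
    cfg = replace(small_config(n_participants=2, trials=40), components=(),
                  noise_sd=9.0)
    ep = simulate_dataset(cfg)
    # CAR removes ~1/n_channels of the variance
    expected = 9.0 * np.sqrt(1 - 1 / ep.n_channels)
    assert abs(ep.data.std() - expected) / expected < 0.05


def test_grand_average_converges_to_template():
    """Noisy class means approach the noiseless template as 1/sqrt(n)."""
    base = replace(small_config(n_participants=1, trials=64),
                   latency_jitter_sd=0.0, participant_amplitude_sd=0.0,
                   participant_topography_sd=0.0)
    tmpl = noiseless_template(base, "post")
    rms = {}
    for trials in (64, 256):
        cfg = replace(base, trials_per_class_per_participant=trials)
        ep = simulate_dataset(cfg)
        mean = ep.data[ep.labels == "post"].mean(axis=0)
        rms[trials] = np.sqrt(np.mean((mean - tmpl) ** 2))
    ratio = rms[64] / rms[256]
    assert 2 / 3 < ratio < 6  # 1/sqrt(n) predicts 2, allow 3x sampling error


def test_ground_truth_mask_single_component():
    cfg = small_config()
    mask = ground_truth_mask(cfg, "post")
    comp = cfg.components[0]
    chans = np.flatnonzero(np.abs(comp.spatial_pattern) > 0.5)
    tsel = np.abs(cfg.times - 0.15) <= comp.temporal_width
    assert set(np.flatnonzero(mask.any(axis=1))) == set(chans)
    assert np.array_equal(mask.any(axis=0), tsel)
    assert ground_truth_mask(cfg, "pre").sum() == 0  # stimulation-free class


def test_ground_truth_mask_union_of_components():
    montage = fibonacci_montage(16)
    c1 = ComponentSpec(0.15, 0.03, 2.0, posterior_pattern(montage, 2, 4), ("a",))
    c2 = ComponentSpec(0.25, 0.04, 2.0, posterior_pattern(montage, 9, 4), ("a",))
    both = SimConfig(class_names=("a",), components=(c1, c2), montage=montage)
    only1 = SimConfig(class_names=("a",), components=(c1,), montage=montage)
    only2 = SimConfig(class_names=("a",), components=(c2,), montage=montage)
    m = ground_truth_mask(both, "a")
    assert np.array_equal(
        m, ground_truth_mask(only1, "a") | ground_truth_mask(only2, "a"))
    with pytest.raises(ValueError, match="unknown class"):
        ground_truth_mask(both, "b")


def test_component_outside_window_rejected_by_name():
    montage = fibonacci_montage(16)
    comp = ComponentSpec(2.0, 0.03, 1.0, posterior_pattern(montage, 0, 3),
                         ("a",), name="stray")
    with pytest.raises(ValueError, match="stray"):
        SimConfig(class_names=("a",), components=(comp,), montage=montage)


def test_montage_invariants():
    m = fibonacci_montage(32)
    assert len(set(m.channel_labels)) == 32
    assert np.allclose(np.linalg.norm(m.positions, axis=1), 1.0, atol=1e-9)
    assert np.all(m.positions[:, 2] > 0)  # upper hemisphere
    with pytest.raises(ValueError):
        fibonacci_montage(4)


def test_permuted_labels_keep_data():
    ep = simulate_dataset(small_config())
    shuf = with_permuted_labels(ep, seed=3)
    assert np.array_equal(np.sort(shuf.labels), np.sort(ep.labels))
    assert shuf.data is ep.data


@settings(max_examples=20, deadline=None, derandomize=True)
@given(n=st.integers(min_value=8, max_value=64))
def test_fibonacci_montage_any_size_on_sphere(n):
    m = fibonacci_montage(n)
    assert np.allclose(np.linalg.norm(m.positions, axis=1), 1.0, atol=1e-9)
    assert len(m.channel_labels) == n
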