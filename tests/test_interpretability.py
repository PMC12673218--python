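"""Correlation scores, Wilcoxon/FDR statistics, surface Laplacian."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata

from eegexplain.interpretability import (GroupComparison, LaplacianParams,
                                         compare_paired, group_significance,
                                         interpretability_timecourse,
                                         max_score_and_latency,
                                         surface_laplacian,
                                         wilcoxon_signed_rank)
from eegexplain.simulate import fibonacci_montage


# -- correlation time course ------------------------------------------------

def test_self_correlation_is_one():
    rng = np.random.default_rng(0)
    eeg = rng.normal(size=(8, 20))
    r = interpretability_timecourse(eeg, np.abs(eeg))
    assert np.allclose(r[~np.isnan(r)], 1.0)


def test_hand_computed_pearson_signs():
    eeg = np.array([[1.0], [2.0], [-3.0], [4.0]])
    up = np.array([[2.0], [4.0], [6.0], [8.0]])
    down = np.array([[4.0], [3.0], [2.0], [1.0]])
    assert np.isclose(interpretability_timecourse(eeg, up)[0], 1.0)
    assert np.isclose(interpretability_timecourse(eeg, down)[0], -1.0)


def test_random_feature_uncorrelated_on_average():
    rng = np.random.default_rng(1)
    eeg = rng.normal(size=(16, 400))
    feat = rng.random(size=(16, 400))
    r = interpretability_timecourse(eeg, feat)
    assert abs(np.nanmean(r)) < 4 / np.sqrt(400 * 13)  # MC error of mean r


def test_constant_vectors_are_undefined():
    eeg = np.ones((5, 3))
    feat = np.random.default_rng(0).random((5, 3))
    assert np.all(np.isnan(interpretability_timecourse(eeg, feat)))  # flat EEG
    varying = np.abs(np.random.default_rng(1).normal(size=(5, 3)))
    assert np.all(np.isnan(interpretability_timecourse(varying, np.full((5, 3), 2.0))))


def test_too_few_channels_rejected():
    with pytest.raises(ValueError, match="3 channels"):
        interpretability_timecourse(np.ones((2, 4)), np.ones((2, 4)))


def test_max_score_and_latency_rules():
    times = np.array([0.0, 0.1, 0.2])
    assert max_score_and_latency(np.array([0.1, 0.9, 0.4]), times) == (0.9, 0.1)
    assert max_score_and_latency(np.array([0.5, 0.5, 0.1]), times)[1] == 0.0
    # undefined at the would-be maximum: next defined maximum wins
    r = np.array([0.3, np.nan, 0.2])
    assert max_score_and_latency(r, times) == (0.3, 0.0)
    with pytest.raises(ValueError):
        max_score_and_latency(np.array([np.nan, np.nan]), times)


# -- Wilcoxon signed-rank ---------------------------------------------------

def enumeration_p(diffs):
    """Two-sided exact p by brute force over all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4
    ws = np.array([sum(r for s, r in zip(signs, ranks) if s)
                   for signs in product([0, 1], repeat=n)])
    return np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 11))
    d = rng.normal(0.2, 1.0, size=n)  # continuous -> no ties
    _, p, _ = wilcoxon_signed_rank(d)
    assert np.isclose(p, enumeration_p(d), atol=1e-12)


def test_all_positive_signs_exact_p():
    """n=8, every difference positive: p = 2/2^8."""
    d = np.arange(1.0, 9.0)
    _, p, _ = wilcoxon_signed_rank(d)
    assert np.isclose(p, 2 / 2**8)


def test_wilcoxon_zero_handling():
    assert wilcoxon_signed_rank(np.zeros(6)) == (0.0, 1.0, 0)
    # zeros discarded, not ranked
    _, p, n = wilcoxon_signed_rank(np.array([0.0, 0.0, 1.0, 2.0, 3.0]))
    assert n == 3


def test_compare_paired_properties():
    rng = np.random.default_rng(0)
    a = rng.normal(size=12)
    res = compare_paired(a + 1.0, a)
    assert np.isclose(res.p_value, 2 / 2**12)  # all signs equal
    swap = compare_paired(a, a + 1.0)
    assert np.isclose(swap.z_statistic, -res.z_statistic)
    assert np.isclose(swap.p_value, res.p_value)
    same = compare_paired(a, a.copy())
    assert same.z_statistic == 0.0 and same.p_value == 1.0
    with pytest.raises(ValueError):
        compare_paired(a[:3], a[:3])


# -- group significance / FDR ----------------------------------------------

def test_all_zero_timecourses_give_empty_mask():
    mask, p, p_adj = group_significance(np.zeros((8, 30)))
    assert not mask.any()
    assert np.all(p == 1.0)


def test_bh_mask_subset_of_uncorrected():
    rng = np.random.default_rng(2)
    tc = rng.normal(0.1, 0.5, size=(10, 60))
    mask, p, p_adj = group_significance(tc, alpha=0.05)
    assert np.all(~mask | (p < 0.05))  # BH significant => raw significant
    order = np.argsort(p)
    assert np.all(np.diff(p_adj[order]) >= -1e-12)  # monotone adjusted p


def test_group_significance_requires_five_participants():
    with pytest.raises(ValueError):
        group_significance(np.zeros((4, 10)))


def test_scores_of_matched_feature_maps_reach_one():
    """Feature = |EEG| recovers max score 1.0 for every participant."""
    rng = np.random.default_rng(3)
    times = np.arange(50) / 256
    scores = []
    for _ in range(6):
        eeg = rng.normal(size=(16, 50))
        r = interpretability_timecourse(eeg, np.abs(eeg))
        scores.append(max_score_and_latency(r, times)[0])
    assert np.allclose(scores, 1.0)


def test_independent_noise_maps_rarely_significant():
    """FDR keeps the group mask empty for unrelated feature maps in at
    least 95% of seeds at alpha = 0.05."""
    times = np.arange(64) / 256
    empty = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        tcs = []
        for _ in range(8):  # participants
            eeg = rng.normal(size=(16, 64))
            feat = rng.random(size=(16, 64))
            tcs.append(interpretability_timecourse(eeg, feat))
        mask, _, _ = group_significance(np.array(tcs), alpha=0.05)
        empty += not mask.any()
    assert empty >= 0.95 * n_seeds


# -- surface Laplacian ------------------------------------------------------

@pytest.fixture(scope="module")
def montage32():
    return fibonacci_montage(32)


def test_laplacian_annihilates_constants(montage32):
    const = np.ones((32, 4)) * 7.5
    out = surface_laplacian(const, montage32)
    assert np.max(np.abs(out)) < 1e-6 * 7.5


def test_laplacian_linearity(montage32):
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(32, 3)), rng.normal(size=(32, 3))
    a, b = 2.5, -1.25
    lhs = surface_laplacian(a * x + b * y, montage32)
    rhs = (a * surface_laplacian(x, montage32)
           + b * surface_laplacian(y, montage32))
    assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-9 * np.abs(rhs).max())


def test_laplacian_commutes_with_relabeling(montage32):
    from eegexplain.simulate import Montage

    rng = np.random.default_rng(1)
    x = rng.normal(size=(32, 2))
    perm = rng.permutation(32)
    permuted = Montage(tuple(montage32.channel_labels[i] for i in perm),
                       montage32.positions[perm])
    out = surface_laplacian(x, montage32)
    out_p = surface_laplacian(x[perm], permuted)
    assert np.allclose(out_p, out[perm], atol=1e-9 * np.abs(out).max())


def test_laplacian_rejects_duplicate_positions(montage32):
    from eegexplain.simulate import Montage

    pos = montage32.positions.copy()
    pos[1] = pos[0]
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    dup = Montage(montage32.channel_labels, pos)
    with pytest.raises(ValueError, match="duplicate"):
        surface_laplacian(np.zeros((32, 2)), dup)


def test_laplacian_params_validation():
    with pytest.raises(ValueError):
        LaplacianParams(lambda2=0.0)
    with pytest.raises(ValueError):
        LaplacianParams(stiffness=1.0)
    assert LaplacianParams().lambda2 == 1e-5
    assert LaplacianParams().stiffness == 4.7
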