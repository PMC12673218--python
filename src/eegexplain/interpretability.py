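"""Interpretability scoring: similarity of learned features to the EEG signal.

The score at each time point is the Pearson correlation, across channels,
between a participant's attribution map and the absolute amplitude of their
averaged EEG.  Group-level inference uses one-sample Wilcoxon signed-rank
tests against zero at every sample with Benjamini-Hochberg FDR correction;
decoder/method/layer contrasts use paired Wilcoxon tests on per-participant
maximum scores and their latencies.  Scalp topographies can be sharpened
with a spherical-spline surface Laplacian (current source density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class LaplacianParams:
    """Spherical-spline surface Laplacian settings."""

    lambda2: float = 1e-5
    stiffness: float = 4.7

    def __post_init__(self):
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be > 0")
        if self.stiffness <= 2:
            raise ValueError("stiffness must be > 2")


@dataclass
class InterpretabilityResult:
    """Per-participant correlation time courses plus group-level summaries."""

    r_timecourses: np.ndarray  # participants x samples, NaN where undefined
    times: np.ndarray
    group_mask: np.ndarray  # per-sample boolean, FDR-corrected
    p_values: np.ndarray  # per-sample raw p
    p_adjusted: np.ndarray
    max_scores: np.ndarray  # per participant
    max_latencies: np.ndarray  # seconds
    method: str = ""
    layer: str = ""
    network: str = ""


@dataclass(frozen=True)
class GroupComparison:
    z_statistic: float
    p_value: float
    n_pairs: int
    label: str = ""


# --------------------------------------------------------------------------
# correlation time course
# --------------------------------------------------------------------------


def interpretability_timecourse(participant_eeg_mean: np.ndarray,
                                participant_feature: np.ndarray) -> np.ndarray:
    """Per-sample Pearson r across channels between |EEG| and the feature map.

    Samples where either operand is constant across channels yield NaN
    (undefined) and are excluded from downstream maxima.
    """
    eeg = np.abs(np.asarray(participant_eeg_mean, dtype=float))
    feat = np.asarray(participant_feature, dtype=float)
    if eeg.shape != feat.shape:
        raise ValueError("EEG mean and feature map must share the channels x samples grid")
    if eeg.shape[0] < 3:
        raise ValueError("need at least 3 channels for a meaningful correlation")
    if np.any(feat < -1e-9):
        raise ValueError("feature map must be nonnegative (aggregate convention)")
    ec = eeg - eeg.mean(axis=0, keepdims=True)
    fc = feat - feat.mean(axis=0, keepdims=True)
    se = np.sqrt((ec**2).sum(axis=0))
    sf = np.sqrt((fc**2).sum(axis=0))
    # a vector is constant when its range is exactly zero (e.g. a feature map
    # broadcast from a channel-collapsed layer); the subtracted mean alone
    # would leave rounding residue of order eps
    const_e = eeg.max(axis=0) == eeg.min(axis=0)
    const_f = feat.max(axis=0) == feat.min(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ec * fc).sum(axis=0) / (se * sf)
    r[const_e | const_f | (se == 0) | (sf == 0)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def max_score_and_latency(r_timecourse: np.ndarray, times: np.ndarray):
    """Maximum defined correlation and its latency; ties -> earliest time."""
    r = np.asarray(r_timecourse, dtype=float)
    ok = ~np.isnan(r)
    if not ok.any():
        raise ValueError("all samples undefined: no maximum exists")
    i = np.flatnonzero(ok)[np.argmax(r[ok])]  # argmax takes the first maximum
    return float(r[i]), float(times[i])


# --------------------------------------------------------------------------
# Wilcoxon signed-rank machinery
# --------------------------------------------------------------------------


def _signed_rank(diffs: np.ndarray):
    """Zero-discarding signed-rank decomposition: (W+, n, sigma with tie term)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0, 0.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    return w_plus, n, sigma


def _exact_two_sided_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p: P(|W - mu| >= |w_obs - mu|) under the
    sign-flip null, by dynamic programming over doubled (integer) ranks.

    Equivalent to enumerating all 2^n sign assignments, but polynomial; ties
    in |differences| are handled exactly through midranks.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks2 = np.round(2 * stats.rankdata(np.abs(d))).astype(int)
    w_obs2 = int(ranks2[d > 0].sum())
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:  # r >= 2: doubled midranks are positive integers
        counts[r:] = counts[r:] + counts[:-r]
    mu2 = total / 2.0
    dev = abs(w_obs2 - mu2)
    sel = np.abs(np.arange(total + 1) - mu2) >= dev - 1e-9
    return float(counts[sel].sum() / 2.0**n)


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25):
    """Two-sided one-sample signed-rank test of the differences against zero.

    Zeros are discarded; p is exact for n <= ``exact_max_n`` (sign-flip
    enumeration via dynamic programming, ties included) and a
    continuity-corrected normal approximation above; z is always reported
    from the normal form.  All-zero differences return (0.0, 1.0, 0).
    """
    w_plus, n, sigma = _signed_rank(diffs)
    if n == 0:
        return 0.0, 1.0, 0
    mu = n * (n + 1) / 4.0
    delta = w_plus - mu
    if sigma == 0:
        z = 0.0
    else:
        z = (delta - 0.5 * np.sign(delta)) / sigma if delta != 0 else 0.0
    if n <= exact_max_n:
        p = _exact_two_sided_p(diffs)
    else:
        p = float(2 * stats.norm.sf(abs(z))) if sigma > 0 else 1.0
    return float(z), min(p, 1.0), n


def group_significance(timecourses: np.ndarray, alpha: float = 0.05):
    """Per-sample Wilcoxon-vs-zero over participants with BH-FDR correction.

    Returns (mask, raw p, adjusted p).  NaN correlations are treated as
    missing for that sample; samples with no usable data get p = 1.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.ndim != 2:
        raise ValueError("timecourses must be participants x samples")
    if tc.shape[0] < 5:
        raise ValueError("need at least 5 participants for group statistics")
    n_samples = tc.shape[1]
    p = np.ones(n_samples)
    for t in range(n_samples):
        vals = tc[:, t]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2 or np.all(vals == 0):
            p[t] = 1.0
        else:
            _, p[t], _ = wilcoxon_signed_rank(vals)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p, p_adj


def compare_paired(values_a: np.ndarray, values_b: np.ndarray,
                   label: str = "") -> GroupComparison:
    """Two-sided paired Wilcoxon signed-rank contrast (z and p).

    Identical vectors give z = 0, p = 1; swapping the operands flips the
    sign of z and leaves p unchanged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 5:
        raise ValueError("need paired 1-D samples of equal length >= 5")
    z, p, n = wilcoxon_signed_rank(a - b)
    if n == 0:
        return GroupComparison(0.0, 1.0, a.size, label)
    return GroupComparison(z, p, n, label)


# --------------------------------------------------------------------------
# surface Laplacian (current source density)
# --------------------------------------------------------------------------


def surface_laplacian(values: np.ndarray, montage, params: LaplacianParams | None = None,
                      head_radius_m: float = 0.095) -> np.ndarray:
    """Spherical-spline current-source-density transform, per sample.

    Accepts any channels x samples grid (EEG topographies or attribution
    maps) on the montage's unit-sphere electrode layout; removes spatially
    constant offsets and sharpens focal sources.
    """
    import mne

    params = params or LaplacianParams()
    vals = np.asarray(values, dtype=float)
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[0] != montage.n_channels:
        raise ValueError("first axis must match the montage channel count")
    pos = montage.positions * head_radius_m
    uniq = {tuple(np.round(p, 12)) for p in pos}
    if len(uniq) < len(pos):
        raise ValueError("duplicate electrode positions in the montage")
    mne.set_log_level("ERROR")
    info = mne.create_info(list(montage.channel_labels), sfreq=1000.0, ch_types="eeg")
    dig = mne.channels.make_dig_montage(
        ch_pos={ch: p for ch, p in zip(montage.channel_labels, pos)},
        coord_frame="head")
    ev = mne.EvokedArray(vals, info)
    ev.set_montage(dig)
    csd = mne.preprocessing.compute_current_source_density(
        ev, lambda2=params.lambda2, stiffness=params.stiffness,
        sphere=(0.0, 0.0, 0.0, head_radius_m))
    out = csd.data
    return out[:, 0] if np.asarray(values).ndim == 1 else out
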