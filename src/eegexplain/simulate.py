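"""Synthetic multi-participant epoched EEG with planted spatiotemporal components.

The generator emulates a stimulus-locked ERP paradigm: every trial is a sum
of class-specific evoked components (a Gaussian time bump times a fixed
scalp pattern, jittered in latency and scaled per participant) plus
1/f^alpha-shaped background noise, re-referenced to the common average.
Because the components are planted, every downstream stage — decoding,
attribution, interpretability scoring — can be checked against known ground
truth, which the real recordings such pipelines target never provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Montage:
    """Electrode identifiers with unit-sphere 3-D positions."""

    channel_labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), each row unit norm

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if pos.shape != (len(self.channel_labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass(frozen=True)
class ComponentSpec:
    """A single evoked component: Gaussian bump in time times a scalp pattern.

    ``temporal_width`` is the Gaussian standard deviation in seconds;
    ``spatial_pattern`` is a per-channel weight vector normalised to unit
    maximum absolute value; ``class_selector`` lists the classes in which
    the component appears.
    """

    peak_latency: float
    temporal_width: float
    amplitude: float
    spatial_pattern: np.ndarray
    class_selector: tuple[str, ...]
    name: str = "component"

    def __post_init__(self):
        pat = np.asarray(self.spatial_pattern, dtype=float)
        object.__setattr__(self, "spatial_pattern", pat)
        if self.peak_latency < 0:
            raise ValueError(f"{self.name}: peak_latency must be >= 0")
        if self.temporal_width <= 0:
            raise ValueError(f"{self.name}: temporal_width must be > 0")
        if not np.any(pat != 0):
            raise ValueError(f"{self.name}: spatial_pattern must have a nonzero entry")


@dataclass(frozen=True)
class SimConfig:
    n_participants: int = 8
    trials_per_class_per_participant: int = 50
    class_names: tuple[str, ...] = ("wood", "flower", "fruit")
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (0.0, 0.75)
    components: tuple[ComponentSpec, ...] = ()
    noise_sd: float = 9.0
    noise_spectral_exponent: float = 1.0
    latency_jitter_sd: float = 0.01
    participant_amplitude_sd: float = 0.2
    participant_topography_sd: float = 0.1
    seed: int = 0
    montage: Montage | None = None

    def __post_init__(self):
        if self.n_participants <= 0 or self.trials_per_class_per_participant <= 0:
            raise ValueError("participant and trial counts must be > 0")
        if len(self.class_names) == 0:
            raise ValueError("at least one class is required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("epoch end must exceed start")
        if self.noise_sd < 0 or self.latency_jitter_sd < 0:
            raise ValueError("noise_sd and latency_jitter_sd must be >= 0")
        duration = self.epoch_window[1] - self.epoch_window[0]
        for comp in self.components:
            if comp.temporal_width >= duration:
                raise ValueError(f"{comp.name}: temporal_width exceeds epoch duration")
            if not (self.epoch_window[0] <= comp.peak_latency <= self.epoch_window[1]):
                raise ValueError(
                    f"component {comp.name!r}: peak {comp.peak_latency} s outside "
                    f"epoch window {self.epoch_window}"
                )
            for cls in comp.class_selector:
                if cls not in self.class_names:
                    raise ValueError(f"{comp.name}: unknown class {cls!r}")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sampling_rate))
        return self.epoch_window[0] + np.arange(n) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass
class EpochsSet:
    """Trials x channels x samples with labels, participant ids and time axis."""

    data: np.ndarray
    labels: np.ndarray  # per-trial class name (str array)
    participants: np.ndarray  # per-trial participant id (int array)
    times: np.ndarray
    montage: Montage
    sampling_rate: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.participants = np.asarray(self.participants)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.participants) == n):
            raise ValueError("data, labels and participants must agree on trial count")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count does not match time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.sampling_rate, rtol=1e-6):
            raise ValueError("times must be uniform at 1/sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def class_names(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def select(self, mask: np.ndarray) -> "EpochsSet":
        return EpochsSet(self.data[mask], self.labels[mask], self.participants[mask],
                         self.times, self.montage, self.sampling_rate)


# --------------------------------------------------------------------------
# montage construction
# --------------------------------------------------------------------------


def fibonacci_montage(n_channels: int = 32) -> Montage:
    """Quasi-uniform electrode layout on the upper unit hemisphere.

    Uses a Fibonacci lattice; labels carry a coarse scalp-region suffix
    (frontal / central / parietal / occipital by the anterior axis).
    """
    if n_channels < 8:
        raise ValueError("need >= 8 channels for a usable montage")
    i = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - (i + 0.5) / n_channels  # z in (0, 1): upper hemisphere
    r = np.sqrt(1.0 - z**2)
    theta = golden * i
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    labels = []
    for k, (x, y, _) in enumerate(pos):
        if y > 0.33:
            region = "frontal"
        elif y > -0.1:
            region = "central"
        elif y > -0.55:
            region = "parietal"
        else:
            region = "occipital"
        labels.append(f"E{k:02d}_{region}")
    return Montage(tuple(labels), pos)


def posterior_pattern(montage: Montage, center_idx: int, n_active: int = 6) -> np.ndarray:
    """Unit-max-abs pattern active on the ``n_active`` channels nearest ``center_idx``."""
    d = np.linalg.norm(montage.positions - montage.positions[center_idx], axis=1)
    order = np.argsort(d)
    pat = np.zeros(montage.n_channels)
    pat[order[:n_active]] = 1.0 - 0.3 * (np.arange(n_active) / max(n_active - 1, 1))
    return pat


# --------------------------------------------------------------------------
# default study configurations
# --------------------------------------------------------------------------


def default_visual_config(seed: int = 0, n_participants: int = 8,
                          trials_per_class: int = 50) -> SimConfig:
    """Three-image-category design: one evoked component per class at 0.15 s,
    each over a distinct 6-channel group, so classes differ by topography."""
    montage = fibonacci_montage(32)
    centers = (2, 9, 16)  # well-separated lattice sites
    comps = tuple(
        ComponentSpec(peak_latency=0.15, temporal_width=0.03, amplitude=3.0,
                      spatial_pattern=posterior_pattern(montage, c, 6),
                      class_selector=(cls,), name=f"evoked_{cls}")
        for cls, c in zip(("wood", "flower", "fruit"), centers)
    )
    return SimConfig(n_participants=n_participants,
                     trials_per_class_per_participant=trials_per_class,
                     class_names=("wood", "flower", "fruit"),
                     components=comps, seed=seed, montage=montage)


def default_prepost_config(seed: int = 0, n_participants: int = 8,
                           trials_per_class: int = 100) -> SimConfig:
    """Stimulation paradigm: 'post' trials carry an evoked component, 'pre'
    trials are stimulation-free (background noise only)."""
    montage = fibonacci_montage(32)
    comp = ComponentSpec(peak_latency=0.15, temporal_width=0.03, amplitude=3.0,
                         spatial_pattern=posterior_pattern(montage, 2, 6),
                         class_selector=("post",), name="evoked_post")
    return SimConfig(n_participants=n_participants,
                     trials_per_class_per_participant=trials_per_class,
                     class_names=("pre", "post"),
                     components=(comp,), seed=seed, montage=montage)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                      sd: float, alpha: float, sampling_rate: float,
                      band: tuple[float, float] = (1.0, 40.0)) -> np.ndarray:
    """Band-limited Gaussian noise with a 1/f^alpha amplitude spectrum.

    The background emulates broadband EEG after the usual 1-40 Hz bandpass:
    power follows f^-alpha inside ``band`` and is zero outside, and the
    output standard deviation equals ``sd`` exactly in expectation.
    """
    white = rng.standard_normal(shape + (n_samples,))
    if sd == 0:
        return np.zeros_like(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    lo, hi = band
    hi = min(hi, sampling_rate / 2.0)
    H = np.zeros_like(freqs)
    sel = (freqs >= lo) & (freqs <= hi)
    H[sel] = freqs[sel] ** (-alpha / 2.0)
    if not np.any(sel):  # degenerate sampling rate: keep all nonzero bins
        H[1:] = freqs[1:] ** (-alpha / 2.0)
    spec = np.fft.rfft(white, axis=-1) * H
    shaped = np.fft.irfft(spec, n=n_samples, axis=-1)
    # Parseval: variance of filtered unit-variance white noise
    full_power = H[0] ** 2 + 2 * np.sum(H[1:-1] ** 2) + (
        H[-1] ** 2 if n_samples % 2 == 0 else 2 * H[-1] ** 2)
    var = full_power / n_samples**2 * n_samples  # = full_power / n
    return shaped * (sd / np.sqrt(var / 1.0))


def noiseless_template(config: SimConfig, class_name: str) -> np.ndarray:
    """Channels x samples evoked template of a class (no noise, no jitter,
    population-level participant factors)."""
    montage = config.montage or fibonacci_montage(32)
    times = config.times
    out = np.zeros((montage.n_channels, times.size))
    for comp in config.components:
        if class_name in comp.class_selector:
            bump = np.exp(-0.5 * ((times - comp.peak_latency) / comp.temporal_width) ** 2)
            out += comp.amplitude * np.outer(comp.spatial_pattern, bump)
    out -= out.mean(axis=0, keepdims=True)  # common average reference
    return out


def simulate_dataset(config: SimConfig) -> EpochsSet:
    """Generate the full multi-participant epoched dataset.

    Trial order is participant-major, then class, then trial index, so the
    dataset is balanced by construction: every (participant, class) cell has
    exactly ``trials_per_class_per_participant`` trials.  Identical configs
    (including seed) yield bit-identical output.
    """
    montage = config.montage or fibonacci_montage(32)
    rng = np.random.default_rng(config.seed)
    times = config.times
    n_t = times.size
    n_ch = montage.n_channels
    classes = config.class_names
    tpc = config.trials_per_class_per_participant

    # per-(participant, component) factors, drawn once per participant
    amp_factor = {}
    topo_pert = {}
    for p in range(config.n_participants):
        for ci, comp in enumerate(config.components):
            amp_factor[p, ci] = 1.0 + config.participant_amplitude_sd * rng.standard_normal()
            topo_pert[p, ci] = (config.participant_topography_sd
                                * np.max(np.abs(comp.spatial_pattern))
                                * rng.standard_normal(n_ch))

    data, labels, participants = [], [], []
    lo, hi = config.epoch_window
    for p in range(config.n_participants):
        for cls in classes:
            sig = np.zeros((tpc, n_ch, n_t))
            for ci, comp in enumerate(config.components):
                if cls not in comp.class_selector:
                    continue
                jitter = rng.normal(0.0, config.latency_jitter_sd, size=tpc)
                peak = np.clip(comp.peak_latency + jitter, lo, hi)
                bump = np.exp(-0.5 * ((times[None, :] - peak[:, None])
                                      / comp.temporal_width) ** 2)
                pattern = comp.spatial_pattern + topo_pert[p, ci]
                amp = comp.amplitude * amp_factor[p, ci]
                sig += amp * pattern[None, :, None] * bump[:, None, :]
            noise = _one_over_f_noise(rng, (tpc, n_ch), n_t, config.noise_sd,
                                      config.noise_spectral_exponent,
                                      config.sampling_rate)
            trials = sig + noise
            trials -= trials.mean(axis=1, keepdims=True)  # common average ref
            data.append(trials)
            labels.extend([cls] * tpc)
            participants.extend([p] * tpc)

    return EpochsSet(np.concatenate(data, axis=0), np.asarray(labels),
                     np.asarray(participants, dtype=int), times, montage,
                     config.sampling_rate)


def ground_truth_mask(config: SimConfig, class_name: str) -> np.ndarray:
    """Binary channels x samples mask of where a class's components live.

    A cell is 1 when any component of the class has |spatial weight| > 0.5 on
    that channel and the sample lies within one temporal width of the peak.
    """
    if class_name not in config.class_names:
        raise ValueError(f"unknown class {class_name!r}")
    montage = config.montage or fibonacci_montage(32)
    times = config.times
    mask = np.zeros((montage.n_channels, times.size), dtype=int)
    for comp in config.components:
        if class_name not in comp.class_selector:
            continue
        chan = np.abs(comp.spatial_pattern) > 0.5
        tsel = np.abs(times - comp.peak_latency) <= comp.temporal_width
        mask[np.ix_(chan, tsel)] = 1
    return mask


def with_permuted_labels(epochs: EpochsSet, seed: int) -> EpochsSet:
    """Return a copy whose trial labels are randomly permuted (chance-level control)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(epochs.n_trials)
    return EpochsSet(epochs.data, epochs.labels[perm], epochs.participants,
                     epochs.times, epochs.montage, epochs.sampling_rate)
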