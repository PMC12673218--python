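import numpy as np
import pytest

from eegexplain.decoding import (ArchitectureSpec, EEGNetClassifier,
                                 ResidualCNNClassifier, TrainedDecoder)
from eegexplain.simulate import (ComponentSpec, Montage, SimConfig,
                                 fibonacci_montage, posterior_pattern,
                                 simulate_dataset)


def small_config(seed: int = 0, n_participants: int = 4, trials: int = 8,
                 n_channels: int = 16, noise_sd: float = 4.0) -> SimConfig:
    """A fast two-class configuration with one planted component."""
    montage = fibonacci_montage(n_channels)
    comp = ComponentSpec(peak_latency=0.15, temporal_width=0.03, amplitude=3.0,
                         spatial_pattern=posterior_pattern(montage, 2, 4),
                         class_selector=("post",), name="evoked_post")
    return SimConfig(n_participants=n_participants,
                     trials_per_class_per_participant=trials,
                     class_names=("pre", "post"), components=(comp,),
                     noise_sd=noise_sd, seed=seed, montage=montage)


@pytest.fixture(scope="session")
def tiny_epochs():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def fitted_eegnet(tiny_epochs):
    """A briefly trained compact CNN; enough structure for gradient tests."""
    est = EEGNetClassifier(max_epochs=3, batch_size=16, random_state=1)
    est.fit(tiny_epochs.data, tiny_epochs.labels)
    return TrainedDecoder(est, ArchitectureSpec(), est.history_, 0,
                          tuple(est.classes_))


@pytest.fixture(scope="session")
def fitted_resnet(tiny_epochs):
    est = ResidualCNNClassifier(n_blocks=2, max_epochs=2, batch_size=16,
                                random_state=1)
    est.fit(tiny_epochs.data, tiny_epochs.labels)
    return TrainedDecoder(est, ArchitectureSpec(family="residual_small",
                                                residual_blocks=2),
                          est.history_, 0, tuple(est.classes_))
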