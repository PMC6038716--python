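import numpy as np
import pytest

from decodem import (
    AnalysisConfig,
    ClassSpec,
    Component,
    EpochSet,
    SimDesign,
    simulate_epochs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_epochs(rng):
    """10 trials x 4 channels x 20 samples, two event codes."""
    times = -100 + np.arange(20) * 1000.0 / 100.0  # 100 Hz
    return EpochSet(
        data=rng.standard_normal((10, 4, 20)),
        times=times,
        srate=100.0,
        event_code=np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]),
        channels=["C1", "C2", "C3", "C4"],
        positions=np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float),
        subject_id="S01",
    )


@pytest.fixture
def two_class_spec():
    return ClassSpec.from_strings(["1", "2"])


def planted_design(
    amp=2.0,
    latency=150.0,
    width=100.0,
    n_channels=6,
    n_per_class=30,
    srate=40.0,
    window=(-100.0, 400.0),
    noise_sd=1.0,
    seed=None,
):
    """Two-class design where code 1 carries a component that code 2 lacks."""
    topo = np.zeros(n_channels)
    topo[: max(n_channels // 3, 1)] = 1.0
    comp = Component(
        topography=topo, latency_ms=latency, width_ms=width, amplitudes={1: amp}
    )
    from decodem import NoiseSpec

    return SimDesign(
        event_counts={1: n_per_class, 2: n_per_class},
        components=[comp],
        noise=NoiseSpec(sd=noise_sd, channel_corr=0.2, spectral_exponent=1.0),
        srate=srate,
        epoch_window_ms=window,
        n_channels=n_channels,
        seed=seed,
    )


@pytest.fixture
def planted_epochs():
    return simulate_epochs(planted_design(seed=7))


@pytest.fixture
def default_cfg():
    return AnalysisConfig(nfolds=4, seed=11)
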