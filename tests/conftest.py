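import numpy as np
import pytest

from catsync import lfp_signal, synthgen


def make_phase_decomposition(
    rng: np.random.Generator,
    n_channels: int = 2,
    n_trials: int = 40,
    n_freqs: int = 10,
    n_times: int = 100,
) -> lfp_signal.SpectralDecomposition:
    """Decomposition with i.i.d. uniform phases — an exact synchrony null."""
    W = np.exp(
        1j * rng.uniform(-np.pi, np.pi, (n_channels, n_trials, n_freqs, n_times))
    ).astype(np.complex64)
    return lfp_signal.SpectralDecomposition(
        W=W,
        freqs=np.linspace(10.0, 40.0, n_freqs),
        times=np.linspace(0.0, 1.0, n_times),
        fs=100.0,
        valid=np.ones((n_freqs, n_times), bool),
    )


def dec_from_phases(phases: np.ndarray, freqs=None, fs: float = 333.0):
    """Wrap explicit phases [channel x trial x freq x time] as a decomposition."""
    W = np.exp(1j * np.asarray(phases)).astype(np.complex64)
    n_f, n_t = W.shape[2], W.shape[3]
    return lfp_signal.SpectralDecomposition(
        W=W,
        freqs=np.asarray(freqs) if freqs is not None else np.linspace(10, 40, n_f),
        times=np.arange(n_t) / fs,
        fs=fs,
        valid=np.ones((n_f, n_t), bool),
    )


@pytest.fixture(scope="session")
def tiny_session() -> synthgen.SessionRecording:
    """Small reference session: 4 channels, 40 trials, one injected beta
    coupling (Category epoch, Above-selective) and one phase-locked,
    category-gained spiking electrode."""
    cfg = synthgen.GeneratorConfig(
        n_channels={"AIP": 2, "cPFC": 2, "lPFC": 0},
        n_trials=40,
        seed=11,
        coupling_spec=(
            synthgen.CouplingSpec((0, 2), band="beta", epoch="category",
                                  kappa_above=2.0, kappa_below=0.2),
        ),
        spike_spec=tuple(
            synthgen.SpikeSpec(
                electrode=e,
                n_units=2,
                baseline_rate=5.0,
                gain_above=2.0 if e == 2 else 1.0,
                mod_depth=0.4 if e == 2 else 0.0,
                lfp_channel=0 if e == 2 else None,
            )
            for e in range(4)
        ),
    )
    return synthgen.generate_session(cfg)


@pytest.fixture(scope="session")
def tiny_dec(tiny_session):
    clean, fs = lfp_signal.preprocess_lfp(tiny_session.lfp, tiny_session.fs)
    return lfp_signal.morlet_transform(
        clean,
        fs,
        times=lfp_signal.decimate_times(tiny_session.times),
        time_range=(-1.2, 2.4),
    )
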