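"""Seeded synthetic multi-electrode sessions with known injected structure.

Each session emulates one recording day of a delayed match-to-spatial-
category experiment: per-channel LFP traces (1 kHz, mV) from three areas
(AIP, cPFC, lPFC), sorted spike times per electrode, and a behavioral
trial table.  The LFP is a sum of

* pink (1/f^alpha) background noise,
* 60 Hz line noise with trial-random phase,
* stimulus-locked evoked transients identical across trials, and
* band-limited latent oscillators shared within designated channel pairs,
  each channel reading the latent phase through an independent von Mises
  jitter whose concentration kappa depends on the trial's category and the
  trial epoch — the ground truth for pairwise phase consistency.

Spikes are inhomogeneous Poisson with a category-dependent rate gain after
sample onset and optional sinusoidal modulation by the phase of a target
LFP oscillation:  lambda(t) = lambda0 * g_cat * (1 + m cos(phi(t) - phi_pref)).
With jitter concentration kappa on both channels of a pair the expected
PPC of their phase differences is (I1(kappa)/I0(kappa))**4; with
modulation depth m the expected spike-field PLV is m/2.

All randomness derives from one master seed through per-(stream, channel,
trial) generators, so regeneration is deterministic and order-independent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .task_model import TaskGeometry, make_trial_table

SCHEMA_VERSION = "1"

#: Frequency bands (Hz) of the analysis, one octave each.
BANDS: dict[str, tuple[float, float]] = {"beta": (16.0, 32.0), "delta": (2.0, 4.0)}

#: Trial epochs (s from sample onset).
EPOCHS: dict[str, tuple[float, float]] = {
    "category": (0.0, 1.3),
    "shift": (1.3, 2.3),
}

AREAS = ("AIP", "cPFC", "lPFC")


@dataclass(frozen=True)
class Timeline:
    """Event markers in seconds relative to sample onset."""

    baseline_start: float = -4.2
    fixation_on: float = -1.2
    sample_on: float = 0.0
    sample_off: float = 0.8
    shift_on: float = 1.3
    test_on: float = 2.3
    second_test_on: float = 3.8
    trial_end: float = 4.3

    def __post_init__(self) -> None:
        marks = [
            self.baseline_start,
            self.fixation_on,
            self.sample_on,
            self.sample_off,
            self.shift_on,
            self.test_on,
            self.second_test_on,
            self.trial_end,
        ]
        if not all(a < b for a, b in zip(marks, marks[1:])):
            raise ValueError("timeline markers must be strictly increasing")

    @property
    def baseline_window(self) -> tuple[float, float]:
        """3 s pre-trial baseline (before fixation onset)."""
        return (self.baseline_start, self.fixation_on)

    @property
    def fixation_baseline(self) -> tuple[float, float]:
        """Last 750 ms of the 1 s fixation window."""
        fix_end = self.fixation_on + 1.0
        return (fix_end - 0.75, fix_end)


@dataclass(frozen=True)
class CouplingSpec:
    """Category-conditional phase coupling between one channel pair."""

    pair: tuple[int, int]
    band: str = "beta"
    epoch: str = "category"
    kappa_above: float = 0.0
    kappa_below: float = 0.0
    amplitude: float = 0.08  # mV rms of each channel's oscillatory component

    def __post_init__(self) -> None:
        if self.kappa_above < 0 or self.kappa_below < 0:
            raise ValueError("von Mises concentrations must be >= 0")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")


@dataclass(frozen=True)
class SpikeSpec:
    """Spiking model for one electrode (2-3 pooled units by default)."""

    electrode: int
    n_units: int = 2
    baseline_rate: float = 5.0  # Hz per unit
    gain_above: float = 1.0
    gain_below: float = 1.0
    mod_depth: float = 0.0  # m in [0, 1)
    preferred_phase: float = 0.0  # rad
    lfp_channel: int | None = None  # channel whose oscillation drives phase
    band: str = "beta"

    def __post_init__(self) -> None:
        if not 0 <= self.mod_depth < 1:
            raise ValueError("mod_depth must lie in [0, 1) to keep the rate nonnegative")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.n_units < 1:
            raise ValueError("each electrode needs at least one unit")


@dataclass(frozen=True)
class GeneratorConfig:
    n_channels: dict[str, int] = field(
        default_factory=lambda: {"AIP": 3, "cPFC": 3, "lPFC": 2}
    )
    n_trials: int = 120
    timeline: Timeline = field(default_factory=Timeline)
    sampling_rate: float = 1000.0
    pink_noise_exponent: float = 1.0
    pink_noise_rms: float = 0.1  # mV
    line_noise_amplitude: float = 0.02  # mV at 60 Hz
    evoked_amplitude: float = 0.05  # mV peak of the stimulus-locked transient
    coupling_spec: tuple[CouplingSpec, ...] = ()
    spike_spec: tuple[SpikeSpec, ...] = ()
    lapse_rate: float = 0.07
    seed: int = 0

    @property
    def total_channels(self) -> int:
        return sum(self.n_channels.values())

    def channel_table(self) -> pd.DataFrame:
        rows = []
        cid = 0
        for area in AREAS:
            for _ in range(self.n_channels.get(area, 0)):
                rows.append({"id": cid, "area": area})
                cid += 1
        return pd.DataFrame(rows, columns=["id", "area"])

    def validate(self) -> None:
        n = self.total_channels
        for cs in self.coupling_spec:
            if not all(0 <= c < n for c in cs.pair) or cs.pair[0] == cs.pair[1]:
                raise ValueError(f"coupling pair {cs.pair} references unknown channels")
        for ss in self.spike_spec:
            if not 0 <= ss.electrode < n:
                raise ValueError(f"spike spec references unknown electrode {ss.electrode}")
            if ss.lfp_channel is not None and not 0 <= ss.lfp_channel < n:
                raise ValueError(
                    f"spike spec targets unknown LFP channel {ss.lfp_channel}"
                )


def default_config(seed: int = 0, n_trials: int = 120) -> GeneratorConfig:
    """The reference session: beta coupling in the Category epoch and delta
    coupling in the Shift epoch, both selective for Above/Below only, plus
    category-gained cPFC spiking phase-locked to AIP beta."""
    return GeneratorConfig(
        n_trials=n_trials,
        seed=seed,
        coupling_spec=(
            CouplingSpec((0, 3), band="beta", epoch="category", kappa_above=2.0, kappa_below=0.2),
            CouplingSpec((1, 4), band="delta", epoch="shift", kappa_above=2.0, kappa_below=0.2),
        ),
        spike_spec=tuple(
            SpikeSpec(
                electrode=e,
                n_units=2,
                baseline_rate=5.0,
                gain_above=2.0 if e in (3, 4) else 1.0,
                gain_below=1.0,
                mod_depth=0.4 if e == 3 else 0.0,
                lfp_channel=0 if e == 3 else None,
                band="beta",
            )
            for e in range(8)
        ),
    )


# ---------------------------------------------------------------------------
# Session container
# ---------------------------------------------------------------------------


@dataclass
class SessionRecording:
    """One simulated recording day.

    ``lfp`` is [channel x trial x sample] in mV at ``fs`` Hz on ``times``
    (s from sample onset).  ``spikes[electrode][trial][unit]`` is a sorted
    array of spike times in seconds.  ``ground_truth`` keeps the generator
    config that produced the session.
    """

    lfp: np.ndarray
    fs: float
    times: np.ndarray
    spikes: list[list[list[np.ndarray]]]
    channels: pd.DataFrame
    trials: pd.DataFrame
    ground_truth: GeneratorConfig

    def pooled_spikes(self, electrode: int) -> list[np.ndarray]:
        """Multiunit: merged spike times of all units per trial."""
        per_trial = self.spikes[electrode]
        if not per_trial or not per_trial[0]:
            raise ValueError(f"electrode {electrode} has no units")
        return [np.sort(np.concatenate(units)) if units else np.array([]) for units in per_trial]

    def validate(self) -> list[str]:
        """Internal consistency checks; returns a list of warnings."""
        notes: list[str] = []
        if not np.all(np.isfinite(self.lfp)):
            raise ValueError("LFP contains non-finite samples")
        t0, t1 = self.times[0], self.times[-1]
        for e, per_trial in enumerate(self.spikes):
            count = 0
            for units in per_trial:
                for st in units:
                    count += st.size
                    if st.size and (st.min() < t0 or st.max() > t1 + 1.0 / self.fs):
                        raise ValueError(f"electrode {e} has spikes outside the trial window")
            if count == 0:
                notes.append(f"electrode {e} fired no spikes in this session")
        return notes


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *stream])


def _pink_noise(n: int, exponent: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^alpha noise with unit rms, via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()

def evoked_template(times: np.ndarray, onset: float, amplitude: float) -> np.ndarray:
    """Damped 10 Hz wavelet starting at ``onset``: an alpha-function
    envelope (tau = 50 ms) times a sinusoid, ~300 ms long."""
    dt = times - onset
    env = np.where(dt > 0, (dt / 0.05) * np.exp(1 - dt / 0.05), 0.0)
    return amplitude * env * np.sin(2 * np.pi * 10.0 * np.clip(dt, 0, None))


def _band_filter(band: tuple[float, float], fs: float):
    return sps.butter(4, band, btype="bandpass", fs=fs, output="sos")


def _latent_oscillator(
    n: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-rms analytic narrowband Gaussian process a(t) e^{i phi(t)}."""
    x = rng.standard_normal(n)
    sos = _band_filter(band, fs)
    xb = sps.sosfiltfilt(sos, x)
    z = sps.hilbert(xb)
    return z / np.sqrt(np.mean(np.abs(z) ** 2) / 2.0)


def _epoch_jitter_series(
    times: np.ndarray,
    epoch: tuple[float, float],
    kappa: float,
    rng: np.random.Generator,
    ramp: float = 0.05,
) -> np.ndarray:
    """Piecewise-constant phase offset: von Mises(0, kappa) inside the
    designated epoch, uniform outside, blended with a 50 ms cosine ramp at
    the epoch edges (interpolated on the unit circle)."""
    th_out_pre = rng.uniform(-np.pi, np.pi)
    th_in = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
    th_out_post = rng.uniform(-np.pi, np.pi)
    z = np.empty(times.size, dtype=complex)
    e0, e1 = epoch

    def blend(t, t_edge, za, zb):
        # cosine crossfade of unit phasors over [t_edge - ramp/2, t_edge + ramp/2]
        w = np.clip((t - (t_edge - ramp / 2)) / ramp, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        mix = (1 - w) * za + w * zb
        mag = np.abs(mix)
        mag[mag < 1e-12] = 1.0
        return mix / mag

    za, zi, zb = np.exp(1j * th_out_pre), np.exp(1j * th_in), np.exp(1j * th_out_post)
    z[:] = za
    z[times >= e0 - ramp / 2] = blend(times[times >= e0 - ramp / 2], e0, za, zi)
    z[times >= e1 - ramp / 2] = blend(times[times >= e1 - ramp / 2], e1, zi, zb)
    return np.angle(z)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_STREAM_PINK, _STREAM_LINE, _STREAM_LATENT, _STREAM_JITTER, _STREAM_SPIKE, _STREAM_BEHAV = range(6)


def generate_session(config: GeneratorConfig) -> SessionRecording:
    """Generate one deterministic session from ``config.seed``."""
    config.validate()
    tl = config.timeline
    fs = config.sampling_rate
    n_samp = int(round((tl.trial_end - tl.baseline_start) * fs))
    times = tl.baseline_start + np.arange(n_samp) / fs
    n_ch = config.total_channels
    n_tr = config.n_trials

    trials = make_trial_table(
        TaskGeometry(), n_tr, _rng(config.seed, _STREAM_BEHAV), config.lapse_rate
    )
    is_above = (trials["category_ab"] == "Above").to_numpy()

    lfp = np.zeros((n_ch, n_tr, n_samp), dtype=np.float64)

    # background + line noise
    for ch in range(n_ch):
        for tr in range(n_tr):
            rng = _rng(config.seed, _STREAM_PINK, ch, tr)
            lfp[ch, tr] = config.pink_noise_rms * _pink_noise(
                n_samp, config.pink_noise_exponent, fs, rng
            )
            phase = _rng(config.seed, _STREAM_LINE, ch, tr).uniform(0, 2 * np.pi)
            lfp[ch, tr] += config.line_noise_amplitude * np.sin(
                2 * np.pi * 60.0 * times + phase
            )

    # evoked transients, identical across trials
    evoked = np.zeros(n_samp)
    for onset in (tl.sample_on, tl.shift_on, tl.test_on):
        evoked += evoked_template(times, onset, config.evoked_amplitude)
    lfp += evoked[None, None, :]

    # latent coupled oscillators; keep per-(channel, band) ground-truth phases
    phases: dict[tuple[int, str], np.ndarray] = {}
    for k, cs in enumerate(config.coupling_spec):
        band = BANDS[cs.band]
        epoch = EPOCHS[cs.epoch]
        for tr in range(n_tr):
            latent = _latent_oscillator(
                n_samp, band, fs, _rng(config.seed, _STREAM_LATENT, k, tr)
            )
            kappa = cs.kappa_above if is_above[tr] else cs.kappa_below
            for side, ch in enumerate(cs.pair):
                theta = _epoch_jitter_series(
                    times, epoch, kappa, _rng(config.seed, _STREAM_JITTER, k, tr, side)
                )
                contrib = latent * np.exp(1j * theta)
                lfp[ch, tr] += cs.amplitude * contrib.real
                key = (ch, cs.band)
                if key not in phases:
                    phases[key] = np.zeros((n_tr, n_samp))
                phases[key][tr] = np.angle(contrib)

    # spikes
    spikes: list[list[list[np.ndarray]]] = [
        [[] for _ in range(n_tr)] for _ in range(n_ch)
    ]
    for ss in config.spike_spec:
        for tr in range(n_tr):
            g = ss.gain_above if is_above[tr] else ss.gain_below
            if ss.mod_depth > 0 and ss.lfp_channel is not None:
                key = (ss.lfp_channel, ss.band)
                if key in phases:
                    phi = phases[key][tr]
                else:  # fall back to the channel's band-filtered analytic phase
                    sos = _band_filter(BANDS[ss.band], fs)
                    phi = np.angle(sps.hilbert(sps.sosfiltfilt(sos, lfp[ss.lfp_channel, tr])))
            else:
                phi = None
            for unit in range(ss.n_units):
                rng = _rng(config.seed, _STREAM_SPIKE, ss.electrode, tr, unit)
                st = synth_spike_train(
                    ss.baseline_rate,
                    g,
                    ss.mod_depth,
                    ss.preferred_phase,
                    phi,
                    times,
                    fs,
                    rng,
                    gain_from=tl.sample_on,
                )
                spikes[ss.electrode][tr].append(st)

    session = SessionRecording(
        lfp=lfp.astype(np.float32),
        fs=fs,
        times=times,
        spikes=spikes,
        channels=config.channel_table(),
        trials=trials,
        ground_truth=config,
    )
    session.validate()
    return session


def synth_spike_train(
    baseline_rate: float,
    gain: float,
    mod_depth: float,
    preferred_phase: float,
    phase_series: np.ndarray | None,
    times: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    gain_from: float = 0.0,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes by thinning.

    lambda(t) = baseline_rate * g(t) * (1 + m cos(phase(t) - preferred)),
    with the category gain g applied from ``gain_from`` (sample onset)
    onward and g = 1 before.  Expected count ~ integral of lambda.
    """
    if not 0 <= mod_depth < 1:
        raise ValueError("modulation depth must be in [0, 1)")
    lam = np.full(times.size, baseline_rate, dtype=float)
    lam[times >= gain_from] *= gain
    if mod_depth > 0 and phase_series is not None:
        lam *= 1.0 + mod_depth * np.cos(phase_series - preferred_phase)
    if np.any(lam < 0):
        raise ValueError("negative instantaneous rate")
    lam_max = lam.max()
    if lam_max == 0:
        return np.array([])
    duration = times[-1] - times[0]
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(times[0], times[-1], n_cand))
    idx = np.clip(((cand - times[0]) * fs).astype(int), 0, times.size - 1)
    keep = rng.uniform(0, lam_max, n_cand) < lam[idx]
    return cand[keep]


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------


def _config_to_json(config: GeneratorConfig) -> str:
    d = asdict(config)
    return json.dumps(d)


def _config_from_json(text: str) -> GeneratorConfig:
    d = json.loads(text)
    d["timeline"] = Timeline(**d["timeline"])
    d["coupling_spec"] = tuple(
        CouplingSpec(**{**c, "pair": tuple(c["pair"])}) for c in d["coupling_spec"]
    )
    d["spike_spec"] = tuple(SpikeSpec(**s) for s in d["spike_spec"])
    return GeneratorConfig(**d)


def write_session(session: SessionRecording, path) -> None:
    """Persist a session to HDF5 (ragged spikes via flat + index arrays)."""
    flat, elec_idx, trial_idx, unit_idx = [], [], [], []
    for e, per_trial in enumerate(session.spikes):
        for tr, units in enumerate(per_trial):
            for u, st in enumerate(units):
                flat.append(np.asarray(st, float))
                elec_idx.extend([e] * len(st))
                trial_idx.extend([tr] * len(st))
                unit_idx.extend([u] * len(st))
    flat_times = np.concatenate(flat) if flat else np.array([])

    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = SCHEMA_VERSION
        h5.attrs["fs"] = session.fs
        h5.attrs["n_units_per_electrode"] = json.dumps(
            [len(per_trial[0]) if per_trial else 0 for per_trial in session.spikes]
        )
        h5.create_dataset("lfp", data=session.lfp, compression="gzip", compression_opts=1)
        h5.create_dataset("times", data=session.times)
        g = h5.create_group("spikes")
        g.create_dataset("times", data=flat_times)
        g.create_dataset("electrode", data=np.asarray(elec_idx, np.int32))
        g.create_dataset("trial", data=np.asarray(trial_idx, np.int32))
        g.create_dataset("unit", data=np.asarray(unit_idx, np.int32))
        ch = h5.create_group("channels")
        ch.create_dataset("id", data=session.channels["id"].to_numpy())
        ch.create_dataset(
            "area", data=np.array(session.channels["area"], dtype=h5py.string_dtype())
        )
        tr = h5.create_group("trials")
        for col in session.trials.columns:
            vals = session.trials[col].to_numpy()
            if vals.dtype == object or vals.dtype.kind in "US":
                tr.create_dataset(col, data=np.array(vals, dtype=h5py.string_dtype()))
            else:
                tr.create_dataset(col, data=vals)
        h5.create_dataset("ground_truth", data=_config_to_json(session.ground_truth))


def read_session(path) -> SessionRecording:
    """Load a session written by :func:`write_session` (lossless)."""
    with h5py.File(path, "r") as h5:
        version = h5.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported session schema {version!r}; expected {SCHEMA_VERSION!r}"
            )
        lfp = h5["lfp"][()]
        times = h5["times"][()]
        fs = float(h5.attrs["fs"])
        units_per_elec = json.loads(h5.attrs["n_units_per_electrode"])
        st = h5["spikes/times"][()]
        se = h5["spikes/electrode"][()]
        strial = h5["spikes/trial"][()]
        su = h5["spikes/unit"][()]
        channels = pd.DataFrame(
            {
                "id": h5["channels/id"][()],
                "area": [a.decode() for a in h5["channels/area"][()]],
            }
        )
        tr = {}
        for col in h5["trials"]:
            vals = h5["trials"][col][()]
            if vals.dtype.kind in "OS":
                vals = np.array([v.decode() for v in vals])
            tr[col] = vals
        trials = pd.DataFrame(tr)
        config = _config_from_json(h5["ground_truth"][()].decode())

    n_tr = len(trials)
    spikes: list[list[list[np.ndarray]]] = []
    for e, nu in enumerate(units_per_elec):
        per_trial = []
        for t in range(n_tr):
            units = []
            for u in range(nu):
                mask = (se == e) & (strial == t) & (su == u)
                units.append(np.sort(st[mask]))
            per_trial.append(units)
        spikes.append(per_trial)

    session = SessionRecording(
        lfp=lfp, fs=fs, times=times, spikes=spikes,
        channels=channels, trials=trials, ground_truth=config,
    )
    notes = session.validate()
    for n in notes:
        warnings.warn(n, stacklevel=2)
    return session


def expected_ppc(kappa: float) -> float:
    """Ground-truth PPC for a pair whose channels each carry independent
    von Mises(0, kappa) phase jitter: (I1(k)/I0(k))**4."""
    from scipy.special import i0, i1

    if kappa == 0:
        return 0.0
    r = i1(kappa) / i0(kappa)
    return float(r**4)
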