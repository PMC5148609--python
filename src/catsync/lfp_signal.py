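"""LFP preprocessing and Morlet time-frequency decomposition.

Pipeline: zero-phase Butterworth bandstop at 59-61 Hz (line-noise
removal), anti-aliased decimation from 1 kHz to 333 Hz, subtraction of
the per-channel cross-trial mean at each time sample (removes the
stimulus-evoked component and isolates induced oscillations), then
convolution with a Morlet wavelet (omega0 = 6) on a log-spaced grid of 61
frequencies covering six octaves, f_k = 2 * 2**(0.1 k) Hz for k = 0..60.

Power maps are normalized by multiplying |W|^2 with f (relative to a 1 Hz
reference), which flattens the 1/f power-law decay of the LFP spectrum.
Samples inside a wavelet's cone of influence at the trial edges are
flagged, not dropped; epoch averages exclude flagged bins below 4 Hz
where the cone is widest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len as fftpack_next_fast_len

from .synthgen import BANDS, EPOCHS

OMEGA0_DEFAULT = 6.0


def default_freq_grid() -> np.ndarray:
    """61 log-spaced frequencies, 2-128 Hz at 0.1-octave resolution."""
    return 2.0 * 2.0 ** (0.1 * np.arange(61))


@dataclass(frozen=True)
class PreprocessConfig:
    notch_band: tuple[float, float] = (59.0, 61.0)
    notch_order: int = 10
    decimation: int = 3
    evoked_removal: bool = True

    def __post_init__(self) -> None:
        if self.notch_band[0] <= 0 or self.notch_band[1] >= 500.0:
            raise ValueError("notch band must lie inside (0, Nyquist)")


def preprocess_lfp(
    raw: np.ndarray, fs: float, config: PreprocessConfig | None = None
) -> tuple[np.ndarray, float]:
    """Bandstop -> decimate -> evoked removal on [channel x trial x sample].

    Returns the cleaned array at fs / 3 and the new sampling rate.  The
    cross-trial mean subtraction requires at least two trials; residuals
    have exactly zero cross-trial mean at every sample.
    """
    config = config or PreprocessConfig()
    x = np.asarray(raw, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError("expected raw LFP shaped [channel x trial x sample]")
    if config.evoked_removal and x.shape[1] < 2:
        raise ValueError("evoked removal needs at least 2 trials")

    sos = sps.butter(config.notch_order, config.notch_band, btype="bandstop", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=-1)
    x = sps.decimate(x, config.decimation, ftype="fir", axis=-1, zero_phase=True)
    if config.evoked_removal:
        x = x - x.mean(axis=1, keepdims=True)
    return x, fs / config.decimation


def decimate_times(times: np.ndarray, decimation: int = 3) -> np.ndarray:
    """Time stamps matching :func:`preprocess_lfp`'s output samples."""
    return np.asarray(times)[::decimation]


@dataclass
class SpectralDecomposition:
    """Complex Morlet coefficients W[channel x trial x frequency x time].

    ``valid`` flags bins outside the cone of influence (True = reliable).
    Phase is ``np.angle(W)``; |W|^2 is proportional to power.
    """

    W: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    fs: float
    omega0: float = OMEGA0_DEFAULT
    valid: np.ndarray = field(default=None)  # [frequency x time] bool

    def phase(self) -> np.ndarray:
        return np.angle(self.W)

    def band_indices(self, band: str | tuple[float, float]) -> np.ndarray:
        lo, hi = BANDS[band] if isinstance(band, str) else band
        return np.flatnonzero((self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9))

    def epoch_indices(self, epoch: str | tuple[float, float]) -> np.ndarray:
        t0, t1 = EPOCHS[epoch] if isinstance(epoch, str) else epoch
        return np.flatnonzero((self.times >= t0) & (self.times < t1))


def _morlet_scales(freqs: np.ndarray, omega0: float) -> np.ndarray:
    # Fourier-factor relation between scale and center frequency.
    return (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi * freqs)


def morlet_transform(
    clean: np.ndarray,
    fs: float,
    times: np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    omega0: float = OMEGA0_DEFAULT,
    time_range: tuple[float, float] | None = None,
    dtype=np.complex64,
) -> SpectralDecomposition:
    """FFT-based Morlet wavelet transform of [channel x trial x sample].

    ``time_range`` optionally crops the output along time (the transform
    is still computed on the full traces, so cropping does not introduce
    edge effects).  Frequencies above the Nyquist rate raise.
    """
    x = np.asarray(clean, dtype=np.float64)
    squeeze = False
    if x.ndim == 1:
        x = x[None, None]
        squeeze = True
    elif x.ndim == 2:
        x = x[None]
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[-1] > fs / 2:
        raise ValueError(f"frequency {freqs[-1]:g} Hz exceeds Nyquist ({fs / 2:g} Hz)")
    n_ch, n_tr, n_t = x.shape
    if times is None:
        times = np.arange(n_t) / fs
    times = np.asarray(times, float)

    nfft = int(fftpack_next_fast_len(2 * n_t))
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, 1.0 / fs)
    scales = _morlet_scales(freqs, omega0)
    # Torrence-Compo style frequency-domain mother wavelet, analytic.
    psi = np.zeros((freqs.size, nfft))
    pos = omega > 0
    for i, s in enumerate(scales):
        psi[i, pos] = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s * fs)
            * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        )

    if time_range is not None:
        keep = np.flatnonzero((times >= time_range[0]) & (times <= time_range[1]))
    else:
        keep = np.arange(n_t)

    W = np.empty((n_ch, n_tr, freqs.size, keep.size), dtype=dtype)
    for ch in range(n_ch):
        X = np.fft.fft(x[ch], n=nfft, axis=-1)  # [trial x nfft]
        for i in range(freqs.size):
            w = np.fft.ifft(X * psi[i][None, :], axis=-1)[:, :n_t]
            W[ch, :, i, :] = w[:, keep]

    # cone of influence: e-folding time sqrt(2) * scale from each trace edge
    coi = np.sqrt(2.0) * scales
    t_edge0, t_edge1 = times[0], times[-1]
    tt = times[keep]
    valid = (tt[None, :] - t_edge0 >= coi[:, None]) & (t_edge1 - tt[None, :] >= coi[:, None])

    out = SpectralDecomposition(
        W=W[0, 0] if squeeze else W,
        freqs=freqs,
        times=tt,
        fs=fs,
        omega0=omega0,
        valid=valid,
    )
    return out


@dataclass
class PowerMap:
    """Trial-averaged, 1/f-corrected power [channel x frequency x time]."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    f_ref: float = 1.0

    def band_epoch_average(
        self,
        band: str | tuple[float, float],
        epoch: str | tuple[float, float],
        coi_exempt_above: float = 4.0,
    ) -> np.ndarray:
        """Mean power per channel over a band x epoch cell.

        Bins inside the cone of influence are excluded below
        ``coi_exempt_above`` Hz (the cone is negligible at higher
        frequencies on these trial lengths).
        """
        lo, hi = BANDS[band] if isinstance(band, str) else band
        t0, t1 = EPOCHS[epoch] if isinstance(epoch, str) else epoch
        fi = np.flatnonzero((self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9))
        ti = np.flatnonzero((self.times >= t0) & (self.times < t1))
        if fi.size == 0 or ti.size == 0:
            raise ValueError("band/epoch selects no bins")
        mask = np.ones((fi.size, ti.size), bool)
        low = self.freqs[fi] < coi_exempt_above
        mask[low] = self.valid[np.ix_(fi, ti)][low]
        sub = self.power[:, fi][:, :, ti]
        denom = mask.sum()
        if denom == 0:
            raise ValueError("all selected bins fall inside the cone of influence")
        return (sub * mask[None]).sum(axis=(1, 2)) / denom


def normalized_power(
    dec: SpectralDecomposition,
    trial_subset: np.ndarray | None = None,
    f_ref: float = 1.0,
) -> PowerMap:
    """power(f, t) = mean over trials of |W|^2 * (f / f_ref)."""
    W = dec.W
    if W.ndim != 4:
        raise ValueError("expected a [channel x trial x frequency x time] decomposition")
    if trial_subset is not None:
        trial_subset = np.asarray(trial_subset)
        if trial_subset.size == 0:
            raise ValueError("empty trial subset")
        W = W[:, trial_subset]
    p = np.mean(np.abs(W.astype(np.complex128)) ** 2, axis=1)
    p *= (dec.freqs / f_ref)[None, :, None]
    return PowerMap(power=p, freqs=dec.freqs, times=dec.times, valid=dec.valid, f_ref=f_ref)
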