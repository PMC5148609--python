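"""Firing-rate selectivity: smoothed z-scored rates and omega-PEV.

Rates are spike counts on contiguous 20 ms bins converted to spikes/s and
convolved with a 200 ms Gaussian window (200 ms read as FWHM, sigma ~ 85
ms; a sigma reading is available via ``width_is_fwhm=False``).  For
selectivity, rates are z-transformed with the mean and variance of the 3 s
pre-trial baseline pooled over trials.

Category selectivity per time bin is the bias-corrected omega-squared
percent explained variance:

    omega2 = (SS_between - df_between * MSE) / (SS_total + MSE) * 100

with the two categories of the chosen dimension as groups (df_between =
1).  The bias correction makes the null expectation zero, so single-bin
values may be slightly negative; they are deliberately not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .synthgen import SessionRecording, Timeline

BIN_WIDTH = 0.020  # s
SMOOTH_WIDTH = 0.200  # s (FWHM by default)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RateSeries:
    """Binned, smoothed firing rates for one unit or pooled electrode."""

    source_id: int | tuple[int, int]
    rate: np.ndarray  # [trial x bin], spikes/s
    z_rate: np.ndarray | None  # baseline-z-scored; None for silent sources
    bin_centers: np.ndarray
    baseline_mean: float
    baseline_sd: float
    silent: bool = False


def smoothed_rates(
    spike_trains: list[np.ndarray],
    timeline: Timeline | None = None,
    bin_width: float = BIN_WIDTH,
    smooth_width: float = SMOOTH_WIDTH,
    width_is_fwhm: bool = True,
    source_id: int | tuple[int, int] = -1,
) -> RateSeries:
    """Binned + Gaussian-smoothed rates, z-scored to the pre-trial baseline.

    ``spike_trains`` holds one array of spike times (s from sample onset)
    per trial.  A unit with zero baseline variance (silent) gets
    ``z_rate=None`` and a warning; callers exclude it from population
    selectivity.
    """
    timeline = timeline or Timeline()
    edges = np.arange(timeline.baseline_start, timeline.trial_end + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    counts = np.stack([np.histogram(st, edges)[0] for st in spike_trains])
    rate = counts / bin_width
    sigma_s = smooth_width * _FWHM_TO_SIGMA if width_is_fwhm else smooth_width
    rate = ndimage.gaussian_filter1d(rate.astype(float), sigma_s / bin_width, axis=1, truncate=3.0)

    b0, b1 = timeline.baseline_window
    base = rate[:, (centers >= b0) & (centers < b1)]
    mu = float(base.mean())
    sd = float(base.std(ddof=0))
    if sd == 0:
        warnings.warn(
            f"source {source_id}: zero baseline variance (silent); excluded from z-scoring",
            stacklevel=2,
        )
        return RateSeries(source_id, rate, None, centers, mu, sd, silent=True)
    return RateSeries(source_id, rate, (rate - mu) / sd, centers, mu, sd)


def pooled_multiunit_rates(
    session: SessionRecording, electrode: int, **kwargs
) -> RateSeries:
    """Rates from all spikes of an electrode's isolated units pooled
    together (multiunit), maximizing spike counts."""
    pooled = session.pooled_spikes(electrode)
    return smoothed_rates(
        pooled, timeline=session.ground_truth.timeline, source_id=electrode, **kwargs
    )


# ---------------------------------------------------------------------------
# omega-PEV
# ---------------------------------------------------------------------------


def omega_pev(responses: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Bias-corrected omega-squared PEV (percent) per time bin.

    ``responses`` is [trial x bin] (a single bin may be passed as
    [trial]); ``labels`` holds the two category values.  Bins with zero
    total variance return 0.
    """
    x = np.asarray(responses, float)
    single = x.ndim == 1
    if single:
        x = x[:, None]
    labels = np.asarray(labels)
    vals = np.unique(labels)
    if vals.size < 2:
        raise ValueError("omega-PEV needs at least 2 groups")
    groups = [x[labels == v] for v in vals]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 trials")
    n = x.shape[0]
    k = vals.size
    grand = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for g in groups:
        ss_between += len(g) * (g.mean(axis=0) - grand) ** 2
    ss_within = ss_total - ss_between
    mse = ss_within / (n - k)
    df_b = k - 1
    denom = ss_total + mse
    out = np.zeros_like(grand)
    nz = denom > 0
    out[nz] = (ss_between[nz] - df_b * mse[nz]) / denom[nz] * 100.0
    return out[0] if single else out


def omega_pev_permutations(
    responses: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """True omega-PEV per bin plus its label-permutation distribution.

    Returns ``(pev[bins], pev_perm[n_perm x bins])``, vectorized over
    permutations via group-sum identities.
    """
    x = np.asarray(responses, float)
    labels = np.asarray(labels)
    vals = np.unique(labels)
    if vals.size != 2:
        raise ValueError("permutation omega-PEV implemented for 2 groups")
    true = omega_pev(x, labels)
    n = x.shape[0]
    na = int((labels == vals[0]).sum())
    M = np.zeros((n_perm, n), dtype=np.float64)
    for r in range(n_perm):
        M[r, rng.permutation(n)[:na]] = 1.0
    s_tot = x.sum(axis=0)
    ss_tot = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
    sa = M @ x  # [perm x bins]
    sb = s_tot[None] - sa
    nb = n - na
    grand = s_tot / n
    ss_between = na * (sa / na - grand[None]) ** 2 + nb * (sb / nb - grand[None]) ** 2
    mse = (ss_tot[None] - ss_between) / (n - 2)
    denom = ss_tot[None] + mse
    pev_perm = np.zeros_like(denom)
    nz = denom > 0
    pev_perm[nz] = (ss_between[nz] - mse[nz]) / denom[nz] * 100.0
    return true, pev_perm


# ---------------------------------------------------------------------------
# Population significance
# ---------------------------------------------------------------------------


def population_significance(
    pev: np.ndarray,
    alpha: float = 0.05,
    min_run: float = 0.100,
    bin_width: float = BIN_WIDTH,
) -> np.ndarray:
    """Per-bin one-sided t-test of population PEV > 0, with a run filter.

    ``pev`` is [unit x bin].  A bin is reported significant only inside a
    contiguous run of sub-threshold p-values lasting >= ``min_run``
    (>= 5 consecutive 20 ms bins by default).
    """
    min_bins = int(round(min_run / bin_width))
    if min_bins < 2:
        raise ValueError("min_run must span at least 2 bins")
    pev = np.asarray(pev, float)
    if pev.shape[0] < 2:
        raise ValueError("population test needs at least 2 units")
    t, p_two = stats.ttest_1samp(pev, 0.0, axis=0)
    p = np.where(t > 0, p_two / 2.0, 1.0 - p_two / 2.0)
    sig = p < alpha
    padded = np.concatenate([[False], sig, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    keep = np.zeros_like(sig)
    for s, e in zip(starts, ends):
        if e - s >= min_bins:
            keep[s:e] = True
    return keep


def percent_significant_units(
    zrates_by_unit: list[np.ndarray],
    labels: np.ndarray,
    alpha_unit: float = 0.01,
    n_perm: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Percent of units individually selective per bin.

    Each unit's per-bin omega-PEV is tested against its own 200-label-
    permutation null (rank-based p); reported is the percentage of units
    with p < ``alpha_unit`` at each bin.
    """
    rng = rng or np.random.default_rng(0)
    sig = []
    for x in zrates_by_unit:
        true, perm = omega_pev_permutations(x, labels, n_perm, rng)
        p = (1.0 + (perm >= true[None]).sum(axis=0)) / (n_perm + 1.0)
        sig.append(p < alpha_unit)
    return 100.0 * np.mean(sig, axis=0)
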