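"""Spike-field phase locking, directionality contrasts and selections.

The phase-locking value (PLV) measures the angular concentration of the
frequency-specific LFP phase at spike times: per trial, PLV_t(f) =
|mean_k exp(i phi_k)| over the trial's spikes, then a spike-count-
weighted average across trials (a pooled-spike variant is available).
Because few spikes inflate raw PLV, it is z-scored against 200
permutations that reassign whole LFP trial traces across trials while
keeping each trial's spike series — the null preserves the number and
temporal pattern of spikes exactly.

Directionality (spikes of area A to LFPs of area B vs the reverse) is a
two-tailed paired t-test on z_PLV across pairs, per frequency and per
band.  Conditioning analyses select the top (or bottom) decile of a score
distribution: beta-synchrony selectivity for pairs, epoch-averaged
omega-PEV for spiking electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfp_signal import SpectralDecomposition
from .synthgen import EPOCHS

#: Beta sub-band used for the frontoparietal directionality contrast.
BETA_NARROW = (22.0, 32.0)


@dataclass
class PLVSpectrum:
    """Frequency-wise PLV and permutation z for one spike->LFP pairing."""

    spike_electrode: int
    lfp_electrode: int
    direction: str
    epoch: str | tuple[float, float]
    freqs: np.ndarray
    plv_raw: np.ndarray  # [freq], in [0, 1]
    z: np.ndarray
    n_spikes: int
    n_trials_with_spikes: int


def _spike_sample_indices(
    spike_trains: list[np.ndarray],
    times: np.ndarray,
    epoch: tuple[float, float],
) -> list[np.ndarray]:
    t0 = times[0]
    dt = float(np.median(np.diff(times)))
    out = []
    for st in spike_trains:
        st = np.asarray(st)
        st = st[(st >= epoch[0]) & (st < epoch[1])]
        idx = np.round((st - t0) / dt).astype(int)
        out.append(idx[(idx >= 0) & (idx < times.size)])
    return out


def _weighted_plv(W_trials: np.ndarray, idx_per_trial: list[np.ndarray], order: np.ndarray,
                  pooled: bool) -> np.ndarray:
    """PLV spectrum with LFP trials taken in ``order`` against fixed spikes."""
    n_f = W_trials.shape[1]
    if pooled:
        acc = np.zeros(n_f, complex)
        total = 0
        for tr, idx in enumerate(idx_per_trial):
            if idx.size == 0:
                continue
            w = W_trials[order[tr]][:, idx]
            acc += (w / np.abs(w)).sum(axis=1)
            total += idx.size
        return np.abs(acc) / total
    num = np.zeros(n_f)
    total = 0
    for tr, idx in enumerate(idx_per_trial):
        if idx.size == 0:
            continue
        w = W_trials[order[tr]][:, idx]
        num += idx.size * np.abs((w / np.abs(w)).mean(axis=1))
        total += idx.size
    return num / total


def plv_z(
    spike_trains: list[np.ndarray],
    dec: SpectralDecomposition,
    lfp_channel: int,
    epoch: str | tuple[float, float] = "category",
    n_perm: int = 200,
    rng: np.random.Generator | None = None,
    pooled: bool = False,
    spike_electrode: int = -1,
    direction: str = "",
) -> PLVSpectrum:
    """Spike-field PLV with LFP-permutation z-score.

    ``spike_trains`` holds the (pooled multiunit) spike times per trial;
    only spikes inside the epoch contribute.  ``pooled=True`` collapses
    all spikes across trials before taking the resultant instead of the
    default per-trial, spike-count-weighted averaging.
    """
    rng = rng or np.random.default_rng(0)
    win = EPOCHS[epoch] if isinstance(epoch, str) else epoch
    W = dec.W[lfp_channel]  # [trial x freq x time]
    n_tr = W.shape[0]
    if len(spike_trains) != n_tr:
        raise ValueError("spike trains and LFP decomposition disagree on trial count")
    if n_tr < 2:
        raise ValueError("PLV permutation needs at least 2 trials")
    idx = _spike_sample_indices(spike_trains, dec.times, win)
    n_spikes = int(sum(i.size for i in idx))
    if n_spikes == 0:
        raise ValueError("no spikes inside the requested epoch")
    identity = np.arange(n_tr)
    raw = _weighted_plv(W, idx, identity, pooled)
    perm_vals = np.empty((n_perm, raw.size))
    for r in range(n_perm):
        perm_vals[r] = _weighted_plv(W, idx, rng.permutation(n_tr), pooled)
    mu = perm_vals.mean(axis=0)
    sd = perm_vals.std(axis=0, ddof=1)
    z = np.full_like(raw, np.nan)
    ok = sd > 0
    z[ok] = (raw[ok] - mu[ok]) / sd[ok]
    return PLVSpectrum(
        spike_electrode=spike_electrode,
        lfp_electrode=lfp_channel,
        direction=direction,
        epoch=epoch,
        freqs=dec.freqs,
        plv_raw=raw,
        z=z,
        n_spikes=n_spikes,
        n_trials_with_spikes=int(sum(i.size > 0 for i in idx)),
    )


def plv_resultant(phases: np.ndarray) -> float:
    """Plain resultant length of a set of spike phases (oracle helper)."""
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("no spike phases")
    return float(np.abs(np.exp(1j * phases).mean()))


# ---------------------------------------------------------------------------
# Directionality
# ---------------------------------------------------------------------------


def directionality_contrast(
    plv_ab: list[PLVSpectrum],
    plv_ba: list[PLVSpectrum],
    band: tuple[float, float] = BETA_NARROW,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test of z_PLV(A->B) vs z_PLV(B->A) per frequency.

    Both lists must describe the same session pairs in the same order.
    The returned frame has one row per frequency (t, p, significant) and
    carries the band-averaged test in ``.attrs['band_test']``.  Swapping
    the arguments negates every difference.
    """
    if len(plv_ab) != len(plv_ba) or len(plv_ab) < 2:
        raise ValueError("need matched pair sets with >= 2 pairs in both directions")
    f = plv_ab[0].freqs
    za = np.stack([p.z for p in plv_ab])  # [pair x freq]
    zb = np.stack([p.z for p in plv_ba])
    t, p = stats.ttest_rel(za, zb, axis=0)
    df = pd.DataFrame(
        {
            "freq": f,
            "mean_diff": (za - zb).mean(axis=0),
            "t": t,
            "p": p,
            "significant": p < alpha,
        }
    )
    bi = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
    tb, pb = stats.ttest_rel(za[:, bi].mean(axis=1), zb[:, bi].mean(axis=1))
    df.attrs["band_test"] = {
        "band": band,
        "mean_ab": float(za[:, bi].mean()),
        "mean_ba": float(zb[:, bi].mean()),
        "t": float(tb),
        "p": float(pb),
    }
    return df


# ---------------------------------------------------------------------------
# Decile selections and conditioned analyses
# ---------------------------------------------------------------------------


@dataclass
class PairSelection:
    criterion: str
    side: str
    selected: list
    tie_flag: bool
    small_n_flag: bool


def top_decile_selection(
    scores: dict,
    fraction: float = 0.10,
    side: str = "top",
    criterion: str = "",
) -> PairSelection:
    """ceil(fraction * n) ids with the highest (or lowest) scores.

    Ties at the threshold are broken deterministically by id order and
    flagged; n < 10 triggers a warning but still returns ceil(0.1 n) >= 1
    ids with ``small_n_flag`` set.
    """
    if side not in ("top", "bottom"):
        raise ValueError("side must be 'top' or 'bottom'")
    ids = sorted(scores)
    n = len(ids)
    if n == 0:
        raise ValueError("no scored ids")
    k = int(np.ceil(fraction * n))
    small = n < 10
    if small:
        warnings.warn(f"decile selection on only {n} ids", stacklevel=2)
    vals = np.array([scores[i] for i in ids], float)
    order = np.argsort(-vals if side == "top" else vals, kind="stable")
    chosen = order[:k]
    threshold = vals[chosen[-1]]
    tie = np.sum(vals == threshold) > np.sum(vals[chosen] == threshold)
    return PairSelection(
        criterion=criterion,
        side=side,
        selected=[ids[i] for i in chosen],
        tie_flag=bool(tie),
        small_n_flag=small,
    )


def selective_spike_plv_analysis(
    plv_by_electrode: dict[int, list[PLVSpectrum]],
    group_a: list[int],
    group_b: list[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group contrast of electrode-averaged PLV z-spectra.

    For each spike electrode the z-spectra against all its target-area
    LFPs are averaged first; groups (e.g. Above/Below-selective vs
    Right/Left-selective top deciles) are then compared per frequency
    with a two-tailed two-sample t-test.  Group means and SEMs are kept
    so the spectra can be plotted as in the conditioned spike-field
    figures.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")

    def electrode_mean(e: int) -> np.ndarray:
        specs = plv_by_electrode[e]
        if not specs:
            raise ValueError(f"electrode {e} has no PLV spectra")
        return np.stack([s.z for s in specs]).mean(axis=0)

    za = np.stack([electrode_mean(e) for e in group_a])
    zb = np.stack([electrode_mean(e) for e in group_b])
    f = next(iter(plv_by_electrode.values()))[0].freqs
    t, p = stats.ttest_ind(za, zb, axis=0)
    return pd.DataFrame(
        {
            "freq": f,
            "mean_a": za.mean(axis=0),
            "sem_a": za.std(axis=0, ddof=1) / np.sqrt(len(group_a)),
            "mean_b": zb.mean(axis=0),
            "sem_b": zb.std(axis=0, ddof=1) / np.sqrt(len(group_b)),
            "t": t,
            "p": p,
            "significant": p < alpha,
        }
    )


def pev_plv_correlation(
    pev_by_electrode: dict[int, float], plv_by_electrode: dict[int, float]
) -> dict[str, float]:
    """Pearson and Spearman correlation of spiking selectivity with
    beta-band spike-field synchrony across electrodes."""
    ids = sorted(set(pev_by_electrode) & set(plv_by_electrode))
    if len(ids) < 3:
        raise ValueError("correlation needs at least 3 electrodes with both scores")
    x = np.array([pev_by_electrode[i] for i in ids], float)
    y = np.array([plv_by_electrode[i] for i in ids], float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr),
        "pearson_p": float(pp),
        "spearman_r": float(sr),
        "spearman_p": float(sp),
        "n": len(ids),
    }
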