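"""LFP-LFP synchrony: pairwise phase consistency and category selectivity.

PPC is computed from per-trial phase differences dphi_i = arg(W_a conj(W_b))
at each time-frequency bin:

    PPC = 2 / (N (N-1)) * sum_{i<j} cos(dphi_i - dphi_j)

evaluated through the algebraically identical resultant form
(N R^2 - N) / (N (N-1)) with R = |sum_i exp(i dphi_i)| (the naive O(N^2)
sum is retained as a test oracle).  PPC is unbiased with respect to trial
count; residual chance-level synchrony is removed by subtracting the mean
PPC of 200 surrogates in which one channel's trial order is shuffled
independently of the other.

Category selectivity is the absolute PPC difference between the two trial
groups of a dimension (Above/Below or Right/Left), z-scored against 200
label permutations that preserve group sizes.  Significance uses the
rank-based permutation p-value (one-sided, since the statistic is an
absolute difference) and a rectangular cluster criterion: a bin survives
only within a region significant at p < 0.05 for >= 60 ms at each of >= 3
consecutive frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfp_signal import SpectralDecomposition
from .synthgen import BANDS, EPOCHS

N_PERMUTATIONS_DEFAULT = 200


def phase_difference_vectors(
    dec: SpectralDecomposition, pair: tuple[int, int], trials: np.ndarray | None = None
) -> np.ndarray:
    """Unit phasors of the per-trial phase difference, [trial x freq x time]."""
    a, b = pair
    Wa = dec.W[a]
    Wb = dec.W[b]
    if trials is not None:
        Wa, Wb = Wa[trials], Wb[trials]
    prod = Wa.astype(np.complex64) * np.conj(Wb.astype(np.complex64))
    mag = np.abs(prod)
    if np.any(mag == 0):
        raise ValueError("phase undefined: zero wavelet coefficient encountered")
    return prod / mag


def ppc_from_vectors(u: np.ndarray, axis: int = 0) -> np.ndarray:
    """PPC via the resultant-length identity along ``axis``."""
    n = u.shape[axis]
    if n < 2:
        raise ValueError("PPC needs at least 2 trials")
    R2 = np.abs(u.sum(axis=axis)) ** 2
    return (R2 - n) / (n * (n - 1.0))


def ppc_pairwise_oracle(dphi: np.ndarray) -> float:
    """Naive O(N^2) pairwise-cosine PPC of a 1-D phase-difference sample."""
    dphi = np.asarray(dphi, float)
    n = dphi.size
    s = 0.0
    for i in range(n - 1):
        s += np.cos(dphi[i] - dphi[i + 1 :]).sum()
    return 2.0 * s / (n * (n - 1.0))


@dataclass
class PPCMap:
    """Raw and surrogate-corrected PPC for one channel pair."""

    pair: tuple[int, int]
    area_pair: str
    ppc_raw: np.ndarray  # [freq x time]
    ppc_corrected: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    n_surrogates: int


def area_pair_label(area_a: str, area_b: str) -> str:
    """Canonical unordered label, e.g. 'AIP-cPFC'."""
    order = {"AIP": 0, "cPFC": 1, "lPFC": 2}
    a, b = sorted([area_a, area_b], key=lambda x: order.get(x, 99))
    return f"{a}-{b}"


def ppc_map(
    dec: SpectralDecomposition,
    pair: tuple[int, int],
    trials: np.ndarray | None = None,
    n_surrogates: int = N_PERMUTATIONS_DEFAULT,
    rng: np.random.Generator | None = None,
    areas: tuple[str, str] = ("?", "?"),
) -> PPCMap:
    """PPC with surrogate bias correction for one channel pair.

    The chance level is the mean PPC over ``n_surrogates`` datasets in
    which channel b's trials are shuffled (without replacement) against
    channel a's, breaking the trial pairing but preserving each channel's
    phase statistics.
    """
    rng = rng or np.random.default_rng(0)
    a, b = pair
    Wa = dec.W[a]
    Wb = dec.W[b]
    if trials is not None:
        Wa, Wb = Wa[trials], Wb[trials]
    n = Wa.shape[0]
    if n < 2:
        raise ValueError("PPC needs at least 2 trials")
    ua = Wa.astype(np.complex64)
    ub = np.conj(Wb.astype(np.complex64))
    if np.any(np.abs(ua) == 0) or np.any(np.abs(ub) == 0):
        raise ValueError("phase undefined: zero wavelet coefficient encountered")
    ua /= np.abs(ua)
    ub /= np.abs(ub)
    raw = ppc_from_vectors(ua * ub, axis=0)
    chance = np.zeros_like(raw, dtype=np.float64)
    for _ in range(n_surrogates):
        perm = rng.permutation(n)
        chance += ppc_from_vectors(ua * ub[perm], axis=0)
    chance /= max(n_surrogates, 1)
    return PPCMap(
        pair=pair,
        area_pair=area_pair_label(*areas),
        ppc_raw=raw,
        ppc_corrected=raw - chance,
        freqs=dec.freqs,
        times=dec.times,
        n_trials=n,
        n_surrogates=n_surrogates,
    )


# ---------------------------------------------------------------------------
# Category selectivity
# ---------------------------------------------------------------------------


@dataclass
class SelectivityZMap:
    """Permutation z-scores of |PPC_A - PPC_B| for one pair and dimension."""

    pair: tuple[int, int]
    area_pair: str
    dimension: str
    D: np.ndarray  # [freq x time]
    z: np.ndarray
    p: np.ndarray  # rank-based one-sided permutation p
    freqs: np.ndarray
    times: np.ndarray
    n_permutations: int
    undefined: np.ndarray  # bins where the permutation spread was zero


def _group_ppc_from_sums(S: np.ndarray, n: int) -> np.ndarray:
    return (np.abs(S) ** 2 - n) / (n * (n - 1.0))


def balanced_groups(
    labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the two label groups, the larger subsampled to equal n."""
    labels = np.asarray(labels)
    vals = np.unique(labels)
    if vals.size != 2:
        raise ValueError(f"expected exactly 2 label values, got {vals.tolist()}")
    ia = np.flatnonzero(labels == vals[0])
    ib = np.flatnonzero(labels == vals[1])
    m = min(ia.size, ib.size)
    if m < 2:
        raise ValueError("each category needs at least 2 trials")
    if ia.size > m:
        ia = rng.choice(ia, m, replace=False)
    if ib.size > m:
        ib = rng.choice(ib, m, replace=False)
    return np.sort(ia), np.sort(ib)


def category_selectivity_z(
    dec: SpectralDecomposition,
    pair: tuple[int, int],
    labels: np.ndarray,
    dimension: str = "above_below",
    n_perm: int = N_PERMUTATIONS_DEFAULT,
    rng: np.random.Generator | None = None,
    balance: bool = True,
    areas: tuple[str, str] = ("?", "?"),
) -> SelectivityZMap:
    """Permutation z-map of category-selective synchrony for one pair.

    The same machinery serves the task-relevant (Above/Below) and
    task-irrelevant (Right/Left) dimensions: only ``labels`` changes.
    Label swapping leaves D and z unchanged (D is an absolute value).
    """
    rng = rng or np.random.default_rng(0)
    ia, ib = (
        balanced_groups(labels, rng)
        if balance
        else tuple(np.flatnonzero(labels == v) for v in np.unique(labels))
    )
    # keep trials in session order with a membership mask, so that
    # swapping the two labels leaves both D and z bit-identical
    idx = np.sort(np.concatenate([ia, ib]))
    in_a = np.isin(idx, ia)
    u = phase_difference_vectors(dec, pair, trials=idx)
    n_tot = idx.size
    na = ia.size
    nb = n_tot - na
    shape_ft = u.shape[1:]
    u_flat = u.reshape(n_tot, -1)

    S_tot = u_flat.sum(axis=0)
    S_a = u_flat[in_a].sum(axis=0)
    D_true = np.abs(
        _group_ppc_from_sums(S_a, na) - _group_ppc_from_sums(S_tot - S_a, nb)
    )

    # permutation matrix: each row a re-assignment preserving group sizes
    M = np.zeros((n_perm, n_tot), dtype=np.float32)
    for r in range(n_perm):
        M[r, rng.permutation(n_tot)[:na]] = 1.0
    S_a_perm = M @ u_flat.real + 1j * (M @ u_flat.imag)
    D_perm = np.abs(
        _group_ppc_from_sums(S_a_perm, na)
        - _group_ppc_from_sums(S_tot[None, :] - S_a_perm, nb)
    )

    mu = D_perm.mean(axis=0)
    sd = D_perm.std(axis=0, ddof=1)
    undefined = sd == 0
    z = np.full(D_true.shape, np.nan)
    z[~undefined] = (D_true[~undefined] - mu[~undefined]) / sd[~undefined]
    # rank-based one-sided p (D >= 0 by construction)
    p = (1.0 + (D_perm >= D_true[None, :]).sum(axis=0)) / (n_perm + 1.0)

    return SelectivityZMap(
        pair=pair,
        area_pair=area_pair_label(*areas),
        dimension=dimension,
        D=D_true.reshape(shape_ft),
        z=z.reshape(shape_ft),
        p=p.reshape(shape_ft),
        freqs=dec.freqs,
        times=dec.times,
        n_permutations=n_perm,
        undefined=undefined.reshape(shape_ft),
    )


def significant_clusters(
    p_map: np.ndarray,
    dt: float,
    alpha: float = 0.05,
    min_duration: float = 0.060,
    min_freq_bins: int = 3,
) -> np.ndarray:
    """Rectangular cluster mask on a [freq x time] p-value map.

    A bin survives iff it belongs to a rectangle of >= ``min_freq_bins``
    consecutive frequencies over a common time run of >= ``min_duration``
    in which every bin has p < alpha.  At the 333 Hz-derived grid, 60 ms
    equals 20 consecutive samples.
    """
    min_len = int(round(min_duration / dt))
    if min_len < 2:
        raise ValueError("min_duration must span at least 2 time samples")
    if min_freq_bins < 1:
        raise ValueError("min_freq_bins must be >= 1")
    sig = np.asarray(p_map) < alpha
    n_f, n_t = sig.shape
    keep = np.zeros_like(sig)
    if n_f < min_freq_bins:
        return keep
    for f0 in range(n_f - min_freq_bins + 1):
        rows = sig[f0 : f0 + min_freq_bins].all(axis=0)
        # run-length scan
        padded = np.concatenate([[False], rows, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                keep[f0 : f0 + min_freq_bins, s:e] = True
    return keep


# ---------------------------------------------------------------------------
# Population summaries
# ---------------------------------------------------------------------------


def selectivity_summary(
    zmaps: list[SelectivityZMap],
    bands: dict[str, tuple[float, float]] | None = None,
    epochs: dict[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
    min_duration: float = 0.060,
    min_freq_bins: int = 3,
) -> pd.DataFrame:
    """Collapse z-maps into (area pair, dimension, band, epoch) cells.

    Reports mean +/- SEM of the band x epoch averaged z across pairs and
    the percent of pairs carrying at least one significant cluster whose
    bins intersect the cell.  Single-pair groups are kept with NaN SEM.
    """
    bands = bands or BANDS
    epochs = epochs or EPOCHS
    rows = []
    by_group: dict[tuple[str, str], list[SelectivityZMap]] = {}
    for zm in zmaps:
        by_group.setdefault((zm.area_pair, zm.dimension), []).append(zm)
    for (area_pair, dimension), maps in by_group.items():
        dt = float(np.median(np.diff(maps[0].times)))
        masks = [
            significant_clusters(zm.p, dt, alpha, min_duration, min_freq_bins)
            for zm in maps
        ]
        for band_name, (lo, hi) in bands.items():
            for epoch_name, (t0, t1) in epochs.items():
                fi = np.flatnonzero((maps[0].freqs >= lo - 1e-9) & (maps[0].freqs <= hi + 1e-9))
                ti = np.flatnonzero((maps[0].times >= t0) & (maps[0].times < t1))
                cell = [np.nanmean(zm.z[np.ix_(fi, ti)]) for zm in maps]
                has_cluster = [bool(m[np.ix_(fi, ti)].any()) for m in masks]
                n = len(cell)
                rows.append(
                    dict(
                        area_pair=area_pair,
                        dimension=dimension,
                        band=band_name,
                        epoch=epoch_name,
                        mean_z=float(np.mean(cell)),
                        sem_z=float(np.std(cell, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                        pct_pairs_significant=100.0 * np.mean(has_cluster),
                        n_pairs=n,
                    )
                )
    return pd.DataFrame(rows)


def baseline_synchrony_comparison(
    dec: SpectralDecomposition,
    pairs: list[tuple[int, int]],
    labels: np.ndarray,
    band: str | tuple[float, float],
    epoch: str | tuple[float, float],
    baseline_window: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Epoch vs pre-trial-fixation synchrony per category preference.

    For each pair the preferred category is the sign of the band/epoch
    averaged PPC difference (Above - Below); epoch and baseline PPC are
    then compared across pairs with two-tailed paired t-tests, separately
    for the preferred and non-preferred category.
    """
    rng = rng or np.random.default_rng(0)
    fi_band = dec.band_indices(band)
    ti_epoch = dec.epoch_indices(epoch)
    ti_base = dec.epoch_indices(baseline_window)
    if ti_base.size == 0:
        raise ValueError("baseline window contains no samples")
    labels = np.asarray(labels)
    vals = np.unique(labels)
    rows = []
    for pair in pairs:
        u = phase_difference_vectors(dec, pair)
        rec: dict = {"pair": pair}
        for v in vals:
            sel = np.flatnonzero(labels == v)
            ppc = ppc_from_vectors(u[sel], axis=0)
            rec[f"epoch_{v}"] = float(ppc[np.ix_(fi_band, ti_epoch)].mean())
            rec[f"baseline_{v}"] = float(ppc[np.ix_(fi_band, ti_base)].mean())
        rows.append(rec)
    df = pd.DataFrame(rows)
    a, b = vals[0], vals[1]
    diff = df[f"epoch_{a}"] - df[f"epoch_{b}"]
    df["preferred"] = np.where(diff >= 0, a, b)
    df["epoch_pref"] = np.where(diff >= 0, df[f"epoch_{a}"], df[f"epoch_{b}"])
    df["epoch_nonpref"] = np.where(diff >= 0, df[f"epoch_{b}"], df[f"epoch_{a}"])
    df["baseline_pref"] = np.where(diff >= 0, df[f"baseline_{a}"], df[f"baseline_{b}"])
    df["baseline_nonpref"] = np.where(diff >= 0, df[f"baseline_{b}"], df[f"baseline_{a}"])
    for which in ("pref", "nonpref"):
        if len(df) >= 2:
            t, p = stats.ttest_rel(df[f"epoch_{which}"], df[f"baseline_{which}"])
            df.attrs[f"ttest_{which}"] = {"t": float(t), "p": float(p)}
        else:  # a single pair carries no across-pair error term
            df.attrs[f"ttest_{which}"] = {"t": np.nan, "p": np.nan}
    return df
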