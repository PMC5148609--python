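# catsync

Analysis pipeline for category-selective oscillatory synchrony in simulated
frontoparietal recordings.

In a delayed match-to-spatial-category task, a sample dot is categorized as
*Above* or *Below* a horizontal boundary and the decision must survive a ±4°
boundary shift, so the category is abstract rather than retinotopic.  This
package implements, end to end, the neural analyses such an experiment calls
for — time-frequency LFP decomposition, pairwise-phase-consistency (PPC)
synchrony with permutation nulls, bias-corrected ω² spiking selectivity, and
spike–field phase locking with directionality contrasts — together with a
seeded synthetic-session generator that injects known coupling, so every
stage can be validated against ground truth.  It is aimed at systems
neuroscientists who want a tested, reproducible reference implementation of
these estimators.

## The statistics at the core

**Pairwise phase consistency.**  For per-trial phase differences
Δφᵢ = arg(Wₐᵢ · W̄ᵦᵢ) at each time–frequency bin,

    PPC = 2/(N(N−1)) Σ_{i<j} cos(Δφᵢ − Δφⱼ)

computed via the identity PPC = (N R² − 1)/(N − 1) with R the resultant
length of the Δφ sample.  Chance level is removed by subtracting the mean
PPC of 200 surrogates in which one channel's trial order is shuffled.
Category selectivity is D = |PPC_above − PPC_below| per bin, z-scored
against 200 label permutations; significance uses the rank-based one-sided
permutation p with a cluster rule (p < 0.05 sustained ≥ 60 ms over ≥ 3
consecutive frequencies).

**ω² percent explained variance.**  Per 20 ms bin, on baseline-z-scored
rates:

    ωPEV = (SS_between − df_between·MSE) / (SS_total + MSE) × 100

The bias correction centers the null at zero (values may be slightly
negative and are not clipped).

**Spike–field phase locking.**  PLV(f) is the resultant length of the LFP
phase at spike times (per trial, spike-count weighted, or pooled), z-scored
against 200 permutations that reassign whole LFP trial traces while keeping
every spike train intact — the control for spurious locking at low spike
counts.  Directionality (A spikes → B LFP vs B spikes → A LFP) is a paired
t-test on z across pairs, per frequency and in the 22–32 Hz band.

LFPs are bandstop-filtered at 59–61 Hz (zero-phase, 10th-order
Butterworth), decimated to 333 Hz, evoked-component subtracted, and
decomposed with a Morlet wavelet (ω₀ = 6) on 61 log-spaced frequencies
covering 2–128 Hz at 0.1-octave resolution.  Power maps are 1/f-normalized.

## Worked example

Simulate the reference session (8 channels across AIP/cPFC/lPFC, 120
trials; beta-band coupling between channels 0 and 3 whose phase
concentration differs between Above and Below trials during the Category
epoch) and recover the injected selectivity:

```python
import numpy as np
from catsync import synthgen, lfp_signal, synchrony

session = synthgen.generate_session(synthgen.default_config(seed=42, n_trials=120))
clean, fs = lfp_signal.preprocess_lfp(session.lfp, session.fs)
dec = lfp_signal.morlet_transform(clean, fs,
                                  times=lfp_signal.decimate_times(session.times),
                                  time_range=(-0.2, 2.4))
labels = session.trials["category_ab"].to_numpy()
zmap = synchrony.category_selectivity_z(dec, (0, 3), labels,
                                        rng=np.random.default_rng(0))
dt = float(np.median(np.diff(dec.times)))
mask = synchrony.significant_clusters(zmap.p, dt)
for band in ("beta", "delta"):
    for epoch in ("category", "shift"):
        fi, ti = dec.band_indices(band), dec.epoch_indices(epoch)
        print(f"{band:5s} x {epoch:8s}: mean z = {np.nanmean(zmap.z[np.ix_(fi, ti)]):+5.2f}, "
              f"cluster bins = {int(mask[np.ix_(fi, ti)].sum())}")
```

Output:

```
beta  x category: mean z = +3.50, cluster bins = 3971
beta  x shift   : mean z = +1.27, cluster bins = 236
delta x category: mean z = +0.18, cluster bins = 0
delta x shift   : mean z = +0.01, cluster bins = 0
```

The injected beta × Category cell carries strongly positive selectivity z
and a large significant cluster; the non-injected delta cells stay at the
null.  (The smaller beta × Shift cluster is the tail of the Category-epoch
coupling smeared by the wavelet's temporal support.)  A thin CLI wraps the
same calls: `catsync simulate`, `catsync task enumerate`, `catsync ppc`,
`catsync selectivity`.

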