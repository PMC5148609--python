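# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic benchmark does and does not establish.

## Task model

Coordinates are degrees of visual angle, x rightward, y upward, origin at
fixation.  The sample grid is 16 base positions (four per quadrant, default
x ∈ {±3, ±6}, y ∈ {±2, ±5}) crossed with a ±0.5° per-axis jitter on 3
discrete levels, giving 16 × 3² = 144 distinct locations; discrete jitter is
forced by that count — continuous jitter would make the enumeration
unbounded.  The |y| = 2 rows are boundary-proximal: a ±4° shift moves the
relevant hemi-boundary across them, which is what the
`boundary_proximal_flip` accuracy factor isolates.  The x values of the base
grid and the 624-location test lattice (26 columns × 24 rows on
half-integer coordinates) are not pinned down by any printed rule; both are
configurable defaults, validated for cardinality and mirror symmetry.  With
these symmetric grids, match and nonmatch outcomes are exactly balanced over
all (sample, test, shift) triples.

Category judgments: Above iff y strictly exceeds the applicable
hemi-boundary (left boundary for x < 0, right for x > 0).  The sample is
always judged against the unshifted meridian; tests against the shifted
boundaries (CW: left +4°, right −4°; CCW reversed).  `P_ABOVE` per location
is inferred from first-test responses: a Go asserts the test matched the
sample, so the implied sample category equals the test's shifted-frame
category; No-go implies the opposite.  The same construction applied to the
test's hemifield yields the Left/Right map, which an observer tracking only
Above/Below renders at chance.

The simulated observer responds to the true match status with a lapse rate
of 0.07 (flipped response), yielding ≈93% accuracy, flat across
eccentricity and hemifield — behaviour is simulated, not fitted.

## Synthetic sessions

A session is 8 channels (3 AIP, 3 cPFC, 2 lPFC) × 120 trials at 1 kHz, in
mV, on a timeline (s, relative to sample onset): baseline −4.2 to −1.2,
fixation −1.2 to −0.2 (boundary display), 0.2 s gap, sample 0–0.8, boundary
shift 1.3, first test 2.3, second test 3.8, trial end 4.3.  Analysis epochs:
Category 0–1.3 s, Shift 1.3–2.3 s, fixation baseline −0.95 to −0.2 s (last
750 ms of fixation).

Each channel's LFP sums:

* **pink noise**, 1/f^α with α = 1 (FFT spectral shaping), 0.1 mV rms —
  typical LFP background;
* **line noise**, 60 Hz at 0.02 mV with trial-random phase (as when trial
  onsets are asynchronous to the mains);
* **evoked transients** at sample, shift and test onsets: a damped 10 Hz
  wavelet (alpha-function envelope, τ = 50 ms), 0.05 mV, identical across
  trials so that cross-trial-mean subtraction removes it exactly;
* **coupled oscillators**: per designated pair, a shared latent narrowband
  process (band-filtered Gaussian noise, analytic via Hilbert — keeps the
  phase well defined) at 0.08 mV rms per channel.  Each channel reads the
  latent phase through an independent von Mises(0, κ) offset, constant
  within an epoch segment and uniform outside the designated epoch, blended
  with 50 ms cosine ramps to avoid edge artifacts.  κ is chosen per trial by
  category (defaults: κ_above = 2.0 vs κ_below = 0.2 — a strong but not
  saturating contrast; expected PPC (I₁(κ)/I₀(κ))⁴ ≈ 0.24 vs ≈ 10⁻⁴).

Expected PPC of a coupled pair is (I₁(κ)/I₀(κ))⁴ because the phase
difference of two independent von Mises jitters has resultant
(I₁(κ)/I₀(κ))².  At the default oscillator-to-background ratio the wavelet
phase estimate is noisy, which attenuates measured PPC below this law —
deliberately so, as real LFP phase estimates are noisy; quantitative
recovery tests use a high-amplitude configuration where the law holds
within Monte-Carlo error.

Spikes are inhomogeneous Poisson by thinning, per unit (2 units/electrode;
electrophysiology typically isolates ~2–3 neurons per electrode):
λ(t) = λ₀ · g_cat(t) · (1 + m cos(φ(t) − φ_pref)), λ₀ = 5 Hz, with the
category gain applied from sample onset (before the sample there is no
category information) and φ the ground-truth phase of a designated channel's
oscillation.  Defaults: gain 2.0 on the cPFC electrodes, m = 0.4 on
electrode 3 against channel 0's beta phase.  The spike-phase density then
has resultant m/2, the ground truth for PLV recovery.

One RNG stream per (component, channel/electrode, trial), derived from the
master seed, so sessions are bit-reproducible and generation order cannot
change results.

Features of real data the generator does **not** emulate: volume
conduction, electrode drift, spike-sorting errors, non-Poisson spiking
(bursting, refractoriness), cross-frequency coupling, and behaviourally
driven state changes.  Passing tests therefore establish estimator
correctness and calibration, not robustness to those confounds.

## Preprocessing and decomposition

Order: zero-phase Butterworth bandstop 59–61 Hz (order-10 design, i.e. 20
poles, applied forward–backward) → anti-aliased FIR decimation by 3 to
333 Hz → subtraction of the per-channel cross-trial mean at each sample
(evoked removal; condition-agnostic).  The notch precedes downsampling;
decimation uses an explicit anti-alias filter because 167–500 Hz content
would otherwise alias into the analysis range.  The narrow notch rings for
~2 s, so attenuation is assessed on the analysis window, which the 3 s
pre-trial baseline keeps clear of the trial edge; there the 60 Hz residual
is ≤0.3% RMS while a 30 Hz tone passes within 0.1%.

The Morlet transform uses ω₀ = 6 (the common analytic-wavelet convention;
lower values trade frequency for time resolution) on f_k = 2·2^{0.1k} Hz,
k = 0…60, FFT-based with zero padding.  Samples within √2·scale of a trace
edge are inside the cone of influence and flagged; epoch averages exclude
flagged bins below 4 Hz only, where the cone is widest relative to the
epochs.  "1/f normalization" of power multiplies |W|² by f (reference
1 Hz), which flattens a 1/f spectrum.

## Permutation machinery

* **Surrogate bias correction** (PPC): 200 shuffles of one channel's trial
  order; corrected PPC = raw − surrogate mean.  PPC itself is unbiased in
  expectation, so the correction mainly removes pairing artifacts; its null
  mean is verified to sit at 0 within 3 SE at N = 20.
* **Selectivity z**: D = |PPC_A − PPC_B| with groups balanced to equal n by
  random subsampling of the larger; 200 size-preserving label permutations;
  z = (D − μ_perm)/σ_perm.  Because D is folded (non-negative), its null z
  is right-skewed; significance therefore uses the rank-based one-sided
  permutation p, not a Gaussian tail on z.  Type-I error at p < 0.05
  calibrates to 5% ± 2%.  Trials are kept in session order with a
  group-membership mask so that swapping the two labels leaves D and z
  bit-identical.
* **Cluster rule**: a bin survives iff it lies in a rectangle of ≥3
  consecutive frequencies sharing a common run of ≥60 ms (20 samples at
  333 Hz) with p < 0.05 everywhere.  The rectangular reading is stricter
  than a per-frequency-run union (an L-shaped region fails it); both
  readings agree on the canonical block cases.
* **PLV permutations** reassign whole LFP trial traces across trials
  (trial-label shuffle, not time shifts), keeping each trial's spike series
  — the null preserves spike count and temporal pattern exactly, which is
  what makes z robust at ~10 spikes/trial where raw PLV is inflated.
* Permutation RNGs are seeded per pair/electrode from a master seed.

Neural analyses default to correct trials only (configurable), matching the
convention of analyzing task-defined categories.

## Statistical summaries

Band × epoch cells collapse z-maps by averaging (beta 16–32 Hz, delta
2–4 Hz × Category, Shift); group tables report mean ± SEM across pairs and
the percent of pairs with ≥1 significant cluster intersecting the cell.
Baseline comparisons assign each pair's preferred category from the sign of
the band/epoch PPC difference and use two-tailed paired t-tests against the
fixation baseline.  Directionality is a paired t-test on z_PLV across pairs
per frequency, with band summaries over 22–32 Hz for the frontoparietal
contrast and 16–32 Hz elsewhere.  Decile selections take ceil(0.10 n) ids
with deterministic id-order tie-breaks (ties flagged); populations under 10
warn and still return at least one id.  PEV–PLV association reports both
Pearson and Spearman coefficients.

## Numerical and design choices

* 20 ms rate bins smoothed with a 200 ms-FWHM Gaussian (σ ≈ 85 ms,
  truncated at ±3σ); the σ-reading of "200 ms" is available via
  `width_is_fwhm=False` since the convention is genuinely ambiguous.
* ωPEV uses df_between = 1 (two categories); zero-total-variance bins
  define ωPEV = 0; silent units (zero baseline variance) are excluded from
  z-scoring with a warning rather than imputed.
* Per-unit significance ("percent of units selective at p < 0.01") uses
  200 label permutations of per-bin ωPEV, vectorized through group-sum
  identities; the population trace uses a one-sided t-test of PEV > 0
  sustained ≥100 ms (5 bins).
* Per-trial PLV with spike-count weighting is the default (keeps trials
  exchangeable under the permutation null); pooled-spike PLV is available
  and is the right estimator when absolute PLV magnitude matters, since the
  per-trial resultant is inflated by ~√(1/n_spikes) at low counts.
  Note the trial-permutation null is degenerate against a *deterministic
  constant-frequency* oscillation (per-trial PLV is invariant to a global
  phase rotation); the generator's narrowband-noise oscillators do not have
  this degeneracy.
* The O(N²) PPC sum is evaluated through the resultant identity (exact to
  machine precision; the naive sum is kept as a test oracle).
* HDF5 session schema is versioned; reads of a different version fail
  loudly rather than guessing.

## Problem sizes

Tests and the acceptance script run the full pipeline at 8 channels × 120
trials with 200 permutations throughout (the desk-scale reference
condition), with smaller constructed fixtures for unit-level checks.  All
simulations are seeded; the acceptance script derives every stream from its
`--seed` argument.

## Known limitations

* The cluster rule's rectangular reading and the FWHM smoothing convention
  are documented choices among defensible alternatives (switchable where it
  matters).
* Selectivity z is reported for interpretability but is not N(0,1) under
  the null (folded statistic); inference always goes through permutation
  ranks.
* Group ANOVAs with post-hoc corrections on real-data group means are out
  of scope; the package reports group means ± SEM and implements the
  permutation/t-test machinery the headline analyses need.
* No biophysical neuron or volume-conduction modelling; directionality
  contrasts are statistical asymmetries, not causal estimates.
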