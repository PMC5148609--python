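import numpy as np
import pytest

from catsync import lfp_signal, spike_field, synthgen
from catsync.spike_field import (
    directionality_contrast,
    pev_plv_correlation,
    plv_resultant,
    plv_z,
    selective_spike_plv_analysis,
    top_decile_selection,
)
from conftest import make_phase_decomposition


def tone_decomposition(f0=22.627417, n_trials=20, rng=None, amplitude=0.3):
    """Clean oscillation at a grid frequency, trial-random phase, plus the
    per-trial phase series that generated it."""
    rng = rng or np.random.default_rng(0)
    fs = 1000.0
    tl = synthgen.Timeline()
    n = int((tl.trial_end - tl.baseline_start) * fs)
    times = tl.baseline_start + np.arange(n) / fs
    lfp = np.zeros((1, n_trials, n))
    phis = []
    for tr in range(n_trials):
        phi = 2 * np.pi * f0 * times + rng.uniform(0, 2 * np.pi)
        lfp[0, tr] = amplitude * np.cos(phi)
        phis.append(phi)
    clean, fs2 = lfp_signal.preprocess_lfp(
        lfp, fs, lfp_signal.PreprocessConfig(evoked_removal=False)
    )
    dec = lfp_signal.morlet_transform(
        clean, fs2, times=lfp_signal.decimate_times(times), time_range=(-3.0, 3.9)
    )
    return dec, times, phis, fs


class TestPLV:
    def test_constant_phase_gives_one(self):
        assert plv_resultant([0.7] * 12) == pytest.approx(1.0)

    def test_four_symmetric_phases_give_zero(self):
        assert plv_resultant([0, np.pi / 2, np.pi, 3 * np.pi / 2]) == pytest.approx(0.0, abs=1e-12)

    def test_plv_z_constant_phase_spikes(self):
        """Spikes placed at a fixed oscillation phase give raw PLV ~ 1 at
        the matching frequency."""
        dec, times, phis, fs = tone_decomposition()
        trains = []
        for phi in phis:
            # spike whenever the oscillation crosses phase 0 upward
            wrapped = np.mod(phi, 2 * np.pi)
            cross = np.flatnonzero(np.diff(wrapped) < -np.pi)
            trains.append(times[cross])
        spec = plv_z(trains, dec, 0, epoch=(-2.0, 3.0), n_perm=20, rng=np.random.default_rng(1))
        k = int(np.argmin(np.abs(dec.freqs - 22.627417)))
        assert spec.plv_raw[k] > 0.98

    @pytest.mark.parametrize("m", [0.2, 0.4, 0.6])
    def test_modulation_depth_recovery(self, m):
        """Sinusoidally modulated Poisson spiking: PLV ~ m/2 at the
        modulating frequency (within 0.03 at > 2000 spikes)."""
        rng = np.random.default_rng(2)
        dec, times, phis, fs = tone_decomposition(n_trials=25, rng=rng)
        trains = [
            synthgen.synth_spike_train(20.0, 1.0, m, 0.0, phi, times, fs, rng)
            for phi in phis
        ]
        # pooled across trials: resultant of >2000 spike phases, where the
        # small-sample inflation of the resultant is negligible
        spec = plv_z(trains, dec, 0, epoch=(-2.5, 3.4), n_perm=10, rng=rng, pooled=True)
        assert spec.n_spikes > 2000
        k = int(np.argmin(np.abs(dec.freqs - 22.627417)))
        assert spec.plv_raw[k] == pytest.approx(m / 2, abs=0.03)

    def test_null_z_calibrated_and_spurious_raw_inflated(self):
        """~10 spikes/trial with no locking: raw PLV is inflated well
        above 0 but the permutation z stays centered on 0."""
        rng = np.random.default_rng(3)
        zs, raws = [], []
        for _ in range(30):
            dec = make_phase_decomposition(rng, n_channels=1, n_trials=12, n_freqs=4, n_times=80)
            trains = [np.sort(rng.uniform(0.0, 0.8, 10)) for _ in range(12)]
            spec = plv_z(trains, dec, 0, epoch=(0.0, 0.79), n_perm=60, rng=rng)
            zs.append(spec.z.mean())
            raws.append(spec.plv_raw.mean())
        zs = np.array(zs)
        assert np.mean(raws) > 0.1  # small-sample inflation of raw PLV
        assert abs(zs.mean()) < 3 * zs.std(ddof=1) / np.sqrt(zs.size)

    def test_errors(self):
        rng = np.random.default_rng(4)
        dec = make_phase_decomposition(rng, n_channels=1, n_trials=5, n_freqs=3, n_times=50)
        with pytest.raises(ValueError, match="no spikes"):
            plv_z([np.array([])] * 5, dec, 0, epoch=(0.0, 0.5))
        dec1 = make_phase_decomposition(rng, n_channels=1, n_trials=1, n_freqs=3, n_times=50)
        with pytest.raises(ValueError, match="trial"):
            plv_z([np.array([0.2])], dec1, 0, epoch=(0.0, 0.5))


class TestDirectionality:
    def _spectra(self, z_values, rng):
        f = lfp_signal.default_freq_grid()
        out = []
        for zv in z_values:
            z = rng.standard_normal(f.size) * 0.3 + zv
            out.append(
                spike_field.PLVSpectrum(
                    spike_electrode=0, lfp_electrode=1, direction="", epoch="category",
                    freqs=f, plv_raw=np.abs(z) / 10, z=z, n_spikes=500, n_trials_with_spikes=40,
                )
            )
        return out

    def test_identical_inputs_never_significant(self):
        rng = np.random.default_rng(5)
        ab = self._spectra(np.zeros(10), rng)
        df = directionality_contrast(ab, ab)
        assert not df["significant"].any()

    def test_argument_swap_negates_differences(self):
        rng = np.random.default_rng(6)
        ab = self._spectra(np.full(10, 0.5), rng)
        ba = self._spectra(np.zeros(10), rng)
        d1 = directionality_contrast(ab, ba)
        d2 = directionality_contrast(ba, ab)
        np.testing.assert_allclose(d1["mean_diff"], -d2["mean_diff"], atol=1e-12)
        np.testing.assert_allclose(d1["p"], d2["p"], atol=1e-12)

    def test_mismatched_pair_sets_error(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="matched pair sets"):
            directionality_contrast(self._spectra(np.zeros(4), rng), self._spectra(np.zeros(3), rng))

    def test_one_way_locking_confined_to_band(self):
        """m = 0.5 locking of A spikes to B's narrowband beta oscillation:
        the paired contrast is significant in the injected band and only
        in the locked direction."""
        rng = np.random.default_rng(8)
        fs = 1000.0
        tl = synthgen.Timeline()
        n = int((tl.trial_end - tl.baseline_start) * fs)
        times = tl.baseline_start + np.arange(n) / fs
        ab, ba = [], []
        for _ in range(8):
            lfp = np.zeros((1, 12, n))
            locked, unlocked = [], []
            for tr in range(12):
                z = synthgen._latent_oscillator(n, (16.0, 32.0), fs, rng)
                # broadband background keeps off-band phases signal-free
                lfp[0, tr] = 0.3 * z.real + 0.1 * synthgen._pink_noise(n, 1.0, fs, rng)
                phi = np.angle(z)
                locked.append(
                    synthgen.synth_spike_train(15.0, 1.0, 0.5, 0.0, phi, times, fs, rng)
                )
                unlocked.append(
                    synthgen.synth_spike_train(15.0, 1.0, 0.0, 0.0, None, times, fs, rng)
                )
            clean, fs2 = lfp_signal.preprocess_lfp(
                lfp, fs, lfp_signal.PreprocessConfig(evoked_removal=False)
            )
            dec = lfp_signal.morlet_transform(
                clean, fs2, times=lfp_signal.decimate_times(times), time_range=(-2.5, 3.5)
            )
            ab.append(plv_z(locked, dec, 0, epoch=(-2.0, 3.0), n_perm=40, rng=rng))
            ba.append(plv_z(unlocked, dec, 0, epoch=(-2.0, 3.0), n_perm=40, rng=rng))
        df = directionality_contrast(ab, ba, band=(16.0, 32.0))
        assert df.attrs["band_test"]["p"] < 0.05
        assert df.attrs["band_test"]["mean_ab"] > df.attrs["band_test"]["mean_ba"]
        in_band = (df["freq"] >= 16) & (df["freq"] <= 32)
        assert (df.loc[in_band, "significant"] & (df.loc[in_band, "mean_diff"] > 0)).any()
        # outside an extended band the 5% false-positive level applies
        outside = (df["freq"] < 11) | (df["freq"] > 45)
        assert df.loc[outside, "significant"].mean() < 0.25


class TestSelections:
    def test_decile_counts(self):
        sel = top_decile_selection({i: float(i) for i in range(20)})
        assert len(sel.selected) == 2
        assert sel.selected == [19, 18]

    def test_top_of_ten(self):
        scores = {i: 10.0 - i for i in range(10)}
        sel = top_decile_selection(scores)
        assert sel.selected == [0]
        assert sel.small_n_flag is False

    def test_bottom_side(self):
        scores = {i: float(i) for i in range(20)}
        sel = top_decile_selection(scores, side="bottom")
        assert sel.selected == [0, 1]

    def test_all_equal_scores_tie_flag(self):
        sel = top_decile_selection({i: 1.0 for i in range(20)})
        assert sel.selected == [0, 1]
        assert sel.tie_flag

    def test_small_population_warns(self):
        with pytest.warns(UserWarning, match="only 5"):
            sel = top_decile_selection({i: float(i) for i in range(5)})
        assert sel.small_n_flag and len(sel.selected) == 1


class TestGroupedPLV:
    def _plv_by_electrode(self, z_by_electrode, rng):
        f = np.linspace(10, 40, 8)
        out = {}
        for e, zv in z_by_electrode.items():
            specs = []
            for lfp_e in range(3):
                z = rng.standard_normal(f.size) * 0.2 + zv
                specs.append(
                    spike_field.PLVSpectrum(
                        spike_electrode=e, lfp_electrode=lfp_e, direction="", epoch="category",
                        freqs=f, plv_raw=np.abs(z) / 10, z=z, n_spikes=300, n_trials_with_spikes=30,
                    )
                )
            out[e] = specs
        return out

    def test_selective_group_stands_out(self):
        rng = np.random.default_rng(9)
        plvs = self._plv_by_electrode({0: 2.0, 1: 2.0, 2: 2.0, 3: 0.0, 4: 0.0, 5: 0.0}, rng)
        df = selective_spike_plv_analysis(plvs, [0, 1, 2], [3, 4, 5])
        assert df["mean_a"].mean() > df["mean_b"].mean() + 1
        assert df["significant"].mean() > 0.5

    def test_group_swap_negates(self):
        rng = np.random.default_rng(10)
        plvs = self._plv_by_electrode({0: 1.0, 1: 1.0, 2: 0.0, 3: 0.0}, rng)
        d1 = selective_spike_plv_analysis(plvs, [0, 1], [2, 3])
        d2 = selective_spike_plv_analysis(plvs, [2, 3], [0, 1])
        np.testing.assert_allclose(d1["mean_a"] - d1["mean_b"], -(d2["mean_a"] - d2["mean_b"]))

    def test_empty_group_errors(self):
        rng = np.random.default_rng(11)
        plvs = self._plv_by_electrode({0: 1.0, 1: 0.0}, rng)
        with pytest.raises(ValueError, match="non-empty"):
            selective_spike_plv_analysis(plvs, [0], [])


class TestCorrelation:
    def test_exact_linear_is_one(self):
        pev = {i: float(i) for i in range(8)}
        plv = {i: 2.0 * i + 1.0 for i in range(8)}
        out = pev_plv_correlation(pev, plv)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["spearman_r"] == pytest.approx(1.0)

    def test_permuted_pairing_in_null_band(self):
        rng = np.random.default_rng(12)
        n = 100
        x = rng.standard_normal(n)
        y = rng.permutation(rng.standard_normal(n))
        out = pev_plv_correlation(dict(enumerate(x)), dict(enumerate(y)))
        assert abs(out["pearson_r"]) < 2 / np.sqrt(n)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            pev_plv_correlation({0: 1.0, 1: 1.0, 2: 1.0}, {0: 1.0, 1: 2.0, 2: 3.0})

    def test_modulation_coupled_to_gain_recovers_positive_r(self):
        """Electrodes whose phase-locking depth grows with their category
        gain show a positive PEV-PLV correlation, mirroring the
        selectivity-synchrony link."""
        rng = np.random.default_rng(13)
        from catsync.spiking import omega_pev

        dec, times, phis, fs = tone_decomposition(n_trials=16, rng=rng)
        labels = np.array(["Above", "Below"] * 8)
        pev_scores, plv_scores = {}, {}
        for e in range(12):
            gain = 1.0 + 0.1 * e
            m = min(0.06 * e, 0.6)
            trains = []
            counts = []
            for tr, phi in enumerate(phis):
                g = gain if labels[tr] == "Above" else 1.0
                st = synthgen.synth_spike_train(12.0, g, m, 0.0, phi, times, fs, rng)
                trains.append(st)
                counts.append(((st >= 0) & (st < 1.3)).sum())
            pev_scores[e] = float(omega_pev(np.array(counts, float), labels))
            spec = plv_z(trains, dec, 0, epoch=(0.0, 1.3), n_perm=30, rng=rng)
            fi = (dec.freqs >= 16) & (dec.freqs <= 32)
            plv_scores[e] = float(spec.z[fi].mean())
        out = pev_plv_correlation(pev_scores, plv_scores)
        assert out["pearson_r"] > 0.3
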