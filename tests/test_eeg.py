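"""EEG chain: filters, ocular correction, epoching, spectra, reactivity."""

import numpy as np
import pandas as pd
import pytest

from stresslab.cohort import CohortSpec, EffectSpec, generate_cohort
from stresslab.eeg import (
    BandPowerTable,
    EEGRecording,
    Marker,
    Spectrum,
    band_roi_power,
    correct_ocular,
    epoch_and_reject,
    normalize,
    periodogram_hamming,
    phase_psd,
    preprocess,
    session_reactivity,
)


def _rec(data, ch_names, sfreq, markers=()):
    return EEGRecording(np.atleast_2d(data), ch_names, sfreq, list(markers))


def _sine(freq, dur, fs):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_stopband_60hz_attenuated(self):
        rec = _rec(_sine(60, 10, 1000.0), ["F3"], 1000.0)
        out = preprocess(rec)
        mid = slice(2000, 8000)   # avoid filter edges
        assert np.abs(out.data[0, mid]).max() < 0.05

    def test_passband_10hz_preserved(self):
        rec = _rec(_sine(10, 10, 1000.0), ["F3"], 1000.0)
        out = preprocess(rec)
        mid = slice(2000, 8000)
        assert np.abs(out.data[0, mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_in_zero_out(self):
        rec = _rec(np.zeros(5000), ["F3"], 1000.0)
        assert np.allclose(preprocess(rec).data, 0.0)

    def test_low_sampling_rate_rejected(self):
        rec = _rec(np.zeros(500), ["F3"], 80.0)
        with pytest.raises(ValueError, match="band edge"):
            preprocess(rec)


class TestOcularCorrection:
    def test_known_blink_mixing_removed(self, rng):
        n, fs = 4000, 250.0
        blink = np.zeros(n)
        for i in (500, 1500, 2900):
            blink[i:i + 100] += np.hanning(100)
        brain = rng.standard_normal((2, n))
        eog = np.vstack([100 * blink + rng.standard_normal(n),
                         80 * blink + rng.standard_normal(n)])
        scalp = brain + np.array([[40.0], [25.0]]) * blink
        rec = _rec(np.vstack([scalp, eog]), ["F3", "F4", "EOG1", "EOG2"], fs)
        out = correct_ocular(rec)
        # residual blink amplitude on frontal channels < 20% of injected
        resid = out.data[:2] - brain
        assert np.abs(resid[:, 500:600]).max() < 0.2 * 40.0

    def test_blink_free_data_nearly_untouched(self, rng):
        data = rng.standard_normal((3, 3000))
        rec = _rec(data, ["F3", "EOG1", "EOG2"], 250.0)
        out = correct_ocular(rec)
        r = np.corrcoef(out.data[0], data[0])[0, 1]
        assert r > 0.99

    def test_flat_eog_identity(self, rng):
        data = rng.standard_normal((3, 1000))
        data[1:] = 0.0
        rec = _rec(data, ["F3", "EOG1", "EOG2"], 250.0)
        out = correct_ocular(rec)
        assert np.array_equal(out.data, rec.data)

    def test_missing_eog_warns_and_skips(self, rng):
        rec = _rec(rng.standard_normal((1, 1000)), ["F3"], 250.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = correct_ocular(rec)
        assert np.array_equal(out.data, rec.data)


class TestEpoching:
    def test_120s_baseline_gives_60_epochs(self, rng):
        fs = 250.0
        rec = _rec(rng.standard_normal((1, int(124 * fs))), ["F3"], fs,
                   [Marker("baseline_open", 0.0, 120.0)])
        es = epoch_and_reject(rec)["baseline_open"]
        assert es.epochs.shape[0] == 60
        assert es.n_kept == 60

    def test_spike_epoch_rejected(self, rng):
        fs = 250.0
        data = rng.standard_normal((1, int(10 * fs)))
        data[0, int(5.3 * fs)] = 500.0    # spike inside epoch index 2
        rec = _rec(data, ["F3"], fs, [Marker("baseline_open", 0.0, 10.0)])
        es = epoch_and_reject(rec, amp_limit=100.0)["baseline_open"]
        assert list(np.flatnonzero(~es.keep)) == [2]
        assert "amplitude" in es.reasons[2]

    def test_flat_epoch_rejected(self):
        fs = 250.0
        rec = _rec(np.zeros((1, int(4 * fs))), ["F3"], fs,
                   [Marker("baseline_open", 0.0, 4.0)])
        es = epoch_and_reject(rec)["baseline_open"]
        assert es.n_kept == 0
        assert all(r == "flat" for r in es.reasons)

    def test_short_phase_yields_zero_epochs_with_warning(self, rng):
        fs = 250.0
        rec = _rec(rng.standard_normal((1, int(3 * fs))), ["F3"], fs,
                   [Marker("prep_D1", 0.0, 1.0)])
        with pytest.warns(UserWarning, match="shorter"):
            es = epoch_and_reject(rec)["prep_D1"]
        assert es.epochs.shape[0] == 0


class TestPSD:
    def test_pure_tone_power_concentrated(self):
        fs, dur = 250.0, 40.0
        x = _sine(10.0, dur, fs).reshape(-1, int(2 * fs))
        es_like = x[:, None, :]
        from stresslab.eeg import EpochSet
        es = EpochSet("t", es_like, ["F3"], fs, np.ones(len(x), bool), [""] * len(x))
        spec = phase_psd(es)
        sel = (spec.freqs >= 9.5) & (spec.freqs <= 10.5)
        assert spec.power[0, sel].sum() / spec.power[0].sum() > 0.90

    def test_white_noise_parseval(self, rng):
        fs, sigma = 250.0, 2.0
        x = sigma * rng.standard_normal((120, int(2 * fs)))   # 120 epochs
        freqs, pxx = periodogram_hamming(x, fs)
        df = freqs[1] - freqs[0]
        total = pxx.mean(axis=0).sum() * df
        assert total == pytest.approx(sigma ** 2, rel=0.05)

    def test_resolution_is_half_hz_for_2s_epochs(self, rng):
        freqs, _ = periodogram_hamming(rng.standard_normal(int(2 * 250.0)), 250.0)
        assert freqs[1] - freqs[0] == pytest.approx(0.5)

    def test_matches_bruteforce_dft_oracle(self, rng):
        """Hand-rolled Hamming periodogram on 16 samples, 1e-10 agreement."""
        fs, n = 16.0, 16
        x = rng.standard_normal(n)
        # periodic (DFT-even) Hamming taper, written out explicitly
        w = 0.54 - 0.46 * np.cos(2 * np.pi * np.arange(n) / n)
        xw = x * w
        scale = 1.0 / (fs * (w ** 2).sum())
        expected = []
        for k in range(n // 2 + 1):
            X = sum(xw[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
            p = scale * abs(X) ** 2
            if 0 < k < n // 2:
                p *= 2.0
            expected.append(p)
        freqs, pxx = periodogram_hamming(x, fs)
        assert np.allclose(pxx, expected, atol=1e-10)

    def test_no_kept_epochs_raises_with_phase_name(self):
        from stresslab.eeg import EpochSet
        es = EpochSet("prep_D2", np.zeros((2, 1, 500)), ["F3"], 250.0,
                      np.zeros(2, bool), ["flat", "flat"])
        with pytest.raises(ValueError, match="prep_D2"):
            phase_psd(es)


class TestBandRoiPower:
    @staticmethod
    def _flat_spectrum(values_by_channel, fmax=50.0):
        freqs = np.arange(0.0, fmax + 0.5, 0.5)
        chs = list(values_by_channel)
        power = np.array([[v] * len(freqs) for v in values_by_channel.values()],
                         dtype=float)
        return Spectrum(freqs, power, chs)

    def test_unit_spectrum_gives_unit_powers(self):
        spec = self._flat_spectrum(dict.fromkeys(
            ["F3", "F7", "F4", "F8", "T7", "P3", "T8", "P4"], 1.0))
        tab = band_roi_power(spec)
        assert np.allclose(tab.channel.to_numpy(), 1.0)
        assert np.allclose(tab.roi.to_numpy(), 1.0)

    def test_alpha_only_spectrum(self):
        freqs = np.arange(0.0, 50.5, 0.5)
        power = np.zeros((8, len(freqs)))
        power[:, (freqs >= 8.0) & (freqs <= 12.5)] = 3.0
        spec = Spectrum(freqs, power, ["F3", "F7", "F4", "F8", "T7", "P3", "T8", "P4"])
        tab = band_roi_power(spec)
        assert (tab.roi.loc["alpha"] == 3.0).all()
        for band in ("delta", "theta", "beta", "gamma"):
            assert (tab.roi.loc[band] == 0.0).all()

    def test_roi_is_mean_of_channel_pair(self):
        vals = dict.fromkeys(["F3", "F7", "F4", "F8", "T7", "P3", "T8", "P4"], 1.0)
        vals["F3"], vals["F7"] = 2.0, 4.0
        tab = band_roi_power(self._flat_spectrum(vals))
        assert (tab.roi["F1"] == 3.0).all()

    def test_short_spectrum_rejected(self):
        spec = self._flat_spectrum({"F3": 1.0}, fmax=30.0)
        with pytest.raises(ValueError, match="bands extend"):
            band_roi_power(spec)

    def test_invariant_to_channel_order(self, rng):
        freqs = np.arange(0.0, 50.5, 0.5)
        chs = ["F3", "F7", "F4", "F8", "T7", "P3", "T8", "P4"]
        power = rng.uniform(0.5, 2.0, size=(8, len(freqs)))
        perm = rng.permutation(8)
        t1 = band_roi_power(Spectrum(freqs, power, chs))
        t2 = band_roi_power(Spectrum(freqs, power[perm], [chs[i] for i in perm]))
        pd.testing.assert_frame_equal(t1.roi, t2.roi)


class TestNormalize:
    @staticmethod
    def _table(value):
        df = pd.DataFrame(value, index=["delta", "theta", "alpha", "beta", "gamma"],
                          columns=["F1", "F2", "TP1", "TP2"])
        return BandPowerTable("x", df.copy(), df)

    def test_task_equals_baseline_gives_zero(self):
        out = normalize(self._table(2.5), self._table(2.5))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_doubling_gives_one(self):
        assert np.allclose(normalize(self._table(2.0), self._table(1.0)).to_numpy(), 1.0)

    def test_halving_gives_minus_half(self):
        assert np.allclose(normalize(self._table(0.5), self._table(1.0)).to_numpy(), -0.5)

    def test_nonpositive_baseline_marked_missing(self):
        base = self._table(1.0)
        base.roi.loc["alpha", "F1"] = 0.0
        out = normalize(self._table(2.0), base)
        assert np.isnan(out.loc["alpha", "F1"])
        assert out.drop(index="alpha").notna().all().all()


class TestEndToEnd:
    def test_alpha_suppression_recovered_in_reactivity(self):
        """Injected dynamic-group alpha suppression shows up in group-mean TR."""
        cohort = generate_cohort(CohortSpec.fast(n_per_group=4, seed=21), EffectSpec())
        rows = []
        for s in cohort:
            tr = session_reactivity(s.eeg)
            tr["group"] = s.group
            rows.append(tr)
        df = pd.concat(rows)
        means = df[df["band"] == "alpha"].groupby("group")["tr_psd"].mean()
        assert means["Dyn-DSST"] < means["Stat-DSST"]

    def test_reactivity_has_full_band_roi_discourse_grid(self, small_cohort):
        tr = session_reactivity(small_cohort[0].eeg)
        assert len(tr) == 5 * 4 * 5
        assert not tr["tr_psd"].isna().any()
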