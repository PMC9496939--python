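"""Spectral quantification tests: DFT scaling against a brute-force oracle,
the local-noise SNR/baseline/Z measures, the consecutive-harmonic stop rule
and the response table."""
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fpvs
from fpvs import spectral as sp
from fpvs.config import SimulationConfig
from fpvs.containers import Epoch
from fpvs.montage import ROIS


def brute_force_dft_amplitude(x: np.ndarray) -> np.ndarray:
    """O(N^2) single-sided amplitude spectrum, written independently of any
    FFT routine."""
    n = len(x)
    n_bins = n // 2 + 1
    out = np.empty(n_bins)
    t = np.arange(n)
    for k in range(n_bins):
        re = np.sum(x * np.cos(2 * np.pi * k * t / n))
        im = -np.sum(x * np.sin(2 * np.pi * k * t / n))
        mag = np.sqrt(re**2 + im**2) / n
        if k != 0 and not (n % 2 == 0 and k == n // 2):
            mag *= 2
        out[k] = mag
    return out


def _flat_with_noise_pattern(target_bin: int, pattern: dict, base: float = 1.0,
                             n_bins: int = 200) -> np.ndarray:
    amps = np.full(n_bins, base)
    for off, v in pattern.items():
        amps[target_bin + off] = v
    return amps


class TestCommonCycle:
    def test_tag_gcd(self):
        assert sp.common_cycle(6.0, 7.5) == pytest.approx(1.5)


class TestCrop:
    def _epoch(self, sfreq=256.0):
        n = int(68 * sfreq)
        return Epoch(data=np.zeros((1, n)), sfreq=sfreq, ch_names=["Oz"])

    def test_nominal_mode_sample_count(self):
        seg = sp.crop_integer_cycles(self._epoch(), "nominal")
        assert seg.shape[1] == 15203 == round(59.3867 * 256)

    def test_exact_bin_mode_centers_tags(self):
        seg = sp.crop_integer_cycles(self._epoch(), "exact-bin")
        n = seg.shape[1]
        assert n == 15360
        assert (6.0 * n / 256.0).is_integer() and (7.5 * n / 256.0).is_integer()

    def test_too_short_epoch(self):
        ep = Epoch(data=np.zeros((1, 1000)), sfreq=256.0, ch_names=["Oz"])
        with pytest.raises(ValueError):
            sp.crop_integer_cycles(ep, "nominal")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            sp.crop_integer_cycles(self._epoch(), "nope")


class TestAverageSegments:
    def test_identity_and_cancellation(self):
        s = np.random.default_rng(0).normal(size=(2, 100))
        np.testing.assert_array_equal(sp.average_segments([s, s]), s)
        np.testing.assert_allclose(sp.average_segments([s, -s]), 0.0, atol=1e-15)

    def test_mixed_lengths(self):
        with pytest.raises(ValueError):
            sp.average_segments([np.zeros((1, 10)), np.zeros((1, 11))])

    def test_sqrt_m_noise_law(self):
        rng = np.random.default_rng(1)
        rms_single, rms_avg = [], []
        for _ in range(40):
            segs = [rng.standard_normal((1, 2000)) for _ in range(4)]
            rms_single.append(np.sqrt(np.mean(segs[0] ** 2)))
            rms_avg.append(np.sqrt(np.mean(sp.average_segments(segs) ** 2)))
        assert np.mean(rms_avg) == pytest.approx(np.mean(rms_single) / 2, rel=0.05)


class TestAmplitudeSpectrum:
    def test_zero_input(self):
        s = sp.amplitude_spectrum(np.zeros((1, 256)), 256.0)
        assert np.all(s.amps == 0)
        assert s.df == pytest.approx(1.0)

    def test_bin_centered_tone_amplitude(self):
        sfreq, n = 256.0, 15360
        t = np.arange(n) / sfreq
        x = 2.0 * np.sin(2 * np.pi * 6.0 * t)
        s = sp.amplitude_spectrum(x, sfreq)
        assert s.amps[0][s.bin_of(6.0)] == pytest.approx(2.0, abs=1e-9)

    @pytest.mark.parametrize("n", [17, 64, 129, 256, 512])
    def test_matches_brute_force_dft(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        s = sp.amplitude_spectrum(x, 256.0)
        np.testing.assert_allclose(s.amps[0], brute_force_dft_amplitude(x), atol=1e-9)


class TestSnr:
    def test_flat_spectrum(self):
        amps = np.full(100, 0.7)
        assert sp.snr(amps, 50) == pytest.approx(1.0)

    def test_trimming_rule_hand_computed(self):
        # noise candidates all 1.0 except a 5.0 and a 0.0 that get trimmed
        amps = _flat_with_noise_pattern(50, {0: 10.0, 3: 5.0, -3: 0.0})
        assert sp.snr(amps, 50) == pytest.approx(10.0)

    def test_zero_noise_mean_flags_inf(self):
        amps = np.zeros(100)
        amps[50] = 1.0
        with pytest.warns(UserWarning):
            assert sp.snr(amps, 50) == np.inf

    def test_white_noise_median_near_one(self):
        rng = np.random.default_rng(2)
        meds = []
        for _ in range(20):
            s = sp.amplitude_spectrum(rng.standard_normal(4096), 256.0)
            vals = [sp.snr(s.amps[0], b) for b in range(50, 1900, 10)]
            meds.append(np.median(vals))
        assert 0.9 < np.mean(meds) < 1.2

    def test_needs_enough_flanks(self):
        with pytest.raises(ValueError):
            sp.snr(np.ones(30), 5)


class TestBaselineCorrected:
    def test_flat_is_zero(self):
        assert sp.baseline_corrected(np.full(60, 1.3), 30) == pytest.approx(0.0)

    def test_hand_computed(self):
        amps = _flat_with_noise_pattern(50, {0: 2.0}, base=0.5)
        assert sp.baseline_corrected(amps, 50) == pytest.approx(1.5)

    def test_null_expectation_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(30):
            s = sp.amplitude_spectrum(rng.standard_normal(4096), 256.0)
            vals.extend(sp.baseline_corrected(s.amps[0], b) for b in range(50, 1900, 16))
        mean_amp = 2 * np.abs(np.fft.rfft(rng.standard_normal(4096))).mean() / 4096
        assert abs(np.mean(vals)) < 0.05 * mean_amp


def _alternating_window(target_bin: int = 50, target: float = 5.0, n_bins: int = 200):
    """Spectrum whose untrimmed noise bins (offsets ±2..±11) alternate 1, 3."""
    amps = np.empty(n_bins)
    amps[::2] = 1.0
    amps[1::2] = 3.0
    amps[target_bin] = target
    return amps


class TestZScore:
    def test_flat_spectrum_degenerate(self):
        with pytest.raises(ValueError, match="SD"):
            sp.zscore_bin(np.ones(100), 50)

    def test_hand_computed_alternating(self):
        # 20 noise values of 1 and 3: mean 2, sample SD 1.02598; Z = 3/1.02598
        amps = _alternating_window()
        assert sp.zscore_bin(amps, 50) == pytest.approx(2.92, abs=0.005)

    def test_null_rate_close_to_nominal(self):
        """P(Z > 1.64) at signal-free bins of group-averaged noise spectra."""
        rng = np.random.default_rng(4)
        n, navg = 4096, 31
        cnt = tot = 0
        for _ in range(6):
            amps = np.mean(
                [sp.amplitude_spectrum(rng.standard_normal(n), 256.0).amps[0]
                 for _ in range(navg)], axis=0,
            )
            for b in range(60, 1980, 1):
                cnt += sp.zscore_bin(amps, b) > 1.64
                tot += 1
        assert tot >= 10_000
        assert cnt / tot == pytest.approx(0.05, abs=0.02)


class TestSelectHarmonics:
    def _spectrum_with_z(self, zs: dict, f0: float, df: float = 1 / 60):
        """Construct a spectrum whose harmonic bins carry prescribed Z values
        over an alternating 1/3 noise floor (mean 2, sample SD 1.02598)."""
        n_bins = int(50.0 / df)
        amps = np.empty(n_bins)
        amps[::2] = 1.0
        amps[1::2] = 3.0
        sd = np.std([1.0] * 10 + [3.0] * 10, ddof=1)
        for k, z in zs.items():
            amps[int(round(k * f0 / df))] = 2.0 + z * sd
        return amps, df

    def test_stop_after_two_consecutive_failures(self):
        amps, df = self._spectrum_with_z(
            {1: 8.1, 2: 3.0, 3: 1.1, 4: 0.9, 5: 0.5, 6: 0.5}, 6.0
        )
        hs = sp.select_harmonics(amps, df, 6.0)
        assert hs.harmonics == [6.0, 12.0]

    def test_nothing_significant(self):
        amps, df = self._spectrum_with_z({k: 0.8 for k in range(1, 7)}, 6.0)
        hs = sp.select_harmonics(amps, df, 6.0)
        assert hs.harmonics == []
        assert not hs

    def test_lone_dip_does_not_stop(self):
        amps, df = self._spectrum_with_z(
            {1: 5.0, 2: 1.0, 3: 5.0, 4: 1.0, 5: 1.0, 6: 0.5}, 6.0
        )
        hs = sp.select_harmonics(amps, df, 6.0)
        assert hs.harmonics == [6.0, 12.0, 18.0]

    def test_shared_30hz_multiple_excluded(self):
        amps, df = self._spectrum_with_z({k: 9.0 for k in range(1, 7)}, 6.0)
        hs = sp.select_harmonics(amps, df, 6.0, max_harmonics=6)
        assert 30.0 not in hs.harmonics
        assert hs.harmonics == [6.0, 12.0, 18.0, 24.0, 36.0]


class TestSummedResponse:
    def test_adds_baseline_corrected_values(self):
        df = 1 / 60
        amps = np.full(int(40 / df), 0.5)
        amps[int(round(6.0 / df))] = 0.5 + 1.2
        amps[int(round(12.0 / df))] = 0.5 + 0.3
        hs = sp.HarmonicSet(6.0, [6.0, 12.0])
        assert sp.summed_response(amps, hs, df) == pytest.approx(1.5)

    def test_empty_set_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert sp.summed_response(np.ones(100), sp.HarmonicSet(6.0, []), 0.1) == 0.0


class TestRoiAggregate:
    def test_mean_and_missing(self):
        vals = {ch: 1.0 for roi in ROIS.values() for ch in roi}
        assert sp.roi_aggregate(vals, "MO") == pytest.approx(1.0)
        vals2 = dict(zip(ROIS["MO"], (1.0, 2.0, 3.0, 6.0)))
        assert sp.roi_aggregate(vals2, "MO") == pytest.approx(3.0)
        vals3 = dict(zip(ROIS["LOT"], (2.0, 4.0, 9.0)))
        assert sp.roi_aggregate(vals3, "LOT") == pytest.approx(5.0)
        with pytest.raises(ValueError):
            sp.roi_aggregate({"P7": 1.0}, "LOT")


class TestIndividualZ:
    def test_flat_windows_degenerate(self):
        hs = sp.HarmonicSet(6.0, [6.0, 12.0])
        with pytest.raises(ValueError):
            sp.individual_z(np.ones(2000), 1 / 60, hs)

    def test_summed_windows_match_hand_computation(self):
        # two windows summing to the alternating 1/3 pattern with center 5
        df = 1 / 60
        n_bins = 2000
        amps = np.empty(n_bins)
        amps[::2] = 0.5
        amps[1::2] = 1.5
        c1, c2 = int(round(6.0 / df)), int(round(12.0 / df))
        # parity alignment: both windows contribute half the final pattern
        assert (c1 % 2) == (c2 % 2) == 0
        amps[c1] = amps[c2] = 2.5
        hs = sp.HarmonicSet(6.0, [6.0, 12.0])
        assert sp.individual_z(amps, df, hs) == pytest.approx(2.92, abs=0.005)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sp.individual_z(np.ones(100), 0.1, sp.HarmonicSet(6.0, []))


class TestEndToEndQuantification:
    def test_phase_is_immaterial_for_amplitudes(self, clean_profile, quiet_config):
        from fpvs import preprocess as pre
        from fpvs.simulate import simulate_sequence

        results = []
        for phase0 in (0.0, 1.3):
            prof = clean_profile
            prof.phases = {k: phase0 for k in prof.phases}
            rec = simulate_sequence(prof, {"face": 6.0, "house": 7.5}, quiet_config, seed=1)
            ep = pre.rereference_average(
                pre.resample(pre.bandpass(pre.segment(rec)[0]), 256.0)
            )
            seg = sp.crop_integer_cycles(ep, "exact-bin")
            s = sp.amplitude_spectrum(seg, 256.0, ep.ch_names)
            results.append(s.channel("PO8")[s.bin_of(6.0)])
        # identical to filter-transient precision: the response measure does
        # not depend on the response phase
        assert results[0] == pytest.approx(results[1], rel=1e-3)

    def test_summed_response_linear_in_amplitude(self, quiet_config):
        from fpvs import preprocess as pre
        from fpvs.simulate import draw_profile, simulate_sequence

        vals = []
        for scale in (1.0, 2.0):
            prof = draw_profile(1, quiet_config, np.random.default_rng(0))
            prof.noise_scale = 0.0
            prof.blink_rate = 0.0
            prof.face_amp = {r: scale * a for r, a in prof.face_amp.items()}
            rec = simulate_sequence(prof, {"face": 6.0, "house": 7.5}, quiet_config, seed=2)
            ep = pre.rereference_average(
                pre.resample(pre.bandpass(pre.segment(rec)[0]), 256.0)
            )
            seg = sp.crop_integer_cycles(ep, "exact-bin")
            s = sp.amplitude_spectrum(seg, 256.0, ep.ch_names)
            hs = sp.HarmonicSet(6.0, [6.0, 12.0])
            vals.append(sp.summed_response(s.channel("PO8"), hs, s.df))
        assert vals[1] == pytest.approx(2 * vals[0], rel=1e-3)
        assert vals[1] > vals[0]

    def test_quantify_study_schema_and_z(self, tiny_epochs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, hsets = sp.quantify_study(tiny_epochs, crop_mode="nominal")
        table = sp.build_response_table(table, 2)
        assert len(table) == 48
        assert set(hsets) == {6.0, 7.5}
        for hs in hsets.values():
            assert hs.harmonics == [hs.f0, 2 * hs.f0]
        # every simulated response is individually significant
        assert (table.z > 1.64).all()

    def test_build_response_table_detects_missing_cells(self, tiny_epochs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, _ = sp.quantify_study(tiny_epochs, crop_mode="nominal")
        broken = table.iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            sp.build_response_table(broken, 2)

    def test_empty_input_empty_table(self):
        table, hsets = sp.quantify_study([])
        assert len(table) == 0 and hsets == {}


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=16, max_value=256), st.integers(min_value=0, max_value=10**6))
def test_spectrum_scaling_matches_brute_force(n, seed):
    """Property: the amplitude spectrum equals the brute-force DFT for any
    length and content."""
    x = np.random.default_rng(seed).normal(size=n)
    s = sp.amplitude_spectrum(x, 128.0)
    np.testing.assert_allclose(s.amps[0], brute_force_dft_amplitude(x), atol=1e-9)
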