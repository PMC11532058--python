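"""Feature tests: PRSA against brute-force anchored averaging, VMD tone
recovery and reconstruction, peak counting against a dense-grid oracle,
and the assembled ten-feature vector."""

import numpy as np
import pytest

import fqrs
from fqrs.errors import InvalidParameterError, NoAnchorError, ZeroEnergyError
from fqrs.features import DEFAULT_PRSA_L


def prsa_bruteforce(x, L):
    """Independent oracle: literal anchored averaging."""
    x = np.asarray(x, dtype=float)
    anchors = [i for i in range(L, len(x) - L) if x[i] > x[i - 1]]
    if not anchors:
        raise NoAnchorError("no anchors")
    return np.mean([x[a - L : a + L] for a in anchors], axis=0), len(anchors)


class TestPrsa:
    def test_constant_segment_has_no_anchors(self):
        with pytest.raises(NoAnchorError):
            fqrs.compute_prsa(np.ones(128), L=8)

    def test_increasing_ramp_gives_linear_curve(self):
        step = 0.5
        x = step * np.arange(64)
        curve = fqrs.compute_prsa(x, L=4)
        diffs = np.diff(curve.curve)
        np.testing.assert_allclose(diffs, step, atol=1e-12)

    def test_sinusoid_curve_keeps_period(self):
        period = 16
        x = np.sin(2 * np.pi * np.arange(128) / period)
        curve = fqrs.compute_prsa(x, L=period)
        oracle, n = prsa_bruteforce(x, period)
        np.testing.assert_allclose(curve.curve, oracle, atol=1e-12)
        assert curve.anchor_count == n
        # oscillation survives the averaging with the same period
        spec = np.abs(np.fft.rfft(curve.curve - curve.curve.mean()))
        assert np.argmax(spec) == len(curve.curve) // period

    def test_matches_bruteforce_on_random_segments(self, random_segments):
        for x in random_segments:
            curve = fqrs.compute_prsa(x, L=DEFAULT_PRSA_L)
            oracle, n = prsa_bruteforce(x, DEFAULT_PRSA_L)
            assert curve.anchor_count == n
            np.testing.assert_allclose(curve.curve, oracle, atol=1e-12)

    def test_l_bounds_enforced(self):
        with pytest.raises(InvalidParameterError):
            fqrs.compute_prsa(np.random.default_rng(0).normal(size=128), L=1)
        with pytest.raises(InvalidParameterError):
            fqrs.compute_prsa(np.random.default_rng(0).normal(size=128), L=64)


class TestPrsaFeatures:
    def test_exact_line_recovers_slope_and_intercept(self):
        k = np.arange(32, dtype=float)
        curve = fqrs.PrsaCurve(curve=0.7 * k - 1.3, anchor_count=5, half_window=16)
        d, slope, ycross = fqrs.prsa_features(curve)
        assert d == pytest.approx(0.7, abs=1e-12)
        assert slope == pytest.approx(0.7, abs=1e-12)
        assert ycross == pytest.approx(-1.3, abs=1e-12)

    def test_constant_curve(self):
        curve = fqrs.PrsaCurve(curve=np.full(32, 2.5), anchor_count=3, half_window=16)
        d, slope, ycross = fqrs.prsa_features(curve)
        assert (d, slope) == (0.0, 0.0)
        assert ycross == pytest.approx(2.5)

    def test_random_curve_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(32)
        curve = fqrs.PrsaCurve(curve=y, anchor_count=4, half_window=16)
        _, slope, ycross = fqrs.prsa_features(curve)
        k = np.arange(32)
        A = np.column_stack([k, np.ones(32)])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert slope == pytest.approx(beta[0], abs=1e-12)
        assert ycross == pytest.approx(beta[1], abs=1e-12)


class TestVmd:
    def test_zero_segment_yields_zero_modes(self):
        modes = fqrs.vmd_decompose(np.zeros(128), k=3)
        np.testing.assert_allclose(modes.modes, 0.0, atol=1e-12)

    def test_single_tone_recovery(self):
        # tone aligned to the mirrored FFT grid, so no spectral leakage
        # feeds the second mode
        fs = 1000.0
        f0 = 125.0
        t = np.arange(128) / fs
        x = np.cos(2 * np.pi * f0 * t)
        modes = fqrs.vmd_decompose(x, k=2, fs=fs)
        energies = np.sum(modes.modes**2, axis=1)
        top = int(np.argmax(energies))
        assert energies[top] / energies.sum() >= 0.90
        assert abs(modes.center_frequencies[top] - f0) <= 2.0

    def test_two_tone_recovery(self):
        fs = 1000.0
        t = np.arange(256) / fs
        x = np.cos(2 * np.pi * 60 * t) + 0.8 * np.cos(2 * np.pi * 220 * t)
        modes = fqrs.vmd_decompose(x, k=3, fs=fs)
        energies = np.sum(modes.modes**2, axis=1)
        leading = np.argsort(energies)[-2:]
        freqs = sorted(modes.center_frequencies[leading])
        assert abs(freqs[0] - 60) <= 2.0
        assert abs(freqs[1] - 220) <= 2.0

    def test_reconstruction_error_on_bandlimited_qrs(self):
        """Relative L2 reconstruction error stays below 5% on smooth,
        compactly supported QRS-shaped segments (clean and fragmented)."""
        tpl = fqrs.default_templates()["II"]
        frag = fqrs.synth_ecg.inject_fragmentation(
            tpl, fqrs.FragmentationSpec.from_severity(1.0, seed=2)
        )
        lo, hi = tpl.qrs_support()
        grid = np.linspace(lo, hi, 128)
        for shape in (tpl, frag):
            x = shape.evaluate(grid)
            modes = fqrs.vmd_decompose(x, k=5)
            err = np.linalg.norm(x - modes.reconstruction()) / np.linalg.norm(x)
            assert err <= 0.05

    def test_center_frequencies_sorted(self):
        rng = np.random.default_rng(2)
        modes = fqrs.vmd_decompose(rng.standard_normal(128), k=5)
        assert np.all(np.diff(modes.center_frequencies) >= 0)


class TestVmdFeatures:
    def _modes(self, arrays, freqs):
        return fqrs.VmdModes(
            modes=np.asarray(arrays, dtype=float),
            center_frequencies=np.asarray(freqs, dtype=float),
            converged=True,
            fs=1000.0,
        )

    def test_energy_in_lowest_mode_only(self):
        m = [np.ones(16)] + [np.zeros(16)] * 4
        e3, e4, e5, *_ = fqrs.vmd_features(self._modes(m, range(5)))
        assert (e3, e4, e5) == (0.0, 0.0, 0.0)

    def test_equal_energy_normalisation(self):
        m = [np.ones(16) * (i + 1) / (i + 1) for i in range(5)]
        e3, e4, e5, *_ = fqrs.vmd_features(self._modes(m, range(5)))
        assert e3 == e4 == e5 == pytest.approx(0.2)

    def test_zero_crossings_match_bruteforce(self):
        x = np.sin(2 * np.pi * np.arange(128) / 128)  # one full cycle
        m = [np.zeros(128)] * 4 + [x]
        *_, z5 = fqrs.vmd_features(self._modes(m, range(5)))
        s = np.sign(x)
        s = s[s != 0]
        assert z5 == int(np.sum(s[:-1] * s[1:] < 0))

    def test_relative_energies_sum_to_one(self):
        rng = np.random.default_rng(3)
        modes = fqrs.vmd_decompose(rng.standard_normal(128), k=5)
        energies = np.sum(modes.modes**2, axis=1)
        assert energies.sum() > 0
        assert np.sum(energies / energies.sum()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_modes_rejected(self):
        m = [np.zeros(16)] * 5
        with pytest.raises(ZeroEnergyError):
            fqrs.vmd_features(self._modes(m, range(5)))


class TestCountQrsPeaks:
    def test_single_gaussian(self):
        t = np.linspace(-0.06, 0.06, 128)
        x = np.exp(-0.5 * (t / 0.016) ** 2)
        assert fqrs.count_qrs_peaks(x) == 1

    def test_rs_biphasic(self):
        tpl = fqrs.generate_beat_template(
            {"R": (1.0, 0.0, 0.016), "S": (-0.4, 0.03, 0.012)}
        )
        lo, hi = tpl.qrs_support()
        x = tpl.evaluate(np.linspace(lo, hi, 128))
        assert fqrs.count_qrs_peaks(x) == 2

    def test_flat_segment(self):
        assert fqrs.count_qrs_peaks(np.zeros(128)) == 0

    def test_scaling_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(128)
        assert fqrs.count_qrs_peaks(x) == fqrs.count_qrs_peaks(3.7 * x)


class TestFeatureVector:
    def test_identical_segments_identical_vectors(self, clean_record):
        segs = fqrs.segment_record(clean_record)
        a = fqrs.extract_feature_vector(segs["II"]).to_array()
        b = fqrs.extract_feature_vector(segs["II"]).to_array()
        np.testing.assert_array_equal(a, b)

    def test_vector_length_and_finiteness_sweep(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.standard_normal(128)
            fv = fqrs.extract_feature_vector(x)
            arr = fv.to_array()
            assert arr.shape == (10,)
            assert np.all(np.isfinite(arr))

    def test_amplitude_scaling(self):
        """Positive scaling leaves shape features unchanged and scales the
        PRSA amplitudes linearly."""
        rng = np.random.default_rng(13)
        x = rng.standard_normal(128)
        c = 2.5
        a = fqrs.extract_feature_vector(x)
        b = fqrs.extract_feature_vector(c * x)
        assert b.peak_count == a.peak_count
        assert (b.vmd_z3, b.vmd_z4, b.vmd_z5) == (a.vmd_z3, a.vmd_z4, a.vmd_z5)
        for name in ("vmd_e3", "vmd_e4", "vmd_e5"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), abs=1e-9)
        for name in ("prsa_mean_derivative", "prsa_fit_slope", "prsa_fit_ycross"):
            assert getattr(b, name) == pytest.approx(
                c * getattr(a, name), rel=1e-9
            )

    def test_fragmented_vs_clean_peak_count(self, templates):
        """Zero-noise fragmented segment counts strictly more peaks."""
        frag = {
            ld: fqrs.FragmentationSpec.from_severity(1.0, seed=i)
            for i, ld in enumerate(fqrs.LEAD_NAMES)
        }
        rec_c = fqrs.generate_ecg12(
            templates, noise=fqrs.NoiseParams.none(), seed=4
        )
        rec_f = fqrs.generate_ecg12(
            templates, frag=frag, noise=fqrs.NoiseParams.none(), seed=4
        )
        segs_c = fqrs.segment_record(rec_c)
        segs_f = fqrs.segment_record(rec_f)
        count_c = np.mean(
            [fqrs.count_qrs_peaks(segs_c[ld]) for ld in fqrs.LEAD_NAMES]
        )
        count_f = np.mean(
            [fqrs.count_qrs_peaks(segs_f[ld]) for ld in fqrs.LEAD_NAMES]
        )
        assert count_f > count_c

    def test_statistical_separation_peaks_and_z5(self, small_training_table):
        df = small_training_table
        clean = df[df.severity == 0]
        frag = df[df.severity > 0]
        assert frag["peak_count"].mean() > clean["peak_count"].mean()
        assert frag["vmd_z5"].mean() > clean["vmd_z5"].mean()
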