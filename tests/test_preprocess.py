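import numpy as np
import pytest

import phasewarp as pw
from phasewarp.errors import ParameterError
from phasewarp.preprocess import load_config, spectral_energy_below
from phasewarp.signal_transform import GenomicSignal


def naive_median(x, window):
    """Oracle: sort-and-middle on each truncated centered window."""
    left, right = (window - 1) // 2, window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(x.size):
        chunk = np.sort(x[max(0, i - left) : min(x.size, i + right + 1)])
        mid = chunk.size // 2
        out[i] = chunk[mid] if chunk.size % 2 else 0.5 * (chunk[mid - 1] + chunk[mid])
    return out


class TestMedianFilter:
    def test_constant_signal_unchanged(self):
        sig = GenomicSignal(np.full(20, 3.7))
        np.testing.assert_array_equal(pw.median_filter(sig, 4).values, sig.values)

    def test_impulse_suppressed(self):
        sig = GenomicSignal(np.array([0.0, 0, 10, 0, 0]))
        assert pw.median_filter(sig, 4).values[2] == 0.0

    def test_window_one_is_identity(self):
        values = np.arange(10.0)
        np.testing.assert_array_equal(
            pw.median_filter(GenomicSignal(values), 1).values, values
        )

    @pytest.mark.parametrize("window", [2, 3, 4, 5, 7])
    def test_matches_naive_oracle(self, rng, window):
        x = rng.normal(size=60)
        got = pw.median_filter(GenomicSignal(x), window).values
        np.testing.assert_allclose(got, naive_median(x, window), atol=1e-12)

    def test_window_longer_than_signal_is_error(self):
        with pytest.raises(ParameterError):
            pw.median_filter(GenomicSignal(np.zeros(3)), 4)

    def test_output_length_equals_input_length(self, rng):
        x = rng.normal(size=41)
        assert pw.median_filter(GenomicSignal(x), 4).values.size == 41


def energy_below_oracle(x, cutoff):
    """Direct DFT power summation, independent of the implementation."""
    x = x - np.mean(x)
    n = x.size
    total, below = 0.0, 0.0
    for k in range(1, n // 2 + 1):
        coeff = np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n))
        p = abs(coeff) ** 2
        total += p
        if k / n < cutoff:
            below += p
    return below / total


class TestDownsampleFactorEstimation:
    def test_sinusoid_at_quarter_band_cannot_be_halved(self):
        t = np.arange(256)
        sig = GenomicSignal(np.sin(2 * np.pi * 0.25 * t))
        assert pw.estimate_downsample_factor(sig, 0.995, max_factor=10) == 1

    def test_white_noise_keeps_full_rate(self, rng):
        sig = GenomicSignal(rng.normal(size=512))
        assert pw.estimate_downsample_factor(sig, 0.995, max_factor=10) == 1

    def test_slow_drift_with_tiny_ripple_caps_at_max(self):
        # band-limited slow drift (2 cycles over the record) plus a high-
        # frequency ripple 40 dB down: the ripple cannot force full rate
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 2 * t / 1000) + 1e-2 * np.sin(2 * np.pi * 0.4 * t)
        assert pw.estimate_downsample_factor(GenomicSignal(x), 0.995, 10) == 10

    def test_constant_signal_returns_max_factor(self):
        sig = GenomicSignal(np.full(64, 2.0))
        assert pw.estimate_downsample_factor(sig, 0.995, max_factor=7) == 7

    def test_agrees_with_direct_dft_oracle(self, rng):
        x = np.cumsum(rng.normal(size=300))
        sig = GenomicSignal(x)
        factor = pw.estimate_downsample_factor(sig, 0.99, max_factor=20)
        assert factor >= 2
        assert energy_below_oracle(x, 1 / (2 * factor)) >= 0.99
        below_next = energy_below_oracle(x, 1 / (2 * (factor + 1)))
        assert below_next < 0.99 or factor == 20

    def test_retained_band_holds_energy_fraction(self, family10):
        """Chain invariant: the estimated factor's band keeps the fraction."""
        seqs, _ = family10
        raw = pw.cumulated_phase(seqs[0])
        k = pw.estimate_downsample_factor(raw, 0.995, max_factor=70)
        assert k >= 2
        assert spectral_energy_below(raw.values, 1 / (2 * k)) >= 0.995


class TestDownsample:
    def test_factor_one_is_identity(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_array_equal(
            pw.downsample(GenomicSignal(x), 1).values, x
        )

    def test_output_length_is_ceiling(self):
        sig = GenomicSignal(np.sin(np.arange(100) / 30))
        out = pw.downsample(sig, 10)
        assert len(out) == 10
        assert out.sample_step == 10
        assert pw.downsample(GenomicSignal(np.zeros(105)), 10).values.size == 11

    def test_dc_level_preserved(self):
        sig = GenomicSignal(np.full(200, 5.25))
        np.testing.assert_allclose(
            pw.downsample(sig, 10).values, 5.25, atol=1e-9
        )

    def test_factor_not_smaller_than_length_is_error(self):
        with pytest.raises(ParameterError):
            pw.downsample(GenomicSignal(np.zeros(5)), 5)


class TestNormalize01:
    def test_linear_map_endpoints(self):
        out = pw.normalize01(GenomicSignal(np.array([2.0, 4.0, 6.0])))
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros(self):
        out = pw.normalize01(GenomicSignal(np.array([5.0, 5.0, 5.0])))
        np.testing.assert_array_equal(out.values, np.zeros(3))

    def test_range_attained(self, rng):
        out = pw.normalize01(GenomicSignal(rng.normal(size=100)))
        assert out.values.min() == pytest.approx(0.0, abs=1e-12)
        assert out.values.max() == pytest.approx(1.0, abs=1e-12)


class TestDetrendPoly:
    def test_exact_quartic_leaves_zero_residual(self):
        t = np.linspace(-1, 1, 200)
        x = 3 - 2 * t + 0.5 * t**2 - t**3 + 4 * t**4
        out = pw.detrend_poly(GenomicSignal(x), 4)
        assert np.max(np.abs(out.values)) <= 1e-8 * np.max(np.abs(x))

    def test_order_zero_is_mean_centering(self, rng):
        x = rng.normal(size=30) + 7
        out = pw.detrend_poly(GenomicSignal(x), 0)
        np.testing.assert_allclose(out.values, x - x.mean(), atol=1e-10)

    def test_line_plus_sine_recovers_sine(self):
        t = np.arange(400)
        sine = np.sin(2 * np.pi * t / 40)
        out = pw.detrend_poly(GenomicSignal(5 + 0.01 * t + sine), 1)
        assert np.corrcoef(out.values, sine)[0, 1] > 0.99
        assert abs(out.values.mean()) < 1e-10

    def test_residual_orthogonal_to_polynomial_basis(self, rng):
        x = np.cumsum(rng.normal(size=300))
        out = pw.detrend_poly(GenomicSignal(x), 4)
        t = np.linspace(0, 1, 300)
        for power in range(5):
            basis = t**power
            inner = np.dot(out.values, basis)
            assert abs(inner) <= 1e-7 * np.linalg.norm(x) * np.linalg.norm(basis)

    def test_short_signal_is_error(self):
        with pytest.raises(ParameterError):
            pw.detrend_poly(GenomicSignal(np.zeros(4)), 4)


class TestPreprocessChain:
    def test_default_chain_shape_and_stage(self, family10):
        seqs, _ = family10
        raw = pw.cumulated_phase(seqs[0])
        out = pw.preprocess(raw)
        assert out.stage == "detrended"
        assert len(out) == int(np.ceil(len(raw) / 10))
        assert out.sample_step == 10
        # quartic trend removed: residual trend of the output is tiny
        refit = pw.detrend_poly(out, 4)
        assert np.allclose(refit.values, out.values, atol=1e-8)

    def test_near_identity_configuration(self, rng):
        config = pw.PreprocessConfig(
            median_window=1, downsample_factor=1, poly_order=0
        )
        x = rng.normal(size=64)
        out = pw.preprocess(GenomicSignal(x), config)
        normalized = (x - x.min()) / (x.max() - x.min())
        np.testing.assert_allclose(
            out.values, normalized - normalized.mean(), atol=1e-10
        )

    def test_constant_raw_signal_maps_to_zero(self):
        out = pw.preprocess(
            GenomicSignal(np.full(100, 2.5)),
            pw.PreprocessConfig(downsample_factor=5),
        )
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_invariant_to_offset_and_positive_scale(self, rng):
        x = np.cumsum(rng.normal(size=500))
        config = pw.PreprocessConfig()
        base = pw.preprocess(GenomicSignal(x), config).values
        shifted = pw.preprocess(GenomicSignal(3.5 * x + 11.0), config).values
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_deterministic_across_runs(self, rng):
        x = np.cumsum(rng.normal(size=500))
        a = pw.preprocess(GenomicSignal(x)).values
        b = pw.preprocess(GenomicSignal(x.copy())).values
        assert np.array_equal(a, b)

    def test_auto_factor_recorded_in_metadata(self, family10):
        seqs, _ = family10
        raw = pw.cumulated_phase(seqs[0])
        out = pw.preprocess(raw, pw.PreprocessConfig(downsample_factor="auto"))
        resolved = out.metadata["preprocess_config"].downsample_factor
        assert isinstance(resolved, int) and resolved >= 2


class TestConfigFile:
    def test_load_round_trip(self, tmp_path):
        p = tmp_path / "prep.cfg"
        p.write_text(
            "# preprocessing\nmedian_window = 6\ndownsample_factor = auto\n"
            "energy_fraction = 0.99\npoly_order = 3\n"
        )
        config = load_config(p)
        assert config == pw.PreprocessConfig(
            median_window=6,
            downsample_factor="auto",
            energy_fraction=0.99,
            poly_order=3,
        )

    def test_unknown_key_is_error(self, tmp_path):
        p = tmp_path / "prep.cfg"
        p.write_text("window = 4\n")
        with pytest.raises(ParameterError):
            load_config(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"median_window": 0},
            {"downsample_factor": 0},
            {"downsample_factor": "guess"},
            {"energy_fraction": 0.0},
            {"poly_order": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            pw.PreprocessConfig(**kwargs)
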