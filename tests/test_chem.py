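"""Chemical QC: content equation, unit conversion, spectra preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conetrace as ct
from conetrace.chem import ExtractionRound, SpectrumTrace, als_baseline


def round_with_content(i_g_per_kg, index=1):
    """ExtractionRound whose content evaluates to ``i_g_per_kg`` exactly."""
    return ExtractionRound(round_index=index, x=i_g_per_kg, a=1.0, C=1.0, f=1.0, m=0.001)


class TestContentEquation:
    def test_zero_peak_area(self):
        assert ct.content_per_round(ExtractionRound(1, x=0.0, a=2.0, m=0.1)) == 0.0

    def test_unit_factor_identity(self):
        r = ExtractionRound(1, x=3.7, a=3.7, C=1.0, f=1.0, m=0.001)
        assert ct.content_per_round(r) == pytest.approx(1.0, rel=1e-12)

    @given(
        x=st.floats(0.1, 1e5),
        a=st.floats(0.1, 1e4),
        c=st.floats(0.5, 2.0),
        f=st.floats(1.0, 100.0),
        m=st.floats(1e-3, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_single_line_oracle(self, x, a, c, f, m):
        r = ExtractionRound(1, x=x, a=a, C=c, f=f, m=m)
        assert ct.content_per_round(r) == pytest.approx(
            (x / a) * (0.001 / m) * c * f, rel=1e-12
        )

    @given(x=st.floats(1.0, 1e4), scale=st.floats(1.5, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_linearity_in_x_and_inverse_in_a(self, x, scale):
        base = ct.content_per_round(ExtractionRound(1, x=x, a=5.0, m=0.1))
        assert ct.content_per_round(
            ExtractionRound(1, x=x * scale, a=5.0, m=0.1)
        ) == pytest.approx(base * scale, rel=1e-12)
        assert ct.content_per_round(
            ExtractionRound(1, x=x, a=5.0 * scale, m=0.1)
        ) == pytest.approx(base / scale, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ExtractionRound(1, x=1.0, a=0.0, m=0.1)
        with pytest.raises(ValueError):
            ExtractionRound(1, x=1.0, a=1.0, m=0.0)
        with pytest.raises(ValueError):
            ExtractionRound(5, x=1.0, a=1.0, m=0.1)


class TestTotalContent:
    def test_efficient_first_round_not_flagged(self):
        rounds = [round_with_content(v, i + 1) for i, v in enumerate((97, 2, 1, 0))]
        res = ct.total_content(rounds)
        assert res.total_g_per_kg == pytest.approx(100.0)
        assert res.first_round_fraction == pytest.approx(0.97)
        assert not res.incomplete_first_extraction

    def test_single_round_fraction_one(self):
        res = ct.total_content([round_with_content(42.0)])
        assert res.first_round_fraction == 1.0

    def test_slow_extraction_flagged(self):
        rounds = [round_with_content(v, i + 1) for i, v in enumerate((90, 5, 3, 2))]
        assert ct.total_content(rounds).incomplete_first_extraction

    def test_round_count_bounds(self):
        with pytest.raises(ValueError):
            ct.total_content([])


class TestArealConversion:
    def test_dimensional_oracle(self):
        # 1.53 g/kg on a 0.1500-g, 50-cm2 swatch -> 45.9 mg/m2
        assert ct.convert_to_areal(1.53, 0.1500, 50.0) == pytest.approx(45.9)

    def test_zero_content(self):
        assert ct.convert_to_areal(0.0, 0.15, 50.0) == 0.0

    def test_area_proportionality(self):
        one = ct.convert_to_areal(2.0, 0.15, 50.0)
        assert ct.convert_to_areal(2.0, 0.15, 100.0) == pytest.approx(one / 2)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ct.convert_to_areal(1.0, 0.15, 0.0)


class TestRsd:
    def test_constant_values(self):
        assert ct.rsd([10, 10, 10]) == 0.0

    def test_hand_arithmetic(self):
        assert ct.rsd([8, 10, 12]) == pytest.approx(20.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            ct.rsd([-8, -10, -12])


def synthetic_spectrum(seed=0, peak_1000=0.0, peak_942=0.0, peak_479=0.0):
    """Gaussian peaks + slow quadratic baseline + noise, 300-1800 1/cm."""
    rng = np.random.default_rng(seed)
    wn = np.arange(300.0, 1800.0, 1.0)
    baseline = 50.0 + 0.02 * (wn - 300) + 2e-5 * (wn - 1000) ** 2
    y = baseline.copy()
    for center, height in ((700, 30.0), (1300, 40.0), (1615, 25.0)):
        y += height * np.exp(-0.5 * ((wn - center) / 8.0) ** 2)
    for center, height in ((1000, peak_1000), (942, peak_942), (479, peak_479)):
        y += height * np.exp(-0.5 * ((wn - center) / 3.0) ** 2)
    y += rng.normal(0, 0.5, size=wn.shape)
    return SpectrumTrace(wavenumber=wn, intensity=y), baseline


class TestPreprocess:
    def test_linear_input_preserved_by_smoothing(self):
        wn = np.arange(400.0, 900.0, 1.0)
        y = 3.0 * wn + 17.0
        out = ct.preprocess_spectrum(
            SpectrumTrace(wavenumber=wn, intensity=y), baseline=False
        )
        # first-order smoothing reproduces any straight line exactly
        assert np.allclose(out.intensity, y / np.linalg.norm(y), atol=1e-12)

    def test_output_unit_norm_and_flags(self):
        s, _ = synthetic_spectrum(1)
        out = ct.preprocess_spectrum(s)
        assert np.linalg.norm(out.intensity) == pytest.approx(1.0, abs=1e-9)
        assert out.smoothed and out.baseline_corrected and out.normalized

    def test_normalization_idempotent(self):
        # linear input: the smoothing step is exact, so a second pass
        # through the chain must reproduce the already-normalized trace
        wn = np.arange(400.0, 900.0, 1.0)
        s = SpectrumTrace(wavenumber=wn, intensity=0.7 * wn + 5.0)
        once = ct.preprocess_spectrum(s, baseline=False)
        twice = ct.preprocess_spectrum(once, baseline=False)
        assert np.allclose(once.intensity, twice.intensity, atol=1e-12)
        assert np.linalg.norm(twice.intensity) == pytest.approx(1.0, abs=1e-12)

    def test_als_baseline_recovers_true_baseline(self):
        s, true_base = synthetic_spectrum(3)
        est = als_baseline(s.intensity)
        wn = s.wavenumber
        away = np.ones(len(wn), bool)
        for center in (700, 1300, 1615):
            away &= np.abs(wn - center) > 40
        rms_err = np.sqrt(np.mean((est[away] - true_base[away]) ** 2))
        rms_base = np.sqrt(np.mean(true_base[away] ** 2))
        assert rms_err / rms_base < 0.05

    def test_als_baseline_below_max_signal(self):
        s, _ = synthetic_spectrum(4)
        est = als_baseline(s.intensity)
        assert (est <= s.intensity.max()).all()

    def test_even_window_rejected(self):
        s, _ = synthetic_spectrum(5)
        with pytest.raises(ValueError, match="odd"):
            ct.preprocess_spectrum(s, sg_window=4)
        with pytest.raises(ValueError, match="order"):
            ct.preprocess_spectrum(s, sg_window=5, sg_order=5)

    def test_monotonicity_validation(self):
        with pytest.raises(ValueError, match="monotone"):
            SpectrumTrace(wavenumber=np.array([1.0, 3.0, 2.0]), intensity=np.zeros(3))


class TestCrystallineMarker:
    def test_flat_spectrum_amorphous_score_zero(self):
        wn = np.arange(300.0, 1800.0, 1.0)
        s = SpectrumTrace(wavenumber=wn, intensity=np.zeros(len(wn)))
        call = ct.crystalline_marker(s)
        assert call.classification == "amorphous-like"
        assert call.score == 0.0

    def test_injected_marker_peak_called_crystalline(self):
        s, _ = synthetic_spectrum(6, peak_1000=25.0)
        call = ct.crystalline_marker(ct.preprocess_spectrum(s))
        assert call.classification == "crystalline-like"
        assert call.score >= 5.0

    def test_secondary_bands_alone_stay_amorphous(self):
        s, _ = synthetic_spectrum(7, peak_1000=0.0, peak_942=20.0, peak_479=20.0)
        call = ct.crystalline_marker(ct.preprocess_spectrum(s))
        assert call.classification == "amorphous-like"
        assert call.secondary_scores["942"] >= 5.0
        assert call.secondary_scores["479"] >= 5.0

    def test_axis_not_covering_marker_rejected(self):
        wn = np.arange(1200.0, 1800.0, 1.0)
        s = SpectrumTrace(wavenumber=wn, intensity=np.ones(len(wn)))
        with pytest.raises(ValueError, match="cover"):
            ct.crystalline_marker(s)


def test_spectrum_text_roundtrip(tmp_path):
    s, _ = synthetic_spectrum(8)
    path = tmp_path / "spec.txt"
    s.write_text(path)
    back = SpectrumTrace.read_text(path)
    assert np.allclose(back.wavenumber, s.wavenumber)
    assert np.allclose(back.intensity, s.intensity, atol=1e-5)
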