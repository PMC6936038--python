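"""Lineage forecasting: CLT density, band probabilities, Z_L normalization
and band calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from homeostat.forecast import (LineageBand, MediaModel, calibrate_bands,
                                fbar_density, forecast_from_moments,
                                lineage_probability, normalize)


class TestFbarDensity:
    def test_nc_one_recovers_ensemble_sigma(self):
        pdf = fbar_density(1.0, 0.5, 1)
        assert pdf(1.0) == pytest.approx(norm.pdf(1.0, 1.0, 0.5))

    def test_variance_shrinks_by_nc(self):
        mu, sigma, Nc = 2.0, 0.6, 15
        pdf = fbar_density(mu, sigma, Nc)
        # the density at the mean pins the standard deviation
        assert pdf(mu) == pytest.approx(1.0 / (sigma / np.sqrt(Nc) * np.sqrt(2 * np.pi)))

    def test_normalization(self):
        pdf = fbar_density(0.3, 0.8, 7)
        total, _ = quad(pdf, -np.inf, np.inf)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            fbar_density(0.0, 0.0, 5)


class TestLineageProbability:
    def test_zero_width_band_has_zero_probability(self):
        band = LineageBand("x", 1.0, 0.0)
        assert lineage_probability(1.0, 0.5, 10, band) == 0.0

    def test_full_support_band(self):
        band = LineageBand("x", 2.0, 1e6)
        assert lineage_probability(2.0, 0.5, 10, band) == pytest.approx(1.0)

    def test_quadrature_oracle_example(self):
        # mu = 2.0, sigma = 0.6, Nc = 15, band 1.87 +/- 0.05
        band = LineageBand("myoblast", 1.87, 0.05)
        px = lineage_probability(2.0, 0.6, 15, band)
        pdf = fbar_density(2.0, 0.6, 15)
        oracle, _ = quad(pdf, band.center - band.half_width,
                         band.center + band.half_width, epsabs=1e-13)
        assert px == pytest.approx(oracle, abs=1e-10)
        assert px == pytest.approx(0.180, abs=1e-3)

    def test_closed_form_equals_quadrature_over_random_tuples(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            mu = rng.uniform(-2, 4)
            sigma = rng.uniform(0.05, 2.0)
            Nc = int(rng.integers(1, 40))
            band = LineageBand("x", rng.uniform(-2, 4), rng.uniform(0, 2))
            px = lineage_probability(mu, sigma, Nc, band)
            pdf = fbar_density(mu, sigma, Nc)
            oracle, _ = quad(pdf, band.center - band.half_width,
                             band.center + band.half_width, epsabs=1e-13)
            assert abs(px - oracle) < 1e-10

    @given(st.floats(-3, 3), st.floats(0.05, 2), st.integers(1, 30),
           st.floats(-3, 3), st.floats(0, 1), st.floats(0.01, 1))
    def test_monotone_in_band_width(self, mu, sigma, Nc, center, hw, extra):
        p1 = lineage_probability(mu, sigma, Nc, LineageBand("x", center, hw))
        p2 = lineage_probability(mu, sigma, Nc, LineageBand("x", center, hw + extra))
        assert p2 >= p1

    @given(st.floats(-3, 3), st.floats(0.05, 2), st.integers(1, 30),
           st.floats(0.01, 1), st.floats(-2, 2).filter(lambda d: d != 0))
    def test_unimodal_in_mu_with_peak_at_band_center(self, center, sigma, Nc,
                                                     hw, shift):
        band = LineageBand("x", center, hw)
        at_peak = lineage_probability(center, sigma, Nc, band)
        off_peak = lineage_probability(center + shift, sigma, Nc, band)
        assert at_peak >= off_peak


class TestNormalize:
    def test_below_unit_total(self):
        probs, undiff, Z = normalize({"a": 0.5, "b": 0.3})
        assert probs == {"a": 0.5, "b": 0.3}
        assert undiff == pytest.approx(0.2) and Z == 1.0

    def test_above_unit_total(self):
        probs, undiff, Z = normalize({"a": 0.9, "b": 0.6})
        assert Z == pytest.approx(1.5)
        assert probs["a"] == pytest.approx(0.6)
        assert probs["b"] == pytest.approx(0.4)
        assert undiff == pytest.approx(0.0)

    def test_no_differentiation(self):
        _, undiff, _ = normalize({"a": 0.0, "b": 0.0})
        assert undiff == 1.0

    def test_invalid_raw_raises(self):
        with pytest.raises(ValueError):
            normalize({"a": 1.2})

    @given(st.dictionaries(st.sampled_from(["a", "b", "c"]),
                           st.floats(0, 1), min_size=1))
    def test_total_probability_is_one(self, raw):
        probs, undiff, _ = normalize(raw)
        assert sum(probs.values()) + undiff == pytest.approx(1.0, abs=1e-12)
        assert undiff >= 0.0
        assert all(0.0 <= v <= 1.0 for v in probs.values())


class TestCalibration:
    def test_noiseless_parameter_recovery(self):
        true = {"osteoblast": LineageBand("osteoblast", 1.8, 0.25),
                "myoblast": LineageBand("myoblast", 2.6, 0.10)}
        Nc = 15
        moments = {c: (mu, sig) for c, (mu, sig) in enumerate(
            [(2.9, 0.15), (2.6, 0.3), (2.2, 0.5), (1.8, 0.6), (1.4, 0.8)])}
        observed = {
            c: {lin: lineage_probability(mu, sig, Nc, band)
                for lin, band in true.items()}
            for c, (mu, sig) in moments.items()}
        cal = calibrate_bands(moments, observed, Nc=Nc)
        for band in cal.media_model.bands:
            assert band.center == pytest.approx(true[band.lineage].center, abs=1e-3)
            assert band.half_width == pytest.approx(true[band.lineage].half_width, abs=1e-3)
            assert cal.residuals[band.lineage] < 1e-6

    def test_single_lineage_band_brackets_dominant_condition(self):
        eps = 0.02
        moments = {"c1": (2.0, 0.4), "c2": (3.0, 0.4)}
        observed = {"c1": {"x": 1 - eps}, "c2": {"x": eps}}
        cal = calibrate_bands(moments, observed, Nc=10)
        band = cal.media_model.bands[0]
        assert band.center - band.half_width <= 2.0 <= band.center + band.half_width

    def test_too_few_conditions_raises(self):
        with pytest.raises(ValueError):
            calibrate_bands({"c1": (2.0, 0.4)}, {"c1": {"x": 0.5}}, Nc=10)


def test_forecast_from_moments_consistency():
    media = MediaModel("growth", (LineageBand("osteoblast", 1.8, 0.3),
                                  LineageBand("myoblast", 2.6, 0.1)), Nc=15)
    fc = forecast_from_moments(1.85, 0.5, media)
    assert fc.Z_L >= 1.0
    assert sum(fc.probabilities.values()) + fc.undifferentiated == pytest.approx(1.0)
    # mu sits in the osteoblast band, far from the myoblast band
    assert fc.probabilities["osteoblast"] > fc.probabilities["myoblast"]


def test_calibrated_band_ordering_on_stiffness_sweep(stiffness_ensembles):
    """On this package's energy scale stiffer substrates lower F̂cyto, so the
    osteoblast band (peaking at 30 kPa) must sit below the myoblast band
    (peaking at 10 kPa)."""
    from homeostat.experiments import GROWTH_CALIBRATION_FRACTIONS
    mom = {E: (float(e.samples["F_cyto"].mean()),
               float(e.samples["F_cyto"].std(ddof=1)))
           for E, e in stiffness_ensembles.items()}
    cal = calibrate_bands(mom, GROWTH_CALIBRATION_FRACTIONS, Nc=15)
    centers = {b.lineage: b.center for b in cal.media_model.bands}
    assert centers["osteoblast"] < centers["myoblast"]
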