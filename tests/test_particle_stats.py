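import numpy as np
import pytest

from holopipe.optics import BeamBoundary
from holopipe.particle_stats import (
    SizeSpectrum,
    beam_volume,
    esd_from_area,
    loglog_origin_fit,
    make_size_bins,
    mean_difference,
    model_ii_regression,
    overall_concentration,
    size_spectrum,
    spectral_slope,
)


class _Item:
    def __init__(self, esd, mult=1):
        self.esd_raw = esd
        self.esd_corrected = esd
        self.multiplicity = mult


class TestEsd:
    def test_unit_and_self_consistency(self):
        assert esd_from_area(np.pi) == pytest.approx(2.0)
        assert esd_from_area(625.0 * np.pi) == pytest.approx(50.0)

    def test_matches_pixel_count_oracle(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.6
        pitch_obj = 1.2  # um per object-plane pixel
        area = mask.sum() * pitch_obj**2
        assert esd_from_area(area) == pytest.approx(
            2.0 * np.sqrt(mask.sum() * pitch_obj**2 / np.pi)
        )

    def test_domain(self):
        with pytest.raises(ValueError):
            esd_from_area(0.0)


class TestBins:
    def test_linear_defaults_first_bin(self):
        edges = make_size_bins("linear")
        assert edges[0] == pytest.approx(2.0)
        assert edges[1] == pytest.approx(5.0)
        assert np.allclose(np.diff(edges), 3.0)
        assert edges[-1] >= 120.0

    def test_log_bins_geometric(self):
        edges = make_size_bins("log", n_log_bins=12)
        assert edges[0] == pytest.approx(10.0)
        assert edges[-1] == pytest.approx(120.0)
        ratios = edges[1:] / edges[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_partition_no_gaps_or_overlaps(self):
        for mode in ("linear", "log"):
            edges = make_size_bins(mode)
            assert np.all(np.diff(edges) > 0)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            make_size_bins("weird")


class TestSizeSpectrum:
    def test_unit_calculation(self):
        spec = size_spectrum([_Item(3.5)], volume=1.0,
                             bins=np.array([2.0, 5.0]), mode="linear")
        assert spec.ssc[0] == pytest.approx(1.0 / 3.0)

    def test_linearity_in_multiplicity(self):
        items = [_Item(d) for d in (3.0, 4.0, 7.0, 11.0)]
        doubled = [_Item(i.esd_raw, 2) for i in items]
        edges = make_size_bins("linear")
        a = size_spectrum(items, 1.0, edges)
        b = size_spectrum(doubled, 1.0, edges)
        assert np.allclose(b.ssc, 2 * a.ssc)

    def test_conservation_identity(self):
        """Sum of ssc * width * volume returns the weighted count exactly."""
        rng = np.random.default_rng(1)
        items = [_Item(rng.uniform(10.5, 119.5), int(rng.integers(1, 8)))
                 for _ in range(500)]
        edges = make_size_bins("log")
        volume = 0.63
        spec = size_spectrum(items, volume, edges, mode="log")
        weighted = sum(i.multiplicity for i in items)
        assert np.sum(spec.ssc * np.diff(edges) * volume) == pytest.approx(weighted)

    def test_out_of_range_detections_not_counted(self):
        spec = size_spectrum([_Item(500.0), _Item(15.0)], 1.0,
                             make_size_bins("log"), mode="log")
        total = np.sum(spec.ssc * np.diff(spec.bin_edges))
        assert total == pytest.approx(1.0)

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            SizeSpectrum(bin_edges=np.array([2.0, 1.0]),
                         bin_centers=np.array([1.5]),
                         ssc=np.array([0.1]), total_volume=1.0, mode="linear")


class TestSpectralSlope:
    def test_exact_power_law_recovered_to_numerical_precision(self):
        edges = make_size_bins("log")
        centers = np.sqrt(edges[:-1] * edges[1:])
        spec = SizeSpectrum(bin_edges=edges, bin_centers=centers,
                            ssc=centers**-4.0, total_volume=1.0, mode="log")
        fit = spectral_slope(spec)
        assert fit.slope == pytest.approx(-4.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        edges = make_size_bins("log")
        centers = np.sqrt(edges[:-1] * edges[1:])
        a = spectral_slope(SizeSpectrum(edges, centers, centers**-3.5, 1.0, "log"))
        b = spectral_slope(SizeSpectrum(edges, centers, 7.0 * centers**-3.5,
                                        1.0, "log"))
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_sampled_junge_population_is_loglog_linear(self):
        from holopipe import sample_junge_diameters

        d = sample_junge_diameters(100_000, -4.0, 10.0, 120.0, seed=5)
        spec = size_spectrum([_Item(x) for x in d], 1.0,
                             make_size_bins("log"), mode="log")
        fit = spectral_slope(spec)
        assert fit.r_squared > 0.99
        assert fit.slope == pytest.approx(-4.0, abs=0.1)

    def test_too_few_bins_rejected(self):
        edges = np.array([10.0, 20.0, 40.0])
        spec = SizeSpectrum(edges, np.sqrt(edges[:-1] * edges[1:]),
                            np.array([1.0, 0.0]), 1.0, "log")
        with pytest.raises(ValueError):
            spectral_slope(spec)


class TestConcentration:
    def test_arithmetic(self):
        items = [_Item(20.0) for _ in range(63)]
        est = overall_concentration(items, 1000, 0.063)
        assert est.concentration == pytest.approx(1.0)
        assert est.weighted_count == 63
        assert est.volume == pytest.approx(63.0)

    def test_zero_detections(self):
        est = overall_concentration([], 10, 0.063)
        assert est.concentration == 0.0

    def test_multiplicities_weighted(self):
        items = [_Item(20.0, 3), _Item(30.0, 5)]
        assert overall_concentration(items, 1, 1.0).weighted_count == 8


class TestBeamVolume:
    def test_cone_limit(self):
        b = BeamBoundary(r1=1000.0, r2=0.0, z_min=1000.0, z_max=19_000.0,
                         working_volume_override=None)
        h = 18_000.0
        assert beam_volume(b) == pytest.approx(np.pi * h * 1000.0**2 / 3 / 1e12)

    def test_cylinder_limit(self):
        b = BeamBoundary(r1=800.0, r2=800.0, z_min=1000.0, z_max=19_000.0,
                         working_volume_override=None)
        h = 18_000.0
        assert beam_volume(b) == pytest.approx(np.pi * h * 800.0**2 / 1e12)

    def test_override_takes_precedence(self, boundary):
        assert beam_volume(boundary) == pytest.approx(0.063)


class TestModelII:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = model_ii_regression(x, 2.0 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_axis_swap_reciprocity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10.0, 2.0, 200)
        y = 3.0 * x + rng.normal(0.0, 1.5, 200)
        f_xy = model_ii_regression(x, y)
        f_yx = model_ii_regression(y, x)
        assert f_xy.slope == pytest.approx(1.0 / f_yx.slope, rel=1e-12)

    def test_slope_is_sd_ratio_on_bivariate_normal(self):
        rng = np.random.default_rng(3)
        slopes = []
        for _ in range(300):
            x = rng.normal(0.0, 2.0, 50)
            y = 0.8 * x + rng.normal(0.0, 1.0, 50)
            slopes.append(model_ii_regression(x, y).slope)
        sd_y = np.sqrt(0.8**2 * 4.0 + 1.0)
        expected = sd_y / 2.0
        se = np.std(slopes) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - expected) < 3.5 * se

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            model_ii_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            model_ii_regression([1.0, 2.0], [1.0, 2.0])


class TestThroughOriginFit:
    def test_identity_and_decade(self):
        x = np.array([1.0, 5.0, 20.0, 300.0])
        assert loglog_origin_fit(x, x).slope == pytest.approx(0.0, abs=1e-12)
        assert loglog_origin_fit(x, 10.0 * x).slope == pytest.approx(1.0)

    def test_offset_recovered_under_lognormal_noise(self):
        rng = np.random.default_rng(4)
        m_values = []
        for _ in range(200):
            x = 10 ** rng.uniform(0.0, 3.0, 40)
            y = x * 10**0.14 * rng.lognormal(0.0, 0.3, 40)
            m_values.append(loglog_origin_fit(x, y).slope)
        se = np.std(m_values) / np.sqrt(len(m_values))
        assert abs(np.mean(m_values) - 0.14) < 3.5 * se

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            loglog_origin_fit([1.0, -2.0], [1.0, 2.0])


class TestMeanDifference:
    def test_identical_series(self):
        mean, sd = mean_difference([5.0, 7.0], [5.0, 7.0])
        assert mean == 0.0 and sd == 0.0

    def test_hand_computed_example(self):
        mean, sd = mean_difference([10.0, 10.0], [11.0, 9.0])
        assert mean == pytest.approx(0.0)
        assert sd == pytest.approx(100.0 * np.sqrt(2) / 10.0, rel=1e-9)  # 14.14

    def test_not_antisymmetric(self):
        a = np.array([10.0, 20.0, 30.0])
        b = np.array([12.0, 15.0, 33.0])
        m_ab, _ = mean_difference(a, b)
        m_ba, _ = mean_difference(b, a)
        assert abs(m_ab) != pytest.approx(abs(m_ba), rel=1e-6)

    def test_zero_reference_excluded(self):
        mean, _ = mean_difference([0.0, 10.0], [5.0, 5.0])
        assert mean == pytest.approx(50.0)
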