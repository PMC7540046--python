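import logging

import numpy as np
import pytest

from holopipe.corrections import (
    DetectionProbabilityModel,
    FitError,
    SizeCalibration,
    apply_concentration_correction,
    apply_size_correction,
    fit_detection_model,
    fit_size_calibration,
    multiplicity_from_coefficient,
    scaling_coefficient,
)
from holopipe.detection import Detection

REFERENCE_CAL = SizeCalibration(a=0.121, b=0.76)
REFERENCE_MODEL = DetectionProbabilityModel(z_o=8000.0, g_r=466.0, g_z=6400.0)


def _det(x, y, z):
    return Detection(mask=np.ones((2, 2), bool), mask_origin=(0, 0),
                     area=100.0, esd_raw=11.3, position=(x, y, z),
                     sharpness=0.2)


class TestSizeCorrection:
    def test_identity_point(self):
        # a * d^b = 1  <=>  d = (1/a)^(1/b)
        d_unit = (1.0 / REFERENCE_CAL.a) ** (1.0 / REFERENCE_CAL.b)
        assert apply_size_correction(0.37, d_unit, REFERENCE_CAL) == pytest.approx(0.37)

    def test_printed_coefficients_scalar_value(self):
        # 1 mm sphere at 16.25 mm: 0.121 * 16.25**0.76 = 1.0072
        assert apply_size_correction(1.0, 16.25, REFERENCE_CAL) == pytest.approx(
            1.007, abs=5e-4
        )

    def test_monotone_in_both_arguments(self):
        s = apply_size_correction(np.array([1.0, 1.5, 2.0]), 10.0, REFERENCE_CAL)
        assert np.all(np.diff(s) > 0)
        s = apply_size_correction(1.0, np.array([5.0, 10.0, 18.0]), REFERENCE_CAL)
        assert np.all(np.diff(s) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            apply_size_correction(-1.0, 10.0, REFERENCE_CAL)
        with pytest.raises(ValueError):
            apply_size_correction(1.0, 0.0, REFERENCE_CAL)


class TestSizeCalibrationFit:
    def _records(self, a, b, n=30, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        d_m = np.linspace(1.0, 19.0, n)
        s_true = 0.050  # 50 um sphere in mm
        s_m = s_true / (a * d_m**b)
        if noise_sd:
            s_m = s_m * rng.lognormal(0.0, noise_sd, size=n)
        return list(zip([s_true] * n, s_m, d_m))

    def test_noiseless_inversion_recovers_coefficients_exactly(self):
        cal = fit_size_calibration(self._records(0.121, 0.76))
        assert cal.a == pytest.approx(0.121, abs=1e-6)
        assert cal.b == pytest.approx(0.76, abs=1e-6)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_five_percent_noise_recovers_exponent(self):
        errors = [
            fit_size_calibration(self._records(0.121, 0.76, noise_sd=0.05,
                                               seed=s)).b - 0.76
            for s in range(10)
        ]
        assert np.all(np.abs(errors) < 0.05)

    def test_linear_law_recovered(self):
        cal = fit_size_calibration(self._records(0.05, 1.0))
        assert cal.b == pytest.approx(1.0, abs=1e-6)

    def test_single_distance_is_rank_deficient(self):
        records = [(0.05, 0.04, 10.0)] * 5
        with pytest.raises(FitError):
            fit_size_calibration(records)
        with pytest.raises(FitError):
            fit_size_calibration(records[:2])


class TestScalingCoefficient:
    def test_peak_is_one(self):
        assert scaling_coefficient((0.0, 0.0, 8000.0), REFERENCE_MODEL) == 1.0

    def test_one_sigma_radial_point(self):
        c = scaling_coefficient((466.0, 0.0, 8000.0), REFERENCE_MODEL)
        assert c == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_radial_symmetry(self):
        a = scaling_coefficient((466.0, 0.0, 8000.0), REFERENCE_MODEL)
        b = scaling_coefficient((3 * 466.0 / 5, 4 * 466.0 / 5, 8000.0), REFERENCE_MODEL)
        assert a == pytest.approx(b, rel=1e-12)

    def test_strictly_decreasing_off_peak(self):
        rs = np.array([0.0, 100.0, 300.0, 700.0])
        cs = scaling_coefficient(
            np.column_stack([rs, np.zeros(4), np.full(4, 8000.0)]), REFERENCE_MODEL
        )
        assert np.all(np.diff(cs) < 0)
        zs = np.array([8000.0, 9000.0, 12_000.0])
        cz = scaling_coefficient(
            np.column_stack([np.zeros(3), np.zeros(3), zs]), REFERENCE_MODEL
        )
        assert np.all(np.diff(cz) < 0)


class TestDetectionModelFit:
    def _separable_sample(self, n, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, REFERENCE_MODEL.g_r, n)
        y = rng.normal(0.0, REFERENCE_MODEL.g_r, n)
        z = rng.normal(REFERENCE_MODEL.z_o, REFERENCE_MODEL.g_z, n)
        return np.column_stack([x, y, z])

    def test_recovers_parameters_from_separable_sample(self):
        pos = self._separable_sample(200_000, seed=1)
        model = fit_detection_model(pos)
        assert model.g_r == pytest.approx(REFERENCE_MODEL.g_r, rel=0.02)
        assert model.z_o == pytest.approx(REFERENCE_MODEL.z_o, rel=0.02)
        assert model.g_z == pytest.approx(REFERENCE_MODEL.g_z, rel=0.02)

    def test_isotropy_swapping_x_and_y(self):
        pos = self._separable_sample(50_000, seed=2)
        m1 = fit_detection_model(pos)
        m2 = fit_detection_model(pos[:, [1, 0, 2]])
        assert m1.g_r == pytest.approx(m2.g_r, rel=1e-6)

    def test_uniform_positions_warn_and_exceed_beam_radius(self, boundary, caplog):
        from holopipe import sample_beam_positions

        pos = sample_beam_positions(50_000, boundary, seed=3)
        with caplog.at_level(logging.WARNING, logger="holopipe.corrections"):
            model = fit_detection_model(pos, boundary=boundary)
        assert model.g_r > boundary.r1 or model.g_z > (
            boundary.z_max - boundary.z_min
        )
        assert any("structure" in r.message for r in caplog.records)

    def test_too_few_positions_rejected(self):
        with pytest.raises(FitError, match="1000"):
            fit_detection_model(self._separable_sample(500))

    def test_marginal_diagnostics_isotropic(self):
        pos = self._separable_sample(50_000, seed=4)
        _, diag = fit_detection_model(pos, return_diagnostics=True)
        assert diag["sigma_x"] == pytest.approx(diag["sigma_y"], rel=0.05)


class TestMultiplicity:
    @pytest.mark.parametrize(
        "c,expected",
        [
            (1.0, 1),        # beam centre: zero replicas
            (1.0 / 3.2, 3),  # threefold under-detection -> three copies
            (0.05, 8),       # periphery: clamped at seven replicas
            (0.5, 2),
            (0.9, 1),
        ],
    )
    def test_mapping(self, c, expected):
        assert multiplicity_from_coefficient(c) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            multiplicity_from_coefficient(0.0)
        with pytest.raises(ValueError):
            multiplicity_from_coefficient(-0.3)

    def test_vectorized(self):
        out = multiplicity_from_coefficient(np.array([1.0, 0.4, 0.05]))
        assert out.tolist() == [1, 2, 8]


class TestConcentrationCorrection:
    def test_beam_centre_detections_unchanged(self):
        dets = [_det(0.0, 0.0, 8000.0) for _ in range(5)]
        out = apply_concentration_correction(dets, REFERENCE_MODEL)
        assert all(d.multiplicity == 1 for d in out)
        assert [d.position for d in out] == [d.position for d in dets]

    def test_added_replica_reading(self):
        dets = [_det(0.0, 0.0, 8000.0), _det(600.0, 0.0, 8000.0)]
        total = apply_concentration_correction(dets, REFERENCE_MODEL)
        added = apply_concentration_correction(dets, REFERENCE_MODEL,
                                               added_replicas=True)
        assert [d.multiplicity for d in added] == [
            min(d.multiplicity + 1, 8) for d in total
        ]

    def test_psd_shape_preserved_under_size_independent_thinning(self, boundary):
        """Thinning is independent of size, so the weighted spectral slope of
        corrected detections matches the generating slope within 0.15."""
        from holopipe import (
            make_size_bins,
            sample_beam_positions,
            sample_junge_diameters,
            size_spectrum,
            spectral_slope,
            thin_by_detection_probability,
        )

        n = 120_000
        pos = sample_beam_positions(n, boundary, seed=10)
        kept_mask = np.zeros(n, dtype=bool)
        kept = thin_by_detection_probability(pos, REFERENCE_MODEL, seed=11)
        # identify kept rows by re-deriving the acceptance draw
        rng = np.random.default_rng(11)
        c = scaling_coefficient(pos, REFERENCE_MODEL)
        kept_mask = rng.random(n) < c
        assert len(kept) == kept_mask.sum()

        diam = sample_junge_diameters(n, -4.0, 10.0, 120.0, seed=12)
        dets = [
            Detection(mask=np.ones((1, 1), bool), mask_origin=(0, 0),
                      area=np.pi * (d / 2) ** 2, esd_raw=d,
                      esd_corrected=d, position=tuple(p), sharpness=1.0)
            for d, p in zip(diam[kept_mask], pos[kept_mask])
        ]
        corrected = apply_concentration_correction(dets, REFERENCE_MODEL)
        edges = make_size_bins(mode="log")
        spec = size_spectrum(corrected, volume=1.0, bins=edges, mode="log")
        slope = spectral_slope(spec).slope
        assert slope == pytest.approx(-4.0, abs=0.15)
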