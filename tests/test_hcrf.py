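"""Reflectance-factor mathematics: c_diff, HCRF, ANIF, ANIX, drift, NDVI."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from goniohcrf import (
    HemisphereDataset,
    IrradianceSeries,
    anif,
    anix,
    brf_panel,
    c_diff,
    drift_indicator,
    hcrf,
    process_session,
    vi_angular,
)
from goniohcrf.geometry import MeasurementScheme, SolarGeometry, ViewGeometry
from goniohcrf.synthetic import default_wavelength_grid

T0 = datetime(2012, 7, 9, 13, 48, tzinfo=timezone(timedelta(hours=-8)))


def _series(drift_fn, n=60, cadence_s=17.0, wl=None):
    wl = default_wavelength_grid() if wl is None else wl
    e0 = np.full(wl.size, 1.2)
    times = tuple(T0 + timedelta(seconds=cadence_s * i) for i in range(n))
    values = np.vstack([e0 * drift_fn(cadence_s * i / 60.0) for i in range(n)])
    return IrradianceSeries(times, wl, values)


class TestCdiff:
    def test_constant_irradiance_unit_weight(self):
        irr = _series(lambda m: 1.0)
        np.testing.assert_allclose(c_diff(irr, T0, T0 + timedelta(minutes=5)), 1.0)

    def test_doubled_irradiance_weight_two(self):
        irr = _series(lambda m: 2.0 if m >= 5 else 1.0)
        np.testing.assert_allclose(c_diff(irr, T0, T0 + timedelta(minutes=8)), 2.0)

    def test_linear_drift_matches_closed_form(self):
        irr = _series(lambda m: 1.0 + 0.004 * m)
        for minutes in (1.7, 5.1, 14.45):
            tx = T0 + timedelta(minutes=minutes)
            got = c_diff(irr, T0, tx)
            # nearest recorded sample defines the closed form
            k = round(minutes * 60.0 / 17.0)
            expected = 1.0 + 0.004 * (17.0 * k / 60.0)
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_out_of_span_rejected(self):
        irr = _series(lambda m: 1.0, n=10)
        with pytest.raises(ValueError, match="span"):
            c_diff(irr, T0, T0 + timedelta(hours=2))

    def test_zero_reference_irradiance_rejected(self):
        irr = _series(lambda m: 0.0 if m == 0 else 1.0)
        with pytest.raises(ValueError, match="positive"):
            c_diff(irr, T0, T0 + timedelta(minutes=1))

    def test_interpolation_between_samples(self):
        irr = _series(lambda m: 1.0 + 0.01 * m, cadence_s=60.0, n=30)
        tx = T0 + timedelta(seconds=90)  # midway, beyond 5 s snap tolerance
        np.testing.assert_allclose(c_diff(irr, T0, tx), 1.015, rtol=1e-12)


class TestHcrfAlgebra:
    wl = default_wavelength_grid()

    def test_identity_surface(self):
        rng = np.random.default_rng(0)
        lref = rng.uniform(0.1, 0.5, self.wl.size)
        cdiff = rng.uniform(0.9, 1.1, self.wl.size)
        cref = rng.uniform(0.98, 1.02, self.wl.size)
        lr = lref * cdiff * cref
        np.testing.assert_allclose(hcrf(lr, lref, cdiff, cref), 1.0, rtol=1e-12)

    def test_half_panel_radiance(self):
        lref = np.full(self.wl.size, 0.4)
        np.testing.assert_allclose(hcrf(0.5 * lref, lref), 0.5)

    def test_values_above_one_not_clipped(self):
        assert hcrf(np.array([2.0]), np.array([1.0]))[0] == 2.0

    def test_joint_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        lr = rng.uniform(0.1, 0.6, 50)
        lref = rng.uniform(0.3, 0.5, 50)
        np.testing.assert_allclose(hcrf(lr, lref), hcrf(17.3 * lr, 17.3 * lref),
                                   rtol=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            hcrf(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_grid_mismatch_rejected(self):
        from goniohcrf import Spectrum
        a = Spectrum(self.wl, np.ones(self.wl.size), "target_radiance", T0)
        b = Spectrum(self.wl[:-1], np.ones(self.wl.size - 1), "panel_radiance", T0)
        with pytest.raises(ValueError, match="grid"):
            hcrf(a, b)


class TestBrfPanel:
    def test_unit_panel(self):
        lref = np.full(10, 0.3)
        np.testing.assert_allclose(brf_panel(lref, lref, 1.0), 1.0)

    def test_correction_coefficient_algebra(self):
        lref = np.full(10, 0.3)
        np.testing.assert_allclose(brf_panel(lref, lref, 0.99), 1.0 / 0.99)

    def test_consistent_with_hcrf(self):
        rng = np.random.default_rng(5)
        lr = rng.uniform(0.1, 0.6, 30)
        lref = rng.uniform(0.3, 0.5, 30)
        rref = rng.uniform(0.95, 1.05, 30)
        np.testing.assert_array_equal(brf_panel(lr, lref, rref),
                                      hcrf(lr, lref, 1.0, rref))


def _mini_hemisphere(values_by_position, wavelengths=None):
    """HemisphereDataset from {(zenith, azimuth): per-λ values}."""
    wl = np.array([500.0, 700.0, 900.0]) if wavelengths is None else wavelengths
    positions = [ViewGeometry(z, a) for z, a in values_by_position]
    zeniths = sorted({p.view_zenith for p in positions})
    rings = tuple((z, tuple(p.view_azimuth for p in positions if p.view_zenith == z))
                  for z in zeniths)
    hcrf_arr = np.vstack([np.broadcast_to(np.asarray(v, float), wl.shape)
                          for v in values_by_position.values()])
    times = [T0 + timedelta(seconds=10 * i) for i in range(len(positions))]
    return HemisphereDataset(MeasurementScheme(rings), SolarGeometry(47.0, 180.0),
                             wl, positions, times, hcrf_arr)


class TestAnif:
    def test_nadir_row_is_one(self):
        hem = _mini_hemisphere({(0.0, 0.0): 0.25, (20.0, 0.0): 0.30, (20.0, 180.0): 0.20})
        out = anif(hem)
        np.testing.assert_array_equal(out[0], 1.0)
        np.testing.assert_allclose(out[1], 1.2)
        np.testing.assert_allclose(out[2], 0.8)

    def test_missing_nadir_is_structural_error(self):
        hem = _mini_hemisphere({(20.0, 0.0): 0.3, (20.0, 180.0): 0.2})
        with pytest.raises(ValueError, match="nadir"):
            anif(hem)

    def test_backward_enhanced_scene_pattern(self, clean_session):
        """On the default backscatter-dominant scene, ANIF exceeds 1 in the
        backward principal-plane directions and falls below 1 forward."""
        data, truth = clean_session
        res = process_session(data)
        hem = res.hemisphere
        a = hem.anif
        red = int(np.argmin(np.abs(hem.wavelengths - 672.0)))
        for i, p in enumerate(hem.positions):
            if p.view_zenith == 30.0 and p.view_azimuth == 0.0:
                assert a[i, red] > 1.05
            if p.view_zenith == 30.0 and p.view_azimuth == 180.0:
                assert a[i, red] < 0.95


class TestAnix:
    def test_constant_field_unity(self):
        hem = _mini_hemisphere({(0.0, 0.0): 0.25, (20.0, 0.0): 0.25, (20.0, 180.0): 0.25})
        summary = anix(hem)
        np.testing.assert_allclose(summary.anix, 1.0)

    def test_max_over_min_arithmetic(self):
        hem = _mini_hemisphere({(0.0, 0.0): 0.25, (20.0, 0.0): 0.30, (20.0, 180.0): 0.20})
        np.testing.assert_allclose(anix(hem).anix, 1.5)

    def test_empty_plane_rejected(self):
        hem = _mini_hemisphere({(0.0, 0.0): 0.25})
        with pytest.raises(ValueError, match="fewer than 2"):
            anix(hem, (45.0, 225.0))

    def test_principal_exceeds_orthogonal_on_pp_dominant_scene(self, clean_session):
        data, _ = clean_session
        res = process_session(data)
        pp = res.anix_principal
        op = res.anix_orthogonal
        assert np.all(pp.anix >= 1.0) and np.all(op.anix >= 1.0)
        assert np.all(pp.anix >= op.anix - 1e-9)
        from goniohcrf.hcrf import NIR_BAND_NM, VISIBLE_BAND_NM
        # anisotropy stronger in the visible than the NIR
        assert pp.region_mean(VISIBLE_BAND_NM) > pp.region_mean(NIR_BAND_NM)


class TestDriftIndicator:
    def test_constant_irradiance_zero_indicators(self):
        irr = _series(lambda m: 1.0)
        lref = irr.values[0] * 0.99
        times = [T0 + timedelta(minutes=m) for m in (2, 5, 8)]
        report = drift_indicator(irr, lref, times, Lref_end=lref, t0=T0)
        np.testing.assert_allclose(report.indicator, 0.0, atol=1e-12)
        assert report.session_score == pytest.approx(0.0, abs=1e-12)
        assert not report.caution.any()

    def test_step_during_middle_ring_carries_largest_indicator(self):
        """A transient irradiance step confined to one ring shows up as that
        ring's positions carrying the largest interpolation indicator."""
        irr = _series(lambda m: 1.06 if 4.0 <= m <= 8.0 else 1.0)
        lref = irr.values[0]
        ring_times = {
            "early": [T0 + timedelta(minutes=m) for m in (1.0, 2.0, 3.0)],
            "affected": [T0 + timedelta(minutes=m) for m in (5.0, 6.0, 7.0)],
            "late": [T0 + timedelta(minutes=m) for m in (10.0, 11.0, 12.0)],
        }
        all_times = sum(ring_times.values(), [])
        report = drift_indicator(irr, lref, all_times, t0=T0)
        by_ring = {k: np.mean(report.indicator[i * 3:(i + 1) * 3])
                   for i, k in enumerate(ring_times)}
        assert by_ring["affected"] > by_ring["early"]
        assert by_ring["affected"] > by_ring["late"]
        assert report.caution[3:6].all() and not report.caution[:3].any()

    def test_session_score_zero_for_uniform_multiplicative_drift(self):
        irr = _series(lambda m: 1.0 + 0.005 * m)
        lref0 = irr.values[0] * 0.99
        t_end = T0 + timedelta(minutes=12)
        lref_end = lref0 * float(1.0 + 0.005 * 12) / 1.0
        report = drift_indicator(irr, lref0, [t_end], Lref_end=lref_end, t0=T0)
        assert report.session_score == pytest.approx(0.0, abs=1e-9)

    def test_missing_end_panel_score_undefined(self):
        irr = _series(lambda m: 1.0)
        report = drift_indicator(irr, irr.values[0], [T0 + timedelta(minutes=1)], t0=T0)
        assert report.session_score is None
        assert report.session_consistent is None


class TestVegetationIndices:
    def test_equal_bands_zero_ndvi(self):
        hem = _mini_hemisphere({(0.0, 0.0): 0.3, (20.0, 0.0): 0.3},
                               wavelengths=np.array([672.0, 864.0]))
        ndvi, norm = vi_angular(hem)
        np.testing.assert_allclose(ndvi, 0.0)
        assert np.isnan(norm).all()  # nadir NDVI = 0: normalization undefined

    def test_nadir_normalized_is_one_at_nadir(self, clean_session):
        data, _ = clean_session
        res = process_session(data)
        i0 = res.hemisphere.nadir_index()
        assert res.ndvi_normalized[i0] == pytest.approx(1.0)

    def test_red_dominated_anisotropy_shifts_ndvi(self, clean_session):
        """Red reflectance is more anisotropic than NIR, so NDVI rises in
        the forward principal-plane directions and falls backward."""
        data, _ = clean_session
        res = process_session(data)
        hem = res.hemisphere
        i0 = hem.nadir_index()
        for i, p in enumerate(hem.positions):
            if p.view_zenith == 30.0 and p.view_azimuth == 180.0:  # forward
                assert res.ndvi[i] > res.ndvi[i0]
            if p.view_zenith == 30.0 and p.view_azimuth == 0.0:  # backward
                assert res.ndvi[i] < res.ndvi[i0]
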