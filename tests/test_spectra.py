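"""Spectrum I/O, radiometric conversion and quality screening."""

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from goniohcrf import (
    CalibrationTable,
    Spectrum,
    dn_to_radiance,
    quality_screen,
    read_spectrum,
    write_spectrum,
)
from goniohcrf.spectra import SpectrumParseError
from goniohcrf.synthetic import default_wavelength_grid, vegetation_reflectance

TS = datetime(2012, 7, 9, 13, 48, tzinfo=timezone(timedelta(hours=-8)))


class TestSpectrumType:
    def test_grid_length_and_bounds(self):
        wl = default_wavelength_grid()
        assert wl.size == 467 and wl[0] == 350.0 and wl[-1] == 1049.0
        sp = Spectrum(wl, np.ones_like(wl), "irradiance", TS)
        assert len(sp) == 467

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([350.0, 352.0, 351.0]), np.ones(3), "dn", TS)

    def test_negative_radiance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(np.array([400.0, 401.0]), np.array([1.0, -0.1]),
                     "target_radiance", TS)

    def test_out_of_band_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="within"):
            Spectrum(np.array([340.0, 400.0]), np.ones(2), "dn", TS)


class TestAsciiDialect:
    def test_read_writes_metadata_and_length(self, tmp_path):
        wl = default_wavelength_grid()
        sp = Spectrum(wl, vegetation_reflectance(wl), "target_radiance", TS,
                      scans_averaged=32)
        path = tmp_path / "s.txt"
        write_spectrum(path, sp)
        back = read_spectrum(path)
        assert len(back) == 467
        assert back.kind == "target_radiance"
        assert back.timestamp == TS
        assert back.scans_averaged == 32

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# kind: dn\n# timestamp: 2012-07-09T13:48:00-08:00\n"
                        "350.0 1.0\n351.5 not_a_number\n")
        with pytest.raises(SpectrumParseError, match=":4:"):
            read_spectrum(path)

    def test_missing_timestamp_is_metadata_error(self, tmp_path):
        path = tmp_path / "nometa.txt"
        path.write_text("# kind: dn\n350.0 1.0\n")
        with pytest.raises(SpectrumParseError, match="timestamp"):
            read_spectrum(path)
        # the plain dialect tolerates the same file
        assert read_spectrum(path, dialect="plain").timestamp is None

    def test_non_monotone_file_rejected(self, tmp_path):
        path = tmp_path / "mono.txt"
        path.write_text("# kind: dn\n# timestamp: 2012-07-09T13:48:00-08:00\n"
                        "352.0 1.0\n350.0 2.0\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            read_spectrum(path)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1e3,
                              allow_nan=False, allow_infinity=False),
                    min_size=2, max_size=40))
    def test_roundtrip_identity_on_values(self, values):
        """write ∘ read is the identity on values to full float precision."""
        import tempfile
        from pathlib import Path
        wl = 350.0 + 1.5 * np.arange(len(values))
        sp = Spectrum(wl, np.array(values), "irradiance", TS)
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "s.txt"
            write_spectrum(path, sp)
            back = read_spectrum(path)
        np.testing.assert_array_equal(back.values, sp.values)
        np.testing.assert_allclose(back.wavelengths, sp.wavelengths, atol=1e-6)


class TestDnToRadiance:
    def setup_method(self):
        self.wl = default_wavelength_grid()
        self.cal = CalibrationTable(self.wl, np.full(self.wl.size, 2.0e-10))

    def test_zero_dn_gives_zero_radiance(self):
        sp = Spectrum(self.wl, np.zeros(self.wl.size), "dn", TS)
        out = dn_to_radiance(sp, self.cal)
        assert out.kind == "target_radiance"
        np.testing.assert_array_equal(out.values, 0.0)

    def test_pointwise_linearity(self):
        sp = Spectrum(self.wl, np.full(self.wl.size, 100.0), "dn", TS)
        out = dn_to_radiance(sp, self.cal)
        np.testing.assert_allclose(out.values, 2.0e-8)

    def test_matches_elementwise_product_oracle(self):
        rng = np.random.default_rng(42)
        dn = rng.uniform(0, 4000, self.wl.size)
        gain = rng.uniform(1e-10, 5e-10, self.wl.size)
        offset = rng.uniform(0, 1e-9, self.wl.size)
        cal = CalibrationTable(self.wl, gain, offset)
        out = dn_to_radiance(Spectrum(self.wl, dn, "dn", TS), cal)
        # brute-force per-wavelength oracle
        expected = np.array([gain[i] * dn[i] + offset[i] for i in range(self.wl.size)])
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_scaling_homogeneity_without_offset(self):
        rng = np.random.default_rng(1)
        dn = rng.uniform(0, 1000, self.wl.size)
        a = 3.7
        f = lambda v: dn_to_radiance(Spectrum(self.wl, v, "dn", TS), self.cal).values
        np.testing.assert_allclose(f(a * dn), a * f(dn), rtol=1e-12)

    def test_coverage_error(self):
        small = CalibrationTable(np.array([400.0, 900.0]), np.array([1e-10, 1e-10]))
        sp = Spectrum(self.wl, np.ones(self.wl.size), "dn", TS)
        with pytest.raises(ValueError, match="cover"):
            dn_to_radiance(sp, small)

    def test_non_dn_input_rejected(self):
        sp = Spectrum(self.wl, np.ones(self.wl.size), "irradiance", TS)
        with pytest.raises(ValueError, match="DN"):
            dn_to_radiance(sp, self.cal)


class TestQualityScreen:
    def _session(self, scale_one=None, noisy_one=None, ring_size=16):
        """Panel + one ring of identical vegetation-shaped targets, with an
        optional scaled or noise-injected member."""
        from goniohcrf.spectra import Acquisition, SessionManifest
        wl = default_wavelength_grid()
        base = vegetation_reflectance(wl)
        t0 = TS
        acqs = [Acquisition("panel", "panel_radiance", t0, 0.0, 0.0)]
        spectra = {"panel": Spectrum(wl, np.full(wl.size, 0.3), "panel_radiance", t0)}
        azimuths = np.linspace(0, 360, ring_size, endpoint=False)
        for i, az in enumerate(azimuths):
            ref = f"t{i}"
            t = t0 + timedelta(seconds=17 * (i + 1))
            vals = base.copy()
            if i == scale_one:
                vals = vals * 5.0
            if i == noisy_one:
                vals = vals * (1.0 + 0.1 * (-1.0) ** np.arange(wl.size))
            acqs.append(Acquisition(ref, "target_radiance", t, 10.0, float(az)))
            spectra[ref] = Spectrum(wl, vals, "target_radiance", t)
        manifest = SessionManifest("QT", 69.0, -148.0, -8.0, tuple(acqs))
        return manifest, spectra

    def test_identical_spectra_all_ok(self):
        manifest, spectra = self._session()
        report = quality_screen(manifest, spectra)
        assert all(flag == "ok" for flag in report.flags.values())

    def test_scaled_member_flagged_outlier(self):
        from oracles import mad_outliers
        manifest, spectra = self._session(scale_one=4)
        report = quality_screen(manifest, spectra)
        assert report.flags["t4"] == "outlier"
        assert report.count("outlier") == 1
        # direct MAD oracle agrees on which member is deviant
        levels = np.array([float(np.mean(spectra[f"t{i}"].values)) for i in range(16)])
        assert list(mad_outliers(levels, 5.0)) == [i == 4 for i in range(16)]

    def test_alternating_noise_flagged_noisy(self):
        manifest, spectra = self._session(noisy_one=7)
        report = quality_screen(manifest, spectra)
        assert report.flags["t7"] == "noisy"

    def test_small_ring_untestable(self):
        manifest, spectra = self._session(ring_size=2)
        report = quality_screen(manifest, spectra)
        assert set(report.flags.values()) == {"untestable"}

    def test_permutation_invariance_within_ring(self):
        manifest, spectra = self._session(scale_one=3)
        report1 = quality_screen(manifest, spectra)
        from goniohcrf.spectra import SessionManifest
        acqs = list(manifest.acquisitions)
        acqs[1:] = acqs[1:][::-1]
        shuffled = SessionManifest("QT", 69.0, -148.0, -8.0, tuple(acqs))
        report2 = quality_screen(shuffled, spectra)
        assert report1.flags == report2.flags

    def test_missing_spectrum_raises(self):
        manifest, spectra = self._session()
        del spectra["t3"]
        with pytest.raises(KeyError, match="t3"):
            quality_screen(manifest, spectra)
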