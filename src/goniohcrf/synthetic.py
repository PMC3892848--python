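"""Synthetic goniometer sessions with known ground truth.

Emulates one full dual-beam session: a start reference-panel measurement,
61 target measurements over the hemisphere scheme, an end panel
measurement, and one simultaneous irradiance spectrum per radiance
acquisition (63 in total).  The scene's bidirectional reflectance factor
is a parametric ground truth — a vegetation-like base spectrum modulated
by a smooth angular kernel with backward enhancement and forward
darkening — so every pipeline stage can be checked against exact values.

The angular kernel is a test fixture, not a canopy radiative-transfer
claim: it reproduces the qualitative anisotropy of low vegetation
(brighter backward, darker forward, stronger in the visible than the NIR)
with a quadratic-bowl + cosine-backscatter shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    MeasurementScheme,
    SolarGeometry,
    ViewGeometry,
    default_scheme,
    solar_position,
)
from .hcrf import IrradianceSeries, PanelCalibration
from .spectra import (
    Acquisition,
    CalibrationTable,
    SessionManifest,
    Spectrum,
    write_manifest,
    write_spectrum,
)

__all__ = [
    "SceneModel",
    "AcquisitionModel",
    "SessionTruth",
    "default_wavelength_grid",
    "vegetation_reflectance",
    "solar_irradiance_shape",
    "synthetic_panel_calibration",
    "simulate_session",
    "conical_average",
]


def default_wavelength_grid() -> np.ndarray:
    """350-1049 nm at 1.5 nm sampling (467 channels)."""
    return np.arange(467) * 1.5 + 350.0


def _nir_weight(wavelengths: np.ndarray) -> np.ndarray:
    """0 in the visible, 1 on the NIR plateau, red-edge transition ~716 nm."""
    return 1.0 / (1.0 + np.exp(-(wavelengths - 716.0) / 18.0))


def vegetation_reflectance(wavelengths: np.ndarray) -> np.ndarray:
    """Vegetation-like nadir reflectance: chlorophyll absorption wells in
    the blue and red, a green bump, the red edge, and an NIR plateau with
    a shallow 970 nm water feature."""
    wl = np.asarray(wavelengths, float)
    visible = 0.045 + 0.05 * np.exp(-((wl - 552.0) ** 2) / (2 * 28.0**2))
    r = visible * (1.0 - _nir_weight(wl)) + (0.36 + 1.5e-5 * (wl - 750.0)) * _nir_weight(wl)
    r *= 1.0 - 0.04 * np.exp(-((wl - 970.0) ** 2) / (2 * 22.0**2))
    return r


def solar_irradiance_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth solar-like spectral irradiance (W·m⁻²·nm⁻¹), a 5800 K Planck
    shape normalised to 1.4 W·m⁻²·nm⁻¹ at 550 nm."""
    wl_m = np.asarray(wavelengths, float) * 1e-9

    def planck(lm: np.ndarray) -> np.ndarray:
        h, c, k, t = 6.626e-34, 2.998e8, 1.381e-23, 5800.0
        return lm**-5 / np.expm1(h * c / (lm * k * t))

    return 1.4 * planck(wl_m) / planck(np.array(550e-9))


@dataclass(frozen=True)
class SceneModel:
    """Parametric ground-truth BRF.

    ``brf(λ, θ_r, φ_r)`` = base(λ) · kernel(λ, θ_r, φ_r) with

        kernel = 1 + B(λ)·(θ_r/θ_max)·cos(φ_r) − D(λ)·(θ_r/θ_max)²

    where φ_r is principal-plane referenced (0° = backward scatter) and
    the strengths B (backscatter) and D (bowl darkening) interpolate
    between visible and NIR values across the red edge — anisotropy is
    stronger in the visible, as absorption suppresses multiple scattering.
    """

    base_reflectance: Callable[[np.ndarray], np.ndarray] = vegetation_reflectance
    backscatter_vis: float = 0.30
    backscatter_nir: float = 0.08
    darkening_vis: float = 0.12
    darkening_nir: float = 0.05
    theta_max: float = 30.0
    lambertian: bool = False

    def kernel(self, wavelengths: np.ndarray, view_zenith: float,
               view_azimuth: float) -> np.ndarray:
        wl = np.asarray(wavelengths, float)
        if self.lambertian:
            return np.ones_like(wl)
        w = _nir_weight(wl)
        b = self.backscatter_vis * (1 - w) + self.backscatter_nir * w
        d = self.darkening_vis * (1 - w) + self.darkening_nir * w
        x = view_zenith / self.theta_max
        k = 1.0 + b * x * math.cos(math.radians(view_azimuth)) - d * x * x
        return np.maximum(k, 1e-6)

    def brf(self, wavelengths: np.ndarray, view_zenith: float,
            view_azimuth: float) -> np.ndarray:
        return self.base_reflectance(np.asarray(wavelengths, float)) * self.kernel(
            wavelengths, view_zenith, view_azimuth
        )


def panel_brf(wavelengths: np.ndarray, sun_zenith: float) -> np.ndarray:
    """The simulated panel's nadir-view reflectance factor: ~0.99 at the 8°
    calibration geometry, declining mildly with sun zenith (the slope mimics
    published Spectralon behaviour)."""
    wl = np.asarray(wavelengths, float)
    r0 = 0.992 - 4.0e-6 * (wl - 350.0)
    return r0 * (1.0 - 3.0e-4 * (sun_zenith - 8.0))


def synthetic_panel_calibration(wavelengths: np.ndarray,
                                anisotropy: bool = True) -> PanelCalibration:
    """Panel calibration matching the simulator's panel model (synthetic
    stand-in for a factory Spectralon calibration + published
    sun-zenith-dependence table).

    The reflectance chain divides by ``c_ref``, so the calibration is
    stored in reciprocal form: ``r_ref = 1 / panel_brf`` at the 8°
    calibration geometry (slightly above 1 for a ~99 % panel), and
    ``c_ref(λ, θ_i) = 1 / panel_brf(λ, θ_i)``.
    """
    wl = np.asarray(wavelengths, float)
    r_ref = 1.0 / panel_brf(wl, 8.0)
    if not anisotropy:
        return PanelCalibration(wl, r_ref, None, source="synthetic-identity")

    def c_ref_fn(w: np.ndarray, sun_zenith: float) -> np.ndarray:
        return 1.0 / panel_brf(w, sun_zenith)

    return PanelCalibration(wl, r_ref, c_ref_fn, source="synthetic-sandmeier-style")


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrument/illumination model for one simulated session.

    ``drift_rate_per_min`` is the smooth multiplicative irradiance trend;
    ``drift_steps`` are (minute, factor) step events (e.g. a thin cloud
    passing).  ``pointing_jitter_sd`` (m, ground) reproduces the measured
    ±6 cm pointing envelope at ~2σ; ``pp_misalignment_sd`` (deg) is the
    compass uncertainty of the principal-plane alignment.  ``noise_sd`` is
    the relative multiplicative sensor noise per channel, bracketing the
    instrument's 0.2-1.6 % reflectance uncertainty.
    """

    irradiance_base: Callable[[np.ndarray], np.ndarray] = solar_irradiance_shape
    drift_rate_per_min: float = 0.002
    drift_steps: tuple[tuple[float, float], ...] = ()
    pointing_jitter_sd: float = 0.03
    pp_misalignment_sd: float = 1.75
    noise_sd: float = 0.005
    slant_distance: float = 2.02
    emit_dn: bool = False
    dn_gain: float = 4.0e-5
    seed: int = 0

    def drift(self, minutes: float) -> float:
        g = 1.0 + self.drift_rate_per_min * minutes
        for t_step, factor in self.drift_steps:
            if minutes >= t_step:
                g *= factor
        if g <= 0:
            raise ValueError("drift factor must stay positive")
        return g


@dataclass
class SessionTruth:
    """Ground-truth record emitted alongside a simulated session."""

    scheme: MeasurementScheme
    sun: SolarGeometry
    wavelengths: np.ndarray
    positions: list[ViewGeometry]
    brf: np.ndarray  # exact BRF on the scheme grid, (n_positions, n_wavelengths)
    drift_factors: np.ndarray  # per target acquisition
    panel_calibration: PanelCalibration

    def save(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "position_id": [f"p{i:02d}" for i in range(len(self.positions))],
            "view_zenith": [p.view_zenith for p in self.positions],
            "view_azimuth": [p.view_azimuth for p in self.positions],
            "drift_factor": self.drift_factors,
        })
        brf = pd.DataFrame(self.brf, columns=[f"brf_{w:.1f}" for w in self.wavelengths])
        pd.concat([df, brf], axis=1).to_csv(path, sep="\t", index=False)


def _jittered_view(view: ViewGeometry, offset_xy: np.ndarray,
                   slant_distance: float) -> ViewGeometry:
    """Effective view geometry when the footprint centre lands ``offset_xy``
    (m, ground plane, PP frame) away from the plot centre."""
    theta = math.radians(view.view_zenith)
    phi = math.radians(view.view_azimuth)
    # Sensor position (PP frame: x toward φ=0, y toward φ=90, z up).
    sensor = np.array([
        slant_distance * math.sin(theta) * math.cos(phi),
        slant_distance * math.sin(theta) * math.sin(phi),
        slant_distance * math.cos(theta),
    ])
    target = np.array([offset_xy[0], offset_xy[1], 0.0])
    d = sensor - target
    r = np.linalg.norm(d)
    eff_zen = math.degrees(math.acos(d[2] / r))
    eff_az = math.degrees(math.atan2(d[1], d[0])) % 360.0 if eff_zen > 1e-9 else 0.0
    return ViewGeometry(eff_zen, eff_az)


def simulate_session(
    scene: SceneModel,
    acq: AcquisitionModel,
    scheme: MeasurementScheme | None = None,
    start_time: datetime | None = None,
    latitude: float = 69.674444,
    longitude: float = -148.720833,
    cadence_s: float = 17.0,
    out_dir: str | Path | None = None,
    plot_id: str = "SYN1",
) -> tuple[SessionManifest, dict[str, Spectrum], IrradianceSeries, SessionTruth]:
    """Generate one complete session, optionally writing it to ``out_dir``.

    Acquisition order: start panel (nadir), the scheme's positions in
    order, end panel (nadir); one irradiance spectrum accompanies every
    radiance acquisition.  Target radiance is ``BRF·E(t)/π`` at the
    jittered effective view geometry; panel radiance is the non-Lambertian
    panel factor times ``E(t)/π``.

    Returns ``(manifest, spectra, irradiance_series, truth)``; identical
    seeds give identical sessions.
    """
    if cadence_s <= 0:
        raise ValueError("cadence must be positive")
    scheme = scheme or default_scheme()
    positions = scheme.positions()
    if not positions:
        raise ValueError("scheme is empty")
    if start_time is None:
        from datetime import timezone
        start_time = datetime(2012, 7, 9, 21, 48, tzinfo=timezone.utc)
    if start_time.tzinfo is None:
        raise ValueError("start_time must be timezone-aware")

    rng = np.random.default_rng(acq.seed)
    wl = default_wavelength_grid()
    e0 = acq.irradiance_base(wl)
    sun = solar_position(latitude, longitude, start_time)
    panel_cal = synthetic_panel_calibration(wl)
    panel_truth = panel_brf(wl, sun.sun_zenith)
    pp_offset = float(rng.normal(0.0, acq.pp_misalignment_sd))

    def noisy(values: np.ndarray) -> np.ndarray:
        if acq.noise_sd == 0:
            return values
        return values * (1.0 + rng.normal(0.0, acq.noise_sd, size=values.shape))

    spectra: dict[str, Spectrum] = {}
    acquisitions: list[Acquisition] = []
    irr_times: list[datetime] = []
    irr_values: list[np.ndarray] = []

    def record_irradiance(t: datetime, e_t: np.ndarray) -> None:
        ref = f"irr_{len(irr_times):03d}"
        meas = np.maximum(noisy(e_t), 0.0)
        spectra[ref] = Spectrum(wl, meas, "irradiance", t)
        acquisitions.append(Acquisition(ref, "irradiance", t))
        irr_times.append(t)
        irr_values.append(meas)

    def record_radiance(ref: str, kind: str, t: datetime, radiance: np.ndarray,
                        view: ViewGeometry) -> None:
        meas = np.maximum(noisy(radiance), 0.0)
        spectra[ref] = Spectrum(wl, meas, kind, t)  # type: ignore[arg-type]
        acquisitions.append(Acquisition(ref, kind, t,  # type: ignore[arg-type]
                                        view_zenith=view.view_zenith,
                                        view_azimuth=view.view_azimuth))

    # -- start panel --------------------------------------------------------
    t = start_time
    e_t = e0 * acq.drift(0.0)
    record_radiance("panel_start", "panel_radiance", t, panel_truth * e_t / math.pi,
                    ViewGeometry(0.0, 0.0))
    record_irradiance(t, e_t)

    # -- targets ------------------------------------------------------------
    truth_brf = np.empty((len(positions), wl.size))
    drift_factors = np.empty(len(positions))
    for i, pos in enumerate(positions):
        t = start_time + timedelta(seconds=cadence_s * (i + 1))
        minutes = cadence_s * (i + 1) / 60.0
        g = acq.drift(minutes)
        drift_factors[i] = g
        e_t = e0 * g
        jitter = rng.normal(0.0, acq.pointing_jitter_sd, size=2) \
            if acq.pointing_jitter_sd > 0 else np.zeros(2)
        eff = _jittered_view(pos, jitter, acq.slant_distance)
        brf_eff = scene.brf(wl, eff.view_zenith, eff.view_azimuth + pp_offset)
        truth_brf[i] = scene.brf(wl, pos.view_zenith, pos.view_azimuth)
        record_radiance(f"tgt_{i:02d}", "target_radiance", t, brf_eff * e_t / math.pi, pos)
        record_irradiance(t, e_t)

    # -- end panel ----------------------------------------------------------
    t = start_time + timedelta(seconds=cadence_s * (len(positions) + 1))
    g = acq.drift(cadence_s * (len(positions) + 1) / 60.0)
    e_t = e0 * g
    record_radiance("panel_end", "panel_radiance", t, panel_truth * e_t / math.pi,
                    ViewGeometry(0.0, 0.0))
    record_irradiance(t, e_t)

    manifest = SessionManifest(
        plot_id=plot_id,
        latitude=latitude,
        longitude=longitude,
        utc_offset=start_time.utcoffset().total_seconds() / 3600.0,
        acquisitions=tuple(acquisitions),
        scheme_id="default-61" if scheme.n_positions == 61 else f"custom-{scheme.n_positions}",
        panel_calibration_ref="panel_calibration.tsv",
    )
    irr = IrradianceSeries(tuple(irr_times), wl, np.vstack(irr_values))
    truth = SessionTruth(scheme, sun, wl, positions, truth_brf, drift_factors, panel_cal)

    if acq.emit_dn:
        cal = CalibrationTable(wl, np.full(wl.size, acq.dn_gain), instrument_id="GER1500-sim")
        quantized: dict[str, Spectrum] = {}
        for ref, sp in spectra.items():
            dn = np.round(sp.values / acq.dn_gain)
            quantized[ref] = Spectrum(wl, dn, "dn", sp.timestamp, sp.scans_averaged)
        spectra = quantized

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "spectra").mkdir(parents=True, exist_ok=True)
        for ref, sp in spectra.items():
            write_spectrum(out_dir / "spectra" / f"{ref}.txt", sp)
        write_manifest(out_dir / "manifest.yaml", manifest)
        _write_panel_calibration(out_dir / "panel_calibration.tsv", panel_cal)
        truth.save(out_dir / "truth.tsv")
        if acq.emit_dn:
            pd.DataFrame({"wavelength": wl, "gain": np.full(wl.size, acq.dn_gain),
                          "offset": np.zeros(wl.size)}).to_csv(
                out_dir / "calibration.tsv", sep="\t", index=False)

    return manifest, spectra, irr, truth


def _write_panel_calibration(path: Path, cal: PanelCalibration) -> None:
    header = [f"# source: {cal.source}", "# c_ref_slope_per_deg: -3.0e-4",
              "# reference_sun_zenith: 8.0"]
    body = pd.DataFrame({"wavelength": cal.wavelengths, "r_ref": cal.r_ref}).to_csv(
        sep="\t", index=False, float_format="%.10g")
    path.write_text("\n".join(header) + "\n" + body)


def load_panel_calibration(path: str | Path, anisotropy: bool = True) -> PanelCalibration:
    """Read a panel calibration table written by the simulator (or a
    user-supplied one in the same layout)."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_head = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_head += 1
        key, _, val = line[1:].partition(":")
        meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", skiprows=n_head)
    wl = df["wavelength"].to_numpy(float)
    r_ref = df["r_ref"].to_numpy(float)
    slope = float(meta.get("c_ref_slope_per_deg", 0.0))
    ref_zen = float(meta.get("reference_sun_zenith", 8.0))
    if not anisotropy or slope == 0.0:
        return PanelCalibration(wl, r_ref, None, source=meta.get("source", "file"))

    def c_ref_fn(w: np.ndarray, sun_zenith: float) -> np.ndarray:
        # r_ref is reciprocal-form; the panel BRF shrinks by (1 + slope·Δθ),
        # so the correction divisor grows by its inverse.
        return np.interp(w, wl, r_ref) / (1.0 + slope * (sun_zenith - ref_zen))

    return PanelCalibration(wl, r_ref, c_ref_fn, source=meta.get("source", "file"))


# ---------------------------------------------------------------------------
# Conical averaging
# ---------------------------------------------------------------------------

def conical_average(
    brf_truth: Callable[[float, float], float],
    view: ViewGeometry,
    ifov: float,
    n_rays: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo average of a directional BRF over the sensor's cone.

    ``brf_truth(view_zenith_deg, view_azimuth_deg)`` is sampled over
    directions uniform in solid angle within the cone of full opening
    ``ifov`` about the nominal view direction; quantifies the
    conical-vs-directional approximation for smooth scenes.
    """
    if ifov <= 0:
        raise ValueError("ifov must be positive")
    half = math.radians(ifov) / 2.0
    rng = np.random.default_rng(seed)
    cos_a = rng.uniform(math.cos(half), 1.0, size=n_rays)
    sin_a = np.sqrt(1.0 - cos_a**2)
    psi = rng.uniform(0.0, 2.0 * math.pi, size=n_rays)

    theta = math.radians(view.view_zenith)
    phi = math.radians(view.view_azimuth)
    v = np.array([math.sin(theta) * math.cos(phi),
                  math.sin(theta) * math.sin(phi),
                  math.cos(theta)])
    helper = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.999 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(v, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)

    dirs = (cos_a[:, None] * v[None, :]
            + sin_a[:, None] * (np.cos(psi)[:, None] * e1[None, :]
                                + np.sin(psi)[:, None] * e2[None, :]))
    zen = np.degrees(np.arccos(np.clip(dirs[:, 2], -1.0, 1.0)))
    az = np.degrees(np.arctan2(dirs[:, 1], dirs[:, 0])) % 360.0
    samples = np.array([brf_truth(z, a) for z, a in zip(zen, az)])
    return float(samples.mean())
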