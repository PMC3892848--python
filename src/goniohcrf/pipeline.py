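"""End-to-end processing chain for one session.

read → (DN→radiance) → quality screen → c_diff → HCRF → ANIF/ANIX/VI →
drift indicator → serialized hemisphere dataset + report.  The CLI is a
thin wrapper around :func:`process_session`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import MeasurementScheme, ViewGeometry, solar_position
from .hcrf import (
    AnisotropySummary,
    DriftReport,
    HemisphereDataset,
    IrradianceSeries,
    NIR_BAND_NM,
    PanelCalibration,
    VISIBLE_BAND_NM,
    anif,
    anix,
    c_diff,
    drift_indicator,
    hcrf,
    vi_angular,
)
from .spectra import (
    CalibrationTable,
    QualityReport,
    SessionManifest,
    Spectrum,
    dn_to_radiance,
    quality_screen,
    read_manifest,
    read_spectrum,
)

__all__ = ["SessionData", "ProcessingResult", "load_session", "process_session", "RunLog"]


class RunLog:
    """Append-only operation log: one ISO-timestamped line per operation."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.lines: list[str] = []

    def write(self, message: str) -> None:
        stamp = datetime.now().astimezone().isoformat(timespec="seconds")
        line = f"{stamp} {message}"
        self.lines.append(line)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")


@dataclass
class SessionData:
    """A fully loaded session ready for processing."""

    manifest: SessionManifest
    spectra: dict[str, Spectrum]
    irradiance: IrradianceSeries
    panel_calibration: PanelCalibration
    calibration: CalibrationTable | None = None


def _irradiance_series(manifest: SessionManifest,
                       spectra: Mapping[str, Spectrum]) -> IrradianceSeries:
    irr_acqs = manifest.irradiance_acquisitions()
    if not irr_acqs:
        raise ValueError("session has no irradiance acquisitions")
    wl = spectra[irr_acqs[0].spectrum_ref].wavelengths
    values = np.vstack([spectra[a.spectrum_ref].values for a in irr_acqs])
    return IrradianceSeries(tuple(a.timestamp for a in irr_acqs), wl, values)


def load_session(session_dir: str | Path,
                 panel_anisotropy: bool = True) -> SessionData:
    """Load a session directory (manifest.yaml + spectra/ + panel table)."""
    from .synthetic import load_panel_calibration

    session_dir = Path(session_dir)
    manifest = read_manifest(session_dir / "manifest.yaml")
    spectra = {
        a.spectrum_ref: read_spectrum(session_dir / "spectra" / f"{a.spectrum_ref}.txt")
        for a in manifest.acquisitions
    }
    cal = None
    cal_path = session_dir / "calibration.tsv"
    if cal_path.exists():
        df = pd.read_csv(cal_path, sep="\t")
        cal = CalibrationTable(df["wavelength"].to_numpy(), df["gain"].to_numpy(),
                               df.get("offset", pd.Series(np.zeros(len(df)))).to_numpy())
    panel_path = session_dir / (manifest.panel_calibration_ref or "panel_calibration.tsv")
    if panel_path.exists():
        panel = load_panel_calibration(panel_path, anisotropy=panel_anisotropy)
    else:
        wl = spectra[manifest.acquisitions[0].spectrum_ref].wavelengths
        panel = PanelCalibration(wl, np.ones_like(wl), None, source="identity")
    # Convert DN spectra to physical units where a calibration is present.
    converted: dict[str, Spectrum] = {}
    for a in manifest.acquisitions:
        sp = spectra[a.spectrum_ref]
        if sp.kind == "dn":
            if cal is None:
                raise ValueError("DN spectra present but no calibration.tsv in session")
            out_kind = a.kind if a.kind != "dn" else "target_radiance"
            sp = dn_to_radiance(sp, cal, kind=out_kind)
        converted[a.spectrum_ref] = sp
    return SessionData(manifest, converted, _irradiance_series(manifest, converted),
                       panel, cal)


@dataclass
class ProcessingResult:
    """Everything the processing chain produces for one session."""

    hemisphere: HemisphereDataset
    quality: QualityReport
    drift: DriftReport
    anix_principal: AnisotropySummary
    anix_orthogonal: AnisotropySummary
    ndvi: np.ndarray
    ndvi_normalized: np.ndarray

    def report_text(self) -> str:
        lines = ["session processing report", "=" * 25]
        sun = self.hemisphere.sun
        lines.append(f"sun zenith {sun.sun_zenith:.2f} deg, azimuth {sun.sun_azimuth:.2f} deg")
        lines.append(f"positions: {len(self.hemisphere.positions)}")
        for flag in ("ok", "noisy", "outlier", "untestable"):
            n = self.quality.count(flag)
            if n:
                lines.append(f"quality[{flag}]: {n}")
        for summary in (self.anix_principal, self.anix_orthogonal):
            vis = summary.region_mean(VISIBLE_BAND_NM)
            nir = summary.region_mean(NIR_BAND_NM)
            lines.append(f"ANIX({summary.plane}): visible {vis:.3f}, NIR {nir:.3f}")
        if self.drift.session_score is None:
            lines.append("drift consistency score: unavailable (no end panel)")
        else:
            lines.append(f"drift consistency score: {self.drift.session_score:.5f}")
        lines.append(f"positions flagged caution (drift): {int(self.drift.caution.sum())}")
        return "\n".join(lines)


def process_session(
    data: SessionData,
    drift_correction: bool = True,
    panel_anisotropy: bool = True,
    red_band: float = 672.0,
    nir_band: float = 864.0,
    drift_caution_threshold: float = 0.02,
    irradiance_tolerance_s: float = 5.0,
    log: RunLog | None = None,
) -> ProcessingResult:
    """Run the full reflectance chain on a loaded session."""
    log = log or RunLog()
    manifest, spectra = data.manifest, data.spectra
    panels = manifest.panel_acquisitions()
    targets = manifest.target_acquisitions()
    if not targets:
        raise ValueError("session has no target acquisitions")
    log.write(f"process start plot={manifest.plot_id} targets={len(targets)}")

    quality = quality_screen(manifest, spectra)
    log.write(f"quality screen: {quality.count('ok')} ok / {len(targets)} targets")

    panel_start = spectra[panels[0].spectrum_ref]
    panel_end = spectra[panels[-1].spectrum_ref] if len(panels) > 1 else None
    t0 = panels[0].timestamp
    sun = solar_position(manifest.latitude, manifest.longitude, t0)
    wl = panel_start.wavelengths
    cref = data.panel_calibration.c_ref(wl, sun.sun_zenith) if panel_anisotropy \
        else np.interp(wl, data.panel_calibration.wavelengths, data.panel_calibration.r_ref)
    log.write(f"sun zenith {sun.sun_zenith:.2f} azimuth {sun.sun_azimuth:.2f}; "
              f"c_ref source {data.panel_calibration.source}")

    rows = []
    positions: list[ViewGeometry] = []
    times: list[datetime] = []
    flags: list[str] = []
    for acq in targets:
        sp = spectra[acq.spectrum_ref]
        w = c_diff(data.irradiance, t0, acq.timestamp, irradiance_tolerance_s) \
            if drift_correction else 1.0
        rows.append(hcrf(sp.values, panel_start.values, w, cref))
        positions.append(ViewGeometry(acq.view_zenith, acq.view_azimuth))
        times.append(acq.timestamp)
        flags.append(quality.flags.get(acq.spectrum_ref, "ok"))
    log.write(f"HCRF computed (drift_correction={'on' if drift_correction else 'off'})")

    zeniths = sorted({p.view_zenith for p in positions})
    rings = tuple((z, tuple(p.view_azimuth for p in positions if p.view_zenith == z))
                  for z in zeniths)
    hem = HemisphereDataset(
        scheme=MeasurementScheme(rings), sun=sun, wavelengths=wl,
        positions=positions, timestamps=times, hcrf=np.vstack(rows), flags=flags,
        metadata={"plot_id": manifest.plot_id,
                  "drift_correction": str(drift_correction),
                  "c_ref_source": data.panel_calibration.source},
    )
    anif(hem)

    drift = drift_indicator(
        data.irradiance, panel_start, [a.timestamp for a in targets],
        Lref_end=panel_end, t0=t0, caution_threshold=drift_caution_threshold,
        tolerance_s=irradiance_tolerance_s,
    )
    hem.drift = drift.indicator
    for i, caution in enumerate(drift.caution):
        if caution and hem.flags[i] == "ok":
            hem.flags[i] = "caution"
    log.write(f"drift indicator: {int(drift.caution.sum())} caution positions")

    summary_pp = anix(hem, (0.0, 180.0), plane="principal")
    summary_op = anix(hem, (90.0, 270.0), plane="orthogonal")
    ndvi, ndvi_norm = vi_angular(hem, red_band, nir_band)
    log.write("ANIF/ANIX/NDVI derived; process complete")

    return ProcessingResult(hem, quality, drift, summary_pp, summary_op, ndvi, ndvi_norm)
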