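"""Session spectra: ASCII I/O, radiometric calibration, quality screening.

The on-disk dialect is a human-readable two-column ASCII format:

.. code-block:: text

    # kind: target_radiance
    # timestamp: 2012-07-09T13:48:00-08:00
    # scans_averaged: 32
    350.0 1.2345678901234567e-02
    351.5 1.2401234567890123e-02
    ...

Header lines are ``# key: value``; the body is whitespace-separated
wavelength (nm) / value pairs.  Values are written with 17 significant
digits so a write/read round trip is exact.  A plain two-column file with
no header parses as well (kind/timestamp must then be supplied by the
manifest).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Spectrum",
    "CalibrationTable",
    "Acquisition",
    "SessionManifest",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "dn_to_radiance",
    "quality_screen",
    "QualityReport",
]

SpectrumKind = Literal["target_radiance", "panel_radiance", "irradiance", "dn"]
_KINDS = ("target_radiance", "panel_radiance", "irradiance", "dn")

WAVELENGTH_MIN_NM = 350.0
WAVELENGTH_MAX_NM = 1050.0


class SpectrumParseError(ValueError):
    """Malformed spectrum file; carries the offending line number."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """One acquisition: a signal on a strictly increasing wavelength grid.

    ``values`` are unitless digital numbers (``kind='dn'``), radiance
    (W·m⁻²·nm⁻¹·sr⁻¹) or irradiance (W·m⁻²·nm⁻¹).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    timestamp: datetime | None = None
    scans_averaged: int = 32

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.shape != vals.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if wl.size and (wl[0] < WAVELENGTH_MIN_NM - 1e-9 or wl[-1] > WAVELENGTH_MAX_NM + 1e-9):
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN_NM}, {WAVELENGTH_MAX_NM}] nm"
            )
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind in ("target_radiance", "panel_radiance", "irradiance") and np.any(vals < 0):
            raise ValueError(f"{self.kind} values must be non-negative")
        if self.timestamp is not None and self.timestamp.tzinfo is None:
            raise ValueError("timestamp must carry an explicit UTC offset")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, float), kind=kind or self.kind)


@dataclass(frozen=True)
class CalibrationTable:
    """Per-wavelength DN→radiance gain/offset for one instrument."""

    wavelengths: np.ndarray
    gain: np.ndarray
    offset: np.ndarray | None = None
    instrument_id: str = ""
    calibration_date: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        g = np.asarray(self.gain, float)
        off = np.zeros_like(g) if self.offset is None else np.asarray(self.offset, float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "offset", off)
        if not (wl.shape == g.shape == off.shape):
            raise ValueError("calibration columns must have equal length")
        if np.any(g <= 0):
            raise ValueError("gain must be strictly positive")

    def covers(self, wavelengths: np.ndarray) -> bool:
        return bool(self.wavelengths[0] <= wavelengths[0] and
                    wavelengths[-1] <= self.wavelengths[-1])


@dataclass(frozen=True)
class Acquisition:
    """Bookkeeping for one spectrum in a session."""

    spectrum_ref: str
    kind: SpectrumKind
    timestamp: datetime
    view_zenith: float | None = None
    view_azimuth: float | None = None
    photo_ref: str | None = None

    def __post_init__(self) -> None:
        if self.kind in ("target_radiance", "panel_radiance", "dn"):
            if self.view_zenith is None or self.view_azimuth is None:
                raise ValueError(f"{self.kind} acquisition requires view geometry")
        elif self.kind == "irradiance":
            if self.view_zenith is not None or self.view_azimuth is not None:
                raise ValueError("irradiance acquisitions carry no view geometry")
        if self.timestamp.tzinfo is None:
            raise ValueError("acquisition timestamp must carry a UTC offset")


@dataclass(frozen=True)
class SessionManifest:
    """One hemisphere session: site, acquisitions, references."""

    plot_id: str
    latitude: float
    longitude: float
    utc_offset: float
    acquisitions: tuple[Acquisition, ...]
    scheme_id: str = "default-61"
    panel_calibration_ref: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "acquisitions", tuple(self.acquisitions))
        panels = self.panel_acquisitions()
        if not panels:
            raise ValueError("session must contain at least one panel acquisition")
        radiance = [a for a in self.acquisitions if a.kind in ("target_radiance", "panel_radiance")]
        if radiance and radiance[0].kind != "panel_radiance":
            raise ValueError("first radiance acquisition must be the reference panel")
        for p in panels:
            if p.view_zenith != 0.0:
                raise ValueError("panel acquisitions must be nadir-view")

    def panel_acquisitions(self) -> list[Acquisition]:
        return [a for a in self.acquisitions if a.kind == "panel_radiance"]

    def target_acquisitions(self) -> list[Acquisition]:
        return [a for a in self.acquisitions if a.kind == "target_radiance"]

    def irradiance_acquisitions(self) -> list[Acquisition]:
        return [a for a in self.acquisitions if a.kind == "irradiance"]


# ---------------------------------------------------------------------------
# ASCII I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^#\s*([A-Za-z_][\w-]*)\s*:\s*(.*?)\s*$")


def write_spectrum(path: str | Path, spectrum: Spectrum) -> None:
    """Write a spectrum in the canonical ASCII dialect (17-digit values)."""
    path = Path(path)
    lines = [f"# kind: {spectrum.kind}"]
    if spectrum.timestamp is not None:
        lines.append(f"# timestamp: {spectrum.timestamp.isoformat()}")
    lines.append(f"# scans_averaged: {spectrum.scans_averaged}")
    for wl, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{wl:.6f} {v:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path, dialect: str = "canonical") -> Spectrum:
    """Read a spectrum file.

    ``dialect='canonical'`` expects the ``# key: value`` header (kind and
    timestamp required); ``dialect='plain'`` accepts a bare two-column
    file and returns ``kind='dn'`` with no timestamp.
    """
    if dialect not in ("canonical", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    wl: list[float] = []
    vals: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _HEADER_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumParseError(f"{path.name}:{lineno}: expected two columns, got {raw!r}")
        try:
            wl.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{path.name}:{lineno}: non-numeric field in {raw!r}") from exc
    if dialect == "canonical":
        if "kind" not in meta:
            raise SpectrumParseError(f"{path.name}: header missing 'kind'")
        if "timestamp" not in meta:
            raise SpectrumParseError(f"{path.name}: header missing 'timestamp'")
        kind = meta["kind"]
        ts = datetime.fromisoformat(meta["timestamp"])
    else:
        kind = meta.get("kind", "dn")
        ts = datetime.fromisoformat(meta["timestamp"]) if "timestamp" in meta else None
    return Spectrum(
        wavelengths=np.array(wl), values=np.array(vals), kind=kind,  # type: ignore[arg-type]
        timestamp=ts, scans_averaged=int(meta.get("scans_averaged", 32)),
    )


def _acq_to_dict(a: Acquisition) -> dict:
    d: dict = {
        "spectrum_ref": a.spectrum_ref,
        "kind": a.kind,
        "timestamp": a.timestamp.isoformat(),
    }
    if a.view_zenith is not None:
        d["view_zenith"] = float(a.view_zenith)
        d["view_azimuth"] = float(a.view_azimuth)
    if a.photo_ref:
        d["photo_ref"] = a.photo_ref
    return d


def write_manifest(path: str | Path, manifest: SessionManifest) -> None:
    doc = {
        "plot_id": manifest.plot_id,
        "latitude": manifest.latitude,
        "longitude": manifest.longitude,
        "utc_offset": manifest.utc_offset,
        "scheme_id": manifest.scheme_id,
        "panel_calibration_ref": manifest.panel_calibration_ref,
        "acquisitions": [_acq_to_dict(a) for a in manifest.acquisitions],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | Path) -> SessionManifest:
    doc = yaml.safe_load(Path(path).read_text())
    acqs = tuple(
        Acquisition(
            spectrum_ref=a["spectrum_ref"],
            kind=a["kind"],
            timestamp=datetime.fromisoformat(a["timestamp"]),
            view_zenith=a.get("view_zenith"),
            view_azimuth=a.get("view_azimuth"),
            photo_ref=a.get("photo_ref"),
        )
        for a in doc["acquisitions"]
    )
    return SessionManifest(
        plot_id=doc["plot_id"],
        latitude=float(doc["latitude"]),
        longitude=float(doc["longitude"]),
        utc_offset=float(doc["utc_offset"]),
        acquisitions=acqs,
        scheme_id=doc.get("scheme_id", "default-61"),
        panel_calibration_ref=doc.get("panel_calibration_ref", ""),
    )


# ---------------------------------------------------------------------------
# Radiometric conversion
# ---------------------------------------------------------------------------

def dn_to_radiance(
    raw: Spectrum, cal: CalibrationTable, kind: SpectrumKind = "target_radiance"
) -> Spectrum:
    """Convert digital numbers to (ir)radiance: ``gain·DN + offset``.

    The calibration table is linearly interpolated onto the spectrum's grid
    (the 1.5 nm sampling makes the interpolation error negligible); it must
    cover the spectrum's wavelength range.
    """
    if raw.kind != "dn":
        raise ValueError(f"expected a DN spectrum, got kind={raw.kind!r}")
    if not cal.covers(raw.wavelengths):
        raise ValueError(
            "calibration grid does not cover the spectrum "
            f"({cal.wavelengths[0]}-{cal.wavelengths[-1]} vs "
            f"{raw.wavelengths[0]}-{raw.wavelengths[-1]} nm)"
        )
    gain = np.interp(raw.wavelengths, cal.wavelengths, cal.gain)
    offset = np.interp(raw.wavelengths, cal.wavelengths, cal.offset)
    return raw.with_values(gain * raw.values + offset, kind=kind)


# ---------------------------------------------------------------------------
# Quality screening
# ---------------------------------------------------------------------------

@dataclass
class QualityReport:
    """Per-acquisition quality flags.

    ``flags`` maps spectrum_ref → one of ``ok | noisy | outlier |
    untestable`` (untestable: ring too small for the outlier test).
    """

    flags: dict[str, str] = field(default_factory=dict)

    def count(self, flag: str) -> int:
        return sum(1 for f in self.flags.values() if f == flag)


def _noise_metric(values: np.ndarray) -> float:
    """Robust high-frequency content: median |second difference| relative
    to the median signal level."""
    if values.size < 3:
        return 0.0
    level = float(np.median(np.abs(values)))
    if level == 0.0:
        return 0.0
    return float(np.median(np.abs(np.diff(values, n=2)))) / level


def quality_screen(
    session: SessionManifest,
    spectra: Mapping[str, Spectrum],
    noise_threshold: float = 0.02,
    outlier_mad_multiple: float = 5.0,
) -> QualityReport:
    """Automatic screening of target acquisitions for noise and outliers.

    Noise test: the median absolute second difference of the spectrum,
    relative to its median level, must stay below ``noise_threshold``
    (clean field spectra at 1.5 nm sampling are smooth at that scale).

    Outlier test: within each view-zenith ring, an acquisition's broadband
    level (mean value) must lie within ``outlier_mad_multiple`` median
    absolute deviations of the ring median.  Rings with fewer than three
    members cannot support the test and are flagged ``untestable``.
    """
    report = QualityReport()
    targets = session.target_acquisitions()
    for acq in targets:
        if acq.spectrum_ref not in spectra:
            raise KeyError(f"spectrum {acq.spectrum_ref!r} referenced but not provided")
    rings: dict[float, list[Acquisition]] = {}
    for acq in targets:
        rings.setdefault(float(acq.view_zenith), []).append(acq)

    for zen, members in rings.items():
        levels = np.array([float(np.mean(spectra[a.spectrum_ref].values)) for a in members])
        testable = len(members) >= 3
        if testable:
            med = np.median(levels)
            mad = np.median(np.abs(levels - med))
        for acq, level in zip(members, levels):
            vals = spectra[acq.spectrum_ref].values
            if _noise_metric(vals) > noise_threshold:
                report.flags[acq.spectrum_ref] = "noisy"
            elif not testable:
                report.flags[acq.spectrum_ref] = "untestable"
            elif mad > 0 and abs(level - med) > outlier_mad_multiple * mad:
                report.flags[acq.spectrum_ref] = "outlier"
            elif mad == 0 and level != med:
                report.flags[acq.spectrum_ref] = "outlier"
            else:
                report.flags[acq.spectrum_ref] = "ok"
    return report
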