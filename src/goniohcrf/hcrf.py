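"""Reflectance-factor mathematics for dual-beam goniometer sessions.

A session measures target radiance :math:`L_r` at each view position, the
radiance :math:`L_{ref}` of a Spectralon reference panel at nadir at the
start (and usually the end) of the scheme, and a continuous irradiance
series :math:`E_{diff}` from a second, cosine-receptor radiometer.  The
hemispherical conical reflectance factor is

.. math::

   HCRF(\\lambda) = \\frac{L_r(\\lambda; t_x)}
        {L_{ref}(\\lambda; t_0)\\; c_{diff}(\\lambda; t_x)\\; c_{ref}(\\lambda, \\theta_i)}

where :math:`c_{diff}(\\lambda; t_x) = E_{diff}(\\lambda; t_x) /
E_{diff}(\\lambda; t_0)` interpolates the panel measurement in time
(cancelling multiplicative irradiance drift) and :math:`c_{ref}` corrects
the panel's non-Lambertian response at the current sun zenith angle.

Derived quantities: the anisotropy factor ANIF (HCRF normalised by the
nadir HCRF), the anisotropy index ANIX (max/min HCRF within an azimuth
plane, per wavelength), angular vegetation indices, and a drift indicator
that flags view positions acquired under strong illumination change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import MeasurementScheme, SolarGeometry, ViewGeometry

__all__ = [
    "PanelCalibration",
    "IrradianceSeries",
    "HemisphereDataset",
    "AnisotropySummary",
    "c_diff",
    "hcrf",
    "brf_panel",
    "anif",
    "anix",
    "drift_indicator",
    "DriftReport",
    "vi_angular",
    "VISIBLE_BAND_NM",
    "NIR_BAND_NM",
    "DEFAULT_RED_NM",
    "DEFAULT_NIR_NM",
]

#: Wavelength regions used for band summaries (nm); the NIR region is
#: truncated at the instrument's 1050 nm limit.
VISIBLE_BAND_NM = (400.0, 700.0)
NIR_BAND_NM = (700.0, 1050.0)

#: Default vegetation-index bands (nm): chlorophyll-absorption red and
#: NIR-plateau wavelengths.
DEFAULT_RED_NM = 672.0
DEFAULT_NIR_NM = 864.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelCalibration:
    """Reference-panel calibration.

    ``r_ref`` is the panel's per-wavelength correction coefficient at the
    8° hemispherical calibration geometry, in the reciprocal form the
    reflectance equation divides by: ``1 / panel reflectance factor``,
    slightly above 1 for a ~99 % Spectralon panel.  ``c_ref_fn``, if
    given, maps ``(wavelengths, sun_zenith)`` to the full non-Lambertian
    correction divisor; when absent the panel anisotropy is ignored and
    ``c_ref == r_ref``.
    """

    wavelengths: np.ndarray
    r_ref: np.ndarray
    c_ref_fn: Callable[[np.ndarray, float], np.ndarray] | None = None
    source: str = "identity"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        r = np.asarray(self.r_ref, float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "r_ref", r)
        if wl.shape != r.shape:
            raise ValueError("wavelengths and r_ref must have equal length")
        if np.any(r <= 0) or np.any(r > 1.05):
            raise ValueError("r_ref must lie in (0, 1.05]")

    def c_ref(self, wavelengths: np.ndarray, sun_zenith: float) -> np.ndarray:
        """Correction factor on the given grid for the given sun zenith."""
        wavelengths = np.asarray(wavelengths, float)
        if self.c_ref_fn is None:
            out = np.interp(wavelengths, self.wavelengths, self.r_ref)
        else:
            out = np.asarray(self.c_ref_fn(wavelengths, sun_zenith), float)
        if np.any(out <= 0):
            raise ValueError("c_ref must be strictly positive")
        return out


@dataclass(frozen=True)
class IrradianceSeries:
    """Continuous irradiance record: one spectrum per timestamp."""

    timestamps: tuple[datetime, ...]
    wavelengths: np.ndarray
    values: np.ndarray  # shape (n_times, n_wavelengths)

    def __post_init__(self) -> None:
        object.__setattr__(self, "timestamps", tuple(self.timestamps))
        wl = np.asarray(self.wavelengths, float)
        vals = np.asarray(self.values, float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.timestamps), wl.size):
            raise ValueError("values must be (n_times, n_wavelengths)")
        secs = [t.timestamp() for t in self.timestamps]
        if np.any(np.diff(secs) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def span(self) -> tuple[datetime, datetime]:
        return self.timestamps[0], self.timestamps[-1]

    def at(self, t: datetime, tolerance_s: float = 5.0) -> np.ndarray:
        """Irradiance spectrum at time ``t``.

        Nearest sample if within ``tolerance_s`` seconds; otherwise linear
        interpolation between the bracketing samples.  ``t`` must lie
        within the recorded span.
        """
        secs = np.array([ts.timestamp() for ts in self.timestamps])
        ts = t.timestamp()
        if ts < secs[0] - tolerance_s or ts > secs[-1] + tolerance_s:
            raise ValueError(f"time {t.isoformat()} outside irradiance record span")
        i = int(np.argmin(np.abs(secs - ts)))
        if abs(secs[i] - ts) <= tolerance_s:
            return self.values[i]
        hi = int(np.searchsorted(secs, ts))
        lo = hi - 1
        w = (ts - secs[lo]) / (secs[hi] - secs[lo])
        return (1 - w) * self.values[lo] + w * self.values[hi]


@dataclass
class HemisphereDataset:
    """HCRF (and derived) values on the scheme grid × wavelength grid."""

    scheme: MeasurementScheme
    sun: SolarGeometry
    wavelengths: np.ndarray
    positions: list[ViewGeometry]
    timestamps: list[datetime]
    hcrf: np.ndarray  # (n_positions, n_wavelengths)
    flags: list[str] = field(default_factory=list)
    drift: np.ndarray | None = None
    anif: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.hcrf = np.asarray(self.hcrf, float)
        n_pos, n_wl = len(self.positions), self.wavelengths.size
        if self.hcrf.shape != (n_pos, n_wl):
            raise ValueError("hcrf must be (n_positions, n_wavelengths)")
        if np.any(self.hcrf < 0):
            raise ValueError("hcrf must be non-negative")
        if not self.flags:
            self.flags = ["ok"] * n_pos
        if len(self.timestamps) != n_pos or len(self.flags) != n_pos:
            raise ValueError("positions, timestamps and flags must align")

    # -- position helpers ---------------------------------------------------

    def nadir_index(self) -> int:
        for i, p in enumerate(self.positions):
            if p.view_zenith == 0.0:
                return i
        raise ValueError("dataset has no nadir position")

    def plane_indices(self, plane_azimuths: tuple[float, float],
                      tolerance: float = 7.5) -> list[int]:
        """Indices of positions in the azimuth plane (nadir always included)."""
        out = []
        for i, p in enumerate(self.positions):
            if p.view_zenith == 0.0:
                out.append(i)
                continue
            for az in plane_azimuths:
                d = abs((p.view_azimuth - az + 180.0) % 360.0 - 180.0)
                if d <= tolerance:
                    out.append(i)
                    break
        return out

    def band_average(self, center_nm: float, halfwidth_nm: float = 5.0) -> np.ndarray:
        """Per-position HCRF averaged over ``center ± halfwidth`` nm."""
        lo, hi = center_nm - halfwidth_nm, center_nm + halfwidth_nm
        if hi < self.wavelengths[0] or lo > self.wavelengths[-1]:
            raise ValueError(f"band {center_nm} nm outside wavelength grid")
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            mask = np.zeros_like(mask)
            mask[int(np.argmin(np.abs(self.wavelengths - center_nm)))] = True
        return self.hcrf[:, mask].mean(axis=1)

    # -- serialization ------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        cols = {
            "position_id": [f"p{i:02d}" for i in range(len(self.positions))],
            "view_zenith": [p.view_zenith for p in self.positions],
            "view_azimuth": [p.view_azimuth for p in self.positions],
            "timestamp": [t.isoformat() for t in self.timestamps],
            "flag": self.flags,
        }
        if self.drift is not None:
            cols["drift_indicator"] = self.drift
        df = pd.DataFrame(cols)
        hc = pd.DataFrame(
            self.hcrf, columns=[f"hcrf_{wl:.1f}" for wl in self.wavelengths]
        )
        return pd.concat([df, hc], axis=1)

    def save(self, path: str | Path) -> None:
        """Tab-separated table with a ``# key: value`` metadata header."""
        path = Path(path)
        header = [
            f"# sun_zenith: {self.sun.sun_zenith:.4f}",
            f"# sun_azimuth: {self.sun.sun_azimuth:.4f}",
        ]
        for k, v in self.metadata.items():
            header.append(f"# {k}: {v}")
        body = self.to_table().to_csv(sep="\t", index=False, float_format="%.10g")
        path.write_text("\n".join(header) + "\n" + body)

    @classmethod
    def load(cls, path: str | Path) -> "HemisphereDataset":
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
        hcols = [c for c in df.columns if c.startswith("hcrf_")]
        wavelengths = np.array([float(c[5:]) for c in hcols])
        positions = [
            ViewGeometry(z, a) for z, a in zip(df["view_zenith"], df["view_azimuth"])
        ]
        sun = SolarGeometry(float(meta.pop("sun_zenith")), float(meta.pop("sun_azimuth")))
        zeniths = sorted({p.view_zenith for p in positions})
        rings = tuple(
            (z, tuple(p.view_azimuth for p in positions if p.view_zenith == z))
            for z in zeniths
        )
        drift = df["drift_indicator"].to_numpy() if "drift_indicator" in df else None
        return cls(
            scheme=MeasurementScheme(rings),
            sun=sun,
            wavelengths=wavelengths,
            positions=positions,
            timestamps=[datetime.fromisoformat(t) for t in df["timestamp"]],
            hcrf=df[hcols].to_numpy(),
            flags=list(df["flag"]),
            drift=drift,
            metadata=meta,
        )


@dataclass(frozen=True)
class AnisotropySummary:
    """ANIX per wavelength for one azimuth plane."""

    plane: str
    plane_azimuths: tuple[float, float]
    wavelengths: np.ndarray
    anix: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.anix) < 1.0 - 1e-12):
            raise ValueError("anix must be >= 1")

    def region_mean(self, band: tuple[float, float]) -> float:
        mask = (self.wavelengths >= band[0]) & (self.wavelengths <= band[1])
        return float(np.mean(self.anix[mask]))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def c_diff(irr: IrradianceSeries, t0: datetime, tx: datetime,
           tolerance_s: float = 5.0) -> np.ndarray:
    """Irradiance drift weight ``E(λ, tx) / E(λ, t0)`` per wavelength."""
    e0 = irr.at(t0, tolerance_s)
    ex = irr.at(tx, tolerance_s)
    if np.any(e0 <= 0):
        raise ValueError("irradiance at t0 must be strictly positive")
    return ex / e0


def _check_grids(*grids: np.ndarray) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape or not np.allclose(g, ref, atol=1e-9):
            raise ValueError("operands are not on a common wavelength grid")


def hcrf(Lr, Lref, cdiff: np.ndarray | float = 1.0,
         cref: np.ndarray | float = 1.0) -> np.ndarray:
    """Hemispherical conical reflectance factor, element-wise.

    ``Lr``/``Lref`` may be `Spectrum` objects (grids are checked) or bare
    arrays on a common grid.  Values above 1 are legitimate and not
    clipped.
    """
    lr, lref = Lr, Lref
    if hasattr(Lr, "wavelengths") and hasattr(Lref, "wavelengths"):
        _check_grids(Lr.wavelengths, Lref.wavelengths)
        lr, lref = Lr.values, Lref.values
    lr = np.asarray(lr, float)
    lref = np.asarray(lref, float)
    denom = lref * np.asarray(cdiff, float) * np.asarray(cref, float)
    if np.any(denom <= 0):
        raise ValueError("HCRF denominator must be strictly positive")
    return lr / denom


def brf_panel(Lr, Lref, Rref: np.ndarray | float) -> np.ndarray:
    """Panel-referenced BRF estimate (single-beam, no drift weighting)."""
    return hcrf(Lr, Lref, cdiff=1.0, cref=Rref)


def anif(hem: HemisphereDataset) -> np.ndarray:
    """Anisotropy factor: HCRF normalised by the nadir HCRF, per wavelength."""
    i0 = hem.nadir_index()
    nadir = hem.hcrf[i0]
    if np.any(nadir <= 0):
        raise ValueError("nadir HCRF must be strictly positive at all wavelengths")
    out = hem.hcrf / nadir[None, :]
    hem.anif = out
    return out


def anix(hem: HemisphereDataset, plane_azimuths: tuple[float, float] = (0.0, 180.0),
         plane: str = "principal", azimuth_tolerance: float = 7.5) -> AnisotropySummary:
    """Anisotropy index: max/min HCRF over an azimuth plane, per wavelength.

    The plane is the set of scheme positions whose azimuth lies within
    ``azimuth_tolerance`` of either ``plane_azimuths`` entry, plus nadir
    (which belongs to every plane).
    """
    idx = hem.plane_indices(plane_azimuths, azimuth_tolerance)
    if len(idx) < 2:
        raise ValueError(f"azimuth plane {plane_azimuths} has fewer than 2 positions")
    sub = hem.hcrf[idx]
    mins = sub.min(axis=0)
    if np.any(mins <= 0):
        raise ValueError("ANIX undefined: zero HCRF within the plane")
    return AnisotropySummary(
        plane=plane,
        plane_azimuths=plane_azimuths,
        wavelengths=hem.wavelengths,
        anix=sub.max(axis=0) / mins,
    )


# ---------------------------------------------------------------------------
# Drift indicator
# ---------------------------------------------------------------------------

@dataclass
class DriftReport:
    """Per-position drift indicators plus a session consistency score.

    ``indicator[i]`` is the broadband magnitude of the panel interpolation
    applied at position ``i``: ``|mean_λ c_diff(t_i) − 1|``; large values
    mark positions whose HCRF relied on strong temporal extrapolation.
    ``session_score`` compares the c_diff-predicted end-of-session panel
    radiance with the measured one (broadband relative mismatch); ``None``
    when no end panel was recorded.
    """

    indicator: np.ndarray
    caution: np.ndarray
    session_score: float | None
    threshold: float

    @property
    def session_consistent(self) -> bool | None:
        if self.session_score is None:
            return None
        return bool(self.session_score < self.threshold)


def drift_indicator(
    irr: IrradianceSeries,
    Lref_start,
    acquisition_times: Sequence[datetime],
    Lref_end=None,
    t0: datetime | None = None,
    caution_threshold: float = 0.02,
    tolerance_s: float = 5.0,
) -> DriftReport:
    """Flag view positions acquired under strong illumination change.

    ``t0`` defaults to the start-panel timestamp.  ``Lref_start`` /
    ``Lref_end`` may be `Spectrum` objects or bare arrays.
    """
    ts0 = t0 if t0 is not None else getattr(Lref_start, "timestamp", None)
    if ts0 is None:
        raise ValueError("t0 required (no timestamp on Lref_start)")
    ind = np.array([
        abs(float(np.mean(c_diff(irr, ts0, tx, tolerance_s))) - 1.0)
        for tx in acquisition_times
    ])
    score = None
    if Lref_end is not None:
        t_end = getattr(Lref_end, "timestamp", None) or acquisition_times[-1]
        w_end = c_diff(irr, ts0, t_end, tolerance_s)
        start_vals = getattr(Lref_start, "values", Lref_start)
        end_vals = getattr(Lref_end, "values", Lref_end)
        predicted = np.asarray(start_vals, float) * w_end
        measured = np.asarray(end_vals, float)
        score = float(abs(np.mean(predicted) - np.mean(measured)) / np.mean(measured))
    return DriftReport(
        indicator=ind,
        caution=ind > caution_threshold,
        session_score=score,
        threshold=caution_threshold,
    )


# ---------------------------------------------------------------------------
# Angular vegetation indices
# ---------------------------------------------------------------------------

def vi_angular(
    hem: HemisphereDataset,
    red_band: float = DEFAULT_RED_NM,
    nir_band: float = DEFAULT_NIR_NM,
    halfwidth_nm: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position NDVI and nadir-normalised NDVI.

    NDVI uses band-averaged HCRF over ``band ± halfwidth``.  Positions
    with a zero denominator get NaN (undefined, not an error).
    """
    red = hem.band_average(red_band, halfwidth_nm)
    nir = hem.band_average(nir_band, halfwidth_nm)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom != 0, (nir - red) / denom, np.nan)
    nadir_ndvi = ndvi[hem.nadir_index()]
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = ndvi / nadir_ndvi if nadir_ndvi not in (0,) else np.full_like(ndvi, np.nan)
    return ndvi, normalized
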