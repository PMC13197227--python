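"""Helical-lattice characterization of an averaged desmotubule coat.

Density on a cylinder of fixed radius about the tubule axis is laid out as
a periodic (azimuth, axial) sheet; an n-start helical coat appears there as
n parallel tilted stripes per axial period.  A 2D Fourier analysis of the
sheet then reads off the start number as the azimuthal order of the
dominant non-DC peak and the pitch of one wrap from the peak's axial
frequency (pitch = m / k_z for the peak at azimuthal order m).

Averages computed from surface-oriented particles contain only a patch of
the cylinder; out-of-box samples carry zero weight and the windowed
spectrum is analysed in the same way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = ["UnwrappedSheet", "LatticeResult", "unwrap_cylinder", "estimate_starts_and_pitch", "scan_radius"]

logger = logging.getLogger(__name__)


@dataclass
class UnwrappedSheet:
    """Density sampled on a cylinder, indexed [azimuth, axial]."""

    grid: np.ndarray
    radius_nm: float
    azimuth_step_deg: float
    axial_step_nm: float
    valid: np.ndarray  # in-box sampling weight, same shape as grid

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius must be positive")

    @property
    def axial_extent_nm(self) -> float:
        return self.grid.shape[1] * self.axial_step_nm


@dataclass
class LatticeResult:
    n_starts: int
    pitch_nm: float
    confidence: float
    radius_nm: float
    flag: str = "ok"  # ok | indeterminate | rings

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_starts": int(self.n_starts),
                    "pitch_nm": None if np.isnan(self.pitch_nm) else float(self.pitch_nm),
                    "confidence": float(self.confidence),
                    "radius_nm": float(self.radius_nm),
                    "flag": self.flag,
                },
                fh,
                indent=1,
            )


def unwrap_cylinder(
    vol: Volume,
    axis_point_nm: np.ndarray,
    axis_dir: np.ndarray,
    radius_nm: float,
    azimuth_step_deg: float = 3.0,
    axial_step_nm: float = 0.5,
    axial_range_nm: tuple[float, float] | None = None,
    azimuth_range_deg: tuple[float, float] | None = None,
) -> UnwrappedSheet:
    """Interpolate density on a cylinder about an axis line.

    ``axis_point_nm`` is any point on the axis; ``axis_dir`` its direction.
    Samples falling outside the volume get value 0 and weight 0 in
    ``valid``.  The default axial range spans the box extent along the axis.
    ``azimuth_range_deg`` zero-weights azimuths outside the given window —
    used for patch averages where only part of the cylinder carries signal.
    """
    p0 = np.asarray(axis_point_nm, dtype=float)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    extent = np.array(vol.shape) * vol.voxel_size_nm
    if radius_nm <= 0 or radius_nm > extent.max():
        raise ValueError("radius outside volume")
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = a - d * (a @ d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    if axial_range_nm is None:
        # projections of the box corners onto the axis, relative to p0
        corners = np.array(
            [[i * extent[0], j * extent[1], k * extent[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        ) + vol.origin_nm
        proj = (corners - p0) @ d
        axial_range_nm = (float(proj.min()), float(proj.max()))
    az = np.arange(0.0, 360.0, azimuth_step_deg)
    ax = np.arange(axial_range_nm[0], axial_range_nm[1] + 1e-9, axial_step_nm)
    azr = np.radians(az)[:, None, None]
    points = (
        p0[None, None, :]
        + ax[None, :, None] * d[None, None, :]
        + radius_nm * (np.cos(azr) * u[None, None, :] + np.sin(azr) * v[None, None, :])
    )
    idx = (points - vol.origin_nm) / vol.voxel_size_nm
    coords = np.moveaxis(idx, -1, 0)
    grid = ndimage.map_coordinates(vol.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0)
    shape = np.array(vol.shape)
    inb = np.all((idx >= 0) & (idx <= shape - 1), axis=-1).astype(float)
    if azimuth_range_deg is not None:
        lo, hi = azimuth_range_deg
        inb *= ((az >= lo) & (az <= hi))[:, None]
    return UnwrappedSheet(grid, radius_nm, azimuth_step_deg, axial_step_nm, inb)


def estimate_starts_and_pitch(
    sheet: UnwrappedSheet,
    max_starts: int = 8,
    confidence_floor: float = 0.1,
    axial_pad: int = 4,
) -> LatticeResult:
    """Count helical starts and estimate pitch from a 2D Fourier peak.

    The dominant non-DC peak of the (windowed) sheet spectrum is located;
    its azimuthal order is the start count and the pitch of one wrap is
    ``m / |k_z|``.  Peaks with azimuthal order zero are flagged ``rings``;
    spectra without a peak above ``confidence_floor`` of the non-DC power
    are flagged ``indeterminate``.  Ties between orders break toward the
    lower order with a logged warning.
    """
    w = sheet.valid
    f = sheet.grid
    tot_w = w.sum()
    if tot_w <= 0:
        return LatticeResult(0, np.nan, 0.0, sheet.radius_nm, "indeterminate")
    n_az, n_ax = f.shape
    kz = np.fft.fftfreq(axial_pad * n_ax, d=sheet.axial_step_nm)
    m_max = min(max_starts, n_az // 2)

    # azimuthally uniform structure (membrane bands, ring stacks) lives in
    # the m = 0 row; remove the per-row azimuthal mean so the remaining
    # power is the azimuthally structured (helical) signal
    w_col = w.sum(axis=0)
    row_mean = np.divide(
        (f * w).sum(axis=0), w_col, out=np.zeros(n_ax), where=w_col > 0
    )
    f_det = (f - row_mean[None, :]) * w
    # padded spectrum for sub-bin peak localization; unpadded for power
    # accounting (zero-padding spreads one physical peak over ~pad bins)
    P = np.abs(np.fft.fft2(f_det, s=(n_az, axial_pad * n_ax))) ** 2
    P1 = np.abs(np.fft.fft2(f_det)) ** 2
    kz1 = np.fft.fftfreq(n_ax, d=sheet.axial_step_nm)
    total = P1[1 : n_az // 2 + 1].sum()  # half-spectrum, Friedel mates excluded
    best = (0.0, 1, 0.0)  # padded power, m, kz
    for m in range(1, m_max + 1):
        j = int(np.argmax(P[m]))
        if P[m, j] > best[0]:
            best = (P[m, j], m, kz[j])
    power, m, kz_peak = best
    # mainlobe energy: unpadded peak bin and its two kz neighbours
    j1 = int(np.argmin(np.abs(kz1 - kz_peak)))
    lobe = sum(P1[m, (j1 + d) % n_ax] for d in (-1, 0, 1))
    confidence = 0.0 if total <= 0 else float(lobe / total)

    if confidence < confidence_floor or total <= 0:
        # no credible helical signal; distinguish achiral ring stacks
        f0 = (f - (f * w).sum() / tot_w) * w
        P0 = np.abs(np.fft.fft2(f0, s=(n_az, axial_pad * n_ax))) ** 2
        ring = P0[0].copy()
        ring[0] = 0.0
        ring[kz < 0] = 0.0
        if ring.max() > max(power, 1e-30) * 3.0:
            return LatticeResult(0, np.nan, confidence, sheet.radius_nm, "rings")
        return LatticeResult(0, np.nan, confidence, sheet.radius_nm, "indeterminate")
    pitch = np.inf if abs(kz_peak) < 1e-12 else m / abs(kz_peak)
    return LatticeResult(int(m), float(pitch), confidence, sheet.radius_nm, "ok")


def scan_radius(
    vol: Volume,
    axis_point_nm,
    axis_dir,
    radius_nm: float,
    scan_nm: float = 2.0,
    scan_step_nm: float = 0.5,
    **kwargs,
) -> tuple[LatticeResult, UnwrappedSheet]:
    """Unwrap at radii within +/- scan_nm and keep the best-confidence result."""
    best: tuple[LatticeResult, UnwrappedSheet] | None = None
    for r in np.arange(radius_nm - scan_nm, radius_nm + scan_nm + 1e-9, scan_step_nm):
        if r <= 1.0:
            continue
        sheet = unwrap_cylinder(vol, axis_point_nm, axis_dir, float(r), **kwargs)
        res = estimate_starts_and_pitch(sheet)
        if best is None or res.confidence > best[0].confidence:
            best = (res, sheet)
    assert best is not None
    return best
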