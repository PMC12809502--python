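"""Detector-space geometry utilities.

Coordinate conventions used throughout:

* pixels are 0-based with centers at integer coordinates; ``x`` is the
  fast axis (array column), ``y`` the slow axis (array row);
* the beam travels along +z in the laboratory frame, the detector plane
  sits at ``detector_distance`` mm;
* the rotation axis lies in the detector plane at azimuth ``phi_axis``
  degrees counter-clockwise from +x; a positive frame increment rotates
  the crystal counter-clockwise about that axis viewed against the beam
  (flip with ``sense=-1`` for hardware with the opposite handedness).

Beam-center search without a beamstop takes the intensity centroid of the
brightest connected blob; with a beamstop it exploits Friedel symmetry of
the diffraction pattern — the pattern correlates best with its own 180
degree rotation when mirrored about the true center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .formats import SmvImage

logger = logging.getLogger("edbatch")

__all__ = ["ExperimentGeometry", "find_beam_center", "spots_to_reciprocal",
           "refine_rotation_axis"]


@dataclass(frozen=True)
class ExperimentGeometry:
    wavelength: float                # Å
    detector_distance: float         # mm
    pixel_size: float                # mm
    beam_center: tuple[float, float]  # (x, y) pixels
    rotation_axis_azimuth: float = 0.0  # degrees in [-180, 180)
    oscillation_per_frame: float = 0.23  # degrees/frame
    sense: int = 1                   # rotation handedness

    def __post_init__(self) -> None:
        if min(self.wavelength, self.detector_distance, self.pixel_size) <= 0:
            raise ValueError("wavelength, distance and pixel size must be "
                             "positive")
        if not -180.0 <= self.rotation_axis_azimuth < 180.0:
            raise ValueError("axis azimuth must lie in [-180, 180)")

    @property
    def axis(self) -> np.ndarray:
        az = np.radians(self.rotation_axis_azimuth)
        return np.array([np.cos(az), np.sin(az), 0.0])


# ---------------------------------------------------------------------------
# Beam center
# ---------------------------------------------------------------------------

def find_beam_center(image: SmvImage, beamstop: bool = False,
                     search_radius: int = 64,
                     shadow_floor: float | None = None
                     ) -> tuple[float, float]:
    """Locate the direct-beam position on the detector, in pixels (x, y).

    ``beamstop=False``: median-filter the image and take the
    intensity-weighted centroid of the connected blob containing the
    brightest pixel.

    ``beamstop=True``: maximize the correlation between the pattern and
    its 180-degree-rotated copy over integer shifts within
    ``search_radius`` pixels of the geometric image center (Friedel
    symmetry); the center is half the optimal shift, refined to sub-pixel
    by parabolic interpolation.  Pixels below ``shadow_floor`` (default:
    half the image median) are treated as beamstop shadow and masked out.
    """
    img = np.asarray(image.pixels, dtype=float)
    if img.size == 0 or img.max() == img.min():
        raise ValueError("no features: image is flat")
    if not beamstop:
        filt = ndimage.median_filter(img, size=3)
        bg = float(np.median(filt))
        thr = bg + 0.5 * (filt.max() - bg)
        labels, _ = ndimage.label(filt >= thr)
        peak = np.unravel_index(np.argmax(filt), filt.shape)
        blob = labels == labels[peak]
        weights = np.where(blob, np.maximum(img - bg, 0.0), 0.0)
        total = weights.sum()
        if total <= 0:
            raise ValueError("no features: empty central blob")
        yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
        return (float((weights * xx).sum() / total),
                float((weights * yy).sum() / total))

    if shadow_floor is None:
        shadow_floor = 0.5 * float(np.median(img))
    mask = img > shadow_floor
    if mask.sum() < 16:
        raise ValueError("no features: beamstop shadow covers the image")
    v = np.where(mask, img - img[mask].mean(), 0.0)
    m = mask.astype(float)
    ny, nx = img.shape
    # autoconvolution C(u) = sum_x v(x) v(u-x): peak at u = 2*center
    shape = (2 * ny, 2 * nx)
    F = np.fft.rfft2(v, s=shape)
    C = np.fft.irfft2(F * F, s=shape)
    Fm = np.fft.rfft2(m, s=shape)
    O = np.fft.irfft2(Fm * Fm, s=shape)
    score = np.where(O > 0.05 * O.max(), C / np.maximum(O, 1.0), -np.inf)

    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    uy = np.arange(shape[0])
    ux = np.arange(shape[1])
    win = (np.abs(uy[:, None] / 2.0 - cy0) <= search_radius) & \
          (np.abs(ux[None, :] / 2.0 - cx0) <= search_radius)
    score = np.where(win, score, -np.inf)
    iy, ix = np.unravel_index(np.argmax(score), score.shape)

    def parabolic(s, i, n):
        if 0 < i < n - 1 and np.isfinite(s[i - 1]) and np.isfinite(s[i + 1]):
            denom = s[i - 1] - 2 * s[i] + s[i + 1]
            if denom < 0:
                return i + 0.5 * (s[i - 1] - s[i + 1]) / denom
        return float(i)

    uy_ref = parabolic(score[:, ix], iy, shape[0])
    ux_ref = parabolic(score[iy, :], ix, shape[1])
    return float(ux_ref / 2.0), float(uy_ref / 2.0)


# ---------------------------------------------------------------------------
# Reciprocal mapping
# ---------------------------------------------------------------------------

def spots_to_reciprocal(spots: pd.DataFrame, geometry: ExperimentGeometry,
                        beamstop_radius: float = 0.0) -> np.ndarray:
    """Map detector spots (x, y, frame) to reciprocal vectors (Å⁻¹) in the
    common crystal frame.

    Each spot defines an Ewald-sphere scattering vector
    s = k_out − k_in with |k| = 1/λ, which is then back-rotated by the
    frame's rotation angle about the axis.  |s| equals 1/d of the spot's
    resolution.  Spots within ``beamstop_radius`` pixels of the beam
    center are skipped (logged count).
    """
    x = spots["x"].to_numpy(dtype=float)
    y = spots["y"].to_numpy(dtype=float)
    frame = spots["frame"].to_numpy(dtype=float)
    cx, cy = geometry.beam_center
    rx = (x - cx) * geometry.pixel_size
    ry = (y - cy) * geometry.pixel_size
    if beamstop_radius > 0:
        r_px = np.hypot(x - cx, y - cy)
        keep = r_px >= beamstop_radius
        skipped = int((~keep).sum())
        if skipped:
            logger.info("spots_to_reciprocal: skipped %d spot(s) inside "
                        "beamstop radius", skipped)
        rx, ry, frame = rx[keep], ry[keep], frame[keep]

    D = geometry.detector_distance
    norm = np.sqrt(rx ** 2 + ry ** 2 + D ** 2)
    inv_lam = 1.0 / geometry.wavelength
    k_out = inv_lam * np.column_stack([rx / norm, ry / norm, D / norm])
    s = k_out - np.array([0.0, 0.0, inv_lam])

    angles = -np.radians(geometry.sense * frame
                         * geometry.oscillation_per_frame)
    u = geometry.axis
    # Rodrigues rotation, vectorized over per-spot angles
    cosa = np.cos(angles)[:, None]
    sina = np.sin(angles)[:, None]
    s_par = (s @ u)[:, None] * u[None, :]
    s_perp = s - s_par
    u_cross = np.cross(np.broadcast_to(u, s.shape), s_perp)
    return s_par + s_perp * cosa + u_cross * sina


# ---------------------------------------------------------------------------
# Rotation-axis refinement
# ---------------------------------------------------------------------------

def _axis_score(spots: pd.DataFrame, geometry: ExperimentGeometry,
                azimuth: float, n_bins_azimuth: int = 180,
                n_bins_elevation: int = 90) -> float:
    """Sharpness of the cylindrical projection about a candidate axis:
    negative Shannon entropy of the 2-D (azimuth x elevation) angular
    histogram, 2-degree bins, of the back-rotated scattering vectors.

    With the correct axis, repeat observations of the same reciprocal
    lattice point (a point crosses the Ewald sphere twice per turn) land
    in the same fine histogram cell, concentrating the distribution; a
    wrong axis scatters them and raises the entropy.  The bins must be
    fine for this coincidence signal to survive, and a 1-D azimuthal
    histogram alone cannot discriminate at all: for the nearly flat
    electron Ewald sphere the lab-frame azimuth about any in-plane axis
    is ~(+-90 deg - phi) regardless of the candidate, so the elevation
    coordinate carries the signal."""
    geom = replace(geometry, rotation_axis_azimuth=azimuth)
    v = spots_to_reciprocal(spots, geom)
    u = geom.axis
    e1 = np.array([0.0, 0.0, 1.0])        # perpendicular to any in-plane axis
    e2 = np.cross(u, e1)
    p_axis = v @ u
    p1, p2 = v @ e1, v @ e2
    psi = np.arctan2(p2, p1)
    elev = np.arctan2(p_axis, np.hypot(p1, p2))
    hist, _, _ = np.histogram2d(
        psi, elev, bins=(n_bins_azimuth, n_bins_elevation),
        range=((-np.pi, np.pi), (-np.pi / 2, np.pi / 2)))
    p = hist.ravel() / max(hist.sum(), 1)
    p = p[p > 0]
    return float(np.sum(p * np.log(p)))   # = -entropy


def refine_rotation_axis(spots: pd.DataFrame, geometry: ExperimentGeometry,
                         coarse_step: float = 1.0, fine_step: float = 0.02,
                         fine_halfwidth: float = 1.5
                         ) -> tuple[float, float]:
    """Refine the in-plane rotation-axis azimuth from a spot list.

    Scans a coarse 1-degree grid over [-180, 180), then a fine grid around
    the best candidate; returns (azimuth_degrees, score).  Requires at
    least 200 spots spanning at least 10 frames.
    """
    if len(spots) < 200:
        raise ValueError("rotation-axis refinement needs >= 200 spots")
    n_frames = len(np.unique(np.floor(spots["frame"].to_numpy())))
    if n_frames < 10:
        raise ValueError("insufficient rotation range: spots span "
                         f"{n_frames} frame(s), need >= 10")
    coarse = np.arange(-180.0, 180.0, coarse_step)
    scores = np.array([_axis_score(spots, geometry, a) for a in coarse])
    best = coarse[int(np.argmax(scores))]
    fine = np.arange(best - fine_halfwidth, best + fine_halfwidth + fine_step,
                     fine_step)
    fine = np.array([((a + 180.0) % 360.0) - 180.0 for a in fine])
    fscores = np.array([_axis_score(spots, geometry, a) for a in fine])
    i = int(np.argmax(fscores))
    return float(fine[i]), float(fscores[i])
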