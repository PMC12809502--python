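"""Synthetic data with known ground truth.

Everything the test surface needs is generated here, deterministically
under a seed:

* Wilson-distributed (exponential) true intensities, one per asu orbit;
* wedge datasets by an exact Ewald-sphere sweep — a reflection is observed
  when its reciprocal point crosses the sphere during the wedge rotation,
  solved in closed form (the crossing condition is sinusoidal in the
  rotation angle), so completeness oracles are exact;
* planted scale factors, B-factors, error models (a, b), outlier frames,
  beam-damage decay, mis-indexing and cluster structure;
* synthetic SMV beam images (Gaussian direct beam or Friedel-symmetric
  spot field with a wedge beamstop) and spot lists with known axis azimuth.

The emulated conditions follow small-molecule / small-wedge electron
diffraction practice: 200 kV electrons (λ = 0.0251 Å), 0.23°/frame
oscillation, wedges of 15–130°, Wilson mean intensity 1000 on an arbitrary
detector scale, counting-statistics sigmas with background 100.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import (DatasetHeader, DatasetRecord, SmvImage, UnitCell,
                      write_xds_ascii)
from .geometry import ExperimentGeometry
from .symmetry import LaueGroup, ReindexOp, enumerate_unique, laue_operators

__all__ = [
    "GroundTruth", "WedgeSpec", "make_ground_truth", "make_dataset",
    "make_cluster_fixture", "make_beam_image", "make_spot_list",
    "sweep_observed_orbits", "write_fixture_tree",
]

DEFAULT_WAVELENGTH = 0.0251   # Å, 200 kV electrons
DEFAULT_BACKGROUND = 100.0    # counts², floor of the counting variance
DEFAULT_MEAN_INTENSITY = 1000.0


@dataclass
class GroundTruth:
    cell: UnitCell
    laue: LaueGroup
    d_max: float
    d_min: float
    hkl: np.ndarray          # (U, 3) asu representatives
    intensity: np.ndarray    # (U,) exponential-distributed means
    seed: int

    @property
    def n_unique(self) -> int:
        return len(self.hkl)


@dataclass
class WedgeSpec:
    """One synthetic acquisition: rotation range, orientation and planted
    distortions."""

    phi_start: float = 0.0
    phi_end: float = 60.0
    oscillation: float = 0.23     # degrees/frame
    orientation: tuple[float, float, float] = (10.0, 20.0, 30.0)  # Euler zyz
    scale: float = 1.0
    b_factor: float = 0.0         # Å²
    error_a: float = 1.0
    error_b: float = 0.0025       # fractional-intensity variance term; ISa=20
    completeness_fraction: float = 1.0
    outlier_frames: list[int] = field(default_factory=list)
    decay_rate: float = 0.0       # per-frame exponential dose factor
    misindex: ReindexOp | None = None

    def __post_init__(self) -> None:
        if self.phi_end <= self.phi_start:
            raise ValueError("empty wedge")
        if not 0.0 < self.completeness_fraction <= 1.0:
            raise ValueError("completeness_fraction must be in (0, 1]")

    @property
    def n_frames(self) -> int:
        return int(math.ceil((self.phi_end - self.phi_start)
                             / self.oscillation))


def make_ground_truth(cell: UnitCell, laue: LaueGroup | str,
                      d_min: float, seed: int, d_max: float = 20.0,
                      mean_intensity: float = DEFAULT_MEAN_INTENSITY
                      ) -> GroundTruth:
    """Exponential (Wilson) intensities, one per asu orbit in the window."""
    if isinstance(laue, str):
        laue = laue_operators(laue)
    hkl = enumerate_unique(cell, laue, d_max, d_min)
    rng = np.random.default_rng(seed)
    intensity = rng.exponential(mean_intensity, size=len(hkl))
    return GroundTruth(cell=cell, laue=laue, d_max=d_max, d_min=d_min,
                       hkl=hkl, intensity=intensity, seed=seed)


# ---------------------------------------------------------------------------
# Ewald sweep
# ---------------------------------------------------------------------------

def _euler_matrix(angles) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.from_euler("zyz", angles, degrees=True).as_matrix()


def _orbit_mates(truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """All distinct symmetry mates of every orbit: (mate_hkl, orbit_index)."""
    ops = truth.laue.operators
    U = len(truth.hkl)
    mates = np.concatenate([truth.hkl @ op.T for op in ops])
    orbit = np.tile(np.arange(U), len(ops))
    packed = np.concatenate([orbit[:, None], mates], axis=1)
    uniq = np.unique(packed, axis=0)
    return uniq[:, 1:], uniq[:, 0]


def _crossings(v: np.ndarray, wavelength: float,
               phi_start: float, phi_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotation angles (degrees) in [phi_start, phi_end] at which reciprocal
    points v cross the Ewald sphere, rotating about the lab x axis.

    The crossing condition |R(φ)v + k_in|² = 1/λ² reduces to
    Rc·cos(φ − δ) = −|v|²λ/2 with Rc = hypot(v_y, v_z), δ = atan2(v_y, v_z):
    closed-form roots, two per turn.
    Returns (point_index, phi_degrees) pairs.
    """
    v = np.atleast_2d(v)
    vsq = (v ** 2).sum(axis=1)
    Rc = np.hypot(v[:, 1], v[:, 2])
    delta = np.arctan2(v[:, 1], v[:, 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -vsq * wavelength / (2.0 * Rc)
    solvable = (Rc > 0) & (np.abs(t) <= 1.0)
    idx_list, phi_list = [], []
    acos = np.arccos(t[solvable])
    base = delta[solvable]
    ids = np.flatnonzero(solvable)
    for sign in (+1.0, -1.0):
        phi = np.degrees(base + sign * acos)
        # bring each root into [phi_start, phi_start + 360)
        phi = phi_start + np.mod(phi - phi_start, 360.0)
        ok = phi <= phi_end
        idx_list.append(ids[ok])
        phi_list.append(phi[ok])
        # a wedge longer than 360° sees the root again each turn
        span = phi_end - phi_start
        n_extra = int(span // 360.0)
        for n in range(1, n_extra + 1):
            phi2 = phi + 360.0 * n
            ok2 = phi2 <= phi_end
            idx_list.append(ids[ok2])
            phi_list.append(phi2[ok2])
    return np.concatenate(idx_list), np.concatenate(phi_list)


def sweep_observed_orbits(truth: GroundTruth, wedge: WedgeSpec,
                          wavelength: float = DEFAULT_WAVELENGTH
                          ) -> np.ndarray:
    """Orbit indices observable in the wedge (no thinning, no noise) — the
    geometric completeness oracle."""
    R = _euler_matrix(wedge.orientation)
    Bmat = np.linalg.inv(truth.cell.orthogonalization_matrix()).T
    mates, orbit = _orbit_mates(truth)
    v = (R @ Bmat @ mates.T).T
    idx, _ = _crossings(v, wavelength, wedge.phi_start, wedge.phi_end)
    return np.unique(orbit[idx])


def make_dataset(truth: GroundTruth, wedge: WedgeSpec, seed: int,
                 dataset_id: str = "synthetic",
                 wavelength: float = DEFAULT_WAVELENGTH,
                 background: float = DEFAULT_BACKGROUND) -> DatasetRecord:
    """Simulate one wedge dataset from the ground truth.

    Observed intensity per Ewald crossing:
    I_obs = k·exp(−2B s²)·decay(frame)·I_true + ε, with the recorded sigma
    from counting statistics (σ² = I_model + background) and the actual
    noise drawn with variance a·(σ² + b·I_model²) — so the error-model fit
    can recover the planted (a, b).  Outlier frames are scaled ×0.1;
    ``completeness_fraction`` randomly thins whole orbits; a mis-indexing
    operator, if planted, is applied to the output indices last.
    """
    rng = np.random.default_rng(seed)
    R = _euler_matrix(wedge.orientation)
    Bmat = np.linalg.inv(truth.cell.orthogonalization_matrix()).T
    mates, orbit = _orbit_mates(truth)

    if wedge.completeness_fraction < 1.0:
        keep_orbit = rng.random(truth.n_unique) < wedge.completeness_fraction
        sel = keep_orbit[orbit]
        mates, orbit = mates[sel], orbit[sel]

    v = (R @ Bmat @ mates.T).T
    idx, phi = _crossings(v, wavelength, wedge.phi_start, wedge.phi_end)
    if len(idx) == 0:
        raise ValueError("wedge sweeps no reflections")
    hkl = mates[idx]
    orb = orbit[idx]
    frame = 1.0 + (phi - wedge.phi_start) / wedge.oscillation

    d = truth.cell.d_spacing(hkl)
    s2 = 1.0 / (4.0 * d ** 2)
    i_true = truth.intensity[orb]
    model = wedge.scale * np.exp(-2.0 * wedge.b_factor * s2) * i_true
    if wedge.decay_rate:
        model = model * np.exp(-wedge.decay_rate * (frame - 1.0))
    if wedge.outlier_frames:
        bad = np.isin(np.floor(frame).astype(int), wedge.outlier_frames)
        model = np.where(bad, 0.1 * model, model)

    sigma = np.sqrt(np.maximum(model, 0.0) + background)
    noise_sd = np.sqrt(wedge.error_a * (sigma ** 2
                                        + wedge.error_b * model ** 2))
    i_obs = model + rng.normal(0.0, 1.0, size=len(model)) * noise_sd

    if wedge.misindex is not None:
        hkl = hkl @ wedge.misindex.as_array().T

    n_frames = wedge.n_frames
    header = DatasetHeader(
        unit_cell=truth.cell,
        space_group_number=1,
        wavelength=wavelength,
        oscillation_per_frame=wedge.oscillation,
        frame_range=(1, n_frames + 1),
        beam_center=(256.0, 256.0),
    )
    df = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
        "intensity": i_obs, "sigma": sigma, "frame": frame,
    })
    return DatasetRecord(dataset_id=dataset_id, header=header,
                         reflections=df)


# ---------------------------------------------------------------------------
# Cluster fixtures
# ---------------------------------------------------------------------------

def make_cluster_fixture(n_a: int, n_b: int, separation: float, seed: int,
                         cell: UnitCell | None = None,
                         laue: str = "-1", d_min: float = 1.0,
                         same_cell: bool = False,
                         wedge_range: float = 60.0):
    """Two planted dataset groups with independent intensities.

    Group B's cell lengths are scaled by (1 + separation) unless
    ``same_cell``; per-dataset cell jitter of 0.2% emulates refinement
    scatter.  Returns (datasets, labels, truth_a, truth_b).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each planted group needs at least 2 datasets")
    rng = np.random.default_rng(seed)
    if cell is None:
        cell = UnitCell(12.0, 14.0, 16.0, 85.0, 95.0, 100.0)
    cell_b = cell if same_cell else UnitCell(
        cell.a * (1 + separation), cell.b * (1 + separation),
        cell.c * (1 + separation), cell.alpha, cell.beta, cell.gamma)
    truth_a = make_ground_truth(cell, laue, d_min, seed=int(rng.integers(2**31)))
    truth_b = make_ground_truth(cell_b, laue, d_min, seed=int(rng.integers(2**31)))

    datasets, labels = [], []
    for gi, (truth, n) in enumerate(((truth_a, n_a), (truth_b, n_b))):
        for i in range(n):
            start = float(rng.uniform(0, 300))
            ori = tuple(rng.uniform(0, 360, size=3))
            jitter = 1.0 + 0.002 * rng.standard_normal()
            wedge = WedgeSpec(phi_start=start, phi_end=start + wedge_range,
                              orientation=ori)
            rec = make_dataset(truth, wedge, seed=int(rng.integers(2**31)),
                               dataset_id=f"grp{'ab'[gi]}_{i}")
            c = truth.cell
            rec.header.unit_cell = UnitCell(
                c.a * jitter, c.b * jitter, c.c * jitter,
                c.alpha, c.beta, c.gamma)
            datasets.append(rec)
            labels.append(gi)
    return datasets, labels, truth_a, truth_b


# ---------------------------------------------------------------------------
# Images and spot lists
# ---------------------------------------------------------------------------

def make_beam_image(center: tuple[float, float], beamstop: bool, seed: int,
                    shape: tuple[int, int] = (256, 256),
                    background: float = 20.0) -> SmvImage:
    """Synthetic SMV image with a known beam position.

    Without a beamstop: Poisson background plus a Gaussian direct beam at
    ``center``.  With a beamstop: a Friedel-symmetric spot field around
    ``center`` with a wedge-shaped shadow (pixels zeroed) over the center.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    img = rng.poisson(background, size=shape).astype(float)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = center
    if not beamstop:
        img += 30000.0 * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                / (2 * 3.0 ** 2))
    else:
        n_spots = 60
        r = rng.uniform(15, min(nx, ny) * 0.45, size=n_spots)
        theta = rng.uniform(0, 2 * np.pi, size=n_spots)
        amp = rng.uniform(1500, 6000, size=n_spots)
        for ri, ti, ai in zip(r, theta, amp):
            for sgn in (+1, -1):
                px = cx + sgn * ri * np.cos(ti)
                py = cy + sgn * ri * np.sin(ti)
                img += ai * np.exp(-((xx - px) ** 2 + (yy - py) ** 2)
                                   / (2 * 1.5 ** 2))
        # wedge shadow: angular sector around the center plus a stem
        ang = np.arctan2(yy - cy, xx - cx)
        rad = np.hypot(xx - cx, yy - cy)
        shadow = (np.abs(np.mod(ang - 0.4 + np.pi, 2 * np.pi) - np.pi) < 0.35) \
            & (rad < min(nx, ny) * 0.5)
        shadow |= rad < 8
        img[shadow] = 0.0
    header = {
        "DIM": "2", "SIZE1": str(nx), "SIZE2": str(ny),
        "PIXEL_SIZE": "0.0550", "DISTANCE": "958",
        "WAVELENGTH": "0.0251", "OSC_START": "0.0", "OSC_RANGE": "0.23",
        "BEAM_CENTER_X": f"{cx * 0.055:.4f}",
        "BEAM_CENTER_Y": f"{cy * 0.055:.4f}",
    }
    return SmvImage(header=header,
                    pixels=np.clip(img, 0, 65535).astype(np.uint16))


def make_spot_list(cell: UnitCell, orientation, phi_axis: float,
                   geometry: ExperimentGeometry, seed: int,
                   n_frames: int = 100, d_min: float = 1.0,
                   jitter_px: float = 0.3) -> pd.DataFrame:
    """Detector spot centroids for a lattice rotating about an axis at
    azimuth ``phi_axis`` — exact Ewald-crossing positions plus sub-pixel
    jitter.  Ground truth for rotation-axis refinement."""
    rng = np.random.default_rng(seed)
    laue = laue_operators("-1")
    hkl = enumerate_unique(cell, laue, 50.0, d_min)
    hkl = np.concatenate([hkl, -hkl])   # both Friedel mates diffract
    R = _euler_matrix(orientation)
    Bmat = np.linalg.inv(cell.orthogonalization_matrix()).T
    v = (R @ Bmat @ hkl.T).T

    # rotate about the in-plane axis u: express the crossing condition in
    # the (z, u x .) components of the axis-perpendicular part
    az = math.radians(phi_axis)
    u = np.array([math.cos(az), math.sin(az), 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(u, ez)
    v_par = (v @ u)[:, None] * u
    v_perp = v - v_par
    # z(φ) = (v_perp·ez) cosφ − (v_perp·e2) sinφ for rotation by +φ about u
    a_z = v_perp @ ez
    b_z = np.cross(np.broadcast_to(u, v_perp.shape), v_perp) @ ez
    vsq = (v ** 2).sum(axis=1)
    Rc = np.hypot(a_z, b_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -vsq * geometry.wavelength / (2.0 * Rc)
    delta = np.arctan2(b_z, a_z)
    solvable = (Rc > 0) & (np.abs(t) <= 1)
    phi_max = n_frames * geometry.oscillation_per_frame

    rows = []
    ids = np.flatnonzero(solvable)
    acos = np.arccos(t[solvable])
    for sign in (+1.0, -1.0):
        phi = np.degrees(delta[solvable] + sign * acos) % 360.0
        ok = phi <= phi_max
        for i, p in zip(ids[ok], phi[ok]):
            rows.append((i, p))
    if not rows:
        raise ValueError("no Ewald crossings in the frame range")

    from scipy.spatial.transform import Rotation
    inv_lam = 1.0 / geometry.wavelength
    cx, cy = geometry.beam_center
    out = []
    for i, p in rows:
        Rphi = Rotation.from_rotvec(np.radians(geometry.sense * p) * u)
        s = Rphi.apply(v[i])
        k_out = s + np.array([0.0, 0.0, inv_lam])
        if k_out[2] <= 0:
            continue
        scale = geometry.detector_distance / (k_out[2] * geometry.wavelength
                                              * inv_lam)
        # k_out has magnitude 1/λ: project direction onto detector plane
        px = cx + (k_out[0] / k_out[2]) * geometry.detector_distance \
            / geometry.pixel_size
        py = cy + (k_out[1] / k_out[2]) * geometry.detector_distance \
            / geometry.pixel_size
        if not (0 <= px < 1024 and 0 <= py < 1024):
            continue
        out.append((px + jitter_px * rng.standard_normal(),
                    py + jitter_px * rng.standard_normal(),
                    p / geometry.oscillation_per_frame,
                    1000.0))
    df = pd.DataFrame(out, columns=["x", "y", "frame", "intensity"])
    return df


# ---------------------------------------------------------------------------
# Fixture trees on disk
# ---------------------------------------------------------------------------

def write_fixture_tree(datasets: list[DatasetRecord], root: str | Path,
                       truth_meta: dict | None = None) -> list[Path]:
    """Write each dataset as <root>/<id>/<id>.HKL plus a truth.json with
    the planted parameters."""
    root = Path(root)
    paths = []
    for rec in datasets:
        d = root / rec.dataset_id
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"{rec.dataset_id}.HKL"
        write_xds_ascii(rec, p)
        paths.append(p)
    if truth_meta is not None:
        (root / "truth.json").write_text(json.dumps(truth_meta, indent=1))
    return paths
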