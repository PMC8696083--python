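"""Synthetic tricuspid-valve phantoms.

A phantom case bundles everything one clinical case provides: a multi-frame
grayscale volume sequence with open/close dynamics, a noise-free ground-truth
leaflet label map at the mid-systolic (MS) frame, and a valve annotation
(closed annular curve, A/P/S/L quadrant points, ASC/PSC/APC commissures).

Geometry
--------
The annulus is a saddle-shaped ellipse ``(a cos t, b sin t, h cos 2t)``.
Each leaflet is a thin billowed surface patch swept from the annulus to a
central coaptation zone and restricted to its angular sector; the three
sectors partition the full circle and meet at the commissures.  Surfaces are
sampled densely and voxels within half the leaflet thickness of the nearest
surface sample receive that sample's sector label, which makes the rendered
labels an exact partition.  Frames away from MS open a central orifice by
truncating the patches short of the coaptation zone, following a smooth
phase curve.  Intensity is bright leaflets over a mid-gray myocardial shell
around the annulus and a dark blood pool, degraded by multiplicative
clipped-Gaussian speckle and optional spherical signal-dropout regions.
Noise is applied after label rasterization, so the ground truth is
noise-free by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .core import ImageGrid, LeafletLabelMap, ValveAnnotation, VolumeSequence

__all__ = ["PhantomSpec", "PhantomCase", "make_phantom", "make_dataset"]

#: Intensity levels (arbitrary units before normalization).
_I_LEAFLET = 0.90
_I_MYO = 0.55
_I_BLOOD = 0.10


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic valve; lengths in mm, angles in degrees."""

    annulus_a: float = 9.0          # annulus semi-axis along x (L direction)
    annulus_b: float = 8.0          # annulus semi-axis along y (A direction)
    saddle_height: float = 1.5      # amplitude of the saddle (z = h cos 2t)
    thickness: float = 2.4          # leaflet thickness
    billow: float = 2.5             # mid-leaflet dip below the annular plane
    sector_angles: tuple[float, float, float] = (130.0, 110.0, 120.0)  # anterior, posterior, septal
    n_frames: int = 11
    ms_index: int = 5
    max_opening: float = 0.5        # orifice opening fraction at mid-diastole
    noise_sigma: float = 0.08       # multiplicative speckle std
    dropout_count: int = 0
    dropout_radius: float = 2.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_spacing: float = 0.4       # isotropic, mm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("leaflet thickness must be positive")
        if any(a <= 0 for a in self.sector_angles):
            raise ValueError("sector angles must be positive")
        if abs(sum(self.sector_angles) - 360.0) > 1e-6:
            raise ValueError(f"sector angles must sum to 360, got {sum(self.sector_angles)}")
        if not (0.0 <= self.max_opening <= 1.0):
            raise ValueError("max_opening must lie in [0, 1]")
        if not (0 <= self.ms_index < self.n_frames):
            raise ValueError("ms_index out of range")


@dataclass
class PhantomCase:
    sequence: VolumeSequence
    gt: LeafletLabelMap
    annotation: ValveAnnotation
    spec: PhantomSpec
    seed: int


def _annulus_points(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    return np.stack(
        [
            spec.annulus_a * np.cos(theta),
            spec.annulus_b * np.sin(theta),
            spec.saddle_height * np.cos(2.0 * theta),
        ],
        axis=-1,
    )


def _sector_boundaries(spec: PhantomSpec) -> dict[str, float]:
    """Commissure angles (deg).  Going counter-clockwise from L (0 deg):
    anterior is centred on A (90 deg), then septal around S, posterior around P."""
    ant, post, sept = spec.sector_angles
    asc = 90.0 + ant / 2.0           # anterior-septal boundary
    psc = asc + sept                 # posterior-septal boundary
    apc = psc + post                 # anterior-posterior boundary (== asc - ant mod 360)
    return {"ASC": asc, "PSC": psc, "APC": apc}


def _sector_label(theta_deg: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Leaflet label (1 anterior, 2 posterior, 3 septal) for angles in degrees."""
    ant, post, sept = spec.sector_angles
    asc = _sector_boundaries(spec)["ASC"]
    phi = np.mod(theta_deg - asc, 360.0)
    out = np.full(np.shape(theta_deg), 1, dtype=np.uint8)  # anterior by default
    out[phi < sept + post] = 2
    out[phi < sept] = 3
    return out


def _leaflet_surface_samples(
    spec: PhantomSpec, s_max: float, ds: float
) -> tuple[np.ndarray, np.ndarray]:
    """Sample all leaflet patches for one frame.

    Returns ``(points, labels)`` where ``s`` runs from the annulus (0) toward
    the coaptation centre (1); the patch stops at ``s_max`` (< 1 when the
    orifice is open).
    """
    circumference = math.pi * (3 * (spec.annulus_a + spec.annulus_b)
                               - math.sqrt((3 * spec.annulus_a + spec.annulus_b)
                                           * (spec.annulus_a + 3 * spec.annulus_b)))
    n_theta = max(90, int(circumference / ds))
    radial = max(spec.annulus_a, spec.annulus_b)
    n_s = max(12, int(radial * max(s_max, 1e-3) / ds))
    theta = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
    s = np.linspace(0.0, s_max, n_s)
    tt, ss = np.meshgrid(theta, s, indexing="ij")
    ann = _annulus_points(spec, tt.ravel()).reshape(n_theta, n_s, 3)
    pts = np.empty_like(ann)
    pts[..., 0] = (1.0 - ss) * ann[..., 0]
    pts[..., 1] = (1.0 - ss) * ann[..., 1]
    pts[..., 2] = (1.0 - ss) * ann[..., 2] - spec.billow * np.sin(math.pi * ss)
    labels = np.broadcast_to(
        _sector_label(np.degrees(tt[:, :1]), spec), (n_theta, n_s)
    )
    return pts.reshape(-1, 3), np.ascontiguousarray(labels).reshape(-1)


def _rasterize_leaflets(
    spec: PhantomSpec, grid: ImageGrid, centers_flat: np.ndarray, s_max: float
) -> np.ndarray:
    """Label volume (flat, uint8) for one frame's leaflet geometry."""
    pts, labels = _leaflet_surface_samples(spec, s_max, ds=grid.spacing[0] / 2.0)
    half_t = spec.thickness / 2.0
    # only voxels inside the valve bounding slab can be labeled
    margin = half_t + grid.spacing[0]
    zlim = spec.saddle_height + spec.billow + margin
    mask = (
        (np.abs(centers_flat[:, 2]) <= zlim)
        & (np.abs(centers_flat[:, 0]) <= spec.annulus_a + margin)
        & (np.abs(centers_flat[:, 1]) <= spec.annulus_b + margin)
    )
    out = np.zeros(centers_flat.shape[0], dtype=np.uint8)
    if not mask.any():
        return out
    tree = cKDTree(pts)
    dist, idx = tree.query(centers_flat[mask], distance_upper_bound=half_t)
    hit = np.isfinite(dist)
    sel = np.flatnonzero(mask)[hit]
    out[sel] = labels[idx[hit]]
    return out


def make_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> PhantomCase:
    """Render one deterministic phantom case from ``(spec, seed)``."""
    if spec.thickness < spec.grid_spacing:
        raise ValueError(
            f"grid too coarse: leaflet thickness {spec.thickness} mm is below one voxel "
            f"({spec.grid_spacing} mm); use finer spacing"
        )
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    half_extent = (np.asarray(shape) - 1) / 2.0 * spec.grid_spacing
    grid = ImageGrid(
        shape=shape,
        spacing=(spec.grid_spacing,) * 3,
        origin=tuple(-half_extent),
    )
    centers = grid.voxel_centers().reshape(-1, 3)

    # myocardial shell: a torus-like band around the annulus
    ann_dense = _annulus_points(spec, np.linspace(0, 2 * math.pi, 720, endpoint=False))
    myo = cKDTree(ann_dense).query(centers, distance_upper_bound=3.0)[0]
    myo_mask = np.isfinite(myo)

    phase = 0.5 * (1.0 - np.cos(2.0 * math.pi * (np.arange(spec.n_frames) - spec.ms_index)
                                / spec.n_frames))
    frames: list[np.ndarray] = []
    gt_flat: np.ndarray | None = None
    for f in range(spec.n_frames):
        s_max = 1.0 - spec.max_opening * phase[f]
        lab = _rasterize_leaflets(spec, grid, centers, s_max)
        if f == spec.ms_index:
            gt_flat = lab
        img = np.full(centers.shape[0], _I_BLOOD, dtype=np.float32)
        img[myo_mask] = _I_MYO
        img[lab > 0] = _I_LEAFLET
        # multiplicative speckle; Gaussian clipped at +-3 sigma
        noise = np.clip(rng.standard_normal(img.shape), -3.0, 3.0) * spec.noise_sigma
        img = img * (1.0 + noise.astype(np.float32))
        for _ in range(spec.dropout_count):
            c = rng.uniform(-0.6, 0.6, size=3) * np.array(
                [spec.annulus_a, spec.annulus_b, spec.saddle_height + spec.billow]
            )
            hole = np.linalg.norm(centers - c, axis=1) <= spec.dropout_radius
            img[hole] = _I_BLOOD
        frames.append(np.clip(img, 0.0, None).reshape(shape))

    assert gt_flat is not None
    gt = LeafletLabelMap(labels=gt_flat.reshape(shape), grid=grid)

    n = spec.n_frames
    phase_index = {
        "MS": spec.ms_index,
        "ES": (spec.ms_index + max(1, n // 4)) % n,
        "MD": (spec.ms_index + n // 2) % n,
        "ED": (spec.ms_index + 3 * n // 4) % n,
    }
    sequence = VolumeSequence(frames=frames, grid=grid, phase_index=phase_index)

    theta_curve = np.linspace(0, 2 * math.pi, 24, endpoint=False)
    bounds = _sector_boundaries(spec)
    annotation = ValveAnnotation(
        annulus=_annulus_points(spec, theta_curve),
        quadrant={
            "A": _annulus_points(spec, np.array([math.pi / 2]))[0],
            "P": _annulus_points(spec, np.array([3 * math.pi / 2]))[0],
            "S": _annulus_points(spec, np.array([math.pi]))[0],
            "L": _annulus_points(spec, np.array([0.0]))[0],
        },
        commissures={
            k: _annulus_points(spec, np.array([math.radians(v)]))[0]
            for k, v in bounds.items()
        },
    )
    return PhantomCase(sequence=sequence, gt=gt, annotation=annotation, spec=spec, seed=seed)


def make_dataset(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
    jitter: float = 0.1,
) -> list[PhantomCase]:
    """Generate ``n`` phantoms with bounded uniform perturbations of the spec.

    Jitter scales the annulus axes, saddle height and billow by factors in
    ``[1-jitter, 1+jitter]`` and perturbs the sector split; thickness and the
    grid are left alone so all cases remain representable.  Deterministic
    given ``(base_spec, seed)``; with ``jitter=0`` the cases share geometry
    and differ only in their noise realisation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n)]
    rng = np.random.default_rng(root.generate_state(1)[0] % (2**31))
    cases = []
    for i in range(n):
        if jitter > 0:
            fac = rng.uniform(1 - jitter, 1 + jitter, size=4)
            d_ang = rng.uniform(-jitter * 30, jitter * 30, size=2)
            ant = base_spec.sector_angles[0] + d_ang[0]
            post = base_spec.sector_angles[1] + d_ang[1]
            sect = (ant, post, 360.0 - ant - post)
            spec = replace(
                base_spec,
                annulus_a=base_spec.annulus_a * fac[0],
                annulus_b=base_spec.annulus_b * fac[1],
                saddle_height=base_spec.saddle_height * fac[2],
                billow=base_spec.billow * fac[3],
                sector_angles=sect,
            )
        else:
            rng.uniform(size=6)  # keep the stream aligned with the jittered path
            spec = base_spec
        cases.append(make_phantom(spec, seed=case_seeds[i]))
    return cases
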