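"""Landmark-driven preprocessing: valve coordinate frame, spacing rule,
reorientation/resampling into a fixed ROI, and ground-truth cleanup.

The valve frame is built from the user-placed A and L quadrant landmarks and
the centroid of all four A/P/S/L points: x points from the centroid toward L,
y toward A (orthogonalised against x), z completes a right-handed frame and
approximates the annular-plane normal.  Isotropic resampling uses a maximum
voxel spacing of 0.25 mm while enforcing a minimum leaflet height of 6 voxels:
``spacing = min(0.25, h / 6)`` where ``h`` is the thinnest leaflet's extent
along the valve z axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import SimpleITK as sitk

from .core import ImageGrid, LeafletLabelMap, ValveAnnotation, VolumeSequence
from .io import _array_from_sitk, _sitk_from_array

__all__ = [
    "RigidTransform",
    "ResamplePlan",
    "build_valve_frame",
    "choose_spacing",
    "measure_leaflet_heights",
    "resample_case",
    "clean_labels",
    "MAX_SPACING_MM",
    "MIN_LEAFLET_HEIGHT_VOXELS",
    "DEFAULT_ROI_SHAPE",
]

MAX_SPACING_MM = 0.25
MIN_LEAFLET_HEIGHT_VOXELS = 6
DEFAULT_ROI_SHAPE = (224, 224, 224)

_FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass(frozen=True)
class RigidTransform:
    """Maps world points into the valve frame: ``v = R @ p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - self.translation) @ self.rotation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass(frozen=True)
class ResamplePlan:
    """How a case is brought into the network's fixed ROI."""

    spacing_mm: float
    transform: RigidTransform
    roi_shape: tuple[int, int, int] = DEFAULT_ROI_SHAPE
    resample_enabled: bool = True

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if any(s <= 0 for s in self.roi_shape):
            raise ValueError("roi shape must be positive")


def build_valve_frame(annotation: ValveAnnotation, eps: float = 1e-6) -> RigidTransform:
    """Valve coordinate frame from the A and L landmarks and the APSL centroid."""
    q = annotation.quadrant
    origin = np.mean([q["A"], q["P"], q["S"], q["L"]], axis=0)
    lx = q["L"] - origin
    ay = q["A"] - origin
    if np.linalg.norm(lx) < eps or np.linalg.norm(ay) < eps:
        raise ValueError("degenerate landmarks: L or A coincides with the APSL centroid")
    x = lx / np.linalg.norm(lx)
    cos_angle = abs(np.dot(x, ay) / np.linalg.norm(ay))
    if cos_angle > np.cos(np.radians(1.0)):
        raise ValueError("degenerate landmarks: A-centroid direction is collinear with L-centroid")
    y = ay - np.dot(ay, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.stack([x, y, z], axis=0)  # rows are the valve axes
    return RigidTransform(rotation=R, translation=-R @ origin)


def measure_leaflet_heights(gt: LeafletLabelMap, transform: RigidTransform) -> dict[int, float]:
    """Extent (mm) of each leaflet along the valve-frame z axis.

    Measured as the spread of leaflet voxel centers projected on z.  Leaflets
    are thin roughly parallel to the annular plane, so this is the binding
    dimension for the resampling rule.
    """
    heights: dict[int, float] = {}
    centers = None
    for label in (1, 2, 3):
        idx = np.argwhere(gt.labels == label)
        if idx.size == 0:
            continue
        pts = gt.grid.index_to_physical(idx)
        z = transform.apply(pts)[:, 2]
        heights[label] = float(z.max() - z.min())
    return heights


def choose_spacing(gt: LeafletLabelMap, transform: RigidTransform) -> float:
    """Isotropic spacing: at most 0.25 mm, decreased so the thinnest leaflet
    spans at least 6 voxels along the valve axis."""
    heights = measure_leaflet_heights(gt, transform)
    missing = [lab for lab in (1, 2, 3) if lab not in heights]
    if missing:
        raise ValueError(f"leaflet labels absent from ground truth: {missing}")
    h = min(heights.values())
    return min(MAX_SPACING_MM, h / MIN_LEAFLET_HEIGHT_VOXELS)


def _roi_grid(plan: ResamplePlan, native_spacing: float) -> tuple[ImageGrid, float]:
    spacing = plan.spacing_mm if plan.resample_enabled else native_spacing
    shape = tuple(int(s) for s in plan.roi_shape)
    # APSL centroid (valve-frame origin) sits at the ROI's geometric center
    origin = tuple(-(np.asarray(shape) - 1) / 2.0 * spacing)
    return ImageGrid(shape=shape, spacing=(spacing,) * 3, origin=origin), spacing


def _resample_array(
    arr: np.ndarray,
    grid: ImageGrid,
    out_grid: ImageGrid,
    transform: RigidTransform,
    nearest: bool,
) -> np.ndarray:
    """Resample onto ``out_grid`` (whose coordinates live in the valve frame)."""
    img = _sitk_from_array(
        arr.astype(np.uint8 if nearest else np.float32), grid
    )
    # sitk's resample transform maps output physical points to input points
    A = transform.rotation.T
    b = -transform.rotation.T @ transform.translation
    xf = sitk.AffineTransform(3)
    xf.SetMatrix(tuple(A.ravel()))
    xf.SetTranslation(tuple(b))
    ref = sitk.Image(*out_grid.shape, img.GetPixelID())
    ref.SetSpacing(out_grid.spacing)
    ref.SetOrigin(out_grid.origin)
    ref.SetDirection(out_grid.direction)
    interp = sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear
    out = sitk.Resample(img, ref, xf, interp, 0.0)
    return _array_from_sitk(out)


def resample_case(
    sequence: VolumeSequence,
    gt: LeafletLabelMap,
    annotation: ValveAnnotation,
    plan: ResamplePlan,
    logger=None,
) -> tuple[VolumeSequence, LeafletLabelMap, ValveAnnotation]:
    """Reorient (and optionally resample) a case into the fixed ROI.

    Images are interpolated linearly, labels nearest-neighbor; the annotation
    is mapped into the valve frame.  Voxels sampled outside the source volume
    are zero-filled.  If the annulus does not fit in the ROI a warning is
    logged (never an error).
    """
    native = float(min(sequence.grid.spacing))
    out_grid, spacing = _roi_grid(plan, native)

    half = (np.asarray(out_grid.shape) - 1) / 2.0 * spacing
    ann_v = plan.transform.apply(annotation.annulus)
    overflow = np.maximum(np.abs(ann_v).max(axis=0) - half, 0.0)
    if overflow.max() > 0 and logger is not None:
        logger.warning(
            "annulus exceeds ROI by %s mm at spacing %.3f", np.round(overflow, 2), spacing
        )

    frames = [
        _resample_array(f, sequence.grid, out_grid, plan.transform, nearest=False)
        for f in sequence.frames
    ]
    labels = _resample_array(gt.labels, gt.grid, out_grid, plan.transform, nearest=True)
    new_seq = VolumeSequence(frames=frames, grid=out_grid, phase_index=dict(sequence.phase_index))
    new_gt = LeafletLabelMap(labels=labels.astype(np.uint8), grid=out_grid)
    new_ann = annotation.transformed(plan.transform.apply)
    return new_seq, new_gt, new_ann


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 26-connected component of a binary mask."""
    lab, n = ndi.label(mask, structure=_FULL_CONNECTIVITY)
    if n <= 1:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def clean_labels(
    gt: LeafletLabelMap,
    hole_radius: int = 1,
    max_iterations: int = 20,
) -> LeafletLabelMap:
    """Ground-truth cleanup: per leaflet, keep the largest island, then fill
    holes with an iterative voting filler (radius 1, majority rule)."""
    out = np.zeros_like(gt.labels)
    filler = sitk.VotingBinaryIterativeHoleFillingImageFilter()
    filler.SetRadius([hole_radius] * 3)
    filler.SetMaximumNumberOfIterations(max_iterations)
    filler.SetMajorityThreshold(1)
    filler.SetBackgroundValue(0)
    filler.SetForegroundValue(1)
    for label in gt.present_labels():
        mask = largest_component(gt.labels == label)
        img = _sitk_from_array(mask.astype(np.uint8), gt.grid)
        filled = _array_from_sitk(filler.Execute(img)).astype(bool)
        out[filled] = label
    return LeafletLabelMap(labels=out, grid=gt.grid)
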