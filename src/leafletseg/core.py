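"""Core in-memory containers for valve volumes, labels, and annotations.

All physical coordinates are expressed in millimetres in an LPS frame
(the ITK convention).  Arrays are indexed ``(i, j, k)`` and map to physical
space through :class:`ImageGrid`: ``p = origin + direction @ (spacing * v)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "VolumeSequence",
    "LeafletLabelMap",
    "ValveAnnotation",
    "LEAFLET_NAMES",
    "QUADRANT_NAMES",
    "COMMISSURE_NAMES",
]

#: Label semantics of a :class:`LeafletLabelMap`.
LEAFLET_NAMES = {1: "anterior", 2: "posterior", 3: "septal"}

QUADRANT_NAMES = ("A", "P", "S", "L")
COMMISSURE_NAMES = ("ASC", "PSC", "APC")

#: Cardiac phases that may be annotated on a sequence.
PHASES = ("MS", "MD", "ES", "ED")


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3D voxel lattice: shape, spacing (mm), origin, direction.

    The direction matrix is orthonormal (determinant +1 or -1) and maps voxel
    axes to physical axes.  Voxel ``v`` sits at
    ``origin + direction @ (spacing * v)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1, 0, 0, 0, 1, 0, 0, 0, 1)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        d = self.direction_matrix
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise ValueError("direction matrix is not orthonormal")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        object.__setattr__(self, "direction", tuple(float(x) for x in np.ravel(self.direction)))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices (may be fractional) to physical mm points."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + (idx * np.asarray(self.spacing)) @ self.direction_matrix.T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 3) physical points to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return ((pts - np.asarray(self.origin)) @ self.direction_matrix) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of all voxel centers, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_physical(idx).reshape(*self.shape, 3)

    def approx_equal(self, other: "ImageGrid", tol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class VolumeSequence:
    """Time-ordered 3D grayscale frames sharing one grid.

    ``phase_index`` maps phase names (``MS``, ``MD``, ``ES``, ``ED``) to frame
    indices.  Only the phases actually annotated need to be present.
    """

    frames: list[np.ndarray]
    grid: ImageGrid
    phase_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("sequence must contain at least one frame")
        for i, f in enumerate(self.frames):
            if tuple(f.shape) != self.grid.shape:
                raise ValueError(
                    f"frame {i} shape {f.shape} does not match grid shape {self.grid.shape}"
                )
        for phase, idx in self.phase_index.items():
            if phase not in PHASES:
                raise ValueError(f"unknown phase name {phase!r}")
            if not (0 <= idx < self.n_frames):
                raise ValueError(f"phase {phase} index {idx} out of range [0, {self.n_frames})")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, phase: str) -> np.ndarray:
        if phase not in self.phase_index:
            raise KeyError(f"phase {phase!r} is not annotated on this sequence")
        return self.frames[self.phase_index[phase]]


@dataclass
class LeafletLabelMap:
    """Integer leaflet labels on a grid: 0 background, 1 anterior, 2 posterior, 3 septal."""

    labels: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must have an integer dtype")
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label array shape does not match grid shape")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"label values outside {{0,1,2,3}}: {sorted(bad)}")

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def merged_mask(self) -> np.ndarray:
        """Union of the three leaflets as a single binary mask."""
        return self.labels > 0

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]


@dataclass
class ValveAnnotation:
    """Annular curve plus quadrant and commissural landmarks, in physical mm.

    ``annulus`` is an ordered closed polyline (the closing segment from the
    last point back to the first is implicit).  ``quadrant`` holds the A, P,
    S, L points and ``commissures`` the ASC, PSC, APC points.
    """

    annulus: np.ndarray
    quadrant: dict[str, np.ndarray]
    commissures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.annulus = np.asarray(self.annulus, dtype=float)
        if self.annulus.ndim != 2 or self.annulus.shape[1] != 3 or self.annulus.shape[0] < 8:
            raise ValueError("annulus must be an (N>=8, 3) point array")
        for name in QUADRANT_NAMES:
            if name not in self.quadrant:
                raise ValueError(f"missing landmark {name}")
            self.quadrant[name] = np.asarray(self.quadrant[name], dtype=float).reshape(3)
        for name in COMMISSURE_NAMES:
            if name not in self.commissures:
                raise ValueError(f"missing landmark {name}")
            self.commissures[name] = np.asarray(self.commissures[name], dtype=float).reshape(3)

    def transformed(self, fn) -> "ValveAnnotation":
        """Return a copy with ``fn`` (an (N,3)->(N,3) map) applied to all points."""
        return ValveAnnotation(
            annulus=fn(self.annulus),
            quadrant={k: fn(v[None])[0] for k, v in self.quadrant.items()},
            commissures={k: fn(v[None])[0] for k, v in self.commissures.items()},
        )


def polyline_distance(points: np.ndarray, polyline: np.ndarray, closed: bool = True) -> np.ndarray:
    """Exact distance from each query point to a (closed) polyline's segments."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    a = poly
    b = np.roll(poly, -1, axis=0) if closed else poly[1:]
    if not closed:
        a = poly[:-1]
    ab = b - a  # (M, 3)
    denom = np.einsum("md,md->m", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    # t: (N, M) clamped projection parameter of each point on each segment
    ap = pts[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(pts[:, None, :] - closest, axis=-1)
    return d.min(axis=1)
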