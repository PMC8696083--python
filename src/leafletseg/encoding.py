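"""Assembly of the network's multi-channel input.

A configuration is the cross product of four choices: which frames feed the
network (Single-Phase, Two-Phase, Four-Phase, or the 11-frame consecutive
systolic phases window, CSP), whether an annulus signed-distance-map channel
is added, whether three commissure SDM channels are added, and whether the
case was resampled to the rule-derived spacing.  That yields 4 x 2 x 2 x 2 =
32 configurations in four user-input groups of eight, with channel counts
between 1 and 15; the MS frame is always present.

SDMs are physical: each voxel stores its Euclidean distance in mm to the
boundary of the rasterized structure (annulus tube or commissure sphere),
negative inside, positive outside.  Like the image frames, every SDM channel
is min-max normalized to [0, 1] before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import COMMISSURE_NAMES, ImageGrid, ValveAnnotation, VolumeSequence
from .phantom import PhantomCase

__all__ = [
    "FrameMode",
    "InputConfig",
    "ChannelStack",
    "SignedDistanceMap",
    "select_frames",
    "rasterize_annulus_tube",
    "signed_distance_map",
    "annulus_sdm",
    "commissure_sdms",
    "normalize_channel",
    "assemble_stack",
    "enumerate_configs",
]

DEFAULT_ANNULUS_TUBE_RADIUS = 0.5  # mm
DEFAULT_COMMISSURE_SPHERE_RADIUS = 1.0  # mm


class FrameMode(str, Enum):
    SINGLE = "SINGLE"
    TWO = "TWO"
    FOUR = "FOUR"
    CSP = "CSP"


_N_FRAMES = {FrameMode.SINGLE: 1, FrameMode.TWO: 2, FrameMode.FOUR: 4, FrameMode.CSP: 11}


@dataclass(frozen=True)
class InputConfig:
    frame_mode: FrameMode = FrameMode.SINGLE
    use_annulus: bool = False
    use_commissures: bool = False
    use_resampling: bool = True

    @property
    def n_channels(self) -> int:
        return (
            _N_FRAMES[FrameMode(self.frame_mode)]
            + (1 if self.use_annulus else 0)
            + (3 if self.use_commissures else 0)
        )

    @property
    def name(self) -> str:
        parts = [FrameMode(self.frame_mode).value]
        if self.use_annulus:
            parts.append("ann")
        if self.use_commissures:
            parts.append("com")
        parts.append("res" if self.use_resampling else "nores")
        return "+".join(parts)

    @classmethod
    def from_name(cls, name: str) -> "InputConfig":
        parts = name.split("+")
        return cls(
            frame_mode=FrameMode(parts[0].upper()),
            use_annulus="ann" in parts,
            use_commissures="com" in parts,
            use_resampling="nores" not in parts,
        )


@dataclass
class SignedDistanceMap:
    """Signed Euclidean distance (mm) to a structure boundary: negative
    inside, positive outside, zero on boundary voxels."""

    values: np.ndarray
    grid: ImageGrid


@dataclass
class ChannelStack:
    """The assembled network input: channels normalized to [0, 1] on one grid."""

    channels: np.ndarray  # (C, *grid.shape) float32
    channel_roles: list[str]
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != len(self.channel_roles):
            raise ValueError("channels must be (C, i, j, k) matching channel_roles")
        if not (1 <= self.channels.shape[0] <= 15):
            raise ValueError("channel count must be between 1 and 15")


def select_frames(sequence: VolumeSequence, mode: FrameMode | str) -> list[int]:
    """Frame indices for a frame mode, in the order they enter the network.

    CSP is the MS frame with five adjacent frames on each side, in temporal
    order; it requires the MS index to be at least 5 frames from both ends.
    """
    mode = FrameMode(mode)
    pi = sequence.phase_index
    required = {
        FrameMode.SINGLE: ["MS"],
        FrameMode.TWO: ["MS", "MD"],
        FrameMode.FOUR: ["ES", "ED", "MS", "MD"],
        FrameMode.CSP: ["MS"],
    }[mode]
    for phase in required:
        if phase not in pi:
            raise ValueError(f"phase {phase} is not annotated on this sequence")
    if mode is FrameMode.CSP:
        ms = pi["MS"]
        if ms < 5 or ms > sequence.n_frames - 6:
            raise ValueError(
                f"insufficient adjacent frames for CSP: MS index {ms} must leave five "
                f"frames on each side of a {sequence.n_frames}-frame sequence"
            )
        return list(range(ms - 5, ms + 6))
    return [pi[p] for p in required]


def _frame_roles(sequence: VolumeSequence, mode: FrameMode) -> list[str]:
    if FrameMode(mode) is FrameMode.CSP:
        ms = sequence.phase_index["MS"]
        return [f"frame:MS{i - ms:+d}" if i != ms else "frame:MS" for i in range(ms - 5, ms + 6)]
    names = {FrameMode.SINGLE: ["MS"], FrameMode.TWO: ["MS", "MD"],
             FrameMode.FOUR: ["ES", "ED", "MS", "MD"]}[FrameMode(mode)]
    return [f"frame:{n}" for n in names]


def rasterize_annulus_tube(
    annotation: ValveAnnotation, grid: ImageGrid, radius: float = DEFAULT_ANNULUS_TUBE_RADIUS
) -> np.ndarray:
    """Binary mask of a tube of ``radius`` mm around the closed annular curve."""
    poly = annotation.annulus
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    step = min(grid.spacing) / 2.0
    samples = [closed[0]]
    for a, b, length in zip(closed[:-1], closed[1:], seg):
        n = max(1, int(np.ceil(length / step)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        samples.append(a + t * (b - a))
    pts = np.vstack(samples)
    centers = grid.voxel_centers().reshape(-1, 3)
    d, _ = cKDTree(pts).query(centers, distance_upper_bound=radius + 1e-9)
    mask = np.isfinite(d).reshape(grid.shape)
    if not mask.any():
        raise ValueError("annulus tube rasterizes to an empty mask: curve outside the grid")
    return mask


def signed_distance_map(mask: np.ndarray, grid: ImageGrid) -> SignedDistanceMap:
    """Signed Euclidean distance (mm) to the mask's boundary voxels.

    Boundary voxels are mask voxels with a 6-neighbor outside the mask; their
    value is zero.  Distances are measured between voxel centers with the
    grid's physical spacing, which matches an exhaustive center-to-boundary
    search exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot build an SDM of an empty mask")
    interior = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(3, 1))
    boundary = mask & ~interior
    dist = ndi.distance_transform_edt(~boundary, sampling=grid.spacing)
    values = np.where(mask & ~boundary, -dist, dist)
    return SignedDistanceMap(values=values.astype(np.float32), grid=grid)


def annulus_sdm(
    annotation: ValveAnnotation, grid: ImageGrid, radius: float = DEFAULT_ANNULUS_TUBE_RADIUS
) -> SignedDistanceMap:
    """SDM of the annular curve rasterized as a tube."""
    return signed_distance_map(rasterize_annulus_tube(annotation, grid, radius), grid)


def commissure_sdms(
    annotation: ValveAnnotation,
    grid: ImageGrid,
    radius: float = DEFAULT_COMMISSURE_SPHERE_RADIUS,
) -> list[SignedDistanceMap]:
    """SDMs of the three commissures as rasterized spheres, in ASC, PSC, APC order."""
    for name in COMMISSURE_NAMES:
        if name not in annotation.commissures:
            raise ValueError(f"missing landmark {name}")
    centers = grid.voxel_centers()
    out = []
    for name in COMMISSURE_NAMES:
        c = annotation.commissures[name]
        mask = np.linalg.norm(centers - c, axis=-1) <= radius
        if not mask.any():
            raise ValueError(f"commissure {name} sphere rasterizes outside the grid")
        out.append(signed_distance_map(mask, grid))
    return out


def normalize_channel(arr: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant channel maps to all zeros."""
    arr = np.asarray(arr, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel contains non-finite values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def assemble_stack(
    case: PhantomCase | tuple[VolumeSequence, ValveAnnotation],
    config: InputConfig,
    annulus_radius: float = DEFAULT_ANNULUS_TUBE_RADIUS,
    commissure_radius: float = DEFAULT_COMMISSURE_SPHERE_RADIUS,
) -> ChannelStack:
    """Build the multi-channel input for one (already preprocessed) case."""
    if isinstance(case, PhantomCase):
        sequence, annotation = case.sequence, case.annotation
    else:
        sequence, annotation = case
    mode = FrameMode(config.frame_mode)
    idx = select_frames(sequence, mode)
    channels = [normalize_channel(sequence.frames[i]) for i in idx]
    roles = _frame_roles(sequence, mode)
    if config.use_annulus:
        channels.append(normalize_channel(annulus_sdm(annotation, sequence.grid, annulus_radius).values))
        roles.append("sdm:annulus")
    if config.use_commissures:
        for name, sdm in zip(
            COMMISSURE_NAMES, commissure_sdms(annotation, sequence.grid, commissure_radius)
        ):
            channels.append(normalize_channel(sdm.values))
            roles.append(f"sdm:{name}")
    return ChannelStack(channels=np.stack(channels), channel_roles=roles, grid=sequence.grid)


def enumerate_configs() -> dict[tuple[bool, bool], list[InputConfig]]:
    """All 32 input configurations, grouped into the four user-input groups.

    Groups are keyed by ``(use_annulus, use_commissures)``; each group holds
    the 4 frame modes x 2 resampling states = 8 configurations, in a fixed
    deterministic order.
    """
    groups: dict[tuple[bool, bool], list[InputConfig]] = {}
    for ann in (False, True):
        for com in (False, True):
            group = []
            for mode in (FrameMode.SINGLE, FrameMode.TWO, FrameMode.FOUR, FrameMode.CSP):
                for res in (True, False):
                    group.append(
                        InputConfig(
                            frame_mode=mode,
                            use_annulus=ann,
                            use_commissures=com,
                            use_resampling=res,
                        )
                    )
            groups[(ann, com)] = group
    return groups
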