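"""On-disk formats: NRRD/NIfTI volumes and 3D Slicer markup files.

Internal physical frame is LPS everywhere.  Slicer markups stored in RAS are
converted by negating x and y on read, and the conversion is applied
symmetrically on write, so load-then-save reproduces the source coordinates.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .core import (
    COMMISSURE_NAMES,
    QUADRANT_NAMES,
    ImageGrid,
    LeafletLabelMap,
    ValveAnnotation,
    VolumeSequence,
)

__all__ = [
    "read_volume_sequence",
    "read_image",
    "write_image",
    "read_labelmap",
    "write_labelmap",
    "write_volume_sequence",
    "read_annotation",
    "write_annotation_fcsv",
    "write_annotation_json",
]

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])
_VOLUME_SUFFIXES = (".nrrd", ".nhdr", ".nii", ".nii.gz", ".mha", ".mhd")


# ---------------------------------------------------------------------------
# volumes


def _grid_from_sitk(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _sitk_from_array(arr: np.ndarray, grid: ImageGrid) -> sitk.Image:
    # sitk.GetImageFromArray expects (z, y, x); our arrays are (i, j, k) = (x, y, z)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(arr, (2, 1, 0))))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(grid.direction)
    return img


def _array_from_sitk(img: sitk.Image) -> np.ndarray:
    return np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))


def read_image(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    """Read a single 3D volume (NRRD, NIfTI, MetaImage) as ``(array, grid)``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not str(path.name).lower().endswith(_VOLUME_SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path.name} is not a 3D volume")
    return _array_from_sitk(img), _grid_from_sitk(img)


def write_image(arr: np.ndarray, grid: ImageGrid, path: str | Path) -> Path:
    path = Path(path)
    sitk.WriteImage(_sitk_from_array(arr, grid), str(path))
    return path


def _grid_from_nifti_affine(affine: np.ndarray, shape: Sequence[int]) -> ImageGrid:
    lps = _RAS_TO_LPS @ affine[:3, :]
    spacing = np.linalg.norm(lps[:, :3], axis=0)
    direction = lps[:, :3] / spacing
    return ImageGrid(
        shape=tuple(int(s) for s in shape[:3]),
        spacing=tuple(spacing),
        origin=tuple(lps[:, 3]),
        direction=tuple(direction.ravel()),
    )


def read_volume_sequence(
    paths: str | Path | Sequence[str | Path],
    phase_index: dict[str, int] | None = None,
) -> VolumeSequence:
    """Read a time sequence from per-frame 3D files or from a single 4D NIfTI.

    Phase indices are supplied explicitly (sidecar configuration), never
    inferred from filenames.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        if not path.exists():
            raise FileNotFoundError(path)
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"{path.name}: expected a 3D or 4D volume, got ndim={data.ndim}")
        grid = _grid_from_nifti_affine(img.affine, data.shape)
        frames = [np.ascontiguousarray(data[..., t], dtype=np.float32) for t in range(data.shape[3])]
        return VolumeSequence(frames=frames, grid=grid, phase_index=dict(phase_index or {}))

    frames: list[np.ndarray] = []
    grid: ImageGrid | None = None
    for i, p in enumerate(paths):
        arr, g = read_image(p)
        if grid is None:
            grid = g
        elif not grid.approx_equal(g):
            raise ValueError(
                f"inconsistent sequence: frame {i} ({Path(p).name}) grid does not match frame 0"
            )
        frames.append(arr.astype(np.float32))
    if grid is None:
        raise ValueError("empty path list")
    return VolumeSequence(frames=frames, grid=grid, phase_index=dict(phase_index or {}))


def write_volume_sequence(seq: VolumeSequence, out_dir: str | Path, stem: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, frame in enumerate(seq.frames):
        paths.append(write_image(frame, seq.grid, out_dir / f"{stem}_{t:03d}.nrrd"))
    return paths


def write_channel_stack(channels: np.ndarray, grid: ImageGrid, path: str | Path) -> Path:
    """Write a (C, i, j, k) stack as a multi-component NRRD/NIfTI volume."""
    arr = np.ascontiguousarray(np.transpose(np.asarray(channels), (3, 2, 1, 0)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(grid.direction)
    path = Path(path)
    sitk.WriteImage(img, str(path))
    return path


def read_channel_stack(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, C)
    if arr.ndim == 3:
        arr = arr[..., None]
    return np.transpose(arr, (3, 2, 1, 0)), _grid_from_sitk(img)


def read_labelmap(path: str | Path) -> LeafletLabelMap:
    arr, grid = read_image(path)
    return LeafletLabelMap(labels=np.rint(arr).astype(np.uint8), grid=grid)


def write_labelmap(labelmap: LeafletLabelMap, path: str | Path) -> Path:
    """Write a leaflet label map; re-reading yields bit-identical labels."""
    return write_image(labelmap.labels.astype(np.uint8), labelmap.grid, path)


# ---------------------------------------------------------------------------
# Slicer markups

_LANDMARK_NAMES = set(QUADRANT_NAMES) | set(COMMISSURE_NAMES)


def _read_fcsv(path: Path) -> list[tuple[str, np.ndarray]]:
    """Parse a Slicer FCSV markups file into ordered (label, LPS point) pairs."""
    coord = "LPS"
    rows: list[tuple[str, np.ndarray]] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "CoordinateSystem" in line:
                    value = line.split("=")[-1].strip()
                    coord = {"0": "RAS", "1": "LPS", "RAS": "RAS", "LPS": "LPS"}.get(value, "LPS")
                continue
            fields = next(csv.reader([line]))
            if len(fields) < 4:
                continue
            pt = np.array([float(fields[1]), float(fields[2]), float(fields[3])])
            label = fields[11] if len(fields) > 11 else ""
            rows.append((label, pt))
    if coord == "RAS":
        rows = [(lab, _RAS_TO_LPS @ pt) for lab, pt in rows]
    return rows


def _read_markups_json(path: Path) -> list[tuple[str, list[tuple[str, np.ndarray]]]]:
    """Parse a Slicer markups JSON file into (markup_type, [(label, LPS point)]) lists."""
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for markup in doc.get("markups", []):
        coord = markup.get("coordinateSystem", "LPS").upper()
        pts = []
        for cp in markup.get("controlPoints", []):
            pt = np.asarray(cp["position"], dtype=float)
            if coord == "RAS":
                pt = _RAS_TO_LPS @ pt
            pts.append((cp.get("label", ""), pt))
        out.append((markup.get("type", "Fiducial"), pts))
    return out


def read_annotation(
    markup_files: str | Path | Iterable[str | Path],
    tau_close: float | None = None,
) -> ValveAnnotation:
    """Assemble a :class:`ValveAnnotation` from one or more Slicer markup files.

    The annular curve is taken from a curve markup (JSON) or from the ordered
    point list of a file whose points are not named landmarks; A/P/S/L and
    ASC/PSC/APC are matched by control-point label across all files.

    Raises if a required landmark is missing, or if the annulus endpoints are
    further apart than ``tau_close`` (default: 3x the median segment length),
    i.e. the curve is open.
    """
    if isinstance(markup_files, (str, Path)):
        markup_files = [markup_files]
    named: dict[str, np.ndarray] = {}
    curves: list[np.ndarray] = []
    for path in markup_files:
        path = Path(path)
        if path.suffix == ".fcsv":
            groups = [("Fiducial", _read_fcsv(path))]
        elif path.suffix == ".json":
            groups = _read_markups_json(path)
        else:
            raise ValueError(f"unsupported markup format: {path.name}")
        for mtype, rows in groups:
            labels = [lab for lab, _ in rows]
            is_curve = "curve" in mtype.lower() or (
                len(rows) >= 8 and not any(lab in _LANDMARK_NAMES for lab in labels)
            )
            if is_curve:
                curves.append(np.stack([pt for _, pt in rows]))
            else:
                for lab, pt in rows:
                    if lab in _LANDMARK_NAMES:
                        named[lab] = pt
    for name in (*QUADRANT_NAMES, *COMMISSURE_NAMES):
        if name not in named:
            raise ValueError(f"missing landmark {name}")
    if not curves:
        raise ValueError("no annular curve found in markup files")
    annulus = max(curves, key=len)
    seg = np.linalg.norm(np.diff(annulus, axis=0), axis=1)
    gap = float(np.linalg.norm(annulus[-1] - annulus[0]))
    limit = tau_close if tau_close is not None else 3.0 * float(np.median(seg))
    if gap > limit:
        raise ValueError(
            f"annulus curve is open: endpoint gap {gap:.2f} mm exceeds tolerance {limit:.2f} mm"
        )
    return ValveAnnotation(
        annulus=annulus,
        quadrant={k: named[k] for k in QUADRANT_NAMES},
        commissures={k: named[k] for k in COMMISSURE_NAMES},
    )


def _fcsv_rows(points: Iterable[tuple[str, np.ndarray]], coordinate_system: str) -> str:
    lines = [
        "# Markups fiducial file version = 4.11",
        f"# CoordinateSystem = {coordinate_system}",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    flip = coordinate_system.upper() == "RAS"
    for i, (label, pt) in enumerate(points):
        p = _RAS_TO_LPS @ pt if flip else np.asarray(pt, dtype=float)
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
            f"0,0,0,1,1,1,0,{label},,"
        )
    return "\n".join(lines) + "\n"


def write_annotation_fcsv(
    annotation: ValveAnnotation,
    curve_path: str | Path,
    landmarks_path: str | Path,
    coordinate_system: str = "LPS",
) -> tuple[Path, Path]:
    """Write the annulus curve and the seven landmarks as two FCSV files."""
    curve_path, landmarks_path = Path(curve_path), Path(landmarks_path)
    curve_path.write_text(
        _fcsv_rows([(f"ann_{i}", p) for i, p in enumerate(annotation.annulus)], coordinate_system)
    )
    pts = [(k, annotation.quadrant[k]) for k in QUADRANT_NAMES]
    pts += [(k, annotation.commissures[k]) for k in COMMISSURE_NAMES]
    landmarks_path.write_text(_fcsv_rows(pts, coordinate_system))
    return curve_path, landmarks_path


def write_annotation_json(
    annotation: ValveAnnotation, path: str | Path, coordinate_system: str = "LPS"
) -> Path:
    """Write the full annotation as a single Slicer markups JSON file."""
    flip = coordinate_system.upper() == "RAS"

    def _pos(p: np.ndarray) -> list[float]:
        q = _RAS_TO_LPS @ p if flip else p
        return [float(x) for x in q]

    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json#",
        "markups": [
            {
                "type": "ClosedCurve",
                "coordinateSystem": coordinate_system,
                "controlPoints": [
                    {"label": f"ann_{i}", "position": _pos(p)}
                    for i, p in enumerate(annotation.annulus)
                ],
            },
            {
                "type": "Fiducial",
                "coordinateSystem": coordinate_system,
                "controlPoints": [
                    {"label": k, "position": _pos(annotation.quadrant[k])} for k in QUADRANT_NAMES
                ]
                + [
                    {"label": k, "position": _pos(annotation.commissures[k])}
                    for k in COMMISSURE_NAMES
                ],
            },
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path
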