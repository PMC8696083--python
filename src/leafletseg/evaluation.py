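"""Segmentation accuracy metrics and configuration comparison statistics.

Two metrics compare a predicted segmentation P against the ground truth Q:

* DSC(P, Q) = 2|P n Q| / (|P| + |Q|), the volumetric overlap;
* MBD(P, Q) = (d(P,Q) + d(Q,P)) / 2, where d(P,Q) is the mean Euclidean
  distance from each vertex of P's surface mesh to its nearest vertex on
  Q's mesh.  Surfaces come from marching cubes on the binary masks, with
  vertices in physical mm, so mesh resolution bounds the metric's accuracy.

Scores are reported per leaflet, as the average over the three leaflets, and
for the merged (single-label) valve.  Competing input configurations are
ranked per case by leaflet-average MBD (rank 1 = best, ties averaged) and
compared pairwise with the two-sided Wilcoxon signed-rank test; summaries
are median [IQR].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import rankdata, wilcoxon
from skimage.measure import marching_cubes

from .core import LEAFLET_NAMES, ImageGrid, LeafletLabelMap

__all__ = [
    "SurfaceMesh",
    "dsc",
    "extract_surface",
    "mbd",
    "evaluate_case",
    "rank_configs",
    "paired_compare",
    "median_iqr",
]


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (N, 3) physical mm
    faces: np.ndarray     # (M, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if len(self.vertices) < 4:
            raise ValueError("a closed surface needs at least 4 vertices")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")


def dsc(p: np.ndarray, q: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on one grid."""
    p = np.asarray(p, dtype=bool)
    q = np.asarray(q, dtype=bool)
    if p.shape != q.shape:
        raise ValueError("masks must share one grid")
    np_, nq = int(p.sum()), int(q.sum())
    if np_ == 0 and nq == 0:
        raise ValueError("DSC is undefined for two empty masks")
    return 2.0 * int((p & q).sum()) / (np_ + nq)


def extract_surface(mask: np.ndarray, grid: ImageGrid) -> SurfaceMesh:
    """Iso-surface of a binary mask at 0.5 via marching cubes, vertices in mm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask, 1).astype(np.float32)  # pad so border structures close
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = verts - 1.0  # undo padding offset; verts are fractional (i, j, k)
    return SurfaceMesh(vertices=grid.index_to_physical(verts), faces=faces)


def mbd(mesh_p: SurfaceMesh, mesh_q: SurfaceMesh) -> float:
    """Mean boundary distance: symmetrized mean nearest-vertex distance (mm)."""
    if len(mesh_p.vertices) == 0 or len(mesh_q.vertices) == 0:
        raise ValueError("MBD requires two non-empty meshes")
    d_pq = cKDTree(mesh_q.vertices).query(mesh_p.vertices)[0].mean()
    d_qp = cKDTree(mesh_p.vertices).query(mesh_q.vertices)[0].mean()
    return 0.5 * (float(d_pq) + float(d_qp))


def _metrics_for_masks(pred: np.ndarray, gt: np.ndarray, grid: ImageGrid) -> tuple[float, float]:
    score = dsc(pred, gt)
    distance = mbd(extract_surface(pred, grid), extract_surface(gt, grid))
    return score, distance


def evaluate_case(pred: LeafletLabelMap, gt: LeafletLabelMap) -> dict:
    """Per-leaflet, leaflet-average, and merged DSC/MBD for one case.

    A leaflet that is empty in the prediction is flagged missing and excluded
    from the leaflet average.  The merged (label-blind) valve mask is always
    evaluated when nonempty.
    """
    if not pred.grid.approx_equal(gt.grid):
        raise ValueError("prediction and ground truth are on different grids")
    row: dict = {"missing": []}
    per_leaflet_dsc, per_leaflet_mbd = [], []
    for label, name in LEAFLET_NAMES.items():
        p, q = pred.mask(label), gt.mask(label)
        if not p.any() or not q.any():
            row["missing"].append(name)
            row[f"dsc_{name}"] = np.nan
            row[f"mbd_{name}"] = np.nan
            continue
        d, m = _metrics_for_masks(p, q, gt.grid)
        row[f"dsc_{name}"] = d
        row[f"mbd_{name}"] = m
        per_leaflet_dsc.append(d)
        per_leaflet_mbd.append(m)
    row["dsc_average"] = float(np.mean(per_leaflet_dsc)) if per_leaflet_dsc else np.nan
    row["mbd_average"] = float(np.mean(per_leaflet_mbd)) if per_leaflet_mbd else np.nan
    pm, qm = pred.merged_mask(), gt.merged_mask()
    if pm.any() and qm.any():
        row["dsc_merged"], row["mbd_merged"] = _metrics_for_masks(pm, qm, gt.grid)
    else:
        row["missing"].append("merged")
        row["dsc_merged"] = row["mbd_merged"] = np.nan
    return row


def rank_configs(table: pd.DataFrame) -> pd.DataFrame:
    """Rank configurations by leaflet-average MBD, per case, then on average.

    ``table`` is configurations x cases (rows x columns) of leaflet-average
    MBD.  Within each case the lowest MBD gets rank 1 (ties averaged); the
    winner is the configuration with the lowest mean rank.
    """
    if table.isna().any().any():
        missing = [
            (str(r), str(c)) for r, c in zip(*np.where(table.isna().values))
        ]
        raise ValueError(f"missing MBD cells for (config, case): {missing}")
    ranks = table.apply(lambda col: rankdata(col.values, method="average"), axis=0)
    ranks = pd.DataFrame(ranks.values, index=table.index, columns=table.columns)
    out = pd.DataFrame(
        {
            "mean_rank": ranks.mean(axis=1),
            "mean_mbd": table.mean(axis=1),
        }
    )
    out["winner"] = out["mean_rank"] == out["mean_rank"].min()
    return out.sort_values("mean_rank")


def median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    """Median and [25th, 75th] percentiles with linear interpolation."""
    v = np.asarray(values, dtype=float)
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def paired_compare(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided Wilcoxon signed-rank comparison of paired per-case metrics.

    Zero differences are dropped before ranking; the exact null distribution
    is used for n <= 25 pairs and the normal approximation with continuity
    correction beyond that.  Returns medians with IQR (2 decimals), the
    p-value, and a degenerate flag when all differences are zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    med_a = tuple(round(x, 2) for x in median_iqr(a))
    med_b = tuple(round(x, 2) for x in median_iqr(b))
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return {"median_a": med_a, "median_b": med_b, "p": 1.0, "degenerate": True, "n_effective": 0}
    if nonzero.size < 5:
        raise ValueError("signed-rank test requires at least 5 non-tied pairs")
    method = "exact" if nonzero.size <= 25 else "approx"
    res = wilcoxon(a, b, zero_method="wilcox", correction=(method == "approx"),
                   alternative="two-sided", method=method)
    return {
        "median_a": med_a,
        "median_b": med_b,
        "p": float(res.pvalue),
        "degenerate": False,
        "n_effective": int(nonzero.size),
        "significant": bool(res.pvalue < 0.05),
    }
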