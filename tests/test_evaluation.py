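"""DSC/MBD metrics, surface extraction, ranking, and paired statistics."""

import numpy as np
import pandas as pd
import pytest

from leafletseg.core import ImageGrid, LeafletLabelMap
from leafletseg.evaluation import (
    SurfaceMesh,
    dsc,
    evaluate_case,
    extract_surface,
    mbd,
    median_iqr,
    paired_compare,
    rank_configs,
)


class TestDSC:
    def test_identity_disjoint_and_half(self):
        p = np.zeros((4, 4, 4), dtype=bool)
        p[0, 0, :2] = True
        q = np.zeros_like(p)
        q[0, 0, 1:3] = True
        assert dsc(p, p) == 1.0
        assert dsc(p, np.roll(p, 2, axis=2)) == 0.0
        assert dsc(p, q) == 0.5  # |P|=2, |Q|=2, overlap 1

    def test_symmetric_and_matches_set_arithmetic(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(4, 17, size=3))
            p = rng.random(shape) < 0.3
            q = rng.random(shape) < 0.3
            if not (p.any() or q.any()):
                continue
            expected = 2 * np.sum(p & q) / (np.sum(p) + np.sum(q))
            assert dsc(p, q) == expected == dsc(q, p)

    def test_both_empty_is_an_error(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="undefined"):
            dsc(e, e)


def _euler_characteristic(mesh):
    edges = set()
    for f in mesh.faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            edges.add((min(a, b), max(a, b)))
    return len(mesh.vertices) - len(edges) + len(mesh.faces)


class TestSurface:
    def test_single_voxel_yields_unit_closed_mesh(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        mesh = extract_surface(mask, ImageGrid(shape=(5, 5, 5)))
        extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        np.testing.assert_allclose(extent, 1.0, atol=1e-6)
        assert _euler_characteristic(mesh) == 2

    def test_cube_mesh_closed_in_physical_units(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        grid = ImageGrid(shape=(9, 9, 9), spacing=(0.5, 0.5, 0.5), origin=(-2, -2, -2))
        mesh = extract_surface(mask, grid)
        assert len(mesh.vertices) > 8
        assert _euler_characteristic(mesh) == 2
        extent = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
        np.testing.assert_allclose(extent, 1.5, atol=1e-6)  # 3 voxels * 0.5 mm

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_surface(np.zeros((4, 4, 4), dtype=bool), ImageGrid(shape=(4, 4, 4)))


def _brute_mbd(p, q):
    dp = np.mean([np.min(np.linalg.norm(q - v, axis=1)) for v in p])
    dq = np.mean([np.min(np.linalg.norm(p - v, axis=1)) for v in q])
    return 0.5 * (dp + dq)


class TestMBD:
    def test_identical_meshes_give_zero(self, rng):
        v = rng.random((30, 3))
        faces = np.array([[0, 1, 2]])
        mesh = SurfaceMesh(vertices=v, faces=faces)
        assert mbd(mesh, mesh) == 0.0

    def test_small_translation_recovers_offset(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        grid = ImageGrid(shape=(9, 9, 9))
        mesh = extract_surface(mask, grid)
        shifted = SurfaceMesh(vertices=mesh.vertices + [0.1, 0, 0], faces=mesh.faces)
        assert mbd(mesh, shifted) == pytest.approx(0.1, rel=1e-6)

    def test_translation_detecting(self):
        """MBD grows with the offset for sub-vertex-spacing translations.

        Beyond the vertex-lattice period the nearest-vertex metric aliases
        (a shifted vertex pairs with a different lattice vertex), so the
        monotonicity window is bounded by the mesh resolution.
        """
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        mesh = extract_surface(mask, ImageGrid(shape=(9, 9, 9)))
        prev = -1.0
        for t in (0.0, 0.1, 0.2, 0.35, 0.5):
            cur = mbd(mesh, SurfaceMesh(vertices=mesh.vertices + [t, 0, 0], faces=mesh.faces))
            assert cur >= prev
            prev = cur

    def test_matches_all_pairs_oracle_and_symmetry(self, rng):
        for _ in range(10):
            p = rng.random((rng.integers(8, 40), 3)) * 5
            q = rng.random((rng.integers(8, 40), 3)) * 5
            mp = SurfaceMesh(vertices=p, faces=np.array([[0, 1, 2]]))
            mq = SurfaceMesh(vertices=q, faces=np.array([[0, 1, 2]]))
            assert mbd(mp, mq) == pytest.approx(_brute_mbd(p, q), abs=1e-12)
            assert mbd(mp, mq) == mbd(mq, mp)


class TestEvaluateCase:
    def test_self_comparison_is_perfect(self, phantom_case):
        row = evaluate_case(phantom_case.gt, phantom_case.gt)
        for name in ("anterior", "posterior", "septal", "average", "merged"):
            assert row[f"dsc_{name}"] == 1.0
            assert row[f"mbd_{name}"] == 0.0
        assert row["missing"] == []

    def test_relabeled_leaflet_perfect_merged_imperfect_leaflet(self, phantom_case):
        gt = phantom_case.gt
        swapped = gt.labels.copy()
        swapped[gt.labels == 1] = 2
        swapped[gt.labels == 2] = 1
        pred = LeafletLabelMap(labels=swapped, grid=gt.grid)
        row = evaluate_case(pred, gt)
        assert row["dsc_merged"] == 1.0
        assert row["dsc_anterior"] < 1.0

    def test_missing_leaflet_flagged_merged_still_computed(self, phantom_case):
        gt = phantom_case.gt
        pred_labels = gt.labels.copy()
        pred_labels[pred_labels == 3] = 0
        pred = LeafletLabelMap(labels=pred_labels, grid=gt.grid)
        row = evaluate_case(pred, gt)
        assert row["missing"] == ["septal"]
        assert np.isnan(row["dsc_septal"])
        assert 0 < row["dsc_merged"] < 1.0
        assert row["dsc_average"] == 1.0  # the two present leaflets are exact

    def test_grid_mismatch_rejected(self, phantom_case):
        other = LeafletLabelMap(
            labels=np.zeros((8, 8, 8), dtype=np.uint8), grid=ImageGrid(shape=(8, 8, 8))
        )
        with pytest.raises(ValueError, match="grids"):
            evaluate_case(other, phantom_case.gt)


class TestRanking:
    def test_hand_computed_example(self):
        table = pd.DataFrame(
            [[0.3, 0.2], [0.5, 0.6], [0.7, 0.4]],
            index=["cfg1", "cfg2", "cfg3"],
            columns=["case1", "case2"],
        )
        out = rank_configs(table)
        assert out.loc["cfg1", "mean_rank"] == 1.0
        assert out.loc["cfg2", "mean_rank"] == 2.5
        assert out.loc["cfg3", "mean_rank"] == 2.5
        assert out["winner"].idxmax() == "cfg1"

    def test_all_tied_get_average_ranks(self):
        table = pd.DataFrame(np.full((4, 3), 0.5), index=list("abcd"))
        out = rank_configs(table)
        np.testing.assert_allclose(out["mean_rank"], 2.5)

    def test_mean_ranks_average_to_permutation_mean(self, rng):
        table = pd.DataFrame(rng.random((8, 6)))
        out = rank_configs(table)
        assert out["mean_rank"].mean() == pytest.approx((8 + 1) / 2)
        assert sorted(out["mean_rank"]) == list(out["mean_rank"])

    def test_missing_cells_rejected(self):
        table = pd.DataFrame([[0.3, np.nan], [0.5, 0.6]], index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            rank_configs(table)


class TestPairedCompare:
    def test_identical_samples_are_degenerate(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = paired_compare(a, a)
        assert out["degenerate"] and out["p"] == 1.0

    def test_exact_small_n_p_value(self):
        """Six uniformly positive differences: exact two-sided p = 2/2^6."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = a - np.array([0.11, 0.23, 0.31, 0.43, 0.52, 0.67])
        out = paired_compare(a, b)
        assert out["p"] == pytest.approx(0.03125, abs=1e-12)
        assert out["significant"]

    def test_median_iqr_linear_interpolation(self):
        med, lo, hi = median_iqr(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert (med, lo, hi) == (3.0, 2.0, 4.0)

    def test_reported_medians_rounded_to_2_decimals(self):
        a = np.array([0.333, 0.444, 0.555, 0.666, 0.777, 0.888])
        out = paired_compare(a, a + 0.1)
        assert out["median_a"] == (0.61, 0.47, 0.75)
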