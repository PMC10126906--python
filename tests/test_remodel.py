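"""Remodeling classification, taxicab distances and volume-conserving scaling."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_taxicab
from mechanostat import BinaryVolume, build_surface_table, classify_remodeling, surface_mask, taxicab_dt
from mechanostat.remodel import (
    ClusterLabels,
    label_clusters,
    label_event_surfaces,
    project_distances,
    scale_cluster_distances,
)


def _bv(arr):
    return BinaryVolume(np.asarray(arr, np.uint8), 10.5)


class TestClassify:
    def test_identity_pair_has_no_events(self, random_binary_pair):
        b, _, m = random_binary_pair
        rem = classify_remodeling(b, b, m)
        assert rem.formed.data.sum() == 0
        assert rem.resorbed.data.sum() == 0
        assert rem.quiescent_bone.data.sum() == b.data.sum()

    def test_single_added_voxel(self):
        b = np.zeros((3, 3, 3), np.uint8)
        b[1, 1, 1] = 1
        f = b.copy()
        f[1, 1, 2] = 1
        rem = classify_remodeling(_bv(b), _bv(f), _bv(np.ones_like(b)))
        assert rem.formed.data.sum() == 1 and rem.formed.data[1, 1, 2] == 1

    def test_matches_boolean_set_oracle(self, random_binary_pair):
        b, f, m = random_binary_pair
        rem = classify_remodeling(b, f, m)
        bb, fb = b.bool_data, f.bool_data
        np.testing.assert_array_equal(rem.formed.bool_data, fb & ~bb)
        np.testing.assert_array_equal(rem.resorbed.bool_data, bb & ~fb)
        np.testing.assert_array_equal(rem.quiescent_bone.bool_data, bb & fb)
        # disjoint partition
        total = rem.formed.data + rem.resorbed.data + rem.quiescent_bone.data
        assert total.max() <= 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            classify_remodeling(
                _bv(np.zeros((3, 3, 3))), _bv(np.zeros((4, 3, 3))),
                _bv(np.ones((3, 3, 3))),
            )

    def test_empty_mask_rejected(self, random_binary_pair):
        b, f, _ = random_binary_pair
        with pytest.raises(ValueError, match="mask"):
            classify_remodeling(b, f, _bv(np.zeros((8, 8, 8))))


class TestSurface:
    def test_isolated_voxel_is_surface(self):
        b = np.zeros((3, 3, 3), np.uint8)
        b[1, 1, 1] = 1
        assert surface_mask(_bv(b)).data.sum() == 1

    def test_cube_surface_count(self):
        """A 3x3x3 solid cube has 26 surface voxels and one interior voxel."""
        b = np.zeros((5, 5, 5), np.uint8)
        b[1:4, 1:4, 1:4] = 1
        s = surface_mask(_bv(b))
        assert s.data.sum() == 26
        assert s.data[2, 2, 2] == 0

    def test_empty_volume(self):
        assert surface_mask(_bv(np.zeros((4, 4, 4)))).data.sum() == 0

    def test_volume_boundary_counts_as_background(self):
        """A full 3x3x3 volume: faces touch out-of-bounds, center does not."""
        solid = surface_mask(_bv(np.ones((3, 3, 3))))
        assert solid.data.sum() == 26
        assert solid.data[1, 1, 1] == 0


class TestTaxicabDT:
    def test_bar_profile_through_slab(self):
        """The classic [0,1,2,1,0] profile, realized as a 3-layer slab so
        lateral out-of-bounds background is farther than the slab faces."""
        slab = np.zeros((5, 9, 9), np.uint8)
        slab[1:4] = 1
        dt = taxicab_dt(_bv(slab))
        np.testing.assert_array_equal(dt.data[:, 4, 4], [0, 1, 2, 1, 0])

    def test_single_voxel(self):
        b = np.zeros((3, 3, 3), np.uint8)
        b[1, 1, 1] = 1
        assert taxicab_dt(_bv(b)).data[1, 1, 1] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        bone = (rng.random((10, 10, 10)) < 0.6).astype(np.uint8)
        dt = taxicab_dt(_bv(bone))
        np.testing.assert_array_equal(dt.data, brute_force_taxicab(bone))


class TestEventSurfaces:
    def test_added_voxel_labels_support_as_formation(self, slab_pair):
        """One voxel added atop a slab: the voxel beneath is formation."""
        bone, mask = slab_pair
        f = bone.data.copy()
        f[6, 5, 5] = 1
        rem = classify_remodeling(bone, _bv(f), mask)
        surf = surface_mask(bone)
        formation, resorption, quiescence, _ = label_event_surfaces(surf, rem)
        assert formation[5, 5, 5]
        assert formation.sum() == 1

    def test_removed_voxel_is_resorption(self, slab_pair):
        bone, mask = slab_pair
        f = bone.data.copy()
        f[5, 5, 5] = 0
        rem = classify_remodeling(bone, _bv(f), mask)
        formation, resorption, quiescence, _ = label_event_surfaces(
            surface_mask(bone), rem
        )
        assert resorption[5, 5, 5] and resorption.sum() == 1

    def test_untouched_surface_is_quiescent(self, slab_pair):
        bone, mask = slab_pair
        rem = classify_remodeling(bone, bone, mask)
        formation, resorption, quiescence, collisions = label_event_surfaces(
            surface_mask(bone), rem
        )
        np.testing.assert_array_equal(quiescence, surface_mask(bone).bool_data)
        assert collisions == 0

    def test_collision_resolves_to_resorption(self, slab_pair):
        """A resorbed surface voxel next to a formed cluster stays resorption."""
        bone, mask = slab_pair
        f = bone.data.copy()
        f[5, 5, 5] = 0      # resorbed surface voxel
        f[6, 5, 6] = 1      # formed voxel diagonal in x, adjacent to (5,5,6)
        f[6, 5, 4] = 1
        rem = classify_remodeling(bone, _bv(f), mask)
        formation, resorption, _, _ = label_event_surfaces(surface_mask(bone), rem)
        assert resorption[5, 5, 5] and not formation[5, 5, 5]


class TestProjection:
    def test_single_layer_projects_distance_one(self, slab_pair):
        """A 1-voxel layer projects distance 1 onto the old surface, not the
        value 2 that the buried surface voxel itself would carry."""
        bone, mask = slab_pair
        f = bone.data.copy()
        f[6] = 1  # full extra layer
        rem = classify_remodeling(bone, _bv(f), mask)
        formation, _, _, _ = label_event_surfaces(surface_mask(bone), rem)
        clusters = label_clusters(rem.formed)
        dt = taxicab_dt(_bv(f))
        idx, raw, cid = project_distances(dt, clusters, formation, "formation")
        assert (raw == 1).all()

    def test_two_layer_growth_matches_dt_oracle(self, slab_pair):
        bone, mask = slab_pair
        f = bone.data.copy()
        f[6:8] = 1
        rem = classify_remodeling(bone, _bv(f), mask)
        formation, _, _, _ = label_event_surfaces(surface_mask(bone), rem)
        clusters = label_clusters(rem.formed)
        dt = taxicab_dt(_bv(f))
        idx, raw, cid = project_distances(dt, clusters, formation, "formation")
        oracle = brute_force_taxicab(f)
        # the projected value is the formed-cluster DT directly above
        for (z, y, x), r in zip(idx, raw):
            assert r == oracle[z + 1, y, x]

    def test_resorption_takes_own_inverse_dt(self, slab_pair):
        bone, mask = slab_pair
        f = bone.data.copy()
        f[5, 5, 5] = 0
        rem = classify_remodeling(bone, _bv(f), mask)
        _, resorption, _, _ = label_event_surfaces(surface_mask(bone), rem)
        clusters = label_clusters(rem.resorbed)
        dt_inv = taxicab_dt(_bv(1 - f))
        idx, raw, cid = project_distances(dt_inv, clusters, resorption, "resorption")
        assert list(raw) == [1.0]

    def test_orphan_surface_voxel_rejected(self):
        """A formation-labeled voxel with no formed neighbor is inconsistent."""
        dt = taxicab_dt(_bv(np.ones((3, 3, 3))))
        clusters = ClusterLabels(np.zeros((3, 3, 3), np.int64), {})
        surf = np.zeros((3, 3, 3), bool)
        surf[1, 1, 1] = True
        with pytest.raises(ValueError, match="no formed"):
            project_distances(dt, clusters, surf, "formation")


class TestScaling:
    def test_consistent_cluster_unchanged(self):
        scaled, orphans = scale_cluster_distances(
            np.array([1.0, 1.0, 2.0]), np.array([1, 1, 1]), {1: 4}
        )
        np.testing.assert_allclose(scaled, [1, 1, 2])
        assert orphans == []

    def test_forced_scaling(self):
        scaled, _ = scale_cluster_distances(
            np.array([2.0, 2.0]), np.array([1, 1]), {1: 2}
        )
        np.testing.assert_allclose(scaled, [1, 1])

    def test_orphan_cluster_reported(self):
        scaled, orphans = scale_cluster_distances(
            np.array([1.0]), np.array([1]), {1: 1, 7: 3}
        )
        assert orphans == [7]


class TestSurfaceTable:
    def test_identical_pair_all_quiescent(self, random_binary_pair):
        b, _, m = random_binary_pair
        table, qc = build_surface_table(b, b, m)
        assert (table["event"] == "quiescence").all()
        assert (table["distance_vox"] == 0).all()

    def test_event_partition_of_surface(self, random_binary_pair):
        b, f, m = random_binary_pair
        table, _ = build_surface_table(b, f, m)
        surf = surface_mask(_bv(b.bool_data & m.bool_data))
        assert len(table) == surf.data.sum()
        coords = set(map(tuple, table[["z", "y", "x"]].to_numpy()))
        assert len(coords) == len(table)  # each voxel exactly once

    @pytest.mark.parametrize("seed", range(5))
    def test_volume_conservation(self, seed):
        """Scaled distances sum to cluster volumes; the signed table total
        equals the net voxel change minus orphan-cluster volumes."""
        rng = np.random.default_rng(seed)
        b = (rng.random((10, 10, 10)) < 0.45).astype(np.uint8)
        f = b.copy()
        flip = rng.random(b.shape) < 0.08
        f[flip] = 1 - f[flip]
        table, qc = build_surface_table(_bv(b), _bv(f), _bv(np.ones_like(b)))
        from scipy import ndimage

        struct = ndimage.generate_binary_structure(3, 1)
        for event, sign in (("formation", 1), ("resorption", -1)):
            sub = table[table["event"] == event]
            rows = sub.groupby("cluster_id")["distance_vox"].sum() * sign
            arr = (f & ~b) if event == "formation" else (b & ~f)
            labels, n = ndimage.label(arr, structure=struct)
            volumes = np.bincount(labels.ravel(), minlength=n + 1)
            for cid, s in rows.items():
                assert s == pytest.approx(volumes[cid], rel=1e-9)
        orphan_f = sum(qc["orphan_formation_clusters"].values())
        orphan_r = sum(qc["orphan_resorption_clusters"].values())
        net = qc["n_formed_voxels"] - qc["n_resorbed_voxels"]
        assert table["distance_vox"].sum() == pytest.approx(
            net - orphan_f + orphan_r, abs=1e-9
        )

    def test_formation_cluster_distance_sum(self, slab_pair):
        """A 5-voxel formed cluster contributes exactly 5 to the table."""
        bone, mask = slab_pair
        f = bone.data.copy()
        f[6, 5, 4:7] = 1
        f[6, 6, 5] = 1
        f[7, 5, 5] = 1
        table, _ = build_surface_table(bone, _bv(f), mask)
        formed = table[table["event"] == "formation"]
        assert formed["distance_vox"].sum() == pytest.approx(5.0)
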