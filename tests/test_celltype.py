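"""Connected components, volume filtering, gene calling, region summaries."""

import numpy as np
import pytest

from vusmamba.io import CellRecord
from vusmamba.celltype import (VOLUME_BOUNDS_UM3, assign_genes, detect_cells,
                               extract_cells, filter_valid, label_components,
                               summarize_region)


def _rec(cid, vol, vox=(0, 0, 0), genes=None):
    return CellRecord(cell_id=cid, centroid_vox=vox,
                      centroid_um=tuple(2.0 * v for v in vox),
                      volume_um3=vol, genes=genes or {})


class TestLabeling:
    def test_corner_touching_voxels(self):
        """Diagonal neighbors merge under 26- but not 6-connectivity."""
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        _, counts26 = label_components(m, connectivity=26)
        _, counts6 = label_components(m, connectivity=6)
        assert len(counts26) == 1
        assert len(counts6) == 2

    def test_edge_touching_voxels_18(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[0, 1, 1] = True   # share an edge
        _, c18 = label_components(m, connectivity=18)
        _, c6 = label_components(m, connectivity=6)
        assert len(c18) == 1 and len(c6) == 2

    def test_counts_match_component_sizes(self, rng):
        m = rng.random((10, 10, 10)) > 0.7
        labels, counts = label_components(m)
        assert counts.sum() == m.sum()
        for k, c in enumerate(counts, start=1):
            assert (labels == k).sum() == c

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(np.ones((2, 2, 2)), connectivity=4)


class TestExtract:
    def test_cube_volume_and_centroid(self):
        m = np.zeros((5, 5, 5), bool)
        m[:3, :3, :3] = True  # 27 voxels
        labels, _ = label_components(m)
        cell, = extract_cells(labels, (2.0, 2.0, 2.0))
        assert cell.volume_um3 == pytest.approx(27 * 8.0)  # 216 um^3
        assert cell.centroid_vox == pytest.approx((1.0, 1.0, 1.0))
        assert cell.centroid_um == pytest.approx((2.0, 2.0, 2.0))

    def test_empty_mask(self):
        labels, _ = label_components(np.zeros((3, 3, 3), bool))
        assert extract_cells(labels) == []

    def test_anisotropic_voxels(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, :2] = True
        labels, _ = label_components(m)
        cell, = extract_cells(labels, (3.5, 1.0, 1.0))
        assert cell.volume_um3 == pytest.approx(2 * 3.5)
        assert cell.centroid_um == pytest.approx((0.0, 0.0, 0.5))


class TestFilter:
    def test_boundary_inclusive_window(self):
        cells = [_rec(i, v) for i, v in enumerate([100.0, 110.0, 216.0, 540.0, 541.0])]
        kept = filter_valid(cells)
        assert [c.volume_um3 for c in kept] == [110.0, 216.0, 540.0]

    def test_default_bounds_constant(self):
        assert VOLUME_BOUNDS_UM3 == (110.0, 540.0)

    def test_custom_bounds(self):
        cells = [_rec(1, 50.0), _rec(2, 500.0)]
        assert [c.cell_id for c in filter_valid(cells, (0.0, 100.0))] == [1]


class TestAssignGenes:
    def _nucleus_labels(self):
        labels = np.zeros((4, 8, 8), int)
        labels[1:3, 1:3, 1:3] = 1
        labels[1:3, 5:7, 5:7] = 2
        return labels

    def test_single_voxel_overlap_flips_flag(self):
        labels = self._nucleus_labels()
        cells = [_rec(1, 64.0, (1.5, 1.5, 1.5)), _rec(2, 64.0, (1.5, 5.5, 5.5))]
        marker = np.zeros_like(labels, bool)
        marker[1, 1, 1] = True  # one voxel inside nucleus 1
        out = assign_genes(cells, labels, {"vglut1": marker})
        assert out[0].genes["vglut1"] is True
        assert out[1].genes["vglut1"] is False

    def test_adjacent_but_disjoint_marker_is_negative(self):
        labels = self._nucleus_labels()
        cells = [_rec(1, 64.0, (1.5, 1.5, 1.5))]
        marker = np.zeros_like(labels, bool)
        marker[1, 3, 3] = True  # touches the nucleus bbox, never its voxels
        out = assign_genes(cells, labels, {"vgat": marker})
        assert out[0].genes["vgat"] is False

    def test_monotone_in_marker_mask(self, rng):
        """Growing the marker mask can only add positives, never remove them."""
        labels = self._nucleus_labels()
        cells = [_rec(1, 64.0), _rec(2, 64.0)]
        small = rng.random(labels.shape) > 0.9
        big = small | (rng.random(labels.shape) > 0.9)
        f_small = [c.genes["vgat"] for c in
                   assign_genes(cells, labels, {"vgat": small})]
        f_big = [c.genes["vgat"] for c in
                 assign_genes(cells, labels, {"vgat": big})]
        assert all(not s or b for s, b in zip(f_small, f_big))

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            assign_genes([], np.zeros((2, 2, 2), int),
                         {"vgat": np.zeros((2, 2, 3), bool)})


class TestRegionSummary:
    def test_density_hand_computed(self):
        """80 cells in a 10^6-voxel region at 8 um^3/voxel -> 10^4 per mm^3."""
        region = np.ones((100, 100, 100), bool)
        cells = [_rec(i, 200.0, vox=(i % 100, (i * 7) % 100, (i * 13) % 100),
                      genes={"vglut1": True, "vgat": False}) for i in range(80)]
        s = summarize_region(cells, region, (2.0, 2.0, 2.0))
        assert s.region_volume_mm3 == pytest.approx(8e-3)
        assert s.counts["vglut1_only"] == 80
        assert s.density_per_mm3["vglut1_only"] == pytest.approx(1e4)
        assert s.proportions["vglut1_only"] == 1.0

    def test_centroid_membership(self):
        region = np.zeros((4, 4, 4), bool)
        region[:, :, :2] = True
        inside = _rec(1, 200.0, vox=(1, 1, 0), genes={"vglut1": True})
        outside = _rec(2, 200.0, vox=(1, 1, 3), genes={"vglut1": True})
        s = summarize_region([inside, outside], region)
        assert s.n_cells == 1 and s.counts["vglut1_only"] == 1

    def test_proportions_sum_to_one_when_all_express(self):
        region = np.ones((4, 4, 4), bool)
        genes = [{"vglut1": True, "vgat": False},
                 {"vglut1": False, "vgat": True},
                 {"vglut1": True, "vgat": True},
                 {"vglut1": True, "vgat": False}]
        cells = [_rec(i, 200.0, vox=(1, 1, 1), genes=g)
                 for i, g in enumerate(genes)]
        s = summarize_region(cells, region)
        assert sum(s.proportions.values()) == pytest.approx(1.0)
        assert s.proportions == {"vglut1_only": 0.5, "vgat_only": 0.25,
                                 "double": 0.25}

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            summarize_region([], np.zeros((2, 2, 2), bool))


class TestDetectPipelineOnPhantom:
    def test_exact_recovery_from_perfect_masks(self):
        from vusmamba.synthetic import PhantomSpec, generate_phantom
        spec = PhantomSpec(shape=(24, 96, 96), n_cells=50, seed=9)
        ph = generate_phantom(spec)
        detected = detect_cells(
            ph.gt_masks["hoechst"],
            {"vglut1": ph.gt_masks["vglut1"], "vgat": ph.gt_masks["vgat"]},
            voxel_size_um=spec.voxel_size_um)
        truth = filter_valid(ph.gt_cells)
        assert len(detected) == len(truth)
        # match by centroid, then compare volume and flags exactly
        truth_sorted = sorted(truth, key=lambda c: c.centroid_vox)
        det_sorted = sorted(detected, key=lambda c: c.centroid_vox)
        for t, d in zip(truth_sorted, det_sorted):
            assert d.centroid_vox == pytest.approx(t.centroid_vox, abs=1e-9)
            assert d.volume_um3 == pytest.approx(t.volume_um3, rel=1e-12)
            assert d.genes == t.genes
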