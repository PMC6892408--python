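"""Nucleus detection and the 2-um Iba1 contiguity assignment rule."""

import numpy as np
import pytest

import mgmorph as mg
from conftest import bfs_flood_fill


def _disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _bmask(mask, mpp=0.5):
    return mg.BinaryMask(mask, mpp)


class TestDetectNuclei:
    def test_three_disjoint_discs(self):
        mask = np.zeros((100, 100), bool)
        for center in ((20, 20), (20, 70), (70, 45)):
            mask |= _disc_mask(mask.shape, center, 10)  # 5 um radius at mpp 0.5
        nuclei = mg.detect_nuclei(_bmask(mask), 10.0, 400.0)
        assert len(nuclei) == 3
        assert [n.id for n in nuclei] == [1, 2, 3]
        # raster order of first pixels: the two top discs precede the bottom one
        assert nuclei[0].centroid[0] < nuclei[2].centroid[0]

    def test_small_component_excluded_by_min_area(self):
        mask = np.zeros((50, 50), bool)
        mask |= _disc_mask(mask.shape, (12, 12), 8)
        mask[40, 40] = True  # 0.25 um^2 speck
        nuclei = mg.detect_nuclei(_bmask(mask), 10.0, 400.0)
        assert len(nuclei) == 1

    def test_diagonal_touch_is_single_component_under_8_connectivity(self):
        """Two discs meeting at one pixel corner; oracle is brute-force flood fill."""
        mask = np.zeros((40, 40), bool)
        mask[5:15, 5:15] = True
        mask[15:25, 15:25] = True  # touches (14,14) diagonally
        nuclei = mg.detect_nuclei(_bmask(mask), 0.0, 1e6)
        assert len(nuclei) == 1
        filled8 = bfs_flood_fill(mask, (5, 5), connectivity=8)
        assert len(filled8) == int(mask.sum())  # one 8-connected component
        filled4 = bfs_flood_fill(mask, (5, 5), connectivity=4)
        assert len(filled4) < int(mask.sum())  # but two 4-connected ones

    def test_empty_mask_gives_empty_list(self):
        assert mg.detect_nuclei(_bmask(np.zeros((10, 10), bool))) == []

    def test_bad_area_bounds_rejected(self):
        with pytest.raises(ValueError):
            mg.detect_nuclei(_bmask(np.zeros((5, 5), bool)), 10.0, 5.0)


class TestAssignProcesses:
    def _nucleus_at(self, shape, center, radius=6, mpp=0.5):
        mask = _disc_mask(shape, center, radius)
        nuclei = mg.detect_nuclei(_bmask(mask, mpp), 0.0, 1e6)
        assert len(nuclei) == 1
        return nuclei[0]

    def test_contiguous_branch_within_radius_fully_assigned(self):
        """A long branch whose nearest pixel is 1.5 um away belongs to the cell."""
        shape = (60, 120)
        nucleus = self._nucleus_at(shape, (30, 15))
        iba1 = np.zeros(shape, bool)
        iba1[30, 24:104] = True  # 40-um bar, nearest pixel 3 px = 1.5 um away
        result = mg.assign_processes(_bmask(iba1), [nucleus], radius_um=2.0)
        assert np.array_equal(result.cells[0].process_mask, iba1)
        assert not result.non_process_mask.any()

    def test_blob_beyond_radius_is_non_process(self):
        shape = (60, 60)
        nucleus = self._nucleus_at(shape, (30, 15))
        iba1 = np.zeros(shape, bool)
        iba1[28:33, 28:33] = True  # nearest pixel 7 px = 3.5 um from the disc
        result = mg.assign_processes(_bmask(iba1), [nucleus], radius_um=2.0)
        assert not result.cells[0].process_mask.any()
        assert np.array_equal(result.non_process_mask, iba1)

    def test_radius_is_inclusive(self):
        shape = (30, 60)
        nucleus = self._nucleus_at(shape, (15, 10), radius=5)
        iba1 = np.zeros(shape, bool)
        iba1[15, 19] = True  # exactly 4 px = 2.0 um from the disc edge pixel
        result = mg.assign_processes(_bmask(iba1), [nucleus], radius_um=2.0)
        assert result.cells[0].process_mask[15, 19]

    def test_shared_component_partition_matches_bfs_oracle(self):
        """Partition of a bridging bar equals multi-source nearest-seed BFS."""
        shape = (40, 120)
        na = self._nucleus_at(shape, (20, 15))
        nb_mask = _disc_mask(shape, (20, 100), 6) & ~na.mask
        nb = mg.detect_nuclei(_bmask(nb_mask), 0.0, 1e6)[0]
        nb.id = 2
        iba1 = np.zeros(shape, bool)
        iba1[19:22, 23:93] = True  # one component touching both halos
        result = mg.assign_processes(_bmask(iba1), [na, nb], radius_um=2.0)
        got = np.zeros(shape, dtype=int)
        got[result.cells[0].process_mask] = 1
        got[result.cells[1].process_mask] = 2

        expected = _multi_source_bfs_oracle(iba1, [na, nb], radius_px=4.0)
        assert np.array_equal(got, expected)

    def test_partition_identity_on_synthetic_field(self, segmented_field):
        image, truth, seg = segmented_field
        union = seg.non_process_mask.copy()
        covered = seg.non_process_mask.astype(int).copy()
        for cell in seg.cells:
            union |= cell.process_mask
            covered += cell.process_mask
        maps = mg.unmix_stains(mg.rgb_to_od(image), microns_per_pixel=0.5)
        iba1 = mg.threshold_channel(maps.iba1_od, "otsu", microns_per_pixel=0.5)
        assert np.array_equal(union, iba1.mask)  # tiles the Iba1 mask...
        assert covered.max() <= 1  # ...with pairwise-disjoint pieces

    def test_enlarging_radius_never_demotes_pixels(self, segmented_field):
        image, _, _ = segmented_field
        maps = mg.unmix_stains(mg.rgb_to_od(image), microns_per_pixel=0.5)
        iba1 = mg.threshold_channel(maps.iba1_od, "otsu", microns_per_pixel=0.5)
        pu1 = mg.threshold_channel(maps.pu1_od, "otsu", microns_per_pixel=0.5)
        nuclei = mg.detect_nuclei(pu1)
        small = mg.assign_processes(iba1, nuclei, radius_um=2.0)
        large = mg.assign_processes(iba1, nuclei, radius_um=6.0)
        assigned_small = np.any([c.process_mask for c in small.cells], axis=0)
        assigned_large = np.any([c.process_mask for c in large.cells], axis=0)
        assert not (assigned_small & ~assigned_large).any()

    def test_shape_mismatch_raises(self):
        nucleus = self._nucleus_at((30, 30), (15, 15))
        with pytest.raises(mg.ScaleMismatchError):
            mg.assign_processes(_bmask(np.zeros((20, 20), bool)), [nucleus])


def _multi_source_bfs_oracle(component_mask, nuclei, radius_px):
    """Level-synchronous multi-source BFS labelling, lower id wins ties."""
    from scipy import ndimage

    h, w = component_mask.shape
    labels = np.zeros((h, w), dtype=int)
    frontier = {}
    for nuc in sorted(nuclei, key=lambda n: n.id):
        dist = ndimage.distance_transform_edt(~nuc.mask)
        seeds = component_mask & (dist <= radius_px)
        for r, c in zip(*np.nonzero(seeds)):
            if labels[r, c] == 0:
                labels[r, c] = nuc.id
                frontier[(r, c)] = nuc.id
    while frontier:
        candidates = {}
        for (r, c), lab in frontier.items():
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < h and 0 <= cc < w
                        and component_mask[rr, cc] and labels[rr, cc] == 0
                    ):
                        key = (rr, cc)
                        candidates[key] = min(candidates.get(key, lab), lab)
        for (r, c), lab in candidates.items():
            labels[r, c] = lab
        frontier = candidates
    return labels
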