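import numpy as np
import pytest
from scipy import ndimage

from cellvol3d.boundary_net import ClassicalBoundaryPredictor, predict_boundaries
from cellvol3d.phantoms import CellTruth, PhantomSpec, generate_phantom_stack
from cellvol3d.segmentation import (SeedSet, qc_cells, seeds_from_marks,
                                    segment_at2_cells, segment_stromal_nuclei,
                                    segment_tumor_cells)
from cellvol3d.stack import ImageStack


@pytest.fixture(scope="module")
def confidence_and_truth(request):
    cells = [
        CellTruth(center=(12.0, 8.0, 8.0), cell_volume=600.0,
                  nuclear_volume=200.0, ploidy=2.0),
        CellTruth(center=(12.0, 8.0, 22.0), cell_volume=900.0,
                  nuclear_volume=320.0, ploidy=4.0),
    ]
    spec = PhantomSpec(stack_shape=(48, 32, 60), voxel_size=(0.5, 0.5, 0.5),
                       cells=cells, rng_seed=7)
    stack, cell_labels, nucleus_labels = generate_phantom_stack(spec)
    conf = predict_boundaries(ClassicalBoundaryPredictor(), stack, channel="CK7")
    return spec, conf, cell_labels, nucleus_labels


class TestSegmentTumorCells:
    def test_two_sphere_volumes_within_5pct(self, confidence_and_truth):
        spec, conf, cell_labels, _ = confidence_and_truth
        seeds = SeedSet(np.asarray([c.center for c in spec.cells]))
        labels = segment_tumor_cells(conf, seeds, (0.5, 0.5, 0.5))
        for i in (1, 2):
            est = (labels == i).sum()
            true = (cell_labels == i).sum()
            assert abs(est - true) / true <= 0.05

    def test_no_seed_rejected(self, confidence_and_truth):
        _, conf, _, _ = confidence_and_truth
        with pytest.raises(ValueError, match="seed"):
            segment_tumor_cells(conf, SeedSet(np.empty((0, 3))), 0.5)

    def test_seed_outside_volume_rejected(self, confidence_and_truth):
        _, conf, _, _ = confidence_and_truth
        seeds = SeedSet(np.array([[100.0, 100.0, 100.0]]))
        with pytest.raises(ValueError, match="outside"):
            segment_tumor_cells(conf, seeds, 0.5)

    def test_duplicate_seed_rejected(self, confidence_and_truth):
        _, conf, _, _ = confidence_and_truth
        seeds = SeedSet(np.array([[12.0, 8.0, 8.0], [12.0, 8.0, 8.0]]))
        with pytest.raises(ValueError, match="duplicate"):
            segment_tumor_cells(conf, seeds, 0.5)

    def test_empty_confidence_fills_to_max_radius(self):
        conf = np.zeros((40, 40, 40))
        seeds = SeedSet(np.array([[10.0, 10.0, 10.0]]))
        labels = segment_tumor_cells(conf, seeds, (0.5, 0.5, 0.5),
                                     max_radius_um=5.0)
        vol = (labels == 1).sum() * 0.125
        ball = 4.0 / 3.0 * np.pi * 5.0 ** 3
        assert vol == pytest.approx(ball, rel=0.1)

    def test_labels_disjoint(self, confidence_and_truth):
        spec, conf, _, _ = confidence_and_truth
        seeds = SeedSet(np.asarray([c.center for c in spec.cells]))
        labels = segment_tumor_cells(conf, seeds, (0.5, 0.5, 0.5))
        assert set(np.unique(labels)) <= {0, 1, 2}

    def test_nucleus_containment(self, confidence_and_truth):
        spec, conf, _, nucleus_labels = confidence_and_truth
        seeds = SeedSet(np.asarray([c.center for c in spec.cells]))
        labels = segment_tumor_cells(conf, seeds, (0.5, 0.5, 0.5))
        for i in (1, 2):
            nuc = nucleus_labels == i
            inside = (labels[nuc] == i).sum()
            assert inside / nuc.sum() >= 0.9


def at2_phantom(noise=0.0):
    cells = [CellTruth(center=(10.0, 8.0, 8.0), cell_volume=582.0,
                       nuclear_volume=202.0, cell_class="AT2"),
             CellTruth(center=(10.0, 8.0, 20.0), cell_volume=582.0,
                       nuclear_volume=202.0, cell_class="AT2")]
    spec = PhantomSpec(stack_shape=(40, 32, 56), voxel_size=(0.5, 0.5, 0.5),
                       cells=cells, noise_sd=noise, rng_seed=3)
    return generate_phantom_stack(spec)


class TestSegmentAT2:
    def test_volume_recovery_within_10pct(self):
        stack, cell_labels, _ = at2_phantom()
        labels = segment_at2_cells(stack, spc_threshold=10.0, erosion_um=0.7)
        vox = stack.voxel_volume
        found = sorted(((labels == l).sum() * vox
                        for l in np.unique(labels) if l > 0), reverse=True)[:2]
        for est in found:
            assert est == pytest.approx(582.0, rel=0.10)

    def test_threshold_above_max_gives_empty(self):
        stack, _, _ = at2_phantom()
        with pytest.warns(UserWarning, match="below threshold"):
            labels = segment_at2_cells(stack, spc_threshold=1e6)
        assert labels.max() == 0

    def test_erosion_monotone_contamination(self):
        stack, cell_labels, nucleus_labels = at2_phantom()

        def contamination(erosion):
            labels = segment_at2_cells(stack, spc_threshold=10.0,
                                       erosion_um=erosion)
            count = 0
            for l in np.unique(labels):
                if l == 0:
                    continue
                region = labels == l
                # which true cell does this label mostly cover?
                best, overlap = 0, 0
                for t in np.unique(cell_labels):
                    if t == 0:
                        continue
                    o = (region & (cell_labels == t)).sum()
                    if o > overlap:
                        best, overlap = t, o
                for t in np.unique(nucleus_labels):
                    if t in (0, best):
                        continue
                    if (region & (nucleus_labels == t)).sum() > 0:
                        count += 1
            return count

        assert contamination(0.0) >= contamination(0.7)


class TestSegmentStroma:
    def _stack(self):
        cells = [
            # interior CK7-negative stromal nucleus
            CellTruth(center=(10.0, 10.0, 10.0), cell_volume=400.0,
                      nuclear_volume=150.0, cell_class="stromal"),
            # nucleus close to a face (z ~ 1 um)
            CellTruth(center=(2.5, 10.0, 22.0), cell_volume=400.0,
                      nuclear_volume=150.0, cell_class="stromal"),
            # CK7-positive tumor cell
            CellTruth(center=(10.0, 10.0, 34.0), cell_volume=500.0,
                      nuclear_volume=150.0, cell_class="tumor"),
        ]
        spec = PhantomSpec(stack_shape=(40, 40, 88), voxel_size=(0.5, 0.5, 0.5),
                           cells=cells, rng_seed=5)
        return generate_phantom_stack(spec)

    def test_edge_and_ck7_filters(self):
        stack, cell_labels, nucleus_labels = self._stack()
        labels = segment_stromal_nuclei(stack, dna_threshold=20.0,
                                        edge_margin_um=4.0)
        kept = [l for l in np.unique(labels) if l > 0]
        assert len(kept) == 1
        # the surviving label coincides with the interior stromal nucleus
        region = labels == kept[0]
        overlap = (region & (nucleus_labels == 1)).sum()
        assert overlap / region.sum() > 0.5
        # DNA total recorded for it is positive
        assert stack.channel("DNA")[region].sum() > 0


class TestSeedsFromMarks:
    def test_three_disjoint_spheres(self):
        marks = np.zeros((30, 30, 30))
        for c in [(6, 6, 6), (15, 15, 15), (24, 24, 24)]:
            zz, yy, xx = np.indices(marks.shape)
            marks[((zz - c[0]) ** 2 + (yy - c[1]) ** 2
                   + (xx - c[2]) ** 2) <= 9] = 1.0
        seeds = seeds_from_marks(marks, (0.5, 0.5, 0.5))
        assert len(seeds) == 3

    def test_radius_class_small(self):
        # 5-px-radius blob at 0.15 um voxels -> 1.6 um class
        marks = np.zeros((24, 24, 24))
        zz, yy, xx = np.indices(marks.shape)
        marks[((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 25] = 1.0
        seeds = seeds_from_marks(marks, (0.15, 0.15, 0.15))
        assert seeds.seed_radius == pytest.approx(1.6)

    def test_touching_marks_merge_with_warning(self):
        marks = np.zeros((20, 40, 40))
        zz, yy, xx = np.indices(marks.shape)
        marks[((zz - 10) ** 2 + (yy - 18) ** 2 + (xx - 18) ** 2) <= 64] = 1.0
        marks[((zz - 10) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2) <= 64] = 1.0
        with pytest.warns(UserWarning, match="merged"):
            seeds = seeds_from_marks(marks, (0.5, 0.5, 0.5))
        assert len(seeds) == 1

    def test_no_marks_rejected(self):
        with pytest.raises(ValueError):
            seeds_from_marks(np.zeros((5, 5, 5)), 1.0)


class TestQC:
    def _cells_and_nuclei(self):
        cells = np.zeros((20, 20, 40), dtype=np.int32)
        nuclei = np.zeros_like(cells)
        # interior clean cell 1
        cells[6:14, 6:14, 6:14] = 1
        nuclei[8:12, 8:12, 8:12] = 1
        # cell 2 heavily clipped at the z=0 face
        cells[0:6, 6:14, 20:28] = 2
        nuclei[2:5, 8:12, 22:26] = 2
        return cells, nuclei

    def test_interior_cell_passes(self):
        cells, nuclei = self._cells_and_nuclei()
        report = qc_cells(cells, nuclei)
        assert report.passes(1)

    def test_edge_clipped_cell_fails(self):
        cells, nuclei = self._cells_and_nuclei()
        report = qc_cells(cells, nuclei)
        assert not report.passes(2)
        assert report.flags.loc[2, "edge_clipped"]

    def test_neighbor_nucleus_overlap_fatal(self):
        cells, nuclei = self._cells_and_nuclei()
        # cell 1 swallows 100% of a small foreign nucleus 3
        nuclei[9:11, 9:11, 12:14] = 3
        report = qc_cells(cells, nuclei)
        assert not report.passes(1)
        assert report.flags.loc[1, "nucleus_overlap_violation"]

    def test_multinucleate_flagged_not_fatal(self):
        cells = np.zeros((16, 16, 16), dtype=np.int32)
        nuclei = np.zeros_like(cells)
        cells[4:12, 4:12, 4:12] = 1
        nuclei[5:7, 5:11, 5:11] = 1
        nuclei[9:11, 5:11, 5:11] = 1    # second component, same id
        report = qc_cells(cells, nuclei)
        assert report.flags.loc[1, "multinucleate"]
        assert report.passes(1)
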