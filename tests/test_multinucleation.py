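"""Central-ROI segmentation, nuclei-per-cell counting and the screen ratios."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cytoquant import (
    CellLabelMap,
    NucleiLabelMap,
    SurfaceProjection,
    count_nuclei_per_cell,
    delta_multinucleation,
    multinucleation_frequency,
    multinucleation_ratio,
    segment_cells,
    segment_nuclei,
    select_central_roi,
)
from cytoquant.multinucleation import CellCountTable


def _flat_projection(membrane, nuclei):
    img = np.stack([membrane, nuclei]).astype(float)
    ny, nx = membrane.shape
    return SurfaceProjection(
        image=img,
        anchor_map=np.zeros((ny, nx), dtype=np.int32),
        window_used=np.zeros((ny, nx, 2), dtype=np.int32),
        pixel_size_um=1.0,
        channel_roles={"membrane": 0, "nuclei": 1},
    )


class TestCentralRoi:
    def test_zero_margin_is_full_frame(self):
        proj = _flat_projection(np.zeros((50, 60)), np.zeros((50, 60)))
        assert select_central_roi(proj, margin_fraction=0.0).all()

    def test_rectangle_margin_arithmetic(self):
        proj = _flat_projection(np.zeros((100, 100)), np.zeros((100, 100)))
        roi = select_central_roi(proj, margin_fraction=0.2)
        ys, xs = np.where(roi)
        assert (ys.min(), ys.max(), xs.min(), xs.max()) == (20, 79, 20, 79)

    def test_invalid_margin_rejected(self):
        proj = _flat_projection(np.zeros((20, 20)), np.zeros((20, 20)))
        with pytest.raises(ValueError):
            select_central_roi(proj, margin_fraction=0.5)

    def test_adaptive_roi_stays_inside_tissue(self, tissue_f10):
        *_, proj = tissue_f10
        roi = select_central_roi(proj, margin_fraction=0.1, mode="adaptive")
        assert roi.any()
        assert roi.sum() < np.prod(proj.shape_yx)


class TestSegmentation:
    def test_featureless_membrane_gives_single_roi_region(self):
        proj = _flat_projection(np.zeros((60, 60)), np.zeros((60, 60)))
        roi = select_central_roi(proj, margin_fraction=0.1)
        cells = segment_cells(proj, roi)
        assert cells.n_cells == 1
        assert np.array_equal(cells.labels > 0, roi)

    def test_blank_nuclei_channel_gives_empty_map(self):
        proj = _flat_projection(np.zeros((60, 60)), np.zeros((60, 60)))
        roi = select_central_roi(proj, margin_fraction=0.1)
        assert segment_nuclei(proj, roi).n_nuclei == 0

    def test_touching_nuclei_are_split(self):
        # two blobs 1.2 diameters apart must yield two labels
        ny = nx = 64
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        r = 6.0
        nuc = np.zeros((ny, nx))
        for cy, cx in ((32, 26), (32, 26 + 1.2 * 2 * r)):
            nuc += 1000 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (r / 2) ** 2))
        proj = _flat_projection(np.zeros((ny, nx)), nuc)
        roi = np.ones((ny, nx), dtype=bool)
        nmap = segment_nuclei(proj, roi, min_area_px=10)
        assert nmap.n_nuclei == 2

    def test_cells_recovered_against_ground_truth(self, tissue_f10):
        """Interior cells match the true tessellation one-to-one with high
        overlap, and merged (binucleated) cells stay single regions."""
        spec, stack, truth, anchors, proj = tissue_f10
        roi = select_central_roi(proj, margin_fraction=0.10)
        cells = segment_cells(proj, roi)
        tl = truth.cell_labels
        interior_ids = [
            cid
            for cid in range(1, truth.n_cells + 1)
            if ((tl == cid) & roi).sum() == (tl == cid).sum()
        ]
        jaccards = []
        n_split = 0
        for cid in interior_ids:
            m = tl == cid
            overlap = Counter(cells.labels[m][cells.labels[m] > 0])
            if not overlap:
                n_split += 1
                continue
            seg_id, _ = overlap.most_common(1)[0]
            seg_m = cells.labels == seg_id
            jaccards.append((m & seg_m).sum() / (m | seg_m).sum())
            significant = [s for s, c in overlap.items() if c > 0.25 * m.sum()]
            if len(significant) > 1:
                n_split += 1
        assert n_split == 0
        assert np.mean(jaccards) >= 0.9

    def test_per_cell_counts_match_truth(self, tissue_f10):
        spec, stack, truth, anchors, proj = tissue_f10
        roi = select_central_roi(proj, margin_fraction=0.10)
        cells = segment_cells(proj, roi)
        nuc = segment_nuclei(proj, roi)
        table = count_nuclei_per_cell(cells, nuc)
        tl = truth.cell_labels
        true_counts = truth.nuclei_per_cell()
        ok = tot = 0
        for row in table.qualifying().itertuples():
            seg_m = cells.labels == row.cell_id
            tc = Counter(tl[seg_m]).most_common(1)[0][0]
            tot += 1
            ok += row.n_nuclei == true_counts[tc]
        assert tot > 50
        assert ok / tot >= 0.98


class TestCounting:
    def test_all_nuclei_in_single_cell(self):
        labels = np.ones((40, 40), dtype=np.int32)
        cells = CellLabelMap(labels=labels)
        nmap = NucleiLabelMap(
            labels=np.zeros((40, 40), dtype=np.int32),
            centroids={1: (10.0, 10.0), 2: (20.0, 20.0), 3: (30.0, 5.0)},
        )
        table = count_nuclei_per_cell(cells, nmap)
        assert table.table["n_nuclei"].tolist() == [3]
        assert table.n_unassigned == 0

    def test_background_centroid_left_unassigned(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[:20] = 1
        cells = CellLabelMap(labels=labels)
        nmap = NucleiLabelMap(
            labels=np.zeros((40, 40), dtype=np.int32),
            centroids={1: (10.0, 10.0), 2: (30.0, 10.0)},
        )
        table = count_nuclei_per_cell(cells, nmap)
        assert table.table["n_nuclei"].tolist() == [1]
        assert table.n_unassigned == 1

    def test_geometry_mismatch_is_an_error(self):
        cells = CellLabelMap(labels=np.ones((10, 10), dtype=np.int32))
        nmap = NucleiLabelMap(labels=np.zeros((12, 10), dtype=np.int32))
        with pytest.raises(ValueError, match="geometry"):
            count_nuclei_per_cell(cells, nmap)


def _table(counts, border=None):
    border = border or [False] * len(counts)
    return CellCountTable(
        table=pd.DataFrame(
            {
                "cell_id": range(1, len(counts) + 1),
                "area_px": [100] * len(counts),
                "n_nuclei": counts,
                "touches_border": border,
            }
        )
    )


class TestRatios:
    def test_ratio_arithmetic(self):
        assert multinucleation_ratio(_table([1, 1, 2])) == pytest.approx(4 / 3)
        assert multinucleation_ratio(_table([1, 1, 1])) == 1.0

    def test_frequency_arithmetic(self):
        assert multinucleation_frequency(_table([1, 1, 2])) == pytest.approx(100 / 3)
        assert multinucleation_frequency(_table([1, 1, 1])) == 0.0

    def test_zero_nucleus_cells_are_excluded_and_flagged(self):
        t = _table([1, 0, 2])
        assert multinucleation_ratio(t) == pytest.approx(1.5)
        assert t.n_zero_nucleus == 1

    def test_border_cells_are_excluded(self):
        t = _table([1, 1, 5], border=[False, False, True])
        assert multinucleation_ratio(t) == 1.0

    def test_no_qualifying_cells_is_an_error(self):
        with pytest.raises(ValueError, match="qualifying"):
            multinucleation_ratio(_table([0, 0]))

    def test_frequency_zero_iff_ratio_one(self):
        for counts in ([1, 1, 1, 1], [1, 2, 1], [2, 2]):
            t = _table(counts)
            assert (multinucleation_frequency(t) == 0.0) == (
                multinucleation_ratio(t) == 1.0
            )

    def test_growing_margin_never_adds_qualifying_cells(self, tissue_f10):
        *_, proj = tissue_f10
        previous = None
        for margin in (0.05, 0.15, 0.25):
            roi = select_central_roi(proj, margin_fraction=margin)
            cells = segment_cells(proj, roi)
            nuc = segment_nuclei(proj, roi)
            n_q = len(count_nuclei_per_cell(cells, nuc).qualifying())
            if previous is not None:
                assert n_q <= previous
            previous = n_q


class TestDelta:
    def test_arithmetic(self):
        assert delta_multinucleation(1.2, [1.0, 1.1]) == pytest.approx(0.15)
        assert delta_multinucleation(1.05, [1.0, 1.1]) == pytest.approx(0.0)

    def test_centering_identity(self):
        controls = [1.0, 1.1, 1.25, 1.4]
        deltas = [delta_multinucleation(c, controls) for c in controls]
        assert np.mean(deltas) == pytest.approx(0.0)

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            delta_multinucleation(1.2, [])
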