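"""Multinucleation scoring: central-ROI segmentation and nuclei-per-cell counts.

In a post-mitotic epithelium the number of nuclei per cell directly reports
prior cytokinesis failure.  The pipeline restricts quantification to a
central region of the projected tissue (cells near the chamber border may
have lost membrane/nuclei signal to the projection), segments cells from the
membrane channel with a seeded watershed, segments nuclei from the nuclear
channel, assigns each nucleus to the cell under its centroid, and summarizes:

* multinucleation ratio  = total nuclei / qualifying cells (>= 1);
* multinucleation frequency = % of qualifying cells with >= 2 nuclei;
* delta multinucleation ratio = sample ratio - mean of same-replicate
  sensitized controls (the modifier-screen statistic).

Qualifying cells have at least one nucleus and do not touch the ROI border;
zero-nucleus cells flag segmentation errors and are counted separately for
QC (they are the cases manual validation would correct).  Label maps
round-trip through 16-bit TIFF so a manually corrected map can replace the
automatic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, erosion, h_minima
from skimage.segmentation import watershed

from cytoquant.projection import SurfaceProjection


@dataclass
class CellLabelMap:
    """Cell segmentation: 2D labels (0 = background/excluded), contiguous ids.

    ``border_labels`` holds the ids of cells touching the ROI border; they
    stay in the map (so QC and manual correction can see them) but are
    excluded from the ratio/frequency statistics.
    """

    labels: np.ndarray
    border_labels: frozenset[int] = frozenset()
    roi: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.labels.astype(np.uint16))

    @classmethod
    def load(cls, path: str | Path, border_labels=(), roi=None) -> "CellLabelMap":
        """Load a (possibly manually corrected) label map from TIFF."""
        return cls(
            labels=np.asarray(tifffile.imread(Path(path)), dtype=np.int32),
            border_labels=frozenset(int(b) for b in border_labels),
            roi=roi,
        )


@dataclass
class NucleiLabelMap:
    """Nucleus segmentation with per-label centroids (y, x)."""

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids)


@dataclass
class CellCountTable:
    """Per-cell nucleus counts.

    ``table`` has one row per cell label: ``cell_id, area_px, n_nuclei,
    touches_border``.  ``n_unassigned`` counts nuclei whose centroid fell on
    background (not inside any cell).
    """

    table: pd.DataFrame
    n_unassigned: int = 0

    def qualifying(self) -> pd.DataFrame:
        """Cells entering the statistics: >= 1 nucleus, not on the border."""
        t = self.table
        return t[(t["n_nuclei"] >= 1) & (~t["touches_border"])]

    @property
    def n_zero_nucleus(self) -> int:
        """Interior cells with no nucleus — segmentation-QC count."""
        t = self.table
        return int(((t["n_nuclei"] == 0) & (~t["touches_border"])).sum())


@dataclass
class EggChamberRecord:
    """Per-sample quantification row feeding the screen report."""

    sample_id: str
    group: str
    replicate: str
    nuclei_per_cell: float
    pct_multinucleated: float
    n_cells: int
    delta_ratio: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_multinucleated <= 100.0:
            raise ValueError("pct_multinucleated must be in [0, 100]")
        if self.nuclei_per_cell < 1.0:
            raise ValueError("nuclei_per_cell below 1 implies zero-nucleus cells "
                             "entered the count; exclude them first")


def records_to_frame(records: list[EggChamberRecord]) -> pd.DataFrame:
    """Stack records into the frame consumed by the screen assembly."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in records])


def select_central_roi(
    projection: SurfaceProjection,
    margin_fraction: float = 0.2,
    mode: str = "rectangle",
) -> np.ndarray:
    """Central region of the epithelium in which quantification happens.

    ``rectangle`` (default) shrinks the frame by ``margin_fraction`` per
    side.  ``adaptive`` takes the tissue foreground (Otsu on the membrane
    channel, holes filled, largest component) and erodes it by
    ``margin_fraction`` of its equivalent radius — useful when the tissue
    does not fill the frame.
    """
    if not 0.0 <= margin_fraction < 0.5:
        raise ValueError("margin_fraction must be in [0, 0.5)")
    ny, nx = projection.shape_yx
    if mode == "rectangle":
        my = int(round(margin_fraction * ny))
        mx = int(round(margin_fraction * nx))
        roi = np.zeros((ny, nx), dtype=bool)
        roi[my : ny - my, mx : nx - mx] = True
    elif mode == "adaptive":
        mem = projection.channel("membrane")
        if np.ptp(mem) == 0:
            raise ValueError("membrane channel is featureless; cannot find tissue")
        fg = ndimage.binary_fill_holes(mem > threshold_otsu(mem))
        labels, n = ndimage.label(fg)
        if n == 0:
            raise ValueError("no tissue foreground found")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
        eq_radius = np.sqrt(fg.sum() / np.pi)
        r = int(round(margin_fraction * eq_radius))
        roi = erosion(fg, disk(r)) if r > 0 else fg
    else:
        raise ValueError("mode must be 'rectangle' or 'adaptive'")
    if not roi.any():
        raise ValueError("central ROI is empty; reduce margin_fraction")
    return roi


def _roi_border(roi: np.ndarray) -> np.ndarray:
    """Pixels of the ROI adjacent to outside (or the frame edge)."""
    return roi & ~erosion(roi, disk(1))


def segment_cells(
    projection: SurfaceProjection,
    roi: np.ndarray,
    smooth_sigma: float = 1.2,
    h_rel: float = 0.25,
    min_cell_area_px: int = 80,
) -> CellLabelMap:
    """Watershed segmentation of cells from the membrane channel.

    The membrane image is Gaussian-smoothed, seeds are the h-minima of the
    smoothed image inside the ROI (``h = h_rel * intensity range``; one seed
    per cell interior, since membranes are the ridges), and a seeded
    watershed floods the membrane landscape within the ROI.  Regions smaller
    than ``min_cell_area_px`` are dropped; regions touching the ROI border
    are kept but flagged.  A featureless membrane channel yields a single
    region filling the ROI.
    """
    mem = np.asarray(projection.channel("membrane"), dtype=float)
    if mem.shape != roi.shape:
        raise ValueError("ROI shape does not match projection")
    smoothed = gaussian(mem, sigma=smooth_sigma, preserve_range=True)
    rng_int = float(np.ptp(smoothed[roi])) if roi.any() else 0.0
    if rng_int == 0:
        labels = roi.astype(np.int32)
    else:
        minima = h_minima(smoothed, h_rel * rng_int) & roi
        markers, n_markers = ndimage.label(minima)
        if n_markers == 0:
            labels = roi.astype(np.int32)
        else:
            labels = watershed(smoothed, markers=markers, mask=roi).astype(np.int32)

    # size filter
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    too_small = set(ids[counts < min_cell_area_px].tolist())
    if too_small:
        labels[np.isin(labels, list(too_small))] = 0
    if labels.max() == 0:
        raise ValueError(
            "no cells survived segmentation; review smoothing/h/min-area parameters"
        )

    border_ids = set(np.unique(labels[_roi_border(roi)]).tolist()) - {0}

    # contiguous relabel preserving order
    old_ids = np.unique(labels[labels > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1)
    labels = remap[labels]
    border_new = frozenset(int(remap[i]) for i in border_ids)
    return CellLabelMap(labels=labels, border_labels=border_new, roi=roi)


def segment_nuclei(
    projection: SurfaceProjection,
    roi: np.ndarray,
    min_area_px: int = 25,
    min_peak_distance_px: int = 5,
) -> NucleiLabelMap:
    """Otsu + distance-transform watershed segmentation of nuclei.

    Touching nuclei are split by a watershed on the negated distance
    transform seeded at distance peaks at least ``min_peak_distance_px``
    apart.  Objects below ``min_area_px`` are removed.  An empty map is a
    valid result (blank channel).
    """
    from skimage.feature import peak_local_max

    nuc = np.asarray(projection.channel("nuclei"), dtype=float)
    if nuc.shape != roi.shape:
        raise ValueError("ROI shape does not match projection")
    if np.ptp(nuc) == 0:
        return NucleiLabelMap(labels=np.zeros_like(roi, dtype=np.int32))
    binary = ndimage.binary_fill_holes((nuc > threshold_otsu(nuc)) & roi)
    if not binary.any():
        return NucleiLabelMap(labels=np.zeros_like(roi, dtype=np.int32))
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=min_peak_distance_px, labels=binary, exclude_border=False
    )
    markers = np.zeros_like(dist, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers=markers, mask=binary).astype(np.int32)

    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    small = ids[counts < min_area_px]
    if len(small):
        labels[np.isin(labels, small)] = 0
    old_ids = np.unique(labels[labels > 0])
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1)
    labels = remap[labels]

    centroids = {
        int(p.label): (float(p.centroid[0]), float(p.centroid[1]))
        for p in regionprops(labels)
    }
    return NucleiLabelMap(labels=labels, centroids=centroids)


def count_nuclei_per_cell(cells: CellLabelMap, nuclei: NucleiLabelMap) -> CellCountTable:
    """Assign each nucleus to the cell label under its centroid.

    Nuclei whose centroid lands on background are left unassigned (counted in
    ``n_unassigned``); every cell label gets a row even with zero nuclei.
    """
    if cells.labels.shape != nuclei.labels.shape:
        raise ValueError("cell and nuclei label maps have different geometry")
    counts = np.zeros(cells.n_cells + 1, dtype=int)
    unassigned = 0
    for _nid, (cy, cx) in sorted(nuclei.centroids.items()):
        cell = int(cells.labels[int(round(cy)), int(round(cx))])
        if cell == 0:
            unassigned += 1
        else:
            counts[cell] += 1
    areas = np.bincount(cells.labels.ravel(), minlength=cells.n_cells + 1)
    rows = [
        {
            "cell_id": cid,
            "area_px": int(areas[cid]),
            "n_nuclei": int(counts[cid]),
            "touches_border": cid in cells.border_labels,
        }
        for cid in range(1, cells.n_cells + 1)
    ]
    return CellCountTable(table=pd.DataFrame(rows), n_unassigned=unassigned)


def multinucleation_ratio(table: CellCountTable) -> float:
    """Nuclei per cell over qualifying cells (always >= 1)."""
    q = table.qualifying()
    if len(q) == 0:
        raise ValueError("no qualifying cells (>= 1 nucleus, interior) to score")
    return float(q["n_nuclei"].sum() / len(q))


def multinucleation_frequency(table: CellCountTable) -> float:
    """Percentage of qualifying cells with two or more nuclei."""
    q = table.qualifying()
    if len(q) == 0:
        raise ValueError("no qualifying cells (>= 1 nucleus, interior) to score")
    return float(100.0 * (q["n_nuclei"] >= 2).sum() / len(q))


def delta_multinucleation(sample_ratio: float, control_ratios: list[float]) -> float:
    """Modifier statistic: sample ratio minus the mean control ratio.

    Controls must come from the same replicate as the sample (each experiment
    carries its own sensitized-control group); replicate pairing is enforced
    upstream by :func:`cytoquant.stats.assemble_screen` via the ``replicate``
    column.
    """
    if len(control_ratios) == 0:
        raise ValueError("control_ratios must be non-empty")
    return float(sample_ratio - np.mean(control_ratios))
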