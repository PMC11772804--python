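"""ROI fluorescence quantification and cytokinesis-failure scoring.

Intensity quantification follows line-ROI conventions from interactive image
analysis: a "circular ROI of width w" is an annular band of total width w
along a circle (the cell cortex), a "segmented line of width w" is a band of
width w along a polyline (the cytokinetic ring), and cytoplasmic background
is a small disk.  Pixel membership is decided by the pixel-center distance to
the ROI path.  Corrected signal = ROI mean - cytoplasmic mean, measured on a
z-sum projection of the two planes cross-sectioning the mitotic cell.

Failure scoring classifies logged division events into three categories:
(1) no failure, (2) failure during ring constriction, (3) post-constriction
failure (membrane regression after a completed constriction).  Only small
cells (area cap, to avoid cells already carrying defects from earlier failed
divisions) observed for at least 20 min after ring constriction are eligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from cytoquant.stack import TissueStack


@dataclass
class RoiSpec:
    """Geometry of a measurement ROI.

    ``kind`` is one of ``circle_band`` (center, radius, width_px),
    ``polyline_band`` (vertices as (y, x) pairs, width_px) or ``disk``
    (center, diameter_px).
    """

    kind: str
    center: Optional[tuple[float, float]] = None
    radius: Optional[float] = None
    vertices: Optional[Sequence[tuple[float, float]]] = None
    width_px: Optional[float] = None
    diameter_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "circle_band":
            if self.center is None or self.radius is None or not self.width_px:
                raise ValueError("circle_band needs center, radius and width_px > 0")
            if self.width_px <= 0:
                raise ValueError("width_px must be positive")
        elif self.kind == "polyline_band":
            if self.vertices is None or len(self.vertices) < 2:
                raise ValueError("polyline_band needs >= 2 vertices")
            if not self.width_px or self.width_px <= 0:
                raise ValueError("width_px must be positive")
        elif self.kind == "disk":
            if self.center is None or not self.diameter_px or self.diameter_px <= 0:
                raise ValueError("disk needs center and diameter_px > 0")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")


@dataclass
class IntensityRecord:
    """Background-corrected ROI measurement for one cell/timepoint."""

    sample_id: str
    phase: str  # "metaphase" or "cytokinesis"
    raw_mean: float
    background_mean: float

    @property
    def corrected(self) -> float:
        return self.raw_mean - self.background_mean


def zsum_project(stack: TissueStack, plane_indices: tuple[int, int], channel: int = 0) -> np.ndarray:
    """Pixelwise sum of two distinct planes of one channel."""
    i, j = plane_indices
    if i == j:
        raise ValueError("plane indices must be distinct")
    for idx in (i, j):
        if not 0 <= idx < stack.n_planes:
            raise ValueError(f"plane index {idx} out of range [0, {stack.n_planes})")
    return stack.voxels[channel, i] + stack.voxels[channel, j]


def _segment_distance(py, px, a, b) -> np.ndarray:
    """Distance from points (py, px) to the segment a->b (both (y, x))."""
    ay, ax = a
    by, bx = b
    dy, dx = by - ay, bx - ax
    denom = dy * dy + dx * dx
    if denom == 0:
        return np.hypot(py - ay, px - ax)
    t = np.clip(((py - ay) * dy + (px - ax) * dx) / denom, 0.0, 1.0)
    return np.hypot(py - (ay + t * dy), px - (ax + t * dx))


def roi_mask(image_shape: tuple[int, int], roi: RoiSpec) -> np.ndarray:
    """Boolean pixel-membership mask for `roi` (pixel-center distance rule)."""
    ny, nx = image_shape
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float), indexing="ij")
    if roi.kind == "circle_band":
        cy, cx = roi.center
        dist = np.hypot(yy - cy, xx - cx)
        return np.abs(dist - roi.radius) <= roi.width_px / 2.0
    if roi.kind == "disk":
        cy, cx = roi.center
        return np.hypot(yy - cy, xx - cx) <= roi.diameter_px / 2.0
    # polyline_band: distance to the nearest segment
    dmin = np.full(image_shape, np.inf)
    verts = list(roi.vertices)
    for a, b in zip(verts[:-1], verts[1:]):
        dmin = np.minimum(dmin, _segment_distance(yy, xx, a, b))
    return dmin <= roi.width_px / 2.0


def measure_roi_mean(image: np.ndarray, roi: RoiSpec) -> float:
    """Mean intensity of `image` over the pixels belonging to `roi`."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image (project the stack first)")
    mask = roi_mask(image.shape, roi)
    if not mask.any():
        raise ValueError("ROI covers no pixels of the image")
    return float(image[mask].mean())


def background_correct(
    raw_mean: float,
    image: np.ndarray,
    cytoplasm_roi: RoiSpec,
    sample_id: str = "sample",
    phase: str = "cytokinesis",
) -> IntensityRecord:
    """Subtract the mean cytoplasmic signal (default ROI: 10 px disk)."""
    background = measure_roi_mean(image, cytoplasm_roi)
    return IntensityRecord(
        sample_id=sample_id, phase=phase, raw_mean=float(raw_mean), background_mean=background
    )


# ---------------------------------------------------------------------------
# Cytokinesis-failure scoring
# ---------------------------------------------------------------------------

EVENT_COLUMNS = [
    "constriction_completed",
    "observed_post_min",
    "regressed",
    "regression_time_min",
    "pre_division_area_px",
]


def default_area_cap(events: pd.DataFrame) -> float:
    """Default "small cell" cap: twice the median pre-division area."""
    return 2.0 * float(events["pre_division_area_px"].median())


def score_division_events(
    events: pd.DataFrame,
    max_area_px: float,
    min_observed_min: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and classify division events into the three failure categories.

    Eligibility: cells with ``pre_division_area_px > max_area_px`` are
    dropped (prior-failure suspects), as are completed, non-regressing
    divisions observed for less than ``min_observed_min`` after constriction
    (a late failure could have been missed).  Events that neither completed
    constriction nor regressed are censored (the movie ended mid-furrowing)
    and are excluded with a QC count.  Both filters are pure row predicates,
    so their application order is irrelevant.

    Classification of the remainder:

    * category 1 — constriction completed, no regression;
    * category 2 — regression before constriction completed;
    * category 3 — regression after completed constriction.

    Returns
    -------
    scored : DataFrame
        Retained events with a ``category`` column.
    summary : DataFrame
        One row per group: eligible n, per-category counts and percentages,
        % failing (categories 2+3), mean and SD of the category-3 regression
        time, and counts of dropped rows by reason.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event log missing columns: {missing}")
    ev = events.copy()
    if "group" not in ev.columns:
        ev["group"] = "all"
    if (ev["observed_post_min"] < 0).any():
        raise ValueError("observed_post_min must be non-negative")
    bad = ev["regressed"].astype(bool) & ev["regression_time_min"].isna()
    if bad.any():
        raise ValueError("regressed events must carry regression_time_min")

    oversize = ev["pre_division_area_px"] > max_area_px
    short_obs = (
        ev["constriction_completed"].astype(bool)
        & ~ev["regressed"].astype(bool)
        & (ev["observed_post_min"] < min_observed_min)
    )
    censored = ~ev["constriction_completed"].astype(bool) & ~ev["regressed"].astype(bool)
    keep = ~(oversize | short_obs | censored)
    dropped = pd.DataFrame(
        {
            "group": ev["group"],
            "oversize": oversize & ~keep,
            "short_observation": short_obs & ~oversize,
            "censored": censored & ~oversize & ~short_obs,
        }
    )

    scored = ev[keep].copy()
    completed = scored["constriction_completed"].astype(bool)
    regressed = scored["regressed"].astype(bool)
    scored["category"] = np.select(
        [completed & ~regressed, ~completed & regressed, completed & regressed],
        [1, 2, 3],
    )

    rows = []
    for grp, sub in scored.groupby("group", sort=True):
        n = len(sub)
        counts = sub["category"].value_counts()
        c1, c2, c3 = (int(counts.get(c, 0)) for c in (1, 2, 3))
        reg_times = sub.loc[sub["category"] == 3, "regression_time_min"]
        drop_grp = dropped[dropped["group"] == grp]
        rows.append(
            {
                "group": grp,
                "n_eligible": n,
                "n_category_1": c1,
                "n_category_2": c2,
                "n_category_3": c3,
                "pct_category_1": 100.0 * c1 / n if n else np.nan,
                "pct_category_2": 100.0 * c2 / n if n else np.nan,
                "pct_category_3": 100.0 * c3 / n if n else np.nan,
                "pct_failure": 100.0 * (c2 + c3) / n if n else np.nan,
                "regression_time_mean_min": float(reg_times.mean()) if len(reg_times) else np.nan,
                "regression_time_sd_min": float(reg_times.std(ddof=1)) if len(reg_times) > 1 else np.nan,
                "n_dropped_oversize": int(drop_grp["oversize"].sum()),
                "n_dropped_short_observation": int(drop_grp["short_observation"].sum()),
                "n_dropped_censored": int(drop_grp["censored"].sum()),
            }
        )
    for grp in ev["group"].unique():
        if not any(r["group"] == grp for r in rows):
            drop_grp = dropped[dropped["group"] == grp]
            rows.append(
                {
                    "group": grp, "n_eligible": 0,
                    "n_category_1": 0, "n_category_2": 0, "n_category_3": 0,
                    "pct_category_1": np.nan, "pct_category_2": np.nan,
                    "pct_category_3": np.nan, "pct_failure": np.nan,
                    "regression_time_mean_min": np.nan, "regression_time_sd_min": np.nan,
                    "n_dropped_oversize": int(drop_grp["oversize"].sum()),
                    "n_dropped_short_observation": int(drop_grp["short_observation"].sum()),
                    "n_dropped_censored": int(drop_grp["censored"].sum()),
                }
            )
    summary = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    return scored, summary
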