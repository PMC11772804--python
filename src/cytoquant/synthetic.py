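"""Synthetic epithelium stacks, constriction traces and intensity scenes.

Every downstream stage of the pipeline (projection, segmentation, counting,
rate fitting, ROI quantification, event scoring) is exercised against data
produced here, with full ground truth, so the whole chain is testable without
any microscopy download.

The tissue generator emulates the surface view of a curved, non-proliferative
epithelial monolayer (a stage-10 follicular epithelium): polygonal cells from
a Voronoi tessellation of jittered-grid seeds, a membrane channel drawn along
cell boundaries on the planes straddling a dome-shaped surface, a nuclei
channel of 3D Gaussian blobs sitting on that surface, point-spread blur, and
Poisson–Gaussian camera noise.  Multinucleated cells are rendered by merging
adjacent seed cells — the shared interface carries no membrane signal and each
constituent seed contributes one nucleus — so the membrane channel stays
self-consistent with the ground-truth tessellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import binary_dilation, disk
from skimage.segmentation import find_boundaries

from cytoquant.constriction import DiameterTrace
from cytoquant.intensity import RoiSpec
from cytoquant.stack import TissueStack

# Rendering amplitudes (arbitrary camera units). Chosen so that default
# Poisson/Gaussian noise leaves both channels clearly above background while
# remaining visibly noisy; they are not fit to any real acquisition.
MEMBRANE_AMP = 600.0
NUCLEUS_AMP = 900.0
BACKGROUND = 30.0


@dataclass
class TissueSpec:
    """Parameters of a synthetic epithelial tissue stack.

    Defaults describe the study conditions used throughout the analysis:
    a 384x384 px field at 0.4 um/px (~150 um across), 12 optical sections at
    1 um spacing, ~390 cells (≈8 um across, large post-mitotic follicle
    cells), a gently domed surface, and moderate shot + read noise.  The
    field is kept large relative to a cell so that excluding border-touching
    cells (which disfavors the larger multinucleated cells) perturbs the
    scored population only marginally.
    """

    field_size_px: tuple[int, int] = (384, 384)
    n_planes: int = 12
    pixel_size_um: float = 0.4
    z_spacing_um: float = 1.0
    n_cells_target: int = 390
    multinucleation_fraction: float = 0.0
    nuclei_per_multi_cell: int = 2
    curvature_sag_um: float = 4.0
    membrane_width_px: float = 2.0
    nucleus_radius_um: float = 1.6
    psf_sigma_px: float = 1.0
    poisson_scale: float = 0.1
    gaussian_sd: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.field_size_px
        if ny <= 0 or nx <= 0 or self.n_planes <= 0:
            raise ValueError("field_size_px and n_planes must be positive")
        if self.pixel_size_um <= 0 or self.z_spacing_um <= 0:
            raise ValueError("pixel/z spacing must be positive")
        if self.n_cells_target < 4:
            raise ValueError("n_cells_target must be >= 4")
        if not 0.0 <= self.multinucleation_fraction <= 1.0:
            raise ValueError("multinucleation_fraction must be in [0, 1]")
        if self.nuclei_per_multi_cell < 2:
            raise ValueError("nuclei_per_multi_cell must be >= 2")
        if self.curvature_sag_um < 0 or self.membrane_width_px <= 0:
            raise ValueError("curvature_sag_um >= 0 and membrane_width_px > 0 required")
        if self.nucleus_radius_um <= 0:
            raise ValueError("nucleus_radius_um must be positive")
        if self.psf_sigma_px < 0 or self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("blur/noise parameters must be non-negative")
        z_extent = (self.n_planes - 1) * self.z_spacing_um
        if z_extent < self.curvature_sag_um + 2 * self.z_spacing_um:
            raise ValueError(
                "stack too shallow for curvature_sag_um: need "
                f"(n_planes-1)*z_spacing >= sag + 2*z_spacing, got {z_extent:.1f} um"
            )


@dataclass
class GroundTruth:
    """Simulator-side truth for one tissue stack.

    Attributes
    ----------
    cell_labels
        ``(ny, nx)`` integer array, the true tessellation (1-based cell ids,
        no background: the monolayer fills the field).
    nuclei
        One row per nucleus: ``nucleus_id, cell_id, x_px, y_px, z_um``.
    is_multinucleated
        ``cell_id -> bool``; exactly ``round(fraction * n_cells)`` true.
    """

    cell_labels: np.ndarray
    nuclei: pd.DataFrame
    is_multinucleated: dict[int, bool]

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())

    def nuclei_per_cell(self) -> pd.Series:
        """True nuclei count per cell id."""
        counts = self.nuclei.groupby("cell_id").size()
        return counts.reindex(range(1, self.n_cells + 1), fill_value=0)

    def cell_region(self, cell_id: int) -> np.ndarray:
        return self.cell_labels == cell_id

    def save(self, out_prefix: str | Path) -> None:
        """Write nuclei as CSV and the tessellation as a 16-bit label TIFF."""
        out_prefix = Path(out_prefix)
        self.nuclei.to_csv(out_prefix.with_suffix(".nuclei.csv"), index=False)
        tifffile.imwrite(
            out_prefix.with_suffix(".cells.tif"),
            self.cell_labels.astype(np.uint16),
        )


def surface_z_um(spec: TissueSpec, x_px, y_px) -> np.ndarray:
    """Physical z of the curved tissue surface at (x, y).

    The surface is an elliptic paraboloid dome centered in the field;
    ``curvature_sag_um`` is the peak-to-corner z offset.  The dome is placed
    so that its z range sits centered within the stack.
    """
    ny, nx = spec.field_size_px
    u = (np.asarray(x_px, dtype=float) - (nx - 1) / 2) / ((nx - 1) / 2)
    v = (np.asarray(y_px, dtype=float) - (ny - 1) / 2) / ((ny - 1) / 2)
    dome = 1.0 - (u * u + v * v) / 2.0  # 1 at center, 0 at corners
    z_lo = ((spec.n_planes - 1) * spec.z_spacing_um - spec.curvature_sag_um) / 2.0
    return z_lo + spec.curvature_sag_um * dome


def _seed_points(spec: TissueSpec, n_seeds: int, rng: np.random.Generator):
    """Jittered-grid seed coordinates, (n_seeds, 2) as (x, y)."""
    ny, nx = spec.field_size_px
    ncols = max(2, int(round(math.sqrt(n_seeds * nx / ny))))
    nrows = max(2, math.ceil(n_seeds / ncols))
    total = nrows * ncols
    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    cx = (cc.ravel() + 0.5) * nx / ncols
    cy = (rr.ravel() + 0.5) * ny / nrows
    pitch = math.sqrt(ny * nx / n_seeds)
    jitter = rng.uniform(-0.3, 0.3, size=(total, 2)) * pitch
    pts = np.column_stack([cx, cy]) + jitter
    pts[:, 0] = np.clip(pts[:, 0], 1.0, nx - 2.0)
    pts[:, 1] = np.clip(pts[:, 1], 1.0, ny - 2.0)
    keep = np.sort(rng.choice(total, size=n_seeds, replace=False))
    return pts[keep]


def _region_adjacency(labels: np.ndarray) -> dict[int, dict[int, int]]:
    """Adjacency between regions of a label map with shared-interface length.

    Returns ``region -> {neighbor: n_adjacent_pixel_pairs}`` (4-connectivity).
    """
    adj: dict[int, dict[int, int]] = {}
    for a, b in ((labels[:, :-1], labels[:, 1:]), (labels[:-1, :], labels[1:, :])):
        diff = a != b
        pairs, counts = np.unique(
            np.stack([np.minimum(a[diff], b[diff]), np.maximum(a[diff], b[diff])], axis=1),
            axis=0,
            return_counts=True,
        )
        for (u, w), c in zip(pairs, counts):
            u, w, c = int(u), int(w), int(c)
            adj.setdefault(u, {})[w] = adj.setdefault(u, {}).get(w, 0) + c
            adj.setdefault(w, {})[u] = adj.setdefault(w, {}).get(u, 0) + c
    return adj


def generate_epithelium_stack(spec: TissueSpec) -> tuple[TissueStack, GroundTruth]:
    """Render a two-channel tissue stack with known ground truth.

    Construction guarantees:

    * exactly ``round(multinucleation_fraction * n_cells_target)`` cells are
      multinucleated, each with exactly ``nuclei_per_multi_cell`` nuclei;
      every other cell has exactly one nucleus;
    * every nucleus (x, y) lies inside its cell's region, at the local
      surface z;
    * the run is bit-deterministic given ``spec`` (one seeded generator).

    Returns the stack (membrane = channel 0, nuclei = channel 1) and the
    :class:`GroundTruth`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.field_size_px
    k = spec.nuclei_per_multi_cell
    n_multi = int(round(spec.multinucleation_fraction * spec.n_cells_target))
    n_seeds = spec.n_cells_target + n_multi * (k - 1)

    pitch = math.sqrt(ny * nx / n_seeds)
    if pitch < 4.0:
        raise ValueError(
            f"field too small for n_cells_target: mean cell pitch {pitch:.1f} px < 4 px"
        )

    pts = _seed_points(spec, n_seeds, rng)

    # Voronoi tessellation of the pixel grid by nearest seed.
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    _, seed_idx = cKDTree(pts).query(pix)
    seed_idx = seed_idx.reshape(ny, nx)

    # Merge adjacent seed cells into multinucleated ground-truth cells.  A
    # multinucleated cell is a failed division, so the merged pair shares a
    # full division-plane interface: partners are taken in decreasing order
    # of shared-interface length, never across a corner sliver.
    adj = _region_adjacency(seed_idx)
    min_interface = 0.4 * pitch  # reject corner-contact "neighbors"
    unused = set(range(n_seeds))
    groups: list[list[int]] = []
    for s in rng.permutation(n_seeds):
        if len(groups) == n_multi:
            break
        s = int(s)
        if s not in unused:
            continue
        avail = sorted(
            (nb for nb, length in adj.get(s, {}).items()
             if nb in unused and length >= min_interface),
            key=lambda nb: (-adj[s][nb], nb),
        )
        if len(avail) >= k - 1:
            groups.append([s] + avail[: k - 1])
            unused -= set(groups[-1])
    if len(groups) < n_multi:
        raise RuntimeError(
            "could not place all multinucleated cells; lower the fraction or "
            "increase n_cells_target"
        )

    units = groups + [[s] for s in sorted(unused)]
    units.sort(key=min)  # deterministic cell ids by raster-most seed
    cell_of_seed = np.empty(n_seeds, dtype=np.int32)
    is_multi: dict[int, bool] = {}
    for cell_id, unit in enumerate(units, start=1):
        for s in unit:
            cell_of_seed[s] = cell_id
        is_multi[cell_id] = len(unit) > 1
    cell_labels = cell_of_seed[seed_idx]

    # One nucleus per seed, at the seed region's centroid (Voronoi regions are
    # convex, so the centroid is interior), on the local dome surface.
    npix = np.bincount(seed_idx.ravel(), minlength=n_seeds).astype(float)
    sx = np.bincount(seed_idx.ravel(), weights=xx.ravel(), minlength=n_seeds)
    sy = np.bincount(seed_idx.ravel(), weights=yy.ravel(), minlength=n_seeds)
    nuc_x = sx / npix
    nuc_y = sy / npix
    nuc_z = surface_z_um(spec, nuc_x, nuc_y)
    order = np.lexsort((np.arange(n_seeds), cell_of_seed))
    nuclei = pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n_seeds + 1),
            "cell_id": cell_of_seed[order],
            "x_px": nuc_x[order],
            "y_px": nuc_y[order],
            "z_um": nuc_z[order],
        }
    )

    # Membrane channel: boundary skeleton of the (merged) tessellation, on
    # every plane within +/- 1 plane of the local surface.
    mem2d = find_boundaries(cell_labels, mode="thick")
    extra = int(round((spec.membrane_width_px - 2) / 2))
    if extra > 0:
        mem2d = binary_dilation(mem2d, disk(extra))
    zsurf = surface_z_um(spec, xx, yy)
    plane_z = np.arange(spec.n_planes) * spec.z_spacing_um
    near_surface = (
        np.abs(plane_z[:, None, None] - zsurf[None]) <= spec.z_spacing_um + 1e-9
    )
    membrane = MEMBRANE_AMP * mem2d[None].astype(float) * near_surface

    # Nuclei channel: 3D Gaussian blobs (sigma = radius / 2, isotropic in
    # physical units) at the surface z of each nucleus.
    nucchan = np.zeros((spec.n_planes, ny, nx))
    s_um = spec.nucleus_radius_um / 2.0
    s_xy = s_um / spec.pixel_size_um
    s_z = s_um / spec.z_spacing_um
    hx = int(math.ceil(3 * s_xy))
    hz = int(math.ceil(3 * s_z))
    for row in nuclei.itertuples(index=False):
        x0, y0 = row.x_px, row.y_px
        z0 = row.z_um / spec.z_spacing_um
        xa = slice(max(0, int(x0) - hx), min(nx, int(x0) + hx + 1))
        ya = slice(max(0, int(y0) - hx), min(ny, int(y0) + hx + 1))
        za = slice(max(0, int(z0) - hz), min(spec.n_planes, int(z0) + hz + 2))
        zi = np.arange(za.start, za.stop, dtype=float)[:, None, None]
        yi = np.arange(ya.start, ya.stop, dtype=float)[None, :, None]
        xi = np.arange(xa.start, xa.stop, dtype=float)[None, None, :]
        blob = NUCLEUS_AMP * np.exp(
            -((xi - x0) ** 2 + (yi - y0) ** 2) / (2 * s_xy**2)
            - (zi - z0) ** 2 / (2 * s_z**2)
        )
        nucchan[za, ya, xa] += blob

    voxels = np.stack([membrane, nucchan]) + BACKGROUND
    if spec.psf_sigma_px > 0:
        voxels = ndimage.gaussian_filter(
            voxels, sigma=(0, 0, spec.psf_sigma_px, spec.psf_sigma_px)
        )
    if spec.poisson_scale > 0:
        voxels = rng.poisson(voxels * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.gaussian_sd, size=voxels.shape)
    voxels = np.clip(voxels, 0.0, None)

    stack = TissueStack(
        voxels=voxels,
        pixel_size_um=spec.pixel_size_um,
        z_spacing_um=spec.z_spacing_um,
        channel_roles={"membrane": 0, "nuclei": 1},
        meta={"seed": spec.seed, "spec": asdict(spec)},
    )
    truth = GroundTruth(cell_labels=cell_labels, nuclei=nuclei, is_multinucleated=is_multi)
    return stack, truth


# ---------------------------------------------------------------------------
# Ring-diameter traces
# ---------------------------------------------------------------------------


@dataclass
class TraceSpec:
    """Parameters of a synthetic ring-diameter trace.

    The trace has three regimes: a flat plateau before constriction onset, a
    constant-rate linear phase down to ``tail_fraction`` of the initial
    diameter, and a slope-continuous exponential tail approaching a small
    residual plateau (the midbody stage).  Defaults mimic a follicle-cell
    division: an 8 um ring (cells are ~8 um across) closing at 0.6 um/min,
    sampled once per minute over a 20 min movie.
    """

    d0_um: float = 8.0
    onset_time_min: float = 2.0
    rate_um_per_min: float = 0.6
    tail_fraction: float = 0.25
    dt_min: float = 1.0
    n_frames: int = 20
    noise_sd_um: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.d0_um <= 0 or self.rate_um_per_min <= 0 or self.dt_min <= 0:
            raise ValueError("d0_um, rate_um_per_min and dt_min must be positive")
        if self.onset_time_min < 0 or self.noise_sd_um < 0:
            raise ValueError("onset_time_min and noise_sd_um must be non-negative")
        if not 0.0 <= self.tail_fraction < 1.0:
            raise ValueError("tail_fraction must be in [0, 1)")
        if self.n_frames < 6:
            raise ValueError("n_frames must be >= 6")
        needed = self.onset_time_min + self.d0_um * (1 - self.tail_fraction) / self.rate_um_per_min
        if (self.n_frames - 1) * self.dt_min < needed:
            raise ValueError(
                "trace too short to contain onset plus the constant phase: "
                f"need >= {needed:.1f} min"
            )


def generate_constriction_trace(spec: TraceSpec, sample_id: str = "trace") -> DiameterTrace:
    """Deterministic (given seed) piecewise diameter trace d(t)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.dt_min
    d0, rate, tail = spec.d0_um, spec.rate_um_per_min, spec.tail_fraction
    d = np.full(spec.n_frames, d0, dtype=float)
    t_tail = spec.onset_time_min + d0 * (1 - tail) / rate
    lin = (t > spec.onset_time_min) & (t <= t_tail)
    d[lin] = d0 - rate * (t[lin] - spec.onset_time_min)
    after = t > t_tail
    if tail > 0:
        plateau = 0.3 * tail * d0
        tau = (tail * d0 - plateau) / rate  # slope-continuous at t_tail
        d[after] = plateau + (tail * d0 - plateau) * np.exp(-(t[after] - t_tail) / tau)
    else:
        d[after] = 0.0
    if spec.noise_sd_um > 0:
        d = d + rng.normal(0.0, spec.noise_sd_um, size=d.shape)
    d = np.clip(d, 1e-3, None)
    return DiameterTrace(t_min=t, d_um=d, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Intensity scenes
# ---------------------------------------------------------------------------


def generate_intensity_scene(
    shape: tuple[int, int],
    cortex_value: float,
    ring_value: float,
    cytoplasm_value: float,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TissueStack, dict]:
    """Render a single mitotic cell for ROI-quantification checks.

    The scene is a round cell: uniform cytoplasm, a circular cortex band of
    known mean intensity (3 px wide), a short bright ring segment through the
    equator, and a global additive ``offset`` (camera baseline).  Two
    identical planes each carry half the intensity, so a z-sum projection of
    both reproduces the nominal values exactly when ``noise_sd == 0``.

    Returns the stack (single channel, 2 planes) and a geometry dict with
    ready-made :class:`~cytoquant.intensity.RoiSpec` entries (``cortex``,
    ``ring``, ``cytoplasm``) plus the nominal values.
    """
    if min(shape) < 48:
        raise ValueError("scene must be at least 48 px on a side")
    for name, v in (("cortex", cortex_value), ("ring", ring_value),
                    ("cytoplasm", cytoplasm_value), ("offset", offset)):
        if v < 0:
            raise ValueError(f"{name} value must be non-negative")
    rng = np.random.default_rng(seed)
    ny, nx = shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    radius = 0.35 * min(ny, nx)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    dist = np.hypot(yy - cy, xx - cx)

    img = np.zeros(shape, dtype=float)
    img[dist <= radius + 1.5] = cytoplasm_value
    img[np.abs(dist - radius) <= 1.5] = cortex_value
    half_len = 5.0
    from cytoquant.intensity import _segment_distance

    seg_d = _segment_distance(
        yy.astype(float), xx.astype(float), (cy - half_len, cx), (cy + half_len, cx)
    )
    img[seg_d <= 1.5] = ring_value  # same membership rule as the line ROI
    img = img + offset

    planes = np.stack([img / 2.0, img / 2.0])
    if noise_sd > 0:
        planes = np.clip(planes + rng.normal(0.0, noise_sd, planes.shape), 0.0, None)

    stack = TissueStack(
        voxels=planes[None],  # one channel
        pixel_size_um=1.0,
        z_spacing_um=1.0,
        channel_roles={"signal": 0},
        meta={"seed": seed, "offset": offset},
    )
    geometry = {
        "cortex": RoiSpec(kind="circle_band", center=(cy, cx), radius=radius, width_px=3.0),
        "ring": RoiSpec(
            kind="polyline_band",
            vertices=[(cy - half_len, cx), (cy + half_len, cx)],
            width_px=3.0,
        ),
        "cytoplasm": RoiSpec(
            kind="disk", center=(cy, cx + radius / 2.0), diameter_px=10.0
        ),
        "cortex_value": cortex_value,
        "ring_value": ring_value,
        "cytoplasm_value": cytoplasm_value,
        "offset": offset,
    }
    return stack, geometry


# ---------------------------------------------------------------------------
# Division-event logs
# ---------------------------------------------------------------------------


def generate_division_events(
    n_events: int,
    proportions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    group: str = "sim",
    mean_regression_min: float = 25.0,
    area_mean_px: float = 400.0,
    n_oversize: int = 0,
    n_short_observation: int = 0,
    oversize_area_px: float = 2000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-division event log with planted outcome categories.

    Categories follow the three-way cytokinesis scoring: (1) success,
    (2) failure during ring constriction (regression before constriction
    completes), (3) post-constriction failure (regression after a completed
    constriction).  Planted counts are exact: ``round(p * n)`` for categories
    2 and 3, remainder category 1.  Optional distractors are appended:
    oversize cells (above any sensible area cap) and successful divisions
    observed for < 20 min, both of which the eligibility filters must drop.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    n2 = int(round(proportions[1] * n_events))
    n3 = int(round(proportions[2] * n_events))
    n1 = n_events - n2 - n3
    if min(n1, n2, n3) < 0:
        raise ValueError("proportions incompatible with n_events")

    rows = []

    def _area(n):
        return np.clip(rng.normal(area_mean_px, 0.12 * area_mean_px, n), 50, None)

    areas = _area(n_events + n_oversize + n_short_observation)
    i = 0
    for _ in range(n1):
        rows.append((True, float(rng.uniform(20.0, 60.0)), False, np.nan, areas[i], 1))
        i += 1
    for _ in range(n2):
        rows.append((False, float(rng.uniform(5.0, 30.0)), True,
                     float(rng.uniform(2.0, 8.0)), areas[i], 2))
        i += 1
    for _ in range(n3):
        reg = float(np.clip(rng.normal(mean_regression_min, 5.0), 1.0, None))
        rows.append((True, reg + float(rng.uniform(1.0, 20.0)), True, reg, areas[i], 3))
        i += 1
    for _ in range(n_oversize):
        rows.append((True, float(rng.uniform(20.0, 60.0)), False, np.nan,
                     oversize_area_px, 0))
        i += 1
    for _ in range(n_short_observation):
        rows.append((True, float(rng.uniform(1.0, 19.0)), False, np.nan, areas[i], 0))
        i += 1

    df = pd.DataFrame(
        rows,
        columns=[
            "constriction_completed",
            "observed_post_min",
            "regressed",
            "regression_time_min",
            "pre_division_area_px",
            "true_category",
        ],
    )
    df.insert(0, "cell_id", [f"{group}_{j:04d}" for j in range(len(df))])
    df.insert(1, "group", group)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
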