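"""Curvature-aware, nucleus-anchored local z-projection.

In a curved monolayer the epithelial surface — and with it every nucleus —
drifts through z across the field, so a single projection plane loses cells
at the periphery.  The local projection instead anchors each (y, x) pixel to
its nearest detected nucleus and projects a thin physical section (default
1 um) centered on that nucleus's axial position, following the tissue
surface.  The anchor assignment is a nearest-neighbor (Voronoi) partition of
the plane by nucleus centroids, ties broken toward the smaller nucleus id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from cytoquant.stack import TissueStack

_REDUCERS = {"max": np.max, "mean": np.mean, "sum": np.sum}


@dataclass
class NucleusAnchor:
    """A detected nucleus used as a projection anchor."""

    nucleus_id: int
    x_px: float
    y_px: float
    z_um: float


@dataclass
class SurfaceProjection:
    """Result of a local projection.

    ``image`` is ``(channel, y, x)``; ``anchor_map`` records which nucleus
    anchored each pixel and ``window_used`` the inclusive plane-index window
    ``(z_lo, z_hi)`` projected there.
    """

    image: np.ndarray
    anchor_map: np.ndarray
    window_used: np.ndarray  # (y, x, 2) int
    pixel_size_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(f"projection has no channel with role {role!r}")
        return self.image[self.channel_roles[role]]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.image.shape[1], self.image.shape[2]


def locate_nuclei_3d(stack: TissueStack, min_volume_vox: int = 30) -> list[NucleusAnchor]:
    """Detect nuclei in 3D and return their intensity-weighted centroids.

    The nuclei channel is thresholded globally (Otsu), connected components
    smaller than ``min_volume_vox`` voxels are discarded, and each surviving
    component yields one anchor at its intensity-weighted centroid with
    ``z_um = centroid_z * z_spacing``.  Components are numbered in raster
    order of their first voxel, which fixes the nearest-anchor tie-break.

    Returns an empty list when nothing survives (blank or featureless
    channel); the caller decides the fallback.
    """
    vol = np.asarray(stack.channel("nuclei"), dtype=float)
    if np.ptp(vol) == 0:
        return []
    mask = vol > threshold_otsu(vol)
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    ids = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(vol), labels, ids)
    keep = ids[sizes >= min_volume_vox]
    anchors = []
    centroids = ndimage.center_of_mass(vol, labels, keep)
    for new_id, (zc, yc, xc) in enumerate(centroids, start=1):
        anchors.append(
            NucleusAnchor(
                nucleus_id=new_id,
                x_px=float(xc),
                y_px=float(yc),
                z_um=float(zc) * stack.z_spacing_um,
            )
        )
    return anchors


def _window_planes(stack: TissueStack, z_um: float, thickness_um: float) -> tuple[int, int]:
    """Inclusive plane-index window whose centers lie within half-thickness.

    Falls back to the single nearest plane when the window is empty.
    """
    plane_z = np.arange(stack.n_planes) * stack.z_spacing_um
    inside = np.abs(plane_z - z_um) <= thickness_um / 2.0 + 1e-9
    if inside.any():
        idx = np.flatnonzero(inside)
        return int(idx[0]), int(idx[-1])
    nearest = int(np.argmin(np.abs(plane_z - z_um)))
    return nearest, nearest


def local_projection(
    stack: TissueStack,
    anchors: list[NucleusAnchor],
    thickness_um: float = 1.0,
    reducer: str = "max",
) -> SurfaceProjection:
    """Project a thin section around the nearest nucleus at every pixel.

    Both channels are reduced (default max) over the plane window centered,
    in physical z, on the anchoring nucleus of each pixel.
    """
    if not anchors:
        raise ValueError(
            "no anchors available; fall back to a global mid-stack projection "
            "(mid_stack_projection) instead"
        )
    if thickness_um <= 0:
        raise ValueError("thickness_um must be positive")
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}")
    reduce_fn = _REDUCERS[reducer]

    nz_y, nz_x = stack.voxels.shape[2], stack.voxels.shape[3]
    # Nearest anchor per pixel; cKDTree breaks exact ties toward the lower
    # index, and anchors are supplied in nucleus_id order.
    xy = np.array([(a.x_px, a.y_px) for a in anchors])
    yy, xx = np.meshgrid(np.arange(nz_y), np.arange(nz_x), indexing="ij")
    _, nearest = cKDTree(xy).query(np.column_stack([xx.ravel(), yy.ravel()]))
    nearest = nearest.reshape(nz_y, nz_x)

    windows = [_window_planes(stack, a.z_um, thickness_um) for a in anchors]
    unique_windows = sorted(set(windows))
    reduced = {
        w: reduce_fn(stack.voxels[:, w[0] : w[1] + 1], axis=1) for w in unique_windows
    }

    image = np.empty((stack.n_channels, nz_y, nz_x), dtype=float)
    window_used = np.empty((nz_y, nz_x, 2), dtype=np.int32)
    anchor_map = np.empty((nz_y, nz_x), dtype=np.int32)
    for ai, a in enumerate(anchors):
        sel = nearest == ai
        if not sel.any():
            continue
        w = windows[ai]
        image[:, sel] = reduced[w][:, sel]
        window_used[sel] = w
        anchor_map[sel] = a.nucleus_id

    return SurfaceProjection(
        image=image,
        anchor_map=anchor_map,
        window_used=window_used,
        pixel_size_um=stack.pixel_size_um,
        channel_roles=dict(stack.channel_roles),
    )


def mid_stack_projection(
    stack: TissueStack, thickness_um: float = 1.0, reducer: str = "max"
) -> SurfaceProjection:
    """Fixed projection around the stack's middle plane (flat-tissue fallback
    and the baseline the local projection is judged against)."""
    if reducer not in _REDUCERS:
        raise ValueError(f"reducer must be one of {sorted(_REDUCERS)}")
    z_mid = (stack.n_planes - 1) / 2.0 * stack.z_spacing_um
    w = _window_planes(stack, z_mid, thickness_um)
    image = _REDUCERS[reducer](stack.voxels[:, w[0] : w[1] + 1], axis=1).astype(float)
    ny, nx = stack.shape_yx
    window_used = np.broadcast_to(np.array(w, dtype=np.int32), (ny, nx, 2)).copy()
    return SurfaceProjection(
        image=image,
        anchor_map=np.zeros((ny, nx), dtype=np.int32),
        window_used=window_used,
        pixel_size_um=stack.pixel_size_um,
        channel_roles=dict(stack.channel_roles),
    )
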