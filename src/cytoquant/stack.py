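"""Two-channel 3D tissue stacks with physical calibration and TIFF I/O.

A :class:`TissueStack` is the pipeline's raw input: a ``(channel, z, y, x)``
intensity array plus the physical pixel/z spacing and a mapping of channel
roles (``membrane``, ``nuclei``) to channel indices.  Stacks round-trip to a
multi-page TIFF (channel-major plane order: all z-planes of channel 0, then
channel 1, ...) with a JSON sidecar carrying the calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class TissueStack:
    """Calibrated multi-channel image stack.

    Parameters
    ----------
    voxels
        4D non-negative intensity array, axis order ``(channel, z, y, x)``.
        Coordinates are 0-based with the pixel-center convention; plane ``i``
        sits at physical depth ``i * z_spacing_um``.
    pixel_size_um, z_spacing_um
        Lateral and axial sampling, micrometres.
    channel_roles
        Role name (for example ``"membrane"``, ``"nuclei"``) to channel index.
    meta
        Free-form metadata echoed into the JSON sidecar (seed, spec echo...).
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_spacing_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(
                f"voxels must be (channel, z, y, x); got {self.voxels.ndim} axes"
            )
        if self.pixel_size_um <= 0 or self.z_spacing_um <= 0:
            raise ValueError("pixel_size_um and z_spacing_um must be positive")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")
        n_chan = self.voxels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_chan:
                raise ValueError(f"channel role {role!r} -> {idx} out of range")
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel roles must map to distinct channels")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """3D ``(z, y, x)`` view of the channel carrying `role`."""
        if role not in self.channel_roles:
            raise KeyError(f"stack has no channel with role {role!r}")
        return self.voxels[self.channel_roles[role]]

    def plane_z_um(self, plane_index: int | np.ndarray) -> np.ndarray:
        """Physical z of plane centers (plane 0 at z = 0)."""
        return np.asarray(plane_index, dtype=float) * self.z_spacing_um

    # -- I/O -------------------------------------------------------------------

    def save(self, tiff_path: str | Path) -> Path:
        """Write a channel-major multi-page TIFF plus a JSON sidecar.

        The sidecar is ``<stem>.json`` next to the TIFF and records shape,
        calibration, channel roles and metadata; :meth:`load` restores the
        stack from the pair.
        """
        tiff_path = Path(tiff_path)
        pages = self.voxels.reshape(-1, *self.voxels.shape[2:])
        tifffile.imwrite(tiff_path, pages.astype(np.float32))
        sidecar = {
            "shape_czyx": list(self.voxels.shape),
            "pixel_size_um": self.pixel_size_um,
            "z_spacing_um": self.z_spacing_um,
            "channel_roles": self.channel_roles,
            "plane_order": "channel-major",
            "meta": _jsonable(self.meta),
        }
        tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return tiff_path

    @classmethod
    def load(cls, tiff_path: str | Path) -> "TissueStack":
        tiff_path = Path(tiff_path)
        sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
        pages = tifffile.imread(tiff_path)
        voxels = np.asarray(pages).reshape(sidecar["shape_czyx"])
        return cls(
            voxels=voxels,
            pixel_size_um=sidecar["pixel_size_um"],
            z_spacing_um=sidecar["z_spacing_um"],
            channel_roles={k: int(v) for k, v in sidecar["channel_roles"].items()},
            meta=sidecar.get("meta", {}),
        )


def _jsonable(obj):
    """Best-effort conversion of metadata values to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
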