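"""Image containers and TIFF/YAML I/O.

Confocal stacks are stored z-major (z, y, x), or (c, z, y, x) for
multichannel data, with voxel sizes in µm.  The default z-step of 0.13 µm
matches Nyquist-sampled 3D confocal acquisition with a high-NA objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidParameterError

DEFAULT_DZ = 0.13  # µm

CHANNEL_ROLES = (
    "lamin",
    "actin",
    "vecad",
    "yap",
    "vinculin",
    "pmlc",
    "dna",
    "multi",
)


@dataclass
class ImageStack:
    """An intensity grid with physical voxel sizes and a channel role.

    ``data`` may be 2D (y, x), 3D (z, y, x) or 4D (c, z, y, x).
    ``voxel_size`` is (dx, dy, dz) in µm.
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float] = (0.1, 0.1, DEFAULT_DZ)
    channel: str = "lamin"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2 or self.data.ndim > 4:
            raise InvalidParameterError("data must be 2D, 3D or 4D")
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel sizes must be positive")
        if self.channel not in CHANNEL_ROLES:
            raise InvalidParameterError(f"unknown channel role {self.channel!r}")

    @property
    def dx(self) -> float:
        return self.voxel_size[0]

    @property
    def dy(self) -> float:
        return self.voxel_size[1]

    @property
    def dz(self) -> float:
        return self.voxel_size[2]

    @property
    def pixel_area(self) -> float:
        return self.dx * self.dy

    @property
    def voxel_volume(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def n_planes(self) -> int:
        if self.data.ndim == 2:
            return 1
        return self.data.shape[-3]

    def max_projection(self) -> np.ndarray:
        """Maximum-intensity projection along z (identity for 2D data)."""
        if self.data.ndim == 2:
            return self.data
        if self.data.ndim == 4:
            return self.data.sum(axis=0).max(axis=0)
        return self.data.max(axis=0)

    def plane(self, z: int) -> "ImageStack":
        if self.data.ndim == 2:
            if z != 0:
                raise InvalidParameterError("2D stack has a single plane")
            return self
        return ImageStack(self.data[..., z, :, :], self.voxel_size, self.channel)


def save_stack(stack: ImageStack, tiff_path: str) -> None:
    """Write a stack as multipage TIFF plus a YAML sidecar with voxel sizes
    and the channel role."""
    import tifffile
    import yaml

    tifffile.imwrite(tiff_path, np.asarray(stack.data, dtype=np.float32))
    meta = {
        "voxel_size_um": [float(v) for v in stack.voxel_size],
        "channel": stack.channel,
        "axes": "ZYX" if stack.data.ndim == 3 else ("CZYX" if stack.data.ndim == 4 else "YX"),
    }
    with open(str(tiff_path) + ".yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_stack(tiff_path: str, sidecar: Optional[str] = None) -> ImageStack:
    import tifffile
    import yaml

    data = tifffile.imread(tiff_path)
    sidecar = sidecar or str(tiff_path) + ".yaml"
    try:
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        voxel = tuple(meta.get("voxel_size_um", (0.1, 0.1, DEFAULT_DZ)))
        channel = meta.get("channel", "lamin")
    except FileNotFoundError:
        voxel, channel = (0.1, 0.1, DEFAULT_DZ), "lamin"
    return ImageStack(data, voxel, channel)


def save_labels(labels: np.ndarray, path: str) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def load_labels(path: str) -> np.ndarray:
    import tifffile

    return tifffile.imread(path).astype(np.int32)
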