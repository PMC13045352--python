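"""The universal raster currency: a 3D intensity grid with physical voxel sizes.

Conventions shared by every module:

* array axis order is ``(z, y, x)`` (``(c, z, y, x)`` for multi-channel data);
* all physical quantities are nanometres;
* the coordinate frame is right-handed with 0-based voxel indices and voxel
  *centers* at ``(i + 0.5) * voxel_size`` along each axis, so physical point
  coordinates are also ordered ``(z, y, x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageVolume", "voxel_centers", "phys_to_index", "index_to_phys"]


def voxel_centers(shape, voxel_size):
    """Per-axis arrays of physical voxel-center coordinates (nm)."""
    return tuple(
        (np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)
    )


def phys_to_index(points, voxel_size):
    """Convert physical (z,y,x) nm coordinates to fractional voxel indices."""
    return np.asarray(points, dtype=float) / np.asarray(voxel_size, float) - 0.5


def index_to_phys(indices, voxel_size):
    """Convert (fractional) voxel indices to physical (z,y,x) nm coordinates."""
    return (np.asarray(indices, dtype=float) + 0.5) * np.asarray(voxel_size, float)


@dataclass
class ImageVolume:
    """3D (optionally multi-channel) intensity grid with voxel sizes in nm.

    Parameters
    ----------
    data:
        ``(z, y, x)`` or ``(c, z, y, x)`` float array of intensities.
    voxel_size:
        physical size of one voxel, ``(dz, dy, dx)`` in nm.
    channel_names:
        optional marker labels, one per channel.
    metadata:
        free-form provenance (calibration applied, seed, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_names: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive numbers, got {self.voxel_size}")
        if self.channel_names is not None and self.data.ndim == 4:
            if len(self.channel_names) != self.data.shape[0]:
                raise ValueError("channel_names length does not match channel axis")

    # -- basic queries -----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0] if self.data.ndim == 4 else 1

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (nm) of the volume along (z, y, x)."""
        return tuple(n * v for n, v in zip(self.spatial_shape, self.voxel_size))

    def channel(self, key) -> np.ndarray:
        """A single-channel (z,y,x) view, by index or by channel name."""
        if self.data.ndim == 3:
            if key in (0, None) or (self.channel_names and key == self.channel_names[0]):
                return self.data
            raise KeyError(f"single-channel volume has no channel {key!r}")
        if isinstance(key, str):
            if not self.channel_names or key not in self.channel_names:
                raise KeyError(f"unknown channel {key!r}; have {self.channel_names}")
            key = self.channel_names.index(key)
        return self.data[key]

    def copy(self) -> "ImageVolume":
        return ImageVolume(
            self.data.copy(),
            self.voxel_size,
            list(self.channel_names) if self.channel_names else None,
            dict(self.metadata),
        )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> Path:
        """Write a multi-page TIFF plus a JSON side-car with the voxel size.

        The voxel size also goes into the ImageJ-style TIFF metadata so the
        stack opens correctly in external viewers.
        """
        path = Path(path)
        data = self.data.astype(np.float32)
        dz, dy, dx = self.voxel_size
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={
                "spacing": dz,
                "unit": "nm",
                "axes": "CZYX" if data.ndim == 4 else "ZYX",
            },
        )
        sidecar = {
            "voxel_size_nm": list(self.voxel_size),
            "axes": "czyx" if data.ndim == 4 else "zyx",
            "channel_names": self.channel_names,
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path, voxel_size=None) -> "ImageVolume":
        """Read a TIFF stack; voxel size from TIFF metadata, side-car JSON or
        the explicit override — in that priority order.

        Raises ``ValueError`` if no source provides a voxel size: a default of
        1 nm is never silently assumed.
        """
        path = Path(path)
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_voxel = _voxel_from_tiff(tf)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        channel_names = None
        metadata = {}
        sidecar_voxel = None
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            sidecar_voxel = sidecar.get("voxel_size_nm")
            channel_names = sidecar.get("channel_names")
            metadata = sidecar.get("metadata", {})
        vs = meta_voxel or sidecar_voxel or voxel_size
        if meta_voxel and sidecar_voxel and np.allclose(meta_voxel, sidecar_voxel, rtol=1e-5):
            vs = sidecar_voxel  # TIFF stores rational approximations; side-car is exact
        if vs is None:
            raise ValueError(
                f"{path}: voxel size not found in TIFF metadata or side-car JSON "
                "and no override given; pass voxel_size explicitly"
            )
        if data.ndim == 2:
            data = data[None]
        return cls(np.asarray(data, dtype=np.float32), tuple(vs), channel_names, metadata)


def _voxel_from_tiff(tf: "tifffile.TiffFile"):
    """Extract (dz, dy, dx) in nm from ImageJ TIFF metadata, if present."""
    ij = tf.imagej_metadata
    if not ij or "spacing" not in ij:
        return None
    if ij.get("unit") not in ("nm", "nanometer"):
        return None
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    return (float(ij["spacing"]), float(dy), float(dx))
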