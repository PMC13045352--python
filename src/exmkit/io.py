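"""File formats, run configuration and output manifests.

All physical quantities are serialized in nm / nm^2 / nm^3; pixel units
never leave the I/O boundary.  Every run writes a config echo next to its
outputs, and ``write_outputs`` produces a manifest listing each artifact
with a checksum and the hash of the producing configuration, so full
pipeline runs are verifiable end to end.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .volume import ImageVolume

__all__ = ["RunConfig", "read_volume", "write_outputs"]


@dataclass
class RunConfig:
    """Serializable parameters of one CLI run."""

    command: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    inputs: list = field(default_factory=list)
    out_dir: str = "."
    log_level: str = "INFO"
    ef_source: str = "intrinsic"

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "params": self.params,
            "seed": self.seed,
            "inputs": list(self.inputs),
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "ef_source": self.ef_source,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def echo(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"config_{self.command}.json"
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def read_volume(path, voxel_size=None) -> ImageVolume:
    """Read a multi-page TIFF; voxel size from TIFF metadata, side-car JSON,
    or the explicit override — strictly in that priority order.  A missing
    voxel size is an error, never a silent 1 nm assumption."""
    return ImageVolume.load(path, voxel_size=voxel_size)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(artifacts: dict, out_dir, config: RunConfig | None = None, overwrite: bool = False) -> dict:
    """Write artifacts and return (and save) a manifest.

    ``artifacts`` maps a relative filename to a writer: either bytes/str
    content, a callable ``f(path)`` that writes the file, or an object with a
    ``save``/``export``/``to_csv`` method matched by suffix.  Existing files
    raise unless ``overwrite`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, writer in artifacts.items():
        path = out_dir / name
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
        path.parent.mkdir(parents=True, exist_ok=True)
        if callable(writer):
            writer(path)
        elif isinstance(writer, bytes):
            path.write_bytes(writer)
        elif isinstance(writer, str):
            path.write_text(writer)
        elif isinstance(writer, ImageVolume):
            writer.save(path)
        elif hasattr(writer, "to_csv"):
            writer.to_csv(path, index=False)
        else:
            raise TypeError(f"cannot write artifact {name!r} of type {type(writer)}")
        entries.append(
            {
                "file": name,
                "type": path.suffix.lstrip("."),
                "sha256": _checksum(path),
                "config_hash": config.config_hash() if config else None,
            }
        )
    manifest = {
        "n_artifacts": len(entries),
        "artifacts": entries,
        "seed": config.seed if config else None,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
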