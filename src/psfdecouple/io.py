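"""Stack I/O (TIFF / OME-TIFF) and reproducibility manifests.

Stacks travel as multi-page grayscale TIFF, axis order (z, y, x).  Voxel
sizes are written as OME ``PhysicalSize{X,Y,Z}`` metadata (in micrometres,
per the OME convention) and recovered on read; when a plain TIFF carries no
metadata the caller must supply voxel sizes explicitly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from .errors import ConfigurationError, FormatError, ValidationError
from .stacks import VolumeStack

__all__ = ["read_stack", "write_stack", "RunManifest"]

_SUPPORTED_KINDS = {"u": (8, 16), "i": (8, 16), "f": (32, 64)}


def read_stack(
    path: str | Path,
    *,
    voxel_xy_nm: float | None = None,
    voxel_z_nm: float | None = None,
) -> VolumeStack:
    """Read a multi-page TIFF as a float-valued :class:`VolumeStack`.

    Grayscale 8/16-bit integer and 32/64-bit float files are accepted;
    integer values are preserved exactly as floats.  Voxel sizes come from
    OME metadata when present, else from the keyword arguments; missing
    both raises :class:`ConfigurationError`.
    """

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel != 1:
            raise FormatError(f"{path}: RGB/multi-sample TIFF is not supported")
        data = tif.asarray()
        ome = tif.ome_metadata
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale z-stack, got array of shape {data.shape}"
        )
    kind, bits = data.dtype.kind, data.dtype.itemsize * 8
    if kind not in _SUPPORTED_KINDS or bits not in _SUPPORTED_KINDS[kind]:
        raise FormatError(f"{path}: unsupported sample format {data.dtype}")

    if ome:
        meta_xy, meta_z = _voxel_from_ome(ome)
        voxel_xy_nm = voxel_xy_nm if voxel_xy_nm is not None else meta_xy
        voxel_z_nm = voxel_z_nm if voxel_z_nm is not None else meta_z
    if voxel_xy_nm is None or voxel_z_nm is None:
        raise ConfigurationError(
            f"{path}: no voxel-size metadata; pass voxel_xy_nm and voxel_z_nm"
        )
    return VolumeStack(data.astype(np.float64), voxel_xy_nm, voxel_z_nm)


def _voxel_from_ome(ome_xml: str) -> tuple[float | None, float | None]:
    def grab(attr: str) -> float | None:
        m = re.search(rf'{attr}="([0-9.eE+-]+)"', ome_xml)
        return float(m.group(1)) * 1000.0 if m else None  # um -> nm

    x = grab("PhysicalSizeX")
    z = grab("PhysicalSizeZ")
    return x, z


def write_stack(
    stack: VolumeStack, path: str | Path, *, dtype: str = "float32"
) -> None:
    """Write a stack as OME-TIFF with voxel-size metadata.

    ``dtype`` may be ``float32`` (default) or ``uint16``; exporting values
    outside [0, 65535] as uint16 raises instead of silently clipping.
    """

    if not np.all(np.isfinite(stack.data)):
        raise ValidationError("refusing to write non-finite values")
    if dtype == "float32":
        data = stack.data.astype(np.float32)
    elif dtype == "uint16":
        if stack.data.min() < 0 or stack.data.max() > 65535:
            raise ValidationError("data out of uint16 range; rescale before export")
        data = np.round(stack.data).astype(np.uint16)
    else:
        raise ValidationError(f"unsupported export dtype {dtype!r}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.voxel_xy_nm / 1000.0,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.voxel_xy_nm / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.voxel_z_nm / 1000.0,
            "PhysicalSizeZUnit": "µm",
        },
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int | None] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def record_file(self, role: str, path: str | Path, *, output: bool = False) -> None:
        digest = _sha256(Path(path))
        (self.outputs if output else self.inputs)[str(path)] = digest
        _ = role  # role kept for call-site readability

    def write(self, path: str | Path) -> None:
        """Atomically write the manifest as JSON (temp file + rename)."""
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(self.__dict__, fh, indent=2, default=str)
                fh.write("\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
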