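"""Volume readers/writers (NIfTI, MetaImage) and run manifests.

Volumes are written with spacing/origin in the image header plus a small
JSON sidecar carrying the unit tag and grid geometry; on read, a present
sidecar is cross-checked against the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .grids import GridSpec, Volume

__all__ = ["read_volume", "write_volume", "write_manifest", "read_manifest"]

_SUPPORTED = (".nii", ".nii.gz", ".mha", ".mhd")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _SUPPORTED:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    raise ValueError(f"unsupported volume format: {path} (expected one of {_SUPPORTED})")


def write_volume(volume: Volume, path) -> Path:
    """Write a volume as NIfTI or MetaImage with a JSON sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(volume.grid.spacing))
    img.SetOrigin(tuple(volume.grid.origin))
    sitk.WriteImage(img, str(path))
    sidecar.write_text(
        json.dumps(
            {
                "unit": volume.unit,
                "shape": list(volume.grid.shape),
                "spacing_mm": list(volume.grid.spacing),
                "origin_mm": list(volume.grid.origin),
            },
            indent=2,
        )
    )
    return path


def read_volume(path) -> Volume:
    """Read a NIfTI/MetaImage volume; validate against its sidecar if present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = GridSpec(tuple(values.shape), tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    unit = "1"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        unit = meta.get("unit", "1")
        if tuple(meta["shape"]) != grid.shape:
            raise ValueError(f"sidecar shape {meta['shape']} != header shape {grid.shape}")
        for key, have in (("spacing_mm", grid.spacing), ("origin_mm", grid.origin)):
            want = meta[key]
            if not np.allclose(want, have, rtol=1e-5, atol=1e-5):
                raise ValueError(f"sidecar {key} {want} != header {list(have)}")
    return Volume(grid, values, unit)


def write_manifest(manifest: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_default))
    return path


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
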