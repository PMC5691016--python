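"""File formats: delimited-text profiles and raw-binary dose grids with sidecars.

Profiles are 2-column tab-separated text with a ``#``-prefixed header carrying
axis, units and normalization mode; values are written with 12 significant
digits so a write/read round trip is identity to better than 1e-9 relative.

Dose grids are stored as a pair of files: ``<base>.raw`` holding the voxel
values as little-endian 32-bit floats in C order with z slowest (``[iz, iy,
ix]``), and ``<base>.json`` holding dims, spacing, origin, dtype and axis
order. The reader validates the payload size against the sidecar before
reshaping.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .beam import DoseGrid
from .errors import GridFormatError, ProfileFormatError
from .profiles import Profile

__all__ = ["read_profile", "write_profile", "read_grid", "write_grid"]

_PROFILE_MAGIC = "# protondosim profile"


def write_profile(profile: Profile, path: str | Path) -> Path:
    """Write a profile as headered tab-separated text."""
    path = Path(path)
    lines = [
        _PROFILE_MAGIC,
        f"# axis: {profile.axis}",
        "# units: position_mm, relative_dose",
        f"# normalization: {profile.normalization}",
        "position_mm\trelative_dose",
    ]
    for x, d in zip(profile.positions, profile.dose):
        lines.append(f"{x:.12g}\t{d:.12g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_profile(path: str | Path) -> Profile:
    """Read a profile written by :func:`write_profile`.

    Raises :class:`ProfileFormatError` with the offending line number on any
    malformed row, and on a missing or foreign header. Parsing uses
    locale-independent float conversion.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith(_PROFILE_MAGIC):
        raise ProfileFormatError(
            f"{path} is not a protondosim profile (missing header)", line=1
        )
    axis = "depth"
    normalization = "raw"
    data_start = None
    for i, line in enumerate(lines[1:], start=2):
        if line.startswith("# axis:"):
            axis = line.split(":", 1)[1].strip()
        elif line.startswith("# normalization:"):
            normalization = line.split(":", 1)[1].strip()
        elif line.startswith("#"):
            continue
        else:
            data_start = i
            break
    if data_start is None:
        raise ProfileFormatError(f"{path} has no data rows")
    first = lines[data_start - 1]
    if first.strip() != "position_mm\trelative_dose":
        raise ProfileFormatError(
            f"expected column header 'position_mm<TAB>relative_dose', got {first!r}",
            line=data_start,
        )
    xs, ds = [], []
    for i, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ProfileFormatError(f"expected 2 tab-separated fields, got {len(parts)}", line=i)
        try:
            xs.append(float(parts[0]))
            ds.append(float(parts[1]))
        except ValueError as exc:
            raise ProfileFormatError(str(exc), line=i) from exc
    return Profile(np.asarray(xs), np.asarray(ds), axis=axis, normalization=normalization)


def write_grid(grid: DoseGrid, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.raw`` (little-endian float32, z slowest) + ``<base>.json``."""
    base = Path(base)
    raw_path = base.with_suffix(".raw")
    meta_path = base.with_suffix(".json")
    payload = np.ascontiguousarray(grid.values, dtype="<f4")
    raw_path.write_bytes(payload.tobytes())
    meta = {
        "dims_zyx": list(grid.values.shape),
        "spacing_mm_zyx": list(grid.spacing),
        "origin_mm_zyx": list(grid.origin),
        "dtype": "<f4",
        "order": "C, z slowest (index [iz, iy, ix])",
        "meta": grid.meta,
    }
    meta_path.write_text(json.dumps(meta, indent=1) + "\n")
    return raw_path, meta_path


def read_grid(base: str | Path) -> DoseGrid:
    """Read a grid pair written by :func:`write_grid`; bit-exact round trip."""
    base = Path(base)
    raw_path = base.with_suffix(".raw")
    meta_path = base.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    dims = tuple(int(n) for n in meta["dims_zyx"])
    expected = int(np.prod(dims)) * 4
    payload = raw_path.read_bytes()
    if len(payload) != expected:
        raise GridFormatError(
            f"{raw_path}: payload is {len(payload)} bytes but the sidecar "
            f"dims {dims} require {expected} bytes"
        )
    values = np.frombuffer(payload, dtype="<f4").reshape(dims)
    return DoseGrid(
        spacing=tuple(meta["spacing_mm_zyx"]),
        origin=tuple(meta["origin_mm_zyx"]),
        values=values.copy(),
        meta=meta.get("meta", {}),
    )
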