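"""Grid and report I/O: CSV matrices with JSON sidecars.

Every grid is written as a plain CSV matrix (full float precision) next to
a `<name>.json` sidecar carrying the geometry and physics metadata (grid
origin, cell size, far field, infinite-plane total, units, provenance).
Reads are strict: missing sidecar fields, shape mismatches, and NaN values
are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import CELL_SIZE, GRID_ORIGIN
from .isodose import DoseDensityGrid
from .transport import KermaGrid

_REQUIRED_SIDECAR = ("origin", "cell_size", "far_field", "units", "kind")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_grid(grid, path) -> Path:
    """Write a KermaGrid or DoseDensityGrid as CSV + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, grid.values, delimiter=",", fmt="%.17g")
    if isinstance(grid, KermaGrid):
        meta = {
            "kind": "kerma",
            "origin": list(grid.origin),
            "cell_size": grid.cell_size,
            "far_field": grid.far_field,
            "total_infinite": grid.total_infinite,
            "units": grid.units,
            "observation_point": grid.observation_point,
            "source_depth_cm": grid.source_depth_cm,
            "house_variant": grid.house_variant,
        }
    elif isinstance(grid, DoseDensityGrid):
        meta = {
            "kind": "density",
            "origin": list(GRID_ORIGIN),
            "cell_size": CELL_SIZE,
            "far_field": grid.far_field,
            "total": grid.total,
            "units": "pGy per gamma mm^-2",
            "label": grid.label,
        }
    else:
        raise TypeError(f"cannot serialise {type(grid).__name__}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_grid(path):
    """Read a grid written by write_grid; validates sidecar and values."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _REQUIRED_SIDECAR if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} missing fields: {missing}")
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"grid {path} contains non-finite values")
    if meta["kind"] == "kerma":
        grid = KermaGrid(
            observation_point=meta["observation_point"],
            source_depth_cm=meta["source_depth_cm"],
            values=values,
            far_field=meta["far_field"],
            house_variant=meta.get("house_variant", ""),
            origin=tuple(meta["origin"]),
            cell_size=meta["cell_size"],
            units=meta["units"],
        )
        total = meta.get("total_infinite")
        if total is not None and abs(grid.total_infinite - total) > 1e-6 * max(total, 1.0):
            raise ValueError(f"grid {path}: totals disagree with sidecar")
        return grid
    if meta["kind"] == "density":
        return DoseDensityGrid(values=values, far_field=meta["far_field"],
                               label=meta.get("label", ""))
    raise ValueError(f"unknown grid kind {meta['kind']!r}")


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path
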