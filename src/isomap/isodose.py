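"""Isodose zones: dose-contribution densities, thresholds, and occupancy.

The dose contribution density over the source grid is thresholded to find
the smallest-area set of cells that contributes at least a fraction k of
the infinite-plane total at an observation point; the threshold value is
the isodose ID_k.  With occupancy factors p_i (fraction of indoor time at
observation point i, summing to 1) the same construction applies to the
p-weighted density, and the single-point case is recovered for a
degenerate occupancy.

The mask is the smallest-area cell set reaching the requested fraction:
cells strictly above the threshold plus just enough threshold-tied cells,
taken in deterministic raster order, so the achieved fraction may slightly
exceed k.  The far field — ground beyond the calculation grid — can never
be enclosed by an isodose; if the in-grid cells cannot reach the requested
fraction the result is flagged unreachable and the mask covers every
source cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import box, mapping
from shapely.ops import unary_union

from .geometry import CELL_SIZE, GRID_ORIGIN, HouseModel
from .transport import KermaGrid

DEFAULT_K_FRACTIONS = (0.25, 0.5, 0.75, 0.9)


@dataclass
class OccupancyProfile:
    """Hours spent per room and the derived per-point occupancy factors."""

    hours: dict[str, float]
    point_order: tuple[int, ...]
    p: np.ndarray  # aligned with point_order; sums to 1

    @property
    def total_hours(self) -> float:
        return float(sum(self.hours.values()))

    def factor(self, point_index: int) -> float:
        return float(self.p[self.point_order.index(point_index)])

    def restrict_to(self, points) -> "OccupancyProfile":
        """Zero out factors outside `points` and renormalise (for runs on a
        subset of observation points)."""
        keep = np.array([i in set(points) for i in self.point_order])
        p = self.p * keep
        if p.sum() <= 0:
            raise ValueError("no occupancy left on the selected points")
        return OccupancyProfile(hours=dict(self.hours),
                                point_order=self.point_order, p=p / p.sum())


# Daily hours spent at home in each room, from European time-budget
# surveys: 14 h indoors at home in total.
STANDARD_HOURS = {
    "kitchen": 1.0,
    "dining": 1.0,
    "bedroom": 8.0,
    "bathroom": 0.5,
    "living": 3.5,
}


def occupancy_from_hours(hours: dict[str, float],
                         house: HouseModel) -> OccupancyProfile:
    """Occupancy factors p_i = hours_i / total over the house's points.

    Rooms without stated hours get p = 0.  Room names must exist in the
    house; every observation point inherits the hours of its room.
    """
    if any(h < 0 for h in hours.values()):
        raise ValueError("hours must be >= 0")
    room_names = {r.name for r in house.rooms}
    unknown = set(hours) - room_names
    if unknown:
        raise KeyError(f"rooms not in house: {sorted(unknown)}")
    total = sum(hours.values())
    if total <= 0:
        raise ValueError("at least one room must have positive hours")
    order = tuple(p.index for p in house.observation_points)
    p = np.array([hours.get(pt.room, 0.0) / total
                  for pt in house.observation_points])
    return OccupancyProfile(hours=dict(hours), point_order=order, p=p)


def single_point_occupancy(point_index: int, house: HouseModel) -> OccupancyProfile:
    """Degenerate occupancy: all time at one observation point."""
    order = tuple(p.index for p in house.observation_points)
    p = np.array([1.0 if i == point_index else 0.0 for i in order])
    if p.sum() == 0:
        raise KeyError(f"no observation point #{point_index}")
    room = house.observation_point(point_index).room
    return OccupancyProfile(hours={room: 1.0}, point_order=order, p=p)


@dataclass
class DoseDensityGrid:
    """Per-cell dose contribution density plus far-field remainder."""

    values: np.ndarray
    far_field: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or self.far_field < 0:
            raise ValueError("densities must be >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum() + self.far_field)

    @property
    def in_grid_fraction(self) -> float:
        return float(self.values.sum() / self.total)


def weighted_density(grids: list[KermaGrid],
                     occupancy: OccupancyProfile) -> DoseDensityGrid:
    """Occupancy-weighted cellwise sum of per-point kerma grids.

    All grids must share shape and source depth/scenario; the far field is
    weighted identically.  With a degenerate occupancy this reduces to the
    single point's grid.
    """
    if not grids:
        raise ValueError("no grids")
    shape = grids[0].values.shape
    depth = grids[0].source_depth_cm
    if any(g.values.shape != shape for g in grids):
        raise ValueError("grid shape mismatch")
    if any(g.source_depth_cm != depth for g in grids):
        raise ValueError("grids mix source depths")
    by_point = {g.observation_point: g for g in grids}
    values = np.zeros(shape)
    ff = 0.0
    for idx, w in zip(occupancy.point_order, occupancy.p):
        if w == 0.0:
            continue
        try:
            g = by_point[idx]
        except KeyError:
            raise ValueError(f"missing grid for observation point #{idx}")
        values += w * g.values
        ff += w * g.far_field
    return DoseDensityGrid(values=values, far_field=ff,
                           label=f"depth={depth}cm occupancy-weighted")


def primary_dose_factor(grids: list[KermaGrid],
                        occupancy: OccupancyProfile) -> float:
    """Occupancy-weighted infinite-plane total (pGy per photon mm^-2)."""
    by_point = {g.observation_point: g for g in grids}
    total = 0.0
    for idx, w in zip(occupancy.point_order, occupancy.p):
        if w == 0.0:
            continue
        total += w * by_point[idx].total_infinite
    return float(total)


@dataclass
class IsodoseResult:
    """A thresholded dose-density grid: the discrete isodose zone."""

    k: float
    threshold: float          # ID_k: density of the last included cell
    mask: np.ndarray          # boolean cell matrix
    k_achieved: float
    enclosed_area: float      # m^2
    unreachable: bool = False


def isodose_threshold(density: DoseDensityGrid, k: float) -> IsodoseResult:
    """Smallest-area superlevel set contributing at least fraction k.

    Cells are sorted by density descending (stable, so ties resolve in
    raster order); the mask is the shortest prefix whose sum reaches
    k * total, and ID_k is the density of the last included cell.  If even
    all in-grid cells fall short of k (far-field dominated), the result is
    flagged unreachable with every source cell masked.
    """
    if not (0.0 < k < 1.0):
        raise ValueError("k must be in (0, 1)")
    total = density.total
    if total <= 0:
        raise ValueError("density total must be > 0")
    values = density.values
    in_grid = float(values.sum())
    if in_grid < k * total:
        mask = values > 0
        return IsodoseResult(
            k=k, threshold=0.0, mask=mask,
            k_achieved=in_grid / total,
            enclosed_area=float(mask.sum()) * CELL_SIZE**2,
            unreachable=True)
    flat = values.ravel()
    order = np.argsort(-flat, kind="stable")
    csum = np.cumsum(flat[order])
    # guard against roundoff just below the target
    cut = int(np.searchsorted(csum, k * total - 1e-12 * total))
    threshold = float(flat[order[cut]])
    mask_flat = np.zeros(flat.size, dtype=bool)
    mask_flat[order[:cut + 1]] = True
    mask = mask_flat.reshape(values.shape)
    k_achieved = float(csum[cut] / total)
    return IsodoseResult(
        k=k, threshold=threshold, mask=mask,
        k_achieved=k_achieved,
        enclosed_area=float(mask.sum()) * CELL_SIZE**2)


def export_contours(result: IsodoseResult,
                    origin: tuple[float, float] = GRID_ORIGIN,
                    cell_size: float = CELL_SIZE):
    """Mask boundary polygons on cell edges (shapely geometries).

    The polygons' total area equals the enclosed area.  Empty mask gives
    an empty list.
    """
    rows, cols = np.nonzero(result.mask)
    if len(rows) == 0:
        return []
    boxes = [box(origin[0] + c * cell_size, origin[1] + r * cell_size,
                 origin[0] + (c + 1) * cell_size, origin[1] + (r + 1) * cell_size)
             for r, c in zip(rows, cols)]
    merged = unary_union(boxes)
    if merged.geom_type == "Polygon":
        return [merged]
    return list(merged.geoms)


def contours_geojson(result: IsodoseResult,
                     origin: tuple[float, float] = GRID_ORIGIN,
                     cell_size: float = CELL_SIZE) -> dict:
    """GeoJSON FeatureCollection of the isodose zone polygons (metres)."""
    polys = export_contours(result, origin, cell_size)
    features = [{
        "type": "Feature",
        "geometry": mapping(p),
        "properties": {
            "k": result.k,
            "k_achieved": result.k_achieved,
            "ID_k": result.threshold,
            "unreachable": result.unreachable,
        },
    } for p in polys]
    return {"type": "FeatureCollection", "features": features}
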