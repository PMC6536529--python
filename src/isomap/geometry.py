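"""House geometry: footprint, wall stacks, apertures, rooms, and ray paths.

Coordinate convention (right-handed): origin at the southwest footprint
corner, x east, y north, z up, z = 0 at the soil surface.  The house is an
axis-aligned 10 m x 15 m rectangle; walls are modelled as thin planes at the
footprint boundary carrying their full layered thickness, so a ray crossing
a wall plane at incidence angle theta accumulates thickness/cos(theta) of
each layer.  Apertures (windows/doors) replace the wall stack by 0.8 cm of
glass.  Interior walls are thin gypsum planes.  Wooden frames are neglected.

The source grid is 1 m x 1 m cells extending 10 m laterally from every side
of the house: 30 columns (x in [-10, 20]) by 35 rows (y in [-10, 25]); cell
(col, row) has its SW corner at (col - 10, row - 10) and its centre at the
half-integers.  The 150 cells under the footprint carry no source.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np

from .materials import AttenuationTable, MaterialSpec

# Source grid geometry (metres).  Fixed by the 10 m lateral extent of the
# calculation grid around the 10 m x 15 m footprint.
GRID_MARGIN = 10.0
GRID_ORIGIN = (-10.0, -10.0)
CELL_SIZE = 1.0
NX, NY = 30, 35  # columns (x), rows (y)

_WALL_AXIS = {"S": ("y", 0.0), "N": ("y", 15.0), "W": ("x", 0.0), "E": ("x", 10.0)}


class ValidationError(ValueError):
    """A house specification violates one of its invariants."""


@dataclass(frozen=True)
class WallStack:
    """Ordered layer stack (material name, thickness in cm), outermost first."""

    layers: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for name, t in self.layers:
            if t <= 0:
                raise ValidationError(f"wall layer {name!r}: thickness {t} cm must be > 0")

    @property
    def total_thickness(self) -> float:
        return sum(t for _, t in self.layers)


@dataclass(frozen=True)
class Aperture:
    """A rectangular opening (window or door) in an exterior wall.

    offset: along-wall coordinate of the left edge (x for S/N walls, y for
    W/E walls); z0: sill height; all metres.
    """

    wall: str
    name: str
    offset: float
    width: float
    z0: float
    height: float

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Room:
    name: str
    bounds: tuple[float, float, float, float]  # x0, y0, x1, y1 (m)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0) * (y1 - y0)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bounds
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass(frozen=True)
class ObservationPoint:
    index: int
    room: str
    x: float
    y: float
    z: float  # detector sphere centre height, 1 m above ground

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class InteriorWall:
    """Thin gypsum plane: orientation 'x' => plane x = position spanning
    y in [lo, hi]; orientation 'y' => plane y = position spanning x in [lo, hi]."""

    orientation: str
    position: float
    lo: float
    hi: float
    thickness_cm: float


@dataclass
class HouseModel:
    variant: str
    width_x: float
    length_y: float
    wall_height: float
    materials: dict[str, MaterialSpec]
    wall_stacks: dict[str, WallStack]  # keys: exterior, roof, ceiling
    apertures: tuple[Aperture, ...]
    rooms: tuple[Room, ...]
    interior_walls: tuple[InteriorWall, ...]
    observation_points: tuple[ObservationPoint, ...]
    aperture_material: str = "glass"
    aperture_thickness_cm: float = 0.8
    _attenuation: AttenuationTable | None = field(default=None, repr=False)

    @property
    def footprint_area(self) -> float:
        return self.width_x * self.length_y

    @property
    def aperture_area(self) -> float:
        return sum(a.area for a in self.apertures)

    @property
    def attenuation(self) -> AttenuationTable:
        if self._attenuation is None:
            self._attenuation = AttenuationTable.from_materials(self.materials)
        return self._attenuation

    def wall_extent(self, wall: str) -> float:
        """Length (m) of one of the four exterior wall segments."""
        axis, _ = _WALL_AXIS[wall]
        return self.width_x if axis == "y" else self.length_y

    def observation_point(self, index: int) -> ObservationPoint:
        for p in self.observation_points:
            if p.index == index:
                return p
        raise KeyError(f"no observation point #{index}")

    def footprint_cell_mask(self) -> np.ndarray:
        """Boolean (NY, NX) mask of the grid cells under the footprint."""
        mask = np.zeros((NY, NX), dtype=bool)
        cx = GRID_ORIGIN[0] + (np.arange(NX) + 0.5) * CELL_SIZE
        cy = GRID_ORIGIN[1] + (np.arange(NY) + 0.5) * CELL_SIZE
        inx = (cx > 0) & (cx < self.width_x)
        iny = (cy > 0) & (cy < self.length_y)
        mask[np.ix_(iny, inx)] = True
        return mask


# ---------------------------------------------------------------------------
# construction & validation

def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_spec(variant: str) -> dict:
    """Load the bundled structured house specification for a variant."""
    if variant not in ("wooden", "brick"):
        raise ValidationError(f"unknown house variant {variant!r}")
    ref = resources.files("isomap.data").joinpath(f"house_{variant}.json")
    return json.loads(ref.read_text())


def build_house(variant: str, spec_overrides: dict | None = None) -> HouseModel:
    """Build a HouseModel from the bundled spec, optionally overridden.

    The wooden and brick variants differ only in the exterior wall stack and
    the roof wood thickness.  Raises ValidationError naming the offending
    field when an override breaks an invariant.
    """
    spec = load_spec(variant)
    if spec_overrides:
        spec = _deep_update(spec, spec_overrides)
    materials = {
        name: MaterialSpec(name=name,
                           composition=tuple((el, f) for el, f in m["composition"]),
                           density=m["density"])
        for name, m in spec["materials"].items()
    }
    stacks = {key: WallStack(tuple((n, t) for n, t in layers))
              for key, layers in spec["wall_stacks"].items()}
    house = HouseModel(
        variant=spec["variant"],
        width_x=spec["footprint"]["width_x"],
        length_y=spec["footprint"]["length_y"],
        wall_height=spec["wall_height"],
        materials=materials,
        wall_stacks=stacks,
        apertures=tuple(Aperture(**a) for a in spec["apertures"]),
        rooms=tuple(Room(r["name"], tuple(r["bounds"])) for r in spec["rooms"]),
        interior_walls=tuple(InteriorWall(**w) for w in spec["interior_walls"]),
        observation_points=tuple(ObservationPoint(**p) for p in spec["observation_points"]),
        aperture_material=spec["aperture_material"],
        aperture_thickness_cm=spec["aperture_thickness_cm"],
    )
    report = validate_house(house)
    if not report.passed:
        raise ValidationError("; ".join(report.failures))
    return house


@dataclass
class ValidationReport:
    footprint_area: float
    aperture_area: float
    n_observation_points: int
    checks: dict[str, bool]
    failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.failures


def validate_house(house: HouseModel) -> ValidationReport:
    """Check the published invariants; failures are reported, not raised."""
    checks: dict[str, bool] = {}
    failures: list[str] = []

    def check(name: str, ok: bool, msg: str) -> None:
        checks[name] = bool(ok)
        if not ok:
            failures.append(msg)

    check("footprint_area", abs(house.footprint_area - 150.0) < 1e-9,
          f"footprint area {house.footprint_area} m^2 != 150 m^2")
    check("aperture_area", abs(house.aperture_area - 25.3) < 1e-6,
          f"aperture area {house.aperture_area:.4f} m^2 != 25.3 m^2")
    check("observation_point_count", len(house.observation_points) == 11,
          f"{len(house.observation_points)} observation points, expected 11")
    inside = all(0 < p.x < house.width_x and 0 < p.y < house.length_y
                 for p in house.observation_points)
    check("observation_points_inside", inside,
          "observation point outside footprint")
    for a in house.apertures:
        extent = house.wall_extent(a.wall)
        ok = (0 <= a.offset and a.offset + a.width <= extent
              and 0 <= a.z0 and a.z0 + a.height <= house.wall_height)
        check(f"aperture_{a.name}_in_wall", ok,
              f"aperture {a.name!r} does not lie within wall {a.wall}")
    room_area = sum(r.area for r in house.rooms)
    check("rooms_tile_footprint", abs(room_area - house.footprint_area) < 1e-9,
          f"room areas sum to {room_area} m^2, footprint {house.footprint_area} m^2")
    return ValidationReport(
        footprint_area=house.footprint_area,
        aperture_area=house.aperture_area,
        n_observation_points=len(house.observation_points),
        checks=checks,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# ray tracing

def _wall_crossing(house: HouseModel, wall: str, src, det):
    """Parameter t in (0,1) where segment src->det crosses the wall plane
    within its extent, or None.  Returns (t, u, z, cos_n)."""
    axis, pos = _WALL_AXIS[wall]
    i = 0 if axis == "x" else 1
    denom = det[i] - src[i]
    if denom == 0:
        return None
    t = (pos - src[i]) / denom
    if not (0.0 < t < 1.0):
        return None
    p = [src[0] + t * (det[0] - src[0]),
         src[1] + t * (det[1] - src[1]),
         src[2] + t * (det[2] - src[2])]
    u = p[1] if axis == "x" else p[0]
    extent = house.wall_extent(wall)
    if not (0.0 <= u <= extent) or not (0.0 <= p[2] <= house.wall_height):
        return None
    dist = math.dist(src, det)
    cos_n = abs(denom) / dist
    return t, u, p[2], cos_n


def trace_path(source_point, detector_point, house: HouseModel,
               soil_surface: float = 0.0) -> list[tuple[str, float]]:
    """Ordered (material, path length cm) segments of the straight ray.

    Segments partition the ray: lengths sum to the Euclidean distance (the
    thin-plane wall approximation books layer slant thicknesses against the
    air budget).  A buried source contributes a soil segment equal to its
    slant path to the surface; rays through an aperture report glass instead
    of the wall stack.
    """
    src = tuple(map(float, source_point))
    det = tuple(map(float, detector_point))
    dist_m = math.dist(src, det)
    if dist_m == 0:
        raise ValueError("degenerate zero-length ray")
    dist_cm = dist_m * 100.0

    events: list[tuple[float, list[tuple[str, float]]]] = []

    sz = src[2] - soil_surface
    dz = det[2] - soil_surface
    if sz < 0:
        if dz <= 0:
            raise ValueError("detector at or below soil surface is unsupported")
        frac = -sz / (dz - sz)
        events.append((0.0, [("soil", dist_cm * frac)]))

    for wall in ("S", "N", "W", "E"):
        hit = _wall_crossing(house, wall, src, det)
        if hit is None:
            continue
        t, u, z, cos_n = hit
        in_aperture = any(
            a.wall == wall and a.offset <= u <= a.offset + a.width
            and a.z0 <= z <= a.z0 + a.height
            for a in house.apertures)
        if in_aperture:
            events.append((t, [(house.aperture_material,
                                house.aperture_thickness_cm / cos_n)]))
        else:
            segs = [(name, thick / cos_n)
                    for name, thick in house.wall_stacks["exterior"].layers]
            events.append((t, segs))

    for w in house.interior_walls:
        i = 0 if w.orientation == "x" else 1
        j = 1 - i
        denom = det[i] - src[i]
        if denom == 0:
            continue
        t = (w.position - src[i]) / denom
        if not (0.0 < t < 1.0):
            continue
        u = src[j] + t * (det[j] - src[j])
        z = src[2] + t * (det[2] - src[2])
        if w.lo <= u <= w.hi and 0.0 <= z <= house.wall_height:
            cos_n = abs(denom) / dist_m
            events.append((t, [("gypsum", w.thickness_cm / cos_n)]))

    events.sort(key=lambda e: e[0])
    segments: list[tuple[str, float]] = []
    used = 0.0
    for _, segs in events:
        segments.extend(segs)
        used += sum(l for _, l in segs)
    air_len = dist_cm - used
    if air_len > 0:
        segments.append(("air", air_len))
    return segments


def path_optical_depth(house: HouseModel, detector_xyz, sources_xyz: np.ndarray,
                       mu: AttenuationTable | None = None):
    """Vectorised total optical depth for N rays to one detector.

    sources_xyz: (N, 3) array in metres.  Returns (tau, dist_cm) arrays.
    Consistent with trace_path (same planes and aperture rules), but sums
    mu * length directly for speed.
    """
    if mu is None:
        mu = house.attenuation
    det = np.asarray(detector_xyz, dtype=float)
    src = np.asarray(sources_xyz, dtype=float)
    delta = det[None, :] - src
    dist_m = np.linalg.norm(delta, axis=1)
    if np.any(dist_m == 0):
        raise ValueError("degenerate zero-length ray")
    dist_cm = dist_m * 100.0
    tau = np.zeros(len(src))
    mat_len = np.zeros(len(src))

    # soil slant path for buried sources
    below = src[:, 2] < 0
    if np.any(below):
        frac = np.where(below, -src[:, 2] / (det[2] - src[:, 2]), 0.0)
        soil_len = dist_cm * frac
        tau += mu["soil"] * soil_len
        mat_len += soil_len

    # precompute stack optical thickness per unit cos and geometric thickness
    stack = house.wall_stacks["exterior"]
    stack_opt = sum(mu[name] * t for name, t in stack.layers)
    stack_geo = stack.total_thickness
    glass_opt = mu[house.aperture_material] * house.aperture_thickness_cm

    for wall in ("S", "N", "W", "E"):
        axis, pos = _WALL_AXIS[wall]
        i = 0 if axis == "x" else 1
        j = 1 - i
        denom = delta[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom != 0, (pos - src[:, i]) / denom, -1.0)
        valid = (t > 0.0) & (t < 1.0)
        if not np.any(valid):
            continue
        u = src[:, j] + t * delta[:, j]
        z = src[:, 2] + t * delta[:, 2]
        extent = house.wall_extent(wall)
        crossing = valid & (u >= 0.0) & (u <= extent) & (z >= 0.0) & (z <= house.wall_height)
        if not np.any(crossing):
            continue
        cos_n = np.abs(denom) / dist_m
        in_ap = np.zeros(len(src), dtype=bool)
        for a in house.apertures:
            if a.wall != wall:
                continue
            in_ap |= ((u >= a.offset) & (u <= a.offset + a.width)
                      & (z >= a.z0) & (z <= a.z0 + a.height))
        through_glass = crossing & in_ap
        through_wall = crossing & ~in_ap
        with np.errstate(divide="ignore"):
            inv_cos = np.where(cos_n > 0, 1.0 / cos_n, np.inf)
        tau += np.where(through_glass, glass_opt * inv_cos, 0.0)
        tau += np.where(through_wall, stack_opt * inv_cos, 0.0)
        mat_len += np.where(through_glass, house.aperture_thickness_cm * inv_cos, 0.0)
        mat_len += np.where(through_wall, stack_geo * inv_cos, 0.0)

    for w in house.interior_walls:
        i = 0 if w.orientation == "x" else 1
        j = 1 - i
        denom = delta[:, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom != 0, (w.position - src[:, i]) / denom, -1.0)
        valid = (t > 0.0) & (t < 1.0)
        if not np.any(valid):
            continue
        u = src[:, j] + t * delta[:, j]
        z = src[:, 2] + t * delta[:, 2]
        crossing = valid & (u >= w.lo) & (u <= w.hi) & (z >= 0.0) & (z <= house.wall_height)
        if not np.any(crossing):
            continue
        cos_n = np.abs(denom) / dist_m
        with np.errstate(divide="ignore"):
            seg = np.where(crossing & (cos_n > 0), w.thickness_cm / cos_n, 0.0)
        tau += mu["gypsum"] * seg
        mat_len += seg

    air_len = np.clip(dist_cm - mat_len, 0.0, None)
    tau += mu["air"] * air_len
    return tau, dist_cm


def cell_centers() -> tuple[np.ndarray, np.ndarray]:
    """x (NX,) and y (NY,) coordinates of cell centres, metres."""
    cx = GRID_ORIGIN[0] + (np.arange(NX) + 0.5) * CELL_SIZE
    cy = GRID_ORIGIN[1] + (np.arange(NY) + 0.5) * CELL_SIZE
    return cx, cy


def cells_in_grid(house: HouseModel) -> np.ndarray:
    """(M, 2) integer (col, row) indices of all source cells (non-footprint)."""
    mask = ~house.footprint_cell_mask()
    rows, cols = np.nonzero(mask)
    return np.column_stack([cols, rows])
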