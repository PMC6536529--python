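"""Constrained random contamination fields (patchy fallout scenarios).

Field-survey dose-rate maps over fallout-contaminated settlements show
patchy contamination with signal classes spanning 0 to 5 (kcps) and limited
contrast between adjacent metres of ground.  This module draws per-cell
dimensionless scaling factors on the source grid: values in [0, 5],
orthogonally adjacent cells differing by at most 1 and diagonally adjacent
cells by at most 1.4.  Values are continuous uniform on the feasible
interval (the diagonal bound is not binding on integers, which implies a
continuum), drawn sequentially in raster order so the constraints hold by
construction; a given seed reproduces the field bit for bit.  Raster-order
sampling has a slight directional anisotropy; optional Gibbs re-sweeps
(sweeps > 0) reduce it.

Footprint cells carry no source and are excluded (NaN); the constraints
apply only between source cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isodose import DoseDensityGrid, OccupancyProfile, weighted_density
from .transport import KermaGrid

VALUE_RANGE = (0.0, 5.0)

#: seeds of the repository's three bundled contamination scenarios
BUNDLED_SCENARIO_SEEDS = (101, 202, 303)
MAX_ORTHOGONAL_DELTA = 1.0
MAX_DIAGONAL_DELTA = 1.4


@dataclass
class VariabilityField:
    """Dimensionless per-cell scaling factors with neighbour constraints."""

    values: np.ndarray             # (NY, NX); NaN where no source (footprint)
    seed: int
    value_range: tuple[float, float] = VALUE_RANGE
    max_orthogonal_delta: float = MAX_ORTHOGONAL_DELTA
    max_diagonal_delta: float = MAX_DIAGONAL_DELTA
    sweeps: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def _feasible_interval(vals: np.ndarray, deltas: np.ndarray,
                       lo: float, hi: float) -> tuple[float, float]:
    for v, d in zip(vals, deltas):
        if not np.isnan(v):
            lo = max(lo, v - d)
            hi = min(hi, v + d)
    return lo, hi


def generate_field(shape: tuple[int, int], seed: int,
                   exclude_mask: np.ndarray | None = None,
                   sweeps: int = 0) -> VariabilityField:
    """Draw a constrained field of the given (rows, cols) shape.

    exclude_mask: boolean matrix of cells with no source (footprint); the
    field is drawn over the full rectangle — the contamination pattern
    exists under the house too, there is just no exposed source there —
    and excluded cells are masked to NaN afterwards.  Drawing over the
    full grid keeps the sequential scheme feasible: with all four
    already-drawn neighbours (W, NW, N, NE) present, the intersection of
    [0, 5] with their intervals is provably non-empty for the (1, 1.4)
    constraint pair; guarded anyway.
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    vals = np.empty(shape)
    lo0, hi0 = VALUE_RANGE

    def draw(r: int, c: int) -> float:
        nbrs, deltas = [], []
        for dr, dc, dd in ((0, -1, MAX_ORTHOGONAL_DELTA),
                           (-1, 0, MAX_ORTHOGONAL_DELTA),
                           (-1, -1, MAX_DIAGONAL_DELTA),
                           (-1, 1, MAX_DIAGONAL_DELTA)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx:
                nbrs.append(vals[rr, cc])
                deltas.append(dd)
        lo, hi = _feasible_interval(np.array(nbrs), np.array(deltas), lo0, hi0)
        if hi < lo:
            raise RuntimeError(f"infeasible constraint interval at cell {(r, c)}")
        return rng.uniform(lo, hi)

    for r in range(ny):
        for c in range(nx):
            vals[r, c] = draw(r, c)

    for _ in range(sweeps):
        # Gibbs re-sweep: resample each cell given all 8 current neighbours
        for r in range(ny):
            for c in range(nx):
                nbrs, deltas = [], []
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < ny and 0 <= cc < nx:
                            nbrs.append(vals[rr, cc])
                            deltas.append(MAX_ORTHOGONAL_DELTA
                                          if dr == 0 or dc == 0
                                          else MAX_DIAGONAL_DELTA)
                lo, hi = _feasible_interval(np.array(nbrs), np.array(deltas),
                                            lo0, hi0)
                if hi < lo:
                    raise RuntimeError(f"infeasible interval at cell {(r, c)}")
                vals[r, c] = rng.uniform(lo, hi)

    if exclude_mask is not None:
        vals = np.where(exclude_mask, np.nan, vals)
    return VariabilityField(values=vals, seed=seed, sweeps=sweeps)


def check_constraints(field: VariabilityField) -> tuple[bool, list]:
    """Exhaustive pairwise check; returns (ok, violation list)."""
    v = field.values
    lo, hi = field.value_range
    violations: list[tuple] = []
    finite = np.isfinite(v)
    bad = finite & ((v < lo) | (v > hi))
    for r, c in zip(*np.nonzero(bad)):
        violations.append(("range", (int(r), int(c)), float(v[r, c])))

    def pairs(dr: int, dc: int, bound: float) -> None:
        a = v[max(dr, 0):v.shape[0] + min(dr, 0), max(dc, 0):v.shape[1] + min(dc, 0)]
        b = v[max(-dr, 0):v.shape[0] + min(-dr, 0), max(-dc, 0):v.shape[1] + min(-dc, 0)]
        d = np.abs(a - b)
        for r, c in zip(*np.nonzero(np.isfinite(d) & (d > bound + 1e-12))):
            violations.append(("delta", (int(r), int(c)), (dr, dc), float(d[r, c])))

    pairs(0, 1, field.max_orthogonal_delta)
    pairs(1, 0, field.max_orthogonal_delta)
    pairs(1, 1, field.max_diagonal_delta)
    pairs(1, -1, field.max_diagonal_delta)
    return (len(violations) == 0, violations)


def adjusted_primary_dose_factor(grids: list[KermaGrid],
                                 occupancy: OccupancyProfile,
                                 field: VariabilityField) -> float:
    """Primary dose factor under patchy contamination.

    D' = (D_inf - sum_j K_j) * mean(s) + sum_j s_j K_j: the far field (and
    only it) scales with the field mean, the in-grid cells cellwise.  K_j
    are the occupancy-weighted depth-0 cell kermas.
    """
    return scaled_density(grids, occupancy, field).total


def scaled_density(grids: list[KermaGrid], occupancy: OccupancyProfile,
                   field: VariabilityField) -> DoseDensityGrid:
    """Occupancy-weighted density with the variability field applied."""
    homog = weighted_density(grids, occupancy)
    if field.values.shape != homog.values.shape:
        raise ValueError("field shape does not match grid shape")
    s = np.nan_to_num(field.values, nan=0.0)
    return DoseDensityGrid(values=homog.values * s,
                           far_field=homog.far_field * field.mean,
                           label=f"{homog.label} x variability(seed={field.seed})")
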