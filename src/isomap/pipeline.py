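"""End-to-end orchestration: geometry -> transport -> (migration |
variability) -> isodose -> decontamination, with reproducible
configuration and a manifest of output digests.

Every stochastic stage (the variability fields) derives its seeds from the
global seed unless scenario seeds are given explicitly; all other stages
are deterministic, so rerunning an identical config reproduces identical
file digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decontamination, gridio, isodose, migration, transport, variability
from .geometry import build_house, validate_house
from .isodose import STANDARD_HOURS

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    house_variants: tuple[str, ...] = ("wooden", "brick")
    depths_cm: tuple[float, ...] = (0.0, 2.5, 5.0)
    occupancy_hours: dict[str, float] = field(default_factory=lambda: dict(STANDARD_HOURS))
    migration_params: tuple[tuple[float, float], ...] = migration.SWEDISH_PARAM_SETS
    migration_times_a: tuple[float, ...] = (0.1, 1.0, 5.0)
    n_variability_scenarios: int = 3
    variability_seeds: tuple[int, ...] | None = None
    k_fractions: tuple[float, ...] = isodose.DEFAULT_K_FRACTIONS
    buffer_distance_m: float = 2.0
    decon_area_m2: float = 116.0
    efficiency: float = 1.0
    seed: int = 0
    n_quad: int = 4
    observation_points: tuple[int, ...] | None = None  # None => all 11

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        # JSON round-trips tuples as lists; normalise
        for name in ("house_variants", "depths_cm", "migration_times_a",
                     "k_fractions"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.migration_params = tuple(tuple(p) for p in cfg.migration_params)
        if cfg.variability_seeds is not None:
            cfg.variability_seeds = tuple(cfg.variability_seeds)
        if cfg.observation_points is not None:
            cfg.observation_points = tuple(cfg.observation_points)
        return cfg

    def scenario_seeds(self) -> tuple[int, ...]:
        if self.variability_seeds is not None:
            return self.variability_seeds
        ss = np.random.SeedSequence(self.seed)
        return tuple(int(s) % (2**31)
                     for s in ss.generate_state(self.n_variability_scenarios))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, output_dir) -> RunManifest:
    """Execute the full pipeline; write all artifacts + manifest under
    output_dir.  Idempotent for a fixed config."""
    from . import __version__

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    written: list[Path] = []
    tcfg = transport.TransportConfig(n_quad=config.n_quad)
    table2_rows = []

    for variant in config.house_variants:
        t0 = time.time()
        house = build_house(variant)
        report = validate_house(house)
        written.append(gridio.write_json(
            {"variant": variant, "passed": report.passed,
             "footprint_area": report.footprint_area,
             "aperture_area": report.aperture_area,
             "checks": report.checks},
            out / f"{variant}_validation.json"))
        if not report.passed:
            raise RuntimeError(f"stage geometry [{variant}]: {report.failures}")
        manifest.timings_s[f"geometry_{variant}"] = time.time() - t0

        t0 = time.time()
        try:
            grids = transport.compute_kerma_grids(
                house, depths_cm=config.depths_cm, config=tcfg,
                observation_points=config.observation_points)
        except Exception as e:
            raise RuntimeError(f"stage transport [{variant}]: {e}") from e
        for g in grids:
            written.append(gridio.write_grid(
                g, out / "grids" / f"{variant}_p{g.observation_point:02d}_d{g.source_depth_cm:g}.csv"))
        manifest.timings_s[f"transport_{variant}"] = time.time() - t0
        for idx in sorted({g.observation_point for g in grids}):
            by_d = {g.source_depth_cm: g for g in grids if g.observation_point == idx}
            if 0.0 in by_d and 2.5 in by_d:
                r = by_d[0.0].total_infinite / by_d[2.5].total_infinite
                if not (4.0 <= r <= 8.0):
                    manifest.warnings.append(
                        f"{variant} point {idx}: depth-0/2.5 ratio {r:.2f} outside [4, 8]")

        occ = isodose.occupancy_from_hours(config.occupancy_hours, house)
        if config.observation_points is not None:
            occ = occ.restrict_to(config.observation_points)
        g0 = transport.grids_by_depth(grids, 0.0)
        density = isodose.weighted_density(g0, occ)
        written.append(gridio.write_grid(density, out / f"{variant}_density_occupancy_d0.csv"))
        for k in config.k_fractions:
            res = isodose.isodose_threshold(density, k)
            written.append(gridio.write_json(
                isodose.contours_geojson(res),
                out / "isodose" / f"{variant}_occupancy_d0_k{int(round(k * 100)):02d}.geojson"))

        t0 = time.time()
        if all(d in config.depths_cm for d in (0.0, 2.5, 5.0)):
            points = sorted({g.observation_point for g in grids})
            for D_s, v_s in config.migration_params:
                params = migration.MigrationParams(D_s=D_s, v_s=v_s)
                for t_a in config.migration_times_a:
                    weights = migration.activity_depth_weights(params, t_a)
                    eff = []
                    for idx in points:
                        by_d = {g.source_depth_cm: g for g in grids
                                if g.observation_point == idx}
                        eff.append(migration.depth_weighted_grid(by_d, params, t_a,
                                                                 weights=weights))
                    dens_t = isodose.DoseDensityGrid(
                        values=sum(w * g.values for w, g in zip(occ.p, eff)),
                        far_field=float(sum(w * g.far_field
                                            for w, g in zip(occ.p, eff))),
                        label=f"{variant} Ds={D_s} vs={v_s} t={t_a}a")
                    written.append(gridio.write_grid(
                        dens_t,
                        out / "migration" / f"{variant}_Ds{D_s:g}_vs{v_s:g}_t{t_a:g}.csv"))
        manifest.timings_s[f"migration_{variant}"] = time.time() - t0

        normal = decontamination.buffer_selection(house, config.buffer_distance_m,
                                                  config.efficiency)
        optimized = decontamination.optimized_selection(density, config.decon_area_m2,
                                                        config.efficiency)
        rep = decontamination.evaluate(density, normal, optimized,
                                       provenance={"house": variant,
                                                   "scenario": "homogeneous"})
        table2_rows.append({"house": variant, "scenario": "homogeneous",
                            **{k: v for k, v in rep.to_dict().items()
                               if k != "provenance"}})
        for i, seed in enumerate(config.scenario_seeds(), start=1):
            fld = variability.generate_field(density.values.shape, seed,
                                             exclude_mask=house.footprint_cell_mask())
            ok, violations = variability.check_constraints(fld)
            if not ok:
                raise RuntimeError(
                    f"stage variability [{variant} scenario {i}]: {violations[:3]}")
            written.append(gridio.write_json(
                {"seed": seed, "sweeps": fld.sweeps, "mean": fld.mean,
                 "constraints": {"orthogonal": fld.max_orthogonal_delta,
                                 "diagonal": fld.max_diagonal_delta}},
                out / "variability" / f"{variant}_scenario{i}.json"))
            np.savetxt(out / "variability" / f"{variant}_scenario{i}.csv",
                       fld.values, delimiter=",", fmt="%.17g")
            written.append(out / "variability" / f"{variant}_scenario{i}.csv")
            scaled = variability.scaled_density(g0, occ, fld)
            rep_i = decontamination.evaluate(scaled, normal, optimized,
                                             provenance={"house": variant,
                                                         "scenario": f"variability {i}",
                                                         "seed": seed})
            table2_rows.append({"house": variant, "scenario": f"variability {i}",
                                **{k: v for k, v in rep_i.to_dict().items()
                                   if k != "provenance"}})

    table = pd.DataFrame(table2_rows)
    table_path = out / "decontamination_comparison.csv"
    table.to_csv(table_path, index=False)
    written.append(table_path)

    for p in written:
        manifest.digests[str(p.relative_to(out))] = _digest(Path(p))
    gridio.write_json({"config": config.to_dict(), **manifest.to_dict()},
                      out / "manifest.json")
    return manifest
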