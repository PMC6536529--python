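"""Build the two bundled house models and check their published invariants.

Writes results/house_validation.json.  Expected outcome: both variants
pass — 150 m^2 footprint, 25.3 m^2 of windows/doors, 11 observation
points, rooms tiling the footprint.
"""

from _common import RESULTS

from isomap import build_house, validate_house
from isomap.gridio import write_json

out = {}
for variant in ("wooden", "brick"):
    house = build_house(variant)
    rep = validate_house(house)
    out[variant] = {
        "passed": rep.passed,
        "footprint_area_m2": rep.footprint_area,
        "aperture_area_m2": rep.aperture_area,
        "n_observation_points": rep.n_observation_points,
        "exterior_stack": list(house.wall_stacks["exterior"].layers),
    }
    print(f"{variant:7s}: passed={rep.passed}  footprint={rep.footprint_area:.0f} m^2  "
          f"apertures={rep.aperture_area:.1f} m^2  points={rep.n_observation_points}")

write_json(out, RESULTS / "house_validation.json")
print(f"wrote {RESULTS / 'house_validation.json'}")
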