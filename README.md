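# isomap

Isodose zones and topsoil-removal optimisation around dwellings after
radioactive fallout.

After a release of gamma-emitting radionuclides (Cs-137 being the
reference case), removing a thin layer of soil is one of the few measures
that durably reduces the external dose to residents — but it is expensive,
so it should target the ground that actually matters.  `isomap` computes,
for parameterized single-storey wooden and brick houses, how much each
1 m × 1 m patch of surrounding ground contributes to the air kerma
free-in-air at observation points inside the house, and turns those
contribution maps into *isodose zones*: the smallest ground area whose
removal achieves a chosen fraction of the total dose reduction.

## The model

For an observation point *i*, let ρ_D,i(r) be the dose contribution
density of the ground around the house and D_i,∞ the total (infinite
contaminated plane) dose.  The isodose ID_i,k is the density threshold
whose superlevel set {ρ_D,i ≥ ID_i,k} contributes a chosen fraction

&nbsp;&nbsp;&nbsp;&nbsp;k_i = ∫ f(ρ_D,i(r)) dV / D_i,∞ ,&nbsp;&nbsp; f = ρ_D,i on {ρ_D,i ≥ ID_i,k}, else 0.

With occupancy factors p_i (fraction of indoor time spent at point *i*,
Σp_i = 1) the same construction applies to the weighted density
Σ_i ρ_D,i·p_i and total Σ_i D_i,∞·p_i, giving one zone for the whole
household.  On the 1 m calculation grid the superlevel set is realised as
the minimal-area cell set reaching the requested fraction.

The per-cell contributions come from a deterministic point-kernel
transport model at 0.662 MeV: inverse-square fluence attenuated along the
ray (soil slant path for buried sources, layered wall stacks or window
glass, air) and corrected for scatter with a water-equivalent
point-isotropic buildup factor B(μr).  Vertical migration of the fallout
follows a convection–dispersion profile

&nbsp;&nbsp;&nbsp;&nbsp;C(x,t) = C₀ e^(−ln2·t/T½) · [ e^(−(x−v_s t)²/4D_s t)/√(πD_s t) − (v_s/2D_s) e^(v_s x/D_s) erfc((x+v_s t)/2√(D_s t)) ]

with dispersion coefficient D_s (cm²/a) and convective velocity v_s
(cm/a); dose at time *t* weights the depth-interpolated kerma grids with
C(x,t) over the top 5 cm.  Patchy deposition is emulated by constrained
random fields: per-cell factors in [0, 5] whose orthogonal neighbours
differ by at most 1 and diagonal neighbours by at most 1.4.

## Worked example

```python
from isomap import (build_house, compute_kerma_grids, occupancy_from_hours,
                    weighted_density, isodose_threshold)
from isomap.isodose import STANDARD_HOURS
from isomap.transport import grids_by_depth
from isomap.decontamination import buffer_selection, optimized_selection, evaluate

house = build_house("wooden")
grids = compute_kerma_grids(house)                 # 11 points x 3 depths, ~2 s
occ   = occupancy_from_hours(STANDARD_HOURS, house)  # 14 h/day at home
dens  = weighted_density(grids_by_depth(grids, 0.0), occ)
print(f"primary dose factor {dens.total:.1f} pGy per gamma/mm^2")

zone = isodose_threshold(dens, k=0.25)
print(f"k=0.25 zone: {zone.enclosed_area:.0f} m^2")

normal    = buffer_selection(house, 2.0)           # 116 cells within 2 m
optimized = optimized_selection(dens, normal.area) # 116 best cells
report    = evaluate(dens, normal, optimized)
print(f"reduction {report.rel_reduction_normal:.1f}% (buffer) vs "
      f"{report.rel_reduction_optimized:.1f}% (isodose), "
      f"ratio {report.ratio:.2f}")
```

prints

```
primary dose factor 273.4 pGy per gamma/mm^2
k=0.25 zone: 223 m^2
reduction 13.8% (buffer) vs 18.5% (isodose), ratio 1.34
```

i.e. a resident of the wooden house receives 273 pGy per unit areal
photon emission from an infinite contaminated plane; the 223 m² of ground
with the highest contribution already accounts for a quarter of it; and
removing the 116 m² that the isodose ranking picks reduces the dose 1.34×
more than removing the same area as a 2 m ring around the house.

The numbered scripts under `analysis/` run the full study — geometry
validation, kerma grids, occupancy isodose zones, soil migration over
0.1/1/5 years, three patchy-contamination scenarios, and the
decontamination comparison — writing tables and GeoJSON zones under
`results/`.  Run them in order (`02` writes the grids the later ones
read).

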