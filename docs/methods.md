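# Methods

## Scope and model chain

`isomap` estimates external gamma exposure inside two parameterized
single-storey Swedish houses (wooden and brick) from Cs-137 deposited on
the surrounding ground, and optimises topsoil removal.  The chain is:

1. **house geometry** — a 10 m × 15 m axis-aligned footprint with four
   exterior wall stacks, 13 windows/doors totalling 25.3 m², interior
   gypsum walls, 11 rooms and one observation point per room at 1 m
   height;
2. **transport** — per-cell air kerma free-in-air at each observation
   point from 1 m × 1 m plane sources at 0, 2.5 and 5 cm depth on a
   30 × 35 cell grid (10 m beyond every facade), plus a far-field
   remainder giving the infinite-plane total;
3. **isodose** — occupancy-weighted dose-contribution densities
   thresholded into minimal-area zones;
4. **soil migration** — a convection–dispersion depth profile weighting
   the depth-interpolated grids at later times;
5. **variability** — constrained random fields emulating patchy fallout;
6. **decontamination** — equal-area comparison of a 2 m buffer ring
   against the isodose-ranked cells.

## Transport kernel (deterministic stand-in)

Full Monte Carlo photon transport is out of scope; the kernel is a point
kernel at the single 0.662 MeV line:

    K = conv · exp(−τ) · B(τ) / (4π r²),   conv = E · (μ_en/ρ)_air

with τ the ray's total optical depth.  Design choices:

- **Thin-plane walls.**  Walls sit as planes at the footprint boundary
  carrying their full layered thickness; a crossing at wall-normal
  cosine cosθ books thickness/cosθ of every layer (or 0.8 cm of glass
  through an aperture).  Wooden frames are neglected.  This reproduces
  slab attenuation exactly for flat incidence and avoids a CAD geometry.
- **Attenuation data.**  Elemental mass attenuation coefficients are
  embedded at 0.6/0.8 MeV and log-log interpolated to 0.662 MeV; material
  coefficients follow the mixture rule over the atomic compositions
  (converted to mass fractions) times bulk density.
- **Buildup.**  Scatter is folded into a single water-equivalent
  point-isotropic buildup table evaluated at total optical depth,
  log-interpolated between knots, B(0) = 1.  One parameterization for all
  media is the declared approximation; `use_buildup=False` gives the
  unscattered kernel for oracle tests.
- **Quadrature.**  Each source cell uses a fixed n × n midpoint rule
  (default 4 × 4, within 2% of a 64 × 64 reference); the far field
  integrates 72 azimuths × 48 log-spaced radii from the grid edge to
  500 m, where air attenuation (≈ 4.7 mean free paths) makes the
  remainder negligible.  No random numbers anywhere: grids are
  bit-reproducible per configuration.
- **Sources and detector.**  Surface sources sit 0.1 mm below the
  interface so soil handling is uniform; the detector is the sphere
  centre (a point), since the 30 cm sphere is a tally volume, not
  physics.

Problem sizes: one house = 11 points × 3 depths × 900 cells × 16
quadrature nodes ≈ 4.8·10⁵ rays, about 2 s on one core; the whole
acceptance run is a few seconds.

### Fidelity against the full-transport reference

The stand-in reproduces the qualitative structure the analysis needs:
depth ordering K(0) > K(2.5) > K(5) per cell and point, wooden ≈ 2×
brick totals, and surface/2.5 cm total ratios with median ≈ 6.  At
heavily shielded interior points (dressing room, restroom, hall) the
ratio rises to 10–20 because those points see the outside mostly along
grazing window paths whose soil slant grows fastest with burial; such
points fall outside the soft fidelity band [4, 8] and are logged as
warnings, not failures.  Absolute dose factors depend on the unpublished
internal layout and are not comparable point-by-point to full-transport
values; only orderings and ratios are asserted.

## House fixtures

The published record fixes the footprint, wall stacks (Table-level
layer lists), total aperture area, material compositions/densities and
the room list, but not the internal layout or window positions.  The
bundled fixtures (`src/isomap/data/house_*.json`) therefore place rooms,
interior walls (12 cm gypsum; 17 cm for the two load-bearing walls) and
standard-size windows/doors explicitly, summing to exactly 25.3 m², so
every run and test is deterministic.  The two variants differ only in the
exterior stack and roof wood thickness.  Overrides are deep-merged onto
the bundled spec and re-validated; any violated invariant names the
offending field.

## Isodose construction

On the 1 m grid the continuous superlevel-set definition becomes a
threshold on per-cell contributions.  Cells are ranked by density
(stable sort, so exact ties resolve in raster order) and the mask is the
shortest prefix reaching k · total; ID_k is the density of the last
included cell.  This yields the *smallest-area* zone achieving the
fraction, which we prefer over including all threshold-tied cells: it
matches the minimal-area semantics of the optimisation use-case and the
exhaustive-search oracle, and ties have measure zero for computed grids.
The far field — ground beyond the calculation grid, here 53–72% of the
infinite-plane total at surface deposition — can never be enclosed; a
request above the in-grid fraction returns an `unreachable` flag with all
source cells masked, mirroring the grid-limit caveat such zone maps carry.
The default fraction list {0.25, 0.5, 0.75, 0.9} is a package choice (the
source figures do not list their shading levels).

Occupancy: 14 h/day at home split 8 h bedroom, 3.5 h living room, 1 h
kitchen, 1 h dining room, 0.5 h bathroom (European time-budget surveys);
rooms without stated hours get p = 0 and factors normalise to 1.

## Soil migration

Parameters: C₀ (areal deposition; the printed volumetric unit is read as
a surface pulse feeding a per-depth density), T½ = 30.17 a for Cs-137,
and the two extreme measured western-Swedish combinations
(D_s, v_s) = (0.06 cm²/a, 0.17 cm/a) and (2.63 cm²/a, 0).  The erfc
argument is taken as (x + v_s t)/2√(D_s t) — the dimensionally consistent
form of the cited model family, under which mass is conserved to <10⁻⁹
(verified by quadrature for both parameter sets); the literal printed
variant (x + v_s without t) is available via `as_printed=True` for
comparison.  The erfc product is evaluated through `erfcx` with the
exponent collapsed to −(x−v_s t)²/4D_s t, so it never overflows.

Dose weighting truncates at 5 cm with no renormalisation (deeper activity
is simply lost to the dose estimate) and interpolates the three computed
grids log-linearly in depth (attenuation is exponential; linear
interpolation would overweight intermediate depths).  The depth axis uses
0.5 cm base sublayers *adaptively refined* within ±4σ of the activity
peak: at early times the pulse is ~0.02 cm wide and a fixed 0.5 cm
partition cannot reproduce the t → 0 limit (effective grid → surface
grid within 1%), which the refined partition does.  Each interval
contributes its quadrature-exact activity fraction at its
activity-weighted mean depth.

## Variability fields

Values are continuous uniform on [0, 5] — the ±1.4 diagonal bound is
never binding on integers, which rules out the integer reading of the
survey classes — drawn sequentially in raster order from the interval
allowed by the already-drawn W, NW, N, NE neighbours (±1 orthogonal,
±1.4 diagonal), so constraints hold by construction and a seed fixes the
field bit-for-bit.  The field is drawn over the full rectangle and the
footprint masked afterwards: the contamination pattern exists under the
house (there is just no exposed source), and drawing around the hole can
otherwise deadlock where the raster front rejoins.  Raster sampling has
mild directional anisotropy; optional Gibbs re-sweeps reduce it.  The
adjusted primary dose factor scales in-grid cells cellwise and the far
field by the field mean (non-footprint cells only):
D′ = (D_∞ − ΣK_j)·mean(s) + Σ s_j K_j — linear in the field, identity at
s ≡ 1.

Three bundled seeds (101/202/303) define the repository's scenario
fixtures; the published scenario fields themselves are not reproducible
(no seeds or generator were recorded).

## Decontamination comparison

The buffer plan takes every cell whose centre lies within the given
distance of the walls (2 m ⇒ exactly 116 cells around the 10 × 15 m
footprint; at integer distances on the 1 m grid the centre rule and the
full-extent rule coincide).  The optimized plan takes the equal number of
highest-density cells of the *homogeneous* density — deliberately, so the
patchy scenarios test the robustness claim that homogeneous isodose zones
remain a better guide than a fixed buffer even when the actual deposition
varies.  Removal efficiency defaults to 1.0 (the selected cells'
computed contribution is fully removed); partial removal scales
linearly via `efficiency`.  Reported quantities: dose factors before and
after each plan, relative reductions (full precision internally, rounded
only for display), and their ratio.

## What the synthetic conditions do and do not show

The transport kernel and fixtures emulate the statistical structure of
the reference computations (grid geometry, units, orderings, ratio
scales), not their absolute values: no energy spectrum, no skyshine or
roof-scatter paths (the far field is ground-level rays only), no in-house
deposition, single-storey only, point detector.  Passing tests therefore
demonstrate the correctness of the isodose/migration/variability/
decontamination machinery and the qualitative transport structure — not
dosimetric accuracy for a real building.  The dominance result
(isodose-guided removal beats the buffer in every scenario, mean uplift
≈ 37% here) is structural: it follows from greedy selection on the true
density and survives patchiness because the dose pattern is set mostly by
geometry and shielding, as the homogeneous-vs-patchy Pearson correlations
(0.82–0.98 across scenarios) show.

## Numerical conventions

- Coordinates: origin at the SW footprint corner, x east, y north, z up,
  soil surface z = 0; cells indexed (col, row) with SW corner at
  (col−10, row−10) m and centres at half-integers.
- Tolerances: path additivity 10⁻⁶ relative; grid totals 10⁻⁹;
  quadrature consistency 2%; migration mass conservation 0.5% (measured
  < 10⁻⁹).
- Degenerate inputs: zero-length rays, t ≤ 0 profiles, all-zero
  occupancies, footprint source cells, over-sized removal areas and
  mismatched plan areas all raise with the offending field named.
- Serialisation: CSV matrices at `%.17g` (lossless float64) with JSON
  sidecars carrying units and provenance; reads reject NaN, missing
  sidecar fields and total mismatches.
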