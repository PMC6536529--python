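"""Material compositions and photon interaction data at the Cs-137 line.

All transport in this package runs at a single photon energy, 0.662 MeV
(the Cs-137 gamma line).  Materials are specified by atomic composition
(atom fractions) and bulk density; mass attenuation coefficients are
obtained with the mixture rule from an embedded elemental tabulation,
log-log interpolated to 0.662 MeV.  Scattered radiation is folded into a
point-isotropic buildup factor evaluated at the ray's total optical depth,
using an embedded water-equivalent table (a single parameterization shared
by all media — the declared stand-in approximation of this kernel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ENERGY_MEV = 0.662

# Air mass energy-absorption coefficient at 0.662 MeV (cm^2/g), used to
# convert fluence to air kerma free-in-air.
MU_EN_RHO_AIR = 0.0293

# pGy * cm^2 per unit fluence (photon/cm^2):  E * (mu_en/rho) * 1.602e-10 Gy g/MeV * 1e12 pGy/Gy
KERMA_CONV_PGY_CM2 = ENERGY_MEV * MU_EN_RHO_AIR * 1.602176e-10 * 1e12

# Elemental data: atomic mass (g/mol) and mass attenuation coefficients
# (cm^2/g) at 0.6 and 0.8 MeV, from standard photon cross-section
# tabulations; interpolated log-log to 0.662 MeV.
_ELEMENTS: dict[str, tuple[float, float, float]] = {
    # symbol: (A, mu/rho @ 0.6 MeV, mu/rho @ 0.8 MeV)
    "H":  (1.008,  0.1599,  0.1405),
    "C":  (12.011, 0.08058, 0.07076),
    "N":  (14.007, 0.08063, 0.07081),
    "O":  (15.999, 0.08070, 0.07087),
    "Na": (22.990, 0.07736, 0.06791),
    "Mg": (24.305, 0.07999, 0.07023),
    "Al": (26.982, 0.07802, 0.06841),
    "Si": (28.085, 0.08022, 0.07033),
    "S":  (32.06,  0.08098, 0.07090),
    "Ar": (39.948, 0.07294, 0.06382),
    "K":  (39.098, 0.07864, 0.06878),
    "Ca": (40.078, 0.08125, 0.07100),
    "Mn": (54.938, 0.07405, 0.06461),
    "Fe": (55.845, 0.07583, 0.06631),
}


def elemental_mu_rho(element: str, energy_mev: float = ENERGY_MEV) -> float:
    """Elemental mass attenuation coefficient (cm^2/g), log-log interpolated."""
    try:
        _, mu6, mu8 = _ELEMENTS[element]
    except KeyError:
        raise KeyError(f"no tabulated attenuation coefficient for element {element!r}")
    f = (math.log(energy_mev) - math.log(0.6)) / (math.log(0.8) - math.log(0.6))
    return math.exp((1 - f) * math.log(mu6) + f * math.log(mu8))


def atomic_mass(element: str) -> float:
    try:
        return _ELEMENTS[element][0]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}")


@dataclass(frozen=True)
class MaterialSpec:
    """A material as atomic composition plus bulk density.

    composition: tuple of (element symbol, atom fraction); fractions sum to 1
    within 1e-3.  density in kg/l (== g/cm^3).
    """

    name: str
    composition: tuple[tuple[str, float], ...]
    density: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"material {self.name!r}: atom fractions sum to {total:.5f}, not 1"
            )
        for el, f in self.composition:
            if f < 0:
                raise ValueError(f"material {self.name!r}: negative fraction for {el}")
            atomic_mass(el)  # raises for unknown elements

    def mass_fractions(self) -> dict[str, float]:
        """Convert atom fractions to mass fractions."""
        w = {el: f * atomic_mass(el) for el, f in self.composition}
        norm = sum(w.values())
        return {el: v / norm for el, v in w.items()}

    def mu_rho(self, energy_mev: float = ENERGY_MEV) -> float:
        """Mixture-rule mass attenuation coefficient (cm^2/g)."""
        return sum(
            w * elemental_mu_rho(el, energy_mev)
            for el, w in self.mass_fractions().items()
        )


def linear_attenuation(material: MaterialSpec, energy_mev: float = ENERGY_MEV) -> float:
    """Linear attenuation coefficient mu (cm^-1) = (mu/rho) * rho."""
    return material.mu_rho(energy_mev) * material.density


# Point-isotropic buildup factors for a water-equivalent medium at 0.662 MeV,
# tabulated against optical depth (mean free paths).  Interpolation is linear
# in log(B) against mfp; beyond the last knot the last log-slope is continued
# (contributions there are negligible after e^-20).
_BUILDUP_MFP = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0, 15.0, 20.0])
_BUILDUP_B = np.array([1.0, 1.62, 2.37, 4.26, 6.6, 9.3, 12.4, 19.8, 34.0, 66.0, 110.0])
_LOG_B = np.log(_BUILDUP_B)


def buildup(mfp):
    """Buildup factor B(optical depth); B(0) = 1, nondecreasing.

    Accepts scalars or arrays.  Linear extrapolation of log(B) above the
    tabulated range.
    """
    x = np.asarray(mfp, dtype=float)
    if np.any(x < 0):
        raise ValueError("optical depth must be >= 0")
    hi_slope = (_LOG_B[-1] - _LOG_B[-2]) / (_BUILDUP_MFP[-1] - _BUILDUP_MFP[-2])
    logb = np.interp(x, _BUILDUP_MFP, _LOG_B)
    logb = np.where(x > _BUILDUP_MFP[-1], _LOG_B[-1] + hi_slope * (x - _BUILDUP_MFP[-1]), logb)
    out = np.exp(logb)
    return float(out) if np.isscalar(mfp) else out


@dataclass
class AttenuationTable:
    """Cached linear attenuation coefficients (cm^-1) for a material set."""

    mu: dict[str, float] = field(default_factory=dict)
    energy_mev: float = ENERGY_MEV

    @classmethod
    def from_materials(cls, materials: dict[str, MaterialSpec],
                       energy_mev: float = ENERGY_MEV) -> "AttenuationTable":
        table = cls(energy_mev=energy_mev)
        for name, mat in materials.items():
            table.mu[name] = linear_attenuation(mat, energy_mev)
        return table

    def __getitem__(self, material_name: str) -> float:
        return self.mu[material_name]
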