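"""Physical parameters and diffusion coefficients for protein transport in a
binding hydrogel.

The free diffusivity of the growth factor in water is estimated from the
semiempirical Polson correlation, which needs only temperature, solvent
viscosity and molecular weight.  Binding to immobile heparin sites is treated
as a fast local equilibrium: at any instant a fraction ``f_b`` of the protein
is bound and does not diffuse, so the effective (retarded) diffusivity of the
total concentration is the mobility-weighted average of the free and bound
species.  With an immobile binder (``D_H = 0``) this reduces to the classical
retarded-diffusion form ``D_EW / (1 + K)`` with bound/free ratio
``K = f_b / (1 - f_b)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "POLSON_CONSTANT",
    "CELSIUS_OFFSET",
    "TransportParams",
    "DiffusionCoefficients",
    "polson_diffusivity",
    "effective_diffusivity",
    "bound_fraction_to_ratio",
    "ratio_to_bound_fraction",
]

#: Prefactor of the Polson correlation in SI units: with T in kelvin, viscosity
#: in Pa s and molecular weight in g/mol the result is in m^2/s.
POLSON_CONSTANT = 9.40e-15

CELSIUS_OFFSET = 273.15


def polson_diffusivity(
    temperature_K: float, viscosity_Pa_s: float, molecular_weight_g_mol: float
) -> float:
    """Free aqueous diffusion coefficient from the Polson correlation.

    ``D = 9.40e-15 * T / (mu * M**(1/3))`` in m^2/s.

    Parameters
    ----------
    temperature_K : float
        Absolute temperature in kelvin.
    viscosity_Pa_s : float
        Dynamic viscosity of the solvent in Pa s.
    molecular_weight_g_mol : float
        Molecular weight of the diffusing protein in g/mol.
    """
    if temperature_K <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature_K}")
    if viscosity_Pa_s <= 0:
        raise ValueError(f"viscosity must be > 0 Pa s, got {viscosity_Pa_s}")
    if molecular_weight_g_mol <= 0:
        raise ValueError(
            f"molecular weight must be > 0 g/mol, got {molecular_weight_g_mol}"
        )
    return POLSON_CONSTANT * temperature_K / (
        viscosity_Pa_s * molecular_weight_g_mol ** (1.0 / 3.0)
    )


def effective_diffusivity(
    d_free: float, bound_fraction: float, binder_diffusivity: float = 0.0
) -> float:
    """Binding-retarded diffusivity of the total (free + bound) concentration.

    ``D_eff = (1 - f_b) * D_free + f_b * D_binder``.  Under fast local
    equilibrium only the free fraction moves with the free-solution
    coefficient; the bound fraction moves with the binder (zero for a
    crosslinked matrix).
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError(f"bound_fraction must be in [0, 1], got {bound_fraction}")
    if d_free < 0 or binder_diffusivity < 0:
        raise ValueError("diffusivities must be >= 0")
    return (1.0 - bound_fraction) * d_free + bound_fraction * binder_diffusivity


def bound_fraction_to_ratio(bound_fraction: float) -> float:
    """Equilibrium bound/free mass ratio ``K = f_b / (1 - f_b)``."""
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError(f"bound_fraction must be in [0, 1], got {bound_fraction}")
    if bound_fraction == 1.0:
        raise OverflowError("bound_fraction = 1 corresponds to an infinite ratio")
    return bound_fraction / (1.0 - bound_fraction)


def ratio_to_bound_fraction(ratio: float) -> float:
    """Inverse of :func:`bound_fraction_to_ratio`: ``f_b = K / (1 + K)``."""
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    return ratio / (1.0 + ratio)


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Free-water and binding-corrected diffusivities (m^2/s)."""

    d_water: float
    d_gel: float

    def __post_init__(self) -> None:
        if self.d_water <= 0:
            raise ValueError("d_water must be > 0")
        if self.d_gel < 0:
            raise ValueError("d_gel must be >= 0")


@dataclass(frozen=True)
class TransportParams:
    """Physical constants and binding state of the release system.

    Defaults encode the reference assay: EGF (6.2 kDa) premixed at 50 ng/mL in
    a heparin/hyaluronate gel (4 kg/m^3 binder, 69% porosity) at 37 degC under
    water viscosity, with the binder immobilised by crosslinking.
    """

    temperature_K: float = 37.0 + CELSIUS_OFFSET
    viscosity_Pa_s: float = 6.913e-4
    molecular_weight_g_mol: float = 6200.0
    binder_concentration_kg_m3: float = 4.0
    binder_diffusivity_m2_s: float = 0.0
    porosity: float = 0.69
    bound_fraction: float = 0.995
    initial_concentration_ng_mL: float = 50.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be > 0")
        if self.viscosity_Pa_s <= 0:
            raise ValueError("viscosity_Pa_s must be > 0")
        if self.molecular_weight_g_mol <= 0:
            raise ValueError("molecular_weight_g_mol must be > 0")
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must be in (0, 1]")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must be in [0, 1]")
        if self.binder_diffusivity_m2_s < 0:
            raise ValueError("binder_diffusivity_m2_s must be >= 0")
        if self.binder_concentration_kg_m3 < 0:
            raise ValueError("binder_concentration_kg_m3 must be >= 0")
        if self.initial_concentration_ng_mL < 0:
            raise ValueError("initial_concentration_ng_mL must be >= 0")

    def with_bound_fraction(self, bound_fraction: float) -> "TransportParams":
        return replace(self, bound_fraction=bound_fraction)

    def diffusion_coefficients(self) -> DiffusionCoefficients:
        """Evaluate the free (water) and binding-corrected (gel) diffusivities."""
        d_w = polson_diffusivity(
            self.temperature_K, self.viscosity_Pa_s, self.molecular_weight_g_mol
        )
        d_g = effective_diffusivity(
            d_w, self.bound_fraction, self.binder_diffusivity_m2_s
        )
        return DiffusionCoefficients(d_water=d_w, d_gel=d_g)

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "viscosity_Pa_s": self.viscosity_Pa_s,
            "molecular_weight_g_mol": self.molecular_weight_g_mol,
            "binder_concentration_kg_m3": self.binder_concentration_kg_m3,
            "binder_diffusivity_m2_s": self.binder_diffusivity_m2_s,
            "porosity": self.porosity,
            "bound_fraction": self.bound_fraction,
            "initial_concentration_ng_mL": self.initial_concentration_ng_mL,
        }
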