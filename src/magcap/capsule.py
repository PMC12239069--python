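"""Capsule and fluid properties: geometry and effective magnetic susceptibility.

A microcapsule is a ~190 μm polymer sphere whose shell carries a small mass
fraction (ppm scale) of superparamagnetic iron-oxide nanoparticles. Its
magnetic response enters the transport model only through a single composite
quantity, the effective volume susceptibility chi_p_eff, built from

* the nanoparticle volume fraction phi (converted from the mass-ppm loading
  using the nanoparticle and matrix densities),
* the susceptibility contrast between nanoparticle material and suspending
  fluid, and
* a demagnetization factor N_d (1/3 for a uniformly magnetized sphere).

The default mixing rule is the dilute Maxwell-Garnett / demagnetization form

    chi_eff = phi * (chi_i - chi_f) / (1 + N_d * (chi_i - chi_f))

which is linear in phi, vanishes at zero loading or zero contrast, and
saturates at phi/N_d as the contrast grows. The rule is a plain function so
an alternative mixing law can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants
from .errors import DomainError, ModelValidityError

__all__ = [
    "CapsuleSpec",
    "FluidMedium",
    "volume_fraction_from_ppm",
    "effective_susceptibility",
    "intrinsic_from_effective",
    "capsule_volume",
    "langevin_intrinsic_susceptibility",
]


def volume_fraction_from_ppm(loading_ppm: float, np_density: float, matrix_density: float) -> float:
    """Nanoparticle volume fraction from a mass-ppm loading.

    phi = (w/rho_np) / (w/rho_np + (1-w)/rho_matrix) with w = loading_ppm·1e-6.
    """
    if not (0 <= loading_ppm < 1e6):
        raise DomainError(f"loading_ppm must be in [0, 1e6), got {loading_ppm}")
    if np_density <= 0 or matrix_density <= 0:
        raise DomainError("densities must be positive")
    w = loading_ppm * 1e-6
    v_np = w / np_density
    return v_np / (v_np + (1.0 - w) / matrix_density)


def effective_susceptibility(
    phi: float, chi_intrinsic: float, chi_fluid: float, demag_factor: float
) -> float:
    """Effective capsule susceptibility chi_eff = phi·Δchi / (1 + N_d·Δchi).

    Δchi = chi_intrinsic - chi_fluid. Linear in phi; zero at zero loading or
    zero contrast; with N_d = 1/3 bounded above by 3·phi as Δchi → ∞.
    """
    if not (0 <= phi < 1):
        raise DomainError(f"volume fraction must be in [0, 1), got {phi}")
    if not (0 <= demag_factor <= 1):
        raise DomainError(f"demag_factor must be in [0, 1], got {demag_factor}")
    dchi = chi_intrinsic - chi_fluid
    denom = 1.0 + demag_factor * dchi
    if denom <= 0:
        raise ModelValidityError(
            f"1 + N_d*(chi_i - chi_f) = {denom} <= 0: susceptibility contrast outside "
            "the validity region of the mixing rule"
        )
    return phi * dchi / denom


def intrinsic_from_effective(
    chi_eff: float, phi: float, chi_fluid: float, demag_factor: float
) -> float:
    """Invert the mixing rule: the intrinsic susceptibility reproducing chi_eff.

    Raises :class:`ModelValidityError` if chi_eff is at or beyond the
    saturation value phi/N_d reachable by the rule.
    """
    if phi <= 0:
        raise DomainError("phi must be > 0 to attribute an intrinsic susceptibility")
    ratio = chi_eff / phi
    denom = 1.0 - demag_factor * ratio
    if denom <= 0:
        raise ModelValidityError(
            f"chi_eff = {chi_eff} is unreachable: the mixing rule saturates at phi/N_d = "
            f"{phi / demag_factor if demag_factor > 0 else math.inf}"
        )
    return ratio / denom + chi_fluid


@dataclass(frozen=True)
class CapsuleSpec:
    """Geometry and magnetic composition of one microcapsule.

    Parameters
    ----------
    diameter
        Capsule diameter d_p, meters (the experiments span 180–200 μm).
    np_diameter
        Embedded nanoparticle diameter, meters (5/10/20 nm conditions).
    loading_ppm
        Nanoparticle mass fraction in the polymer phase, ppm by mass.
    intrinsic_susceptibility
        Dimensionless volume susceptibility of the nanoparticle material at
        this nanoparticle size (a per-size input; see the optional Langevin
        helper for a model-based alternative).
    np_density, matrix_density
        Material densities, kg/m³ (defaults: magnetite, PDMS).
    demag_factor
        Demagnetization factor N_d in [0, 1]; 1/3 for a sphere.
    """

    diameter: float
    np_diameter: float
    loading_ppm: float
    intrinsic_susceptibility: float
    np_density: float = constants.MAGNETITE_DENSITY
    matrix_density: float = constants.PDMS_DENSITY
    demag_factor: float = constants.SPHERE_DEMAG_FACTOR

    def __post_init__(self):
        if self.diameter <= 0:
            raise DomainError(f"diameter must be > 0, got {self.diameter}")
        if self.np_diameter <= 0:
            raise DomainError(f"np_diameter must be > 0, got {self.np_diameter}")
        if not (0 <= self.loading_ppm < 1e6):
            raise DomainError(f"loading_ppm must be in [0, 1e6), got {self.loading_ppm}")
        if self.np_density <= 0 or self.matrix_density <= 0:
            raise DomainError("densities must be positive")
        if not (0 <= self.demag_factor <= 1):
            raise DomainError(f"demag_factor must be in [0, 1], got {self.demag_factor}")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def volume(self) -> float:
        """Capsule volume V_p = π·d³/6, m³ (computed, never stored)."""
        return math.pi * self.diameter**3 / 6.0

    @property
    def volume_fraction(self) -> float:
        """Nanoparticle volume fraction phi from the mass-ppm loading."""
        return volume_fraction_from_ppm(self.loading_ppm, self.np_density, self.matrix_density)

    def effective_susceptibility(self, fluid: "FluidMedium") -> float:
        """chi_p_eff of this capsule suspended in ``fluid``."""
        return effective_susceptibility(
            self.volume_fraction,
            self.intrinsic_susceptibility,
            fluid.susceptibility,
            self.demag_factor,
        )

    def with_effective_susceptibility(self, chi_eff: float, fluid: "FluidMedium") -> "CapsuleSpec":
        """A copy whose intrinsic susceptibility reproduces ``chi_eff`` in ``fluid``."""
        chi_i = intrinsic_from_effective(
            chi_eff, self.volume_fraction, fluid.susceptibility, self.demag_factor
        )
        return CapsuleSpec(
            diameter=self.diameter,
            np_diameter=self.np_diameter,
            loading_ppm=self.loading_ppm,
            intrinsic_susceptibility=chi_i,
            np_density=self.np_density,
            matrix_density=self.matrix_density,
            demag_factor=self.demag_factor,
        )

    @property
    def density(self) -> float:
        """Bulk capsule density, kg/m³: volume-fraction-weighted mixture."""
        phi = self.volume_fraction
        return phi * self.np_density + (1.0 - phi) * self.matrix_density


@dataclass(frozen=True)
class FluidMedium:
    """Suspending fluid: dynamic viscosity (Pa·s), volume susceptibility, density (kg/m³)."""

    viscosity: float = constants.WATER_VISCOSITY
    susceptibility: float = constants.WATER_SUSCEPTIBILITY
    density: float = constants.WATER_DENSITY

    def __post_init__(self):
        if self.viscosity <= 0:
            raise DomainError(f"viscosity must be > 0, got {self.viscosity}")
        if self.density <= 0:
            raise DomainError(f"density must be > 0, got {self.density}")


def capsule_volume(spec: CapsuleSpec) -> float:
    """Capsule volume V_p = π·d_p³/6 in m³."""
    return spec.volume


def langevin_intrinsic_susceptibility(
    np_diameter: float,
    flux_density: float,
    temperature: float = 298.15,
    saturation_magnetization: float = constants.MAGNETITE_SATURATION_MAGNETIZATION,
) -> float:
    """Optional Langevin superparamagnet model for the intrinsic susceptibility.

    Treats each nanoparticle as a single-domain moment m = M_s·V_np and
    returns chi_i = M / H with M = M_s·L(ξ), ξ = μ0·m·H / (k_B·T),
    H = B/μ0. This is a modelling extension for exploring size dependence,
    not a measured relationship; the transport pipeline takes chi_i as a
    per-size input.
    """
    if np_diameter <= 0 or temperature <= 0 or saturation_magnetization <= 0:
        raise DomainError("np_diameter, temperature and M_s must be positive")
    if flux_density <= 0:
        raise DomainError("flux_density must be positive")
    v_np = math.pi * np_diameter**3 / 6.0
    m = saturation_magnetization * v_np
    h = flux_density / constants.MU_0
    xi = constants.MU_0 * m * h / (constants.K_B * temperature)
    if xi < 1e-6:
        langevin = xi / 3.0
    else:
        langevin = 1.0 / math.tanh(xi) - 1.0 / xi
    return saturation_magnetization * langevin / h
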