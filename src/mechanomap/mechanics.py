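"""Analytic uniaxial compression surrogate for the agarose loading device.

The calibration device compresses a cylindrical agarose block (default
10 mm diameter x 10 mm height) between two plates by a prescribed plate
displacement.  The block is modeled as a compressible Neo-Hookean solid

    W = (G/2) (I1 - 3) - G ln J + (Lambda/2) (ln J)^2,

with shear modulus G and first Lame parameter Lambda = 2 G nu / (1 - 2 nu).
Under homogeneous frictionless uniaxial compression (axial stretch
lambda <= 1, lateral stretch from the traction-free condition) the axial
Cauchy stress has a closed form up to one scalar root-find, which replaces
full finite-element analysis here; stress in the device is uniform, so the
homogeneous surrogate is adequate for schedule design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import NumericalError, ValidationError

__all__ = [
    "NeoHookeanMaterial",
    "DeviceGeometry",
    "agarose_material",
    "uniaxial_stress",
    "strain_energy_density",
    "displacement_to_stress",
    "stress_to_displacement",
]

#: Tabulated agarose properties: % w/v -> shear modulus G (kPa), at nu = 0.31.
AGAROSE_SHEAR_MODULI = {0.5: 0.4, 1.0: 1.5, 2.0: 4.7}
AGAROSE_POISSON = 0.31


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Compressible Neo-Hookean constants: shear modulus G (kPa), Poisson nu."""

    G: float
    nu: float

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValidationError(f"shear modulus must be positive, got {self.G}")
        if not (0 < self.nu < 0.5):
            raise ValidationError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")

    @property
    def lame_lambda(self) -> float:
        """First Lame parameter Lambda = 2 G nu / (1 - 2 nu), kPa."""
        return 2.0 * self.G * self.nu / (1.0 - 2.0 * self.nu)

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus E = 2 G (1 + nu), kPa."""
        return 2.0 * self.G * (1.0 + self.nu)


@dataclass(frozen=True)
class DeviceGeometry:
    """Cylindrical sample geometry of the compression device (mm)."""

    diameter: float = 10.0
    height: float = 10.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValidationError("diameter and height must be positive")


def agarose_material(concentration: float) -> NeoHookeanMaterial:
    """Neo-Hookean constants for agarose at a given % w/v concentration.

    Tabulated at 0.5 / 1.0 / 2.0 %; log-linear interpolation of G in between
    (gel moduli scale roughly as a power of concentration).  Outside the
    tabulated interval the value is an extrapolation and a warning is raised.
    """
    if concentration <= 0:
        raise ValidationError("concentration must be positive")
    concs = np.array(sorted(AGAROSE_SHEAR_MODULI))
    gs = np.array([AGAROSE_SHEAR_MODULI[c] for c in concs])
    if concentration < concs[0] or concentration > concs[-1]:
        import warnings

        warnings.warn(
            f"concentration {concentration}% outside tabulated range "
            f"[{concs[0]}, {concs[-1]}]%; shear modulus is an extrapolation",
            stacklevel=2,
        )
    logG = np.interp(np.log(concentration), np.log(concs), np.log(gs))
    return NeoHookeanMaterial(G=float(np.exp(logG)), nu=AGAROSE_POISSON)


def strain_energy_density(material: NeoHookeanMaterial, stretches) -> float:
    """W per unit reference volume (kPa) at principal stretches (l1, l2, l3)."""
    l = np.asarray(stretches, dtype=float)
    if np.any(l <= 0):
        raise ValidationError("principal stretches must be positive")
    J = float(np.prod(l))
    I1 = float(np.sum(l**2))
    G, Lam = material.G, material.lame_lambda
    return 0.5 * G * (I1 - 3.0) - G * np.log(J) + 0.5 * Lam * np.log(J) ** 2


def _lateral_stretch(material: NeoHookeanMaterial, lam_axial: float) -> float:
    """Solve the traction-free lateral condition G(lt^2 - 1) + Lam ln J = 0."""
    G, Lam = material.G, material.lame_lambda

    def resid(lt: float) -> float:
        J = lam_axial * lt * lt
        return G * (lt * lt - 1.0) + Lam * np.log(J)

    lo, hi = 1e-3, 10.0
    try:
        return brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16)
    except ValueError as exc:
        raise NumericalError(
            f"lateral-stretch root not bracketed in [{lo}, {hi}] "
            f"for axial stretch {lam_axial}"
        ) from exc


def uniaxial_stress(material: NeoHookeanMaterial, axial_stretch: float) -> float:
    """Magnitude of the axial Cauchy stress (kPa) at axial stretch lambda.

    ``axial_stretch`` in (0, 1]: 1 is the undeformed state, smaller values
    are compression.  The lateral stretch adjusts so the lateral surfaces
    are traction-free.
    """
    lam = float(axial_stretch)
    if not (0 < lam <= 1):
        raise ValidationError(f"axial stretch must lie in (0, 1], got {lam}")
    if lam == 1.0:
        return 0.0
    lt = _lateral_stretch(material, lam)
    J = lam * lt * lt
    G, Lam = material.G, material.lame_lambda
    sigma_axial = (G * (lam * lam - 1.0) + Lam * np.log(J)) / J
    return float(abs(sigma_axial))


def displacement_to_stress(
    material: NeoHookeanMaterial, geometry: DeviceGeometry, dx: float
) -> float:
    """Applied compressive stress (kPa) for a plate displacement dx (mm)."""
    if dx < 0 or dx >= geometry.height:
        raise ValidationError(
            f"displacement must lie in [0, {geometry.height}) mm, got {dx}"
        )
    return uniaxial_stress(material, 1.0 - dx / geometry.height)


def stress_to_displacement(
    material: NeoHookeanMaterial, geometry: DeviceGeometry, stress: float
) -> float:
    """Plate displacement (mm) producing a target compressive stress (kPa)."""
    if stress < 0:
        raise ValidationError("stress must be nonnegative")
    if stress == 0:
        return 0.0

    def resid(dx: float) -> float:
        return displacement_to_stress(material, geometry, dx) - stress

    hi = 0.99 * geometry.height
    if resid(hi) < 0:
        raise ValidationError(
            f"stress {stress} kPa unreachable below {hi} mm displacement"
        )
    return float(brentq(resid, 0.0, hi, xtol=1e-12))
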