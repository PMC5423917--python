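"""Algebraic closure laws for the water-swollen aqueous pore.

These link the free-water concentration in a pore to the adsorbed
monolayer coverage (Langmuir isotherm), the coverage to the pore radius
(closed Steiner-chain packing of water molecules around the pore wall),
the radius to the cuticle porosity, and the porosity to the effective
diffusivity (fractal tortuosity scaling).  All functions are pure,
accept scalars or numpy arrays, and work in strict SI units.

Notation: Gamma is the adsorbed surface concentration (mol/m^2), rp the
pore radius (m), eps the porosity (-), r_H2O the van der Waals radius of
water (m), NA the Avogadro constant (1/mol).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError, PoreOverlapError, SteinerChainError

__all__ = [
    "langmuir_adsorbed",
    "langmuir_slope",
    "pore_radius",
    "pore_radius_slope",
    "adsorbed_from_radius",
    "saturation_gamma",
    "langmuir_beta",
    "porosity",
    "effective_diffusivity",
    "min_gamma",
]

AVOGADRO = 6.02214e23  # 1/mol, default used when no parameter set is in scope


def langmuir_adsorbed(c_H2O, beta, Gamma_S):
    """Monolayer coverage Gamma = Gamma_S * beta*c / (1 + beta*c).

    Strictly increasing in ``c_H2O`` and bounded above by the saturation
    coverage ``Gamma_S``.
    """
    c = np.asarray(c_H2O, dtype=float)
    if np.any(c < 0):
        raise DomainError("langmuir_adsorbed: negative water concentration")
    bc = beta * c
    out = Gamma_S * bc / (1.0 + bc)
    return out if out.ndim else float(out)


def langmuir_slope(c_H2O, beta, Gamma_S):
    """dGamma/dc of the Langmuir isotherm: Gamma_S*beta/(1+beta*c)^2."""
    c = np.asarray(c_H2O, dtype=float)
    out = Gamma_S * beta / (1.0 + beta * c) ** 2
    return out if out.ndim else float(out)


def min_gamma(r_H2O, NA=AVOGADRO):
    """Smallest coverage with a valid Steiner chain (three molecules)."""
    return 3.0 / (np.pi * r_H2O**2 * NA)


def pore_radius(Gamma, r_H2O, NA=AVOGADRO):
    """Pore radius from monolayer coverage.

    rp = r_H2O * [1 + 1/sin(1/(Gamma * r_H2O^2 * NA))].

    The adsorbed molecules form a closed ring of ``n = Gamma*pi*r_H2O^2*NA``
    tangent spheres between the pore wall and the open lumen; the chain
    closes only for n >= 3, below which :class:`SteinerChainError` is
    raised.  Strictly increasing in ``Gamma`` on the valid domain.
    """
    G = np.asarray(Gamma, dtype=float)
    n_ring = G * np.pi * r_H2O**2 * NA
    if np.any(n_ring < 3.0 - 1e-12):
        raise SteinerChainError(
            "Steiner-chain geometry invalid: fewer than 3 adsorbed molecules "
            f"per circumference (min n_ring = {np.min(n_ring):.3g})"
        )
    s = 1.0 / (G * r_H2O**2 * NA)  # = pi / n_ring, <= pi/3
    out = r_H2O * (1.0 + 1.0 / np.sin(s))
    return out if out.ndim else float(out)


def pore_radius_slope(Gamma, r_H2O, NA=AVOGADRO):
    """drp/dGamma of :func:`pore_radius` (analytic, positive on the domain)."""
    G = np.asarray(Gamma, dtype=float)
    s = 1.0 / (G * r_H2O**2 * NA)
    out = r_H2O * s * np.cos(s) / (G * np.sin(s) ** 2)
    return out if out.ndim else float(out)


def adsorbed_from_radius(rp, r_H2O, NA=AVOGADRO):
    """Coverage from pore radius; exact inverse of :func:`pore_radius`.

    Gamma = [r_H2O^2 * NA * arcsin(1/(rp/r_H2O - 1))]^-1, defined for
    rp > 2*r_H2O (arcsin argument below 1).
    """
    r = np.asarray(rp, dtype=float)
    if np.any(r <= 2.0 * r_H2O):
        raise DomainError(
            "adsorbed_from_radius: pore radius must exceed twice the water "
            f"molecule radius (got {np.min(r):.3g} <= {2 * r_H2O:.3g})"
        )
    out = 1.0 / (r_H2O**2 * NA * np.arcsin(1.0 / (r / r_H2O - 1.0)))
    return out if out.ndim else float(out)


def saturation_gamma(rp_max, r_H2O, NA=AVOGADRO):
    """Saturated coverage Gamma_S such that a full monolayer gives rp_max."""
    return adsorbed_from_radius(rp_max, r_H2O, NA)


def langmuir_beta(c_H2O_0, Gamma_0, Gamma_S):
    """Langmuir affinity calibrated so Gamma(c_H2O_0) = Gamma_0 exactly.

    beta = 1 / (c_H2O_0 * (Gamma_S/Gamma_0 - 1)); requires
    0 < Gamma_0 < Gamma_S and c_H2O_0 > 0.
    """
    if not c_H2O_0 > 0:
        raise DomainError("langmuir_beta: reference concentration must be positive")
    if not 0 < Gamma_0 < Gamma_S:
        raise DomainError(
            "langmuir_beta: reference coverage must lie strictly between 0 and "
            f"Gamma_S (got Gamma_0 = {Gamma_0:.4g}, Gamma_S = {Gamma_S:.4g})"
        )
    return 1.0 / (c_H2O_0 * (Gamma_S / Gamma_0 - 1.0))


def porosity(rp, n0, L):
    """Cuticle porosity eps = pi * (rp * (sqrt(n0) + 1) / L)^2.

    Each of the ``n0`` evenly spaced pores on an L x L patch owns a
    circular control area A_Pi = (L/(sqrt(n0)+1))^2; eps is the pore
    cross-section over that area.  Values >= 1 mean overlapping pores and
    raise :class:`PoreOverlapError`.
    """
    r = np.asarray(rp, dtype=float)
    if np.any(r < 0):
        raise DomainError("porosity: negative pore radius")
    eps = np.pi * (r * (np.sqrt(n0) + 1.0) / L) ** 2
    if np.any(eps >= 1.0):
        raise PoreOverlapError(
            f"porosity reached {np.max(eps):.4g} >= 1: pore cross-sections "
            "overlap, the evenly-spaced-pore geometry is invalid"
        )
    return eps if eps.ndim else float(eps)


def effective_diffusivity(D_bulk, eps, Fs):
    """Effective diffusivity D = D_bulk * eps^(Fs/(2-Fs)).

    The exponent Fbar = Fs/(2-Fs) encodes pore tortuosity through the
    fractal scaling dimension Fs, restricted to 1 < Fs < 2.
    """
    if not 1.0 < Fs < 2.0:
        raise DomainError(f"effective_diffusivity: Fs must lie in (1, 2), got {Fs}")
    e = np.asarray(eps, dtype=float)
    if np.any(e < 0) or np.any(e > 1):
        raise DomainError("effective_diffusivity: porosity outside [0, 1]")
    out = D_bulk * e ** (Fs / (2.0 - Fs))
    return out if out.ndim else float(out)
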