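"""Sessile-droplet geometry, evaporation and drop-side boundary closures.

The applied drop is a spherical cap that evaporates in constant-contact-
radius mode (the contact line stays pinned while the contact angle
relaxes).  Diffusion-limited evaporation into still air at relative
humidity H then removes water at the near-constant rate

    dV/dt = -2 * delta * D_evap * psi * r_drop / rho_L,

where psi = Mw*Pv/(R*T) * (1 - H) is the vapor-concentration deficit and
delta ~ 1.994 is the rate constant of the closed-form sessile-drop law
(2*delta is numerically the flat-disk vapor capacitance 4*D*r*dc).  In
the grouped dimensionless time tau = 2*D_evap*psi*t/(r_drop^2*rho_L)
this is V(tau) = delta*r_drop^3 * (V0/(delta*r_drop^3) - tau).

Because the dissolved salt is deliquescent, the drop never dries out:
once its concentration reaches the solubility limit c_sat the volume is
clamped at the solubility floor V_inf = c_AI0*V0/c_sat and the residue
persists as a saturated liquid film.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, VolumeFractionError

__all__ = [
    "DropState",
    "drop_geometry",
    "vapor_concentration",
    "evaporation_rate",
    "floor_time",
    "drop_volume",
    "drop_ai_rhs",
    "water_conc_in_drop",
]


@dataclass
class DropState:
    """Droplet state at one instant.

    V: water volume (m^3); c_AI_drop: AI concentration (mol/m^3);
    m_bound: cumulative AI irreversibly bound to the cuticle surface
    (mol); regime: 'evaporating' while V > V_inf, 'floored' after.
    """

    V: float
    c_AI_drop: float
    m_bound: float = 0.0
    regime: str = "evaporating"


def drop_geometry(V0: float, theta0: float) -> tuple[float, float, float]:
    """Spherical-cap shape factor, contact radius and contact area.

    g(theta) = (1-cos)^2 (2+cos);  r_drop = (3 V0 / (pi g))^(1/3) sin;
    A_drop = pi r_drop^2.  Consistent with the cap volume
    V = (pi/3) (r_drop/sin)^3 g.
    """
    if not 0.0 < theta0 < math.pi:
        raise GeometryError(f"theta0 must lie in (0, pi) rad, got {theta0}")
    if not V0 > 0:
        raise GeometryError(f"V0 must be positive, got {V0}")
    cos = math.cos(theta0)
    g = (1.0 - cos) ** 2 * (2.0 + cos)
    r_drop = (3.0 * V0 / (math.pi * g)) ** (1.0 / 3.0) * math.sin(theta0)
    return g, r_drop, math.pi * r_drop**2


def cap_volume(r_drop: float, theta: float) -> float:
    """Spherical-cap volume at contact radius ``r_drop`` and angle ``theta``."""
    cos = math.cos(theta)
    g = (1.0 - cos) ** 2 * (2.0 + cos)
    return math.pi / 3.0 * (r_drop / math.sin(theta)) ** 3 * g


def vapor_concentration(env) -> float:
    """Evaporative driving concentration psi = Mw*Pv/(R*T)*(1-H), kg/m^3."""
    return env.Mw_H2O * env.Pv / (env.R * env.T) * (1.0 - env.H)


def evaporation_rate(consts, env) -> float:
    """|dV/dt| of the pinned drop before the floor, m^3/s."""
    return 2.0 * env.delta * env.D_evap * consts.psi * consts.r_drop / env.rho_L


def floor_time(consts, env, V0: float) -> float:
    """Time at which the drop volume reaches the solubility floor V_inf.

    Infinite when the air is saturated (psi = 0).
    """
    rate = evaporation_rate(consts, env)
    if rate <= 0.0:
        return math.inf
    return (V0 - consts.V_inf) / rate


def drop_volume(t, consts, env, V0: float):
    """Drop water volume V(t): linear decay clamped at the floor V_inf.

    Continuous at the floor-crossing time (the derivative jumps).
    Accepts scalar or array ``t``.
    """
    rate = evaporation_rate(consts, env)
    V = np.maximum(V0 - rate * np.asarray(t, dtype=float), consts.V_inf)
    return V if V.ndim else float(V)


def drop_ai_rhs(drop: DropState, surface_gradient: float, consts, cuticle,
                D_AI_surface: float, gammabar_scale: float = 1.0
                ) -> tuple[float, float]:
    """Rate of change of the drop's AI content d(V*c)/dt, mol/s.

    Two loss channels: irreversible first-order ion binding to the
    cuticle surface (-k*c) and porous diffusion into the pores under the
    drop, proportional to the pore-coupling group rho0*A_drop*A_Pi and
    the one-sided surface gradient of eps*c_AI.  Returns
    ``(d(V c)/dt, binding_rate)`` so the caller can book the bound mass.
    """
    binding = cuticle.k * drop.c_AI_drop
    coupling = consts.A_drop * cuticle.rho0 * consts.A_Pi * gammabar_scale
    return -binding + coupling * D_AI_surface * surface_gradient, binding


def water_conc_in_drop(c_AI, vbar_AI: float, vbar_H2O: float):
    """Water concentration in the drop from volume conservation.

    c_H2O = (1 - vbar_AI*c_AI)/vbar_H2O, i.e. the AI and water volume
    fractions sum to one.
    """
    c = np.asarray(c_AI, dtype=float)
    if np.any(vbar_AI * c > 1.0 + 1e-12):
        raise VolumeFractionError(
            "solute volume fraction vbar_AI*c_AI exceeds 1 "
            f"(max {np.max(vbar_AI * c):.4g})"
        )
    out = (1.0 - vbar_AI * c) / vbar_H2O
    return out if out.ndim else float(out)
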