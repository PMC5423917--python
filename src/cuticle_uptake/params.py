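"""Parameter sets, unit handling, the tomato-cuticle preset and derived constants.

The model is parameterised by four groups — cuticle structure, solute
(the ionic active ingredient, CaCl2 by default), environment and applied
droplet — plus a numerics block that belongs to the artifact, not the
physics.  Everything is stored in strict SI (kg, m, s, mol, K) with one
deliberate exception: the AI molecular weight is kept in g/mol because it
only ever appears in the g -> ug uptake conversion.

The bundled preset reproduces the Kraemer et al. tomato-fruit-cuticle
uptake experiment (isolated astomatous cuticle, CaCl2 droplets, water
bath receiver): cuticle thickness 18.7 um, maximum pore radius 2.12 nm,
fitted pore density 8.4e14 m^-2, fractal dimension 1.1, ion-binding rate
1.07e-15 m^3/s, 70% relative humidity at 20 C, five 1 uL drops.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import constitutive, droplet
from .exceptions import GeometryError, ParameterError

__all__ = [
    "CuticleParams",
    "SoluteParams",
    "EnvironmentParams",
    "DropletParams",
    "ModelParams",
    "DerivedConstants",
    "NumericsConfig",
    "load_params",
    "derive_constants",
    "applied_mass_ug",
    "kraemer_preset",
    "concentration_mol_m3",
    "KRAEMER_MASS_TO_GL",
]


@dataclass(frozen=True)
class CuticleParams:
    """Cuticle structure and surface chemistry.

    b: thickness (m); rp_max: maximum aqueous-pore radius (m);
    rho0: aqueous-pore areal density (m^-2); Fs: fractal scaling
    dimension (-), 1 < Fs < 2; L: control-volume patch length (m);
    r_H2O: van der Waals radius of water (m); k: surface ion-binding
    rate constant (m^3/s).
    """

    b: float = 1.87e-5
    rp_max: float = 2.12e-9
    rho0: float = 8.4e14
    Fs: float = 1.1
    L: float = 1.0
    r_H2O: float = 1.5e-10
    k: float = 1.07e-15

    def validate(self) -> None:
        if not self.b > 0:
            raise ParameterError(f"b must be positive, got {self.b}")
        if not self.r_H2O > 0:
            raise ParameterError(f"r_H2O must be positive, got {self.r_H2O}")
        if not self.rp_max > self.r_H2O:
            raise ParameterError(
                f"rp_max ({self.rp_max}) must exceed r_H2O ({self.r_H2O})"
            )
        if not self.rho0 > 0:
            raise ParameterError(f"rho0 must be positive, got {self.rho0}")
        if not 1.0 < self.Fs < 2.0:
            raise ParameterError(f"Fs must lie strictly in (1, 2), got {self.Fs}")
        if not self.L > 0:
            raise ParameterError(f"L must be positive, got {self.L}")
        if self.k < 0:
            raise ParameterError(f"k must be non-negative, got {self.k}")


@dataclass(frozen=True)
class SoluteParams:
    """Active-ingredient properties (defaults: CaCl2 in water at 20 C).

    Mw_AI: molecular weight (g/mol, used only in the ug conversion);
    vbar_AI: partial molar volume (m^3/mol); D_AI_bulk: bulk
    self-diffusion coefficient (m^2/s; the Ca2+ value, the slower ion);
    c_sat: deliquescence-limited saturation concentration (mol/m^3).
    """

    Mw_AI: float = 110.98
    vbar_AI: float = 1.6e-5
    D_AI_bulk: float = 7.93e-10
    c_sat: float = 6.71e3

    def validate(self) -> None:
        for name in ("Mw_AI", "vbar_AI", "D_AI_bulk", "c_sat"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class EnvironmentParams:
    """Ambient conditions, water properties and physical constants.

    T (K); H: relative humidity, fraction in [0, 1); Pv: saturated water
    vapor pressure (Pa); D_evap: water-vapor diffusivity in air (m^2/s);
    Mw_H2O (kg/mol); rho_L: liquid water density (kg/m^3); vbar_H2O:
    partial molar volume of water (m^3/mol); D_H2O_bulk: bulk water
    self-diffusion (m^2/s); delta: evaporation-rate constant (-);
    R (Pa m^3/K/mol); NA (1/mol).
    """

    T: float = 293.15
    H: float = 0.7
    Pv: float = 2338.8
    D_evap: float = 2.4e-5
    Mw_H2O: float = 0.018015
    rho_L: float = 998.2071
    vbar_H2O: float = 1.8047e-5
    D_H2O_bulk: float = 2.299e-9
    delta: float = 1.994
    R: float = 8.3145
    NA: float = 6.02214e23

    def validate(self) -> None:
        if not 0.0 <= self.H < 1.0:
            raise ParameterError(f"H must lie in [0, 1), got {self.H}")
        for name in ("T", "Pv", "D_evap", "Mw_H2O", "rho_L", "vbar_H2O",
                     "D_H2O_bulk", "delta", "R", "NA"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class DropletParams:
    """Applied surface droplet(s).

    V0: initial volume per drop (m^3); theta0: initial contact angle
    (rad, 0 < theta0 < pi); c_AI0: initial AI concentration (mol/m^3);
    n_drops: number of drops applied.
    """

    V0: float = 1e-9
    theta0: float = math.radians(99.2)
    c_AI0: float = 1000.0 * 10.0 / 110.98  # 10 g/L CaCl2
    n_drops: int = 5

    def validate(self) -> None:
        if not self.V0 > 0:
            raise ParameterError(f"V0 must be positive, got {self.V0}")
        if not 0.0 < self.theta0 < math.pi:
            raise GeometryError(f"theta0 must lie in (0, pi) rad, got {self.theta0}")
        if self.c_AI0 < 0:
            raise ParameterError(f"c_AI0 must be non-negative, got {self.c_AI0}")
        if self.n_drops < 1:
            raise ParameterError(f"n_drops must be >= 1, got {self.n_drops}")


@dataclass(frozen=True)
class ModelParams:
    """Complete physical parameter set.

    ``gammabar_scale`` is a diagnostic multiplier on the pore-coupling
    group rho0*A_drop*A_Pi everywhere it appears (drop boundary
    condition, uptake conversion, cuticle content); it exists so the
    dimensionless pore-volume ratio gammabar can be perturbed in
    isolation during sensitivity analysis.
    """

    cuticle: CuticleParams = field(default_factory=CuticleParams)
    solute: SoluteParams = field(default_factory=SoluteParams)
    environment: EnvironmentParams = field(default_factory=EnvironmentParams)
    droplet: DropletParams = field(default_factory=DropletParams)
    gammabar_scale: float = 1.0

    def validate(self) -> None:
        self.cuticle.validate()
        self.solute.validate()
        self.environment.validate()
        self.droplet.validate()
        if not self.gammabar_scale > 0:
            raise ParameterError(
                f"gammabar_scale must be positive, got {self.gammabar_scale}"
            )
        if self.droplet.c_AI0 > self.solute.c_sat:
            raise ParameterError(
                f"c_AI0 ({self.droplet.c_AI0:.4g}) exceeds the saturation "
                f"concentration c_sat ({self.solute.c_sat:.4g})"
            )
        # The initial pore radius rp_max*H must leave room for a valid
        # Steiner chain; below ~2*r_H2O/rp_max the monolayer model breaks.
        if self.environment.H * self.cuticle.rp_max <= 2.0 * self.cuticle.r_H2O:
            raise ParameterError(
                f"H = {self.environment.H} gives an initial pore radius "
                f"rp_max*H = {self.environment.H * self.cuticle.rp_max:.3g} m "
                f"<= 2*r_H2O = {2 * self.cuticle.r_H2O:.3g} m; the adsorption "
                "geometry is undefined at this humidity"
            )

    def flat(self) -> dict:
        """Flat config-style echo of every field (SI units)."""
        out = {}
        for group in (self.cuticle, self.solute, self.environment, self.droplet):
            out.update(asdict(group))
        out["gammabar_scale"] = self.gammabar_scale
        return out


@dataclass(frozen=True)
class DerivedConstants:
    """Quantities computed once per run from a :class:`ModelParams`.

    Gamma_S (mol/m^2), beta_H2O (m^3/mol), c_H2O_pure (mol/m^3),
    psi (kg/m^3), g_theta0 (-), r_drop (m), A_drop (m^2), n0 (-),
    A_Pi (m^2), V_inf (m^3), Fbar (-), gammabar (-).
    """

    Gamma_S: float
    beta_H2O: float
    c_H2O_pure: float
    psi: float
    g_theta0: float
    r_drop: float
    A_drop: float
    n0: float
    A_Pi: float
    V_inf: float
    Fbar: float
    gammabar: float


@dataclass
class NumericsConfig:
    """Discretisation and integrator settings (artifact choices).

    n_nodes: uniform mesh nodes across the cuticle (>= 11);
    t_final: simulated duration (s); output_times: explicit report
    times (s), or None for an automatic grid densified around the
    evaporation floor time; rel_tol/abs_tol: BDF integrator tolerances;
    evaporation_switch_tol: volume tolerance for the V = V_inf floor (m^3);
    n_output: size of the automatic output grid;
    face_average: 'arithmetic' (default) or 'harmonic' diffusivity
    averaging at control-volume faces.
    """

    n_nodes: int = 101
    t_final: float = 48 * 3600.0
    output_times: list | None = None
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    evaporation_switch_tol: float = 1e-18
    n_output: int = 500
    face_average: str = "arithmetic"

    def validate(self) -> None:
        if self.n_nodes < 11:
            raise ParameterError(f"n_nodes must be >= 11, got {self.n_nodes}")
        if not self.t_final > 0:
            raise ParameterError(f"t_final must be positive, got {self.t_final}")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ParameterError("integrator tolerances must be positive")
        if self.face_average not in ("arithmetic", "harmonic"):
            raise ParameterError(
                f"face_average must be 'arithmetic' or 'harmonic', got "
                f"{self.face_average!r}"
            )


# --- configuration loading ------------------------------------------------

# flat config key -> (group attribute, field name)
_FIELD_MAP = {}
for _group, _cls in (
    ("cuticle", CuticleParams),
    ("solute", SoluteParams),
    ("environment", EnvironmentParams),
    ("droplet", DropletParams),
):
    for _f in _cls.__dataclass_fields__:
        _FIELD_MAP[_f] = (_group, _f)

#: masses of Ca applied in the reference experiment (ug) -> drop
#: concentration in g/L CaCl2
KRAEMER_MASS_TO_GL = {5: 1.0, 25: 5.0, 50: 10.0, 75: 15.0, 150: 30.0}


def concentration_mol_m3(g_per_L: float, Mw_g_mol: float = 110.98) -> float:
    """Convert a salt concentration from g/L to mol/m^3 (bijective)."""
    return 1000.0 * g_per_L / Mw_g_mol


def kraemer_preset(mass_ug: int | None = None, **overrides) -> ModelParams:
    """The bundled tomato-cuticle preset, optionally at one of the five
    applied masses of Ca (5, 25, 50, 75 or 150 ug; default 50 ug = 10 g/L).
    """
    config = {}
    if mass_ug is not None:
        if mass_ug not in KRAEMER_MASS_TO_GL:
            raise ParameterError(
                f"mass_ug must be one of {sorted(KRAEMER_MASS_TO_GL)}, got {mass_ug}"
            )
        config["c_AI0_gL"] = KRAEMER_MASS_TO_GL[mass_ug]
    config.update(overrides)
    return load_params(config)


def _read_config(source) -> dict:
    if source is None:
        return {}
    if isinstance(source, dict):
        return dict(source)
    path = Path(source)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    if path.suffix.lower() in (".toml", ".cfg"):
        return tomllib.loads(text)
    # sniff: TOML first (a JSON object fails TOML parse and vice versa)
    try:
        return tomllib.loads(text)
    except tomllib.TOMLDecodeError:
        return json.loads(text)


def load_params(config_source=None) -> ModelParams:
    """Build a validated :class:`ModelParams` from a config file or dict.

    Missing keys fall back to the bundled preset.  Keys are the flat
    ASCII parameter names (``b``, ``rp_max``, ``rho0``, ``Fs``, ``k``,
    ``H``, ``T``, ``V0``, ...).  Two unit-suffixed aliases are accepted:
    ``theta0_deg`` (degrees) and ``c_AI0_gL`` (g/L, converted with the
    configured ``Mw_AI``).  Unknown keys are rejected.
    """
    raw = _read_config(config_source)

    if "theta0" in raw and "theta0_deg" in raw:
        raise ParameterError("give theta0 (rad) or theta0_deg, not both")
    if "c_AI0" in raw and "c_AI0_gL" in raw:
        raise ParameterError("give c_AI0 (mol/m^3) or c_AI0_gL, not both")

    groups = {"cuticle": {}, "solute": {}, "environment": {}, "droplet": {}}
    gammabar_scale = 1.0
    Mw_AI = raw.get("Mw_AI", SoluteParams.Mw_AI)

    for key, value in raw.items():
        if key == "theta0_deg":
            groups["droplet"]["theta0"] = _as_float(key, value) * math.pi / 180.0
            continue
        if key == "c_AI0_gL":
            groups["droplet"]["c_AI0"] = concentration_mol_m3(
                _as_float(key, value), _as_float("Mw_AI", Mw_AI)
            )
            continue
        if key == "gammabar_scale":
            gammabar_scale = _as_float(key, value)
            continue
        if key not in _FIELD_MAP:
            raise ParameterError(f"unknown configuration key {key!r}")
        group, name = _FIELD_MAP[key]
        if name == "n_drops":
            groups[group][name] = _as_int(key, value)
        else:
            groups[group][name] = _as_float(key, value)

    params = ModelParams(
        cuticle=CuticleParams(**groups["cuticle"]),
        solute=SoluteParams(**groups["solute"]),
        environment=EnvironmentParams(**groups["environment"]),
        droplet=DropletParams(**groups["droplet"]),
        gammabar_scale=gammabar_scale,
    )
    params.validate()
    return params


def _as_float(key, value) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"field {key!r}: cannot interpret {value!r} as a number") from exc
    if not math.isfinite(out):
        raise ParameterError(f"field {key!r}: value must be finite, got {out}")
    return out


def _as_int(key, value) -> int:
    out = _as_float(key, value)
    if out != int(out):
        raise ParameterError(f"field {key!r}: expected an integer, got {value!r}")
    return int(out)


# --- derived constants ----------------------------------------------------


def derive_constants(params: ModelParams) -> DerivedConstants:
    """Compute every run constant from a validated parameter set.

    Pure and idempotent: identical inputs give identical constants.
    """
    params.validate()
    cut, sol, env, drp = params.cuticle, params.solute, params.environment, params.droplet

    Gamma_S = constitutive.saturation_gamma(cut.rp_max, cut.r_H2O, env.NA)
    c_pure = env.rho_L / env.Mw_H2O
    # Affinity calibrated so that pure water in the pore reproduces the
    # humidity-set initial radius rp_max*H.
    Gamma_0 = constitutive.adsorbed_from_radius(cut.rp_max * env.H, cut.r_H2O, env.NA)
    beta = constitutive.langmuir_beta(c_pure, Gamma_0, Gamma_S)

    psi = droplet.vapor_concentration(env)
    g_theta0, r_drop, A_drop = droplet.drop_geometry(drp.V0, drp.theta0)

    n0 = cut.rho0 * cut.L**2
    A_Pi = (cut.L / (math.sqrt(n0) + 1.0)) ** 2
    V_inf = drp.c_AI0 * drp.V0 / sol.c_sat
    Fbar = cut.Fs / (2.0 - cut.Fs)
    gammabar = cut.rho0 * A_drop * A_Pi * cut.b / drp.V0 * params.gammabar_scale

    return DerivedConstants(
        Gamma_S=Gamma_S,
        beta_H2O=beta,
        c_H2O_pure=c_pure,
        psi=psi,
        g_theta0=g_theta0,
        r_drop=r_drop,
        A_drop=A_drop,
        n0=n0,
        A_Pi=A_Pi,
        V_inf=V_inf,
        Fbar=Fbar,
        gammabar=gammabar,
    )


def applied_mass_ug(params: ModelParams) -> float:
    """Total applied AI mass over all drops, in ug.

    10^6 * Mw_AI[g/mol] * c_AI0[mol/m^3] * V0[m^3] * n_drops.
    """
    drp = params.droplet
    return 1e6 * params.solute.Mw_AI * drp.c_AI0 * drp.V0 * drp.n_drops


def with_overrides(params: ModelParams, **flat_overrides) -> ModelParams:
    """Return a copy of ``params`` with flat-key overrides applied."""
    groups = {"cuticle": {}, "solute": {}, "environment": {}, "droplet": {}}
    top = {}
    for key, value in flat_overrides.items():
        if key == "gammabar_scale":
            top[key] = value
            continue
        if key not in _FIELD_MAP:
            raise ParameterError(f"unknown parameter {key!r}")
        group, name = _FIELD_MAP[key]
        groups[group][name] = value
    new = ModelParams(
        cuticle=replace(params.cuticle, **groups["cuticle"]),
        solute=replace(params.solute, **groups["solute"]),
        environment=replace(params.environment, **groups["environment"]),
        droplet=replace(params.droplet, **groups["droplet"]),
        gammabar_scale=top.get("gammabar_scale", params.gammabar_scale),
    )
    new.validate()
    return new
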