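"""Post-simulation analyses: percent uptake, OFAT sensitivity, humidity
sweeps and calibration of the fitted cuticle parameters.

The sensitivity measure is the dimensionless ratio

    relative sensitivity = |relative change in 48-h percent uptake|
                           / |relative change in the parameter|,

reported as a percentage.  Composite dimensionless parameters are
perturbed through their constituents while holding every other
dimensionless group fixed: the tortuosity exponent Fbar = Fs/(2-Fs)
through Fs, and the pore-volume ratio gammabar through a scale factor on
the pore-coupling group rho0*A_drop*A_Pi (applied consistently in the
drop boundary condition, the uptake conversion and the cuticle content,
so the mass audit stays closed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import DomainError, ParameterError
from .params import ModelParams, NumericsConfig, with_overrides
from .solver import simulate

__all__ = [
    "SensitivityRecord",
    "CalibrationResult",
    "percent_uptake_at",
    "ofat_sensitivity",
    "sensitivity_table",
    "humidity_sweep",
    "calibrate",
    "SENSITIVITY_PARAMETERS",
]

#: parameters accepted by :func:`ofat_sensitivity`
SENSITIVITY_PARAMETERS = (
    "Fbar", "rho0", "H", "k", "V0", "theta0", "b", "gammabar", "c_AI0",
)


@dataclass(frozen=True)
class SensitivityRecord:
    """One OFAT experiment: a parameter, its perturbation and the ratio."""

    parameter: str
    base_value: float
    perturbed_value: float
    base_uptake_pct: float
    perturbed_uptake_pct: float
    relative_sensitivity: float


@dataclass
class CalibrationResult:
    """Fit of the three trial-and-error cuticle parameters.

    fitted: {'Fs', 'k', 'rho0'}; objective: sum of squared uptake
    residuals (ug^2); trace: one dict per multistart with its start,
    solution and objective; success: whether the best start converged.
    """

    fitted: dict
    objective: float
    trace: list
    success: bool


def percent_uptake_at(params: ModelParams, numerics: NumericsConfig | None,
                      t: float) -> float:
    """Percent uptake M_t/applied * 100 at time ``t`` (s)."""
    numerics = replace(numerics) if numerics is not None else NumericsConfig()
    if t > numerics.t_final:
        raise DomainError(f"t = {t} exceeds t_final = {numerics.t_final}")
    numerics.t_final = float(t)
    result = simulate(params, numerics)
    return float(result.percent_uptake[-1])


def _base_value(params: ModelParams, parameter: str) -> float:
    cut, env, drp = params.cuticle, params.environment, params.droplet
    from .params import derive_constants

    consts = derive_constants(params)
    return {
        "Fbar": consts.Fbar, "rho0": cut.rho0, "H": env.H, "k": cut.k,
        "V0": drp.V0, "theta0": drp.theta0, "b": cut.b,
        "gammabar": consts.gammabar, "c_AI0": drp.c_AI0,
    }[parameter]


def perturbed_params(params: ModelParams, parameter: str, frac: float
                     ) -> ModelParams:
    """Copy of ``params`` with one (possibly composite) parameter scaled
    by 1 + frac."""
    if parameter not in SENSITIVITY_PARAMETERS:
        raise ParameterError(
            f"unknown sensitivity parameter {parameter!r}; valid names: "
            f"{', '.join(SENSITIVITY_PARAMETERS)}"
        )
    if frac == 0:
        raise DomainError("perturbation must be nonzero")
    s = 1.0 + frac
    if parameter == "Fbar":
        Fbar = params.cuticle.Fs / (2.0 - params.cuticle.Fs) * s
        return with_overrides(params, Fs=2.0 * Fbar / (1.0 + Fbar))
    if parameter == "gammabar":
        return with_overrides(params, gammabar_scale=params.gammabar_scale * s)
    key = {"rho0": "rho0", "H": "H", "k": "k", "V0": "V0",
           "theta0": "theta0", "b": "b", "c_AI0": "c_AI0"}[parameter]
    group = {"rho0": params.cuticle, "H": params.environment,
             "k": params.cuticle, "V0": params.droplet,
             "theta0": params.droplet, "b": params.cuticle,
             "c_AI0": params.droplet}[parameter]
    return with_overrides(params, **{key: getattr(group, key) * s})


def ofat_sensitivity(params: ModelParams, numerics: NumericsConfig | None,
                     parameter: str, fractional_perturbation: float = 0.1,
                     base_uptake_pct: float | None = None) -> SensitivityRecord:
    """One-factor-at-a-time relative sensitivity of 48-h percent uptake.

    Runs the base configuration (unless ``base_uptake_pct`` is supplied)
    and the perturbed one, and forms |d%U/%U| / |d%p/%p| * 100.
    """
    pert = perturbed_params(params, parameter, fractional_perturbation)
    if base_uptake_pct is None:
        base_uptake_pct = float(simulate(params, numerics).percent_uptake[-1])
    pert_pct = float(simulate(pert, numerics).percent_uptake[-1])
    rel = abs(pert_pct / base_uptake_pct - 1.0) / abs(fractional_perturbation) * 100.0
    return SensitivityRecord(
        parameter=parameter,
        base_value=_base_value(params, parameter),
        perturbed_value=_base_value(pert, parameter),
        base_uptake_pct=base_uptake_pct,
        perturbed_uptake_pct=pert_pct,
        relative_sensitivity=rel,
    )


def sensitivity_table(params: ModelParams, numerics: NumericsConfig | None = None,
                      parameters=SENSITIVITY_PARAMETERS,
                      fractional_perturbation: float = 0.1) -> pd.DataFrame:
    """OFAT table over ``parameters``, sorted by decreasing sensitivity."""
    base = float(simulate(params, numerics).percent_uptake[-1])
    records = [
        ofat_sensitivity(params, numerics, p, fractional_perturbation, base)
        for p in parameters
    ]
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.sort_values("relative_sensitivity", ascending=False,
                          ignore_index=True)


def humidity_sweep(params: ModelParams, numerics: NumericsConfig | None,
                   H_values) -> pd.DataFrame:
    """Final percent uptake for each relative humidity in ``H_values``.

    Failures for individual humidities are recorded as NaN with the
    error message; the sweep continues.
    """
    rows = []
    for H in H_values:
        try:
            p = with_overrides(params, H=float(H))
            pct = float(simulate(p, numerics).percent_uptake[-1])
            rows.append({"H": float(H), "percent_uptake": pct, "error": ""})
        except Exception as exc:  # noqa: BLE001 - sweep robustness
            rows.append({"H": float(H), "percent_uptake": math.nan,
                         "error": str(exc)})
    return pd.DataFrame(rows)


# --- calibration ----------------------------------------------------------

#: fixed multistart list in (Fs, log10 k, log10 rho0) space
_DEFAULT_STARTS = (
    (1.1, -15.0, 15.0),
    (1.3, -14.5, 14.0),
    (1.05, -15.5, 14.7),
    (1.5, -14.0, 15.3),
    (1.2, -16.0, 14.3),
)
_BOUNDS_LO = (1.01, -18.0, 13.0)
_BOUNDS_HI = (1.90, -12.0, 16.5)


def calibrate(params: ModelParams, numerics: NumericsConfig | None,
              observed_t_hours, observed_M_ug,
              starts=_DEFAULT_STARTS) -> CalibrationResult:
    """Fit (Fs, k, rho0) to a cumulative-uptake series by bounded least
    squares.

    Objective: sum over the observation times of (M_t(model) - M_t(obs))^2
    in ug^2, minimised with a trust-region reflective iteration; k and
    rho0 are searched in log10 space.  The multistart list is fixed, so
    the routine is deterministic.
    """
    t_h = np.asarray(observed_t_hours, dtype=float)
    M_obs = np.asarray(observed_M_ug, dtype=float)
    if t_h.size == 0:
        raise DomainError("observed uptake series is empty")
    numerics = replace(numerics) if numerics is not None else NumericsConfig()
    numerics.t_final = float(t_h.max() * 3600.0)
    numerics.output_times = list(t_h * 3600.0)

    def residuals(x):
        Fs, log_k, log_rho = x
        p = with_overrides(params, Fs=float(Fs), k=10.0**log_k, rho0=10.0**log_rho)
        result = simulate(p, numerics)
        M_model = np.interp(t_h * 3600.0, result.times, result.M_t_ug)
        return M_model - M_obs

    trace = []
    best = None
    for start in starts:
        try:
            # diff_step well above the integrator noise floor so the
            # finite-difference Jacobian stays smooth
            fit = least_squares(residuals, start, bounds=(_BOUNDS_LO, _BOUNDS_HI),
                                method="trf", x_scale=(0.1, 0.5, 0.5),
                                diff_step=1e-4, xtol=1e-10, ftol=1e-12,
                                gtol=1e-14, max_nfev=250)
            entry = {"start": tuple(start), "x": tuple(fit.x),
                     "objective": float(2.0 * fit.cost), "success": bool(fit.success),
                     "message": fit.message, "nfev": int(fit.nfev)}
        except Exception as exc:  # noqa: BLE001 - keep other starts alive
            entry = {"start": tuple(start), "x": None,
                     "objective": math.inf, "success": False,
                     "message": str(exc), "nfev": 0}
        trace.append(entry)
        if entry["success"] and (best is None or entry["objective"] < best["objective"]):
            best = entry
    if best is None:
        return CalibrationResult(fitted={}, objective=math.inf, trace=trace,
                                 success=False)
    Fs, log_k, log_rho = best["x"]
    return CalibrationResult(
        fitted={"Fs": float(Fs), "k": float(10.0**log_k),
                "rho0": float(10.0**log_rho)},
        objective=best["objective"], trace=trace, success=True,
    )
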