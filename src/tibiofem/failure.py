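"""Weibull damage-with-repair model of lifetime cartilage failure probability.

The load history is daily cyclic loading at the peak-force strain ``eps``:
one loading cycle per stride of the studied limb, ``daily_distance /
stride_length`` cycles per day. A power law maps strain to the
characteristic number of cycles to failure,

    N_fail = A * (B * eps)^(-m),

which converted to calendar time gives the characteristic life

    t_fail = A * (stride_length / daily_distance) * (B * eps)^(-m)   [days],

the duration at which 63.2 % of cases are expected to have failed. Failure of
the stressed tissue follows a Weibull law with a weakest-link volume scaling,

    P(t) = 1 - exp[ -(V / V_ref) * (t / t_fail)^(k/m) ],

with stressed cartilage volume V, reference specimen volume V_ref = 78.5 mm^3,
Weibull exponent k = 14.3 and power-law exponent m = 12.9 (shape k/m ~ 1.109).
Living cartilage repairs strain-induced damage; repair after damage follows

    P_rep(t) = 1 - exp[ -(t / t_rep)^r ],     t_rep = 5 years, r = 5.2,

again with 63.2 % of damage repaired at t = t_rep. Failure *with* repair is
the failure density thinned by the probability that repair has not yet
occurred,

    P_repair(t) = integral_0^t f(tau) * (1 - P_rep(tau)) d tau,

computed by trapezoidal quadrature on a monthly grid (the first cell is
integrated analytically because the Weibull density has a weak t^(k/m - 1)
singularity at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

DAYS_PER_YEAR = 365.25

__all__ = [
    "FailureParams",
    "FailureCurve",
    "time_to_failure",
    "failure_probability",
    "repair_probability",
    "failure_pdf",
    "failure_with_repair",
    "failure_curve",
    "participant_failure",
    "sensitivity_analysis",
]


@dataclass
class FailureParams:
    """Constants of the damage/repair model (units noted per field)."""

    v_ref: float = 78.5  # mm^3, reference stressed specimen volume
    weibull_exponent: float = 14.3  # k
    power_law_exponent: float = 12.9  # m
    power_law_coefficient: float = 1.0  # A
    weibull_coefficient: float = 1.03  # B
    repair_exponent: float = 5.2  # r
    t_rep: float = 5.0  # years until 63.2 % of damage is repaired
    daily_distance: float = 6000.0  # m/day walked
    horizon: float = 42.0  # years simulated (skeletal maturity to age 60)
    dt: float = 1.0 / 12.0  # years, quadrature step

    def validate(self) -> None:
        for name in (
            "v_ref", "weibull_exponent", "power_law_exponent",
            "power_law_coefficient", "weibull_coefficient", "repair_exponent",
            "t_rep", "daily_distance", "horizon", "dt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt >= self.t_rep:
            raise ValueError("dt must be smaller than the repair time")

    @property
    def shape(self) -> float:
        """Weibull shape of the life distribution, k/m."""
        return self.weibull_exponent / self.power_law_exponent


@dataclass
class FailureCurve:
    times: np.ndarray  # years, uniform 0..horizon
    p_fail: np.ndarray  # without repair
    p_fail_repair: np.ndarray  # with repair
    t_fail: float  # years


def time_to_failure(
    strain: float, stride_length: float, params: FailureParams | None = None
) -> float:
    """Characteristic life in years; strictly decreasing in strain.

    Zero strain means no damage accumulation: returns ``inf`` with a warning
    so unloaded cohort members aggregate cleanly.
    """
    params = params or FailureParams()
    params.validate()
    if stride_length <= 0:
        raise ValueError("stride length must be positive")
    if strain < 0:
        raise ValueError("strain must be >= 0")
    if strain == 0:
        warnings.warn("zero strain: infinite life", stacklevel=2)
        return float("inf")
    cycles = params.power_law_coefficient * (
        params.weibull_coefficient * strain
    ) ** (-params.power_law_exponent)
    days = cycles * stride_length / params.daily_distance
    return days / DAYS_PER_YEAR


def failure_probability(t, v: float, t_fail: float, params: FailureParams | None = None):
    """P(t) = 1 - exp[-(V/V_ref) (t/t_fail)^(k/m)]; in [0, 1], nondecreasing."""
    params = params or FailureParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if v < 0:
        raise ValueError("stressed volume must be >= 0")
    if not t_fail > 0:
        raise ValueError("characteristic life must be positive")
    with np.errstate(divide="ignore"):
        p = -np.expm1(-(v / params.v_ref) * (t / t_fail) ** params.shape)
    return p if p.ndim else float(p)


def repair_probability(t, params: FailureParams | None = None):
    """P_rep(t) = 1 - exp[-(t/t_rep)^r]."""
    params = params or FailureParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    p = -np.expm1(-((t / params.t_rep) ** params.repair_exponent))
    return p if p.ndim else float(p)


def failure_pdf(t, v: float, t_fail: float, params: FailureParams | None = None):
    """Density of the no-repair failure law (1/years); derivative of the CDF.

    With the model constants the shape k/m exceeds 1, so the density vanishes
    at t = 0.
    """
    params = params or FailureParams()
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if not t_fail > 0:
        raise ValueError("characteristic life must be positive")
    a = params.shape
    scale = v / params.v_ref
    with np.errstate(invalid="ignore"):
        u = (t / t_fail) ** (a - 1.0)
    u = np.where(t == 0.0, 0.0 if a > 1 else np.inf, u)
    f = scale * (a / t_fail) * u * np.exp(-scale * u * (t / t_fail))
    return f if f.ndim else float(f)


def _with_repair_on_grid(
    times: np.ndarray, v: float, t_fail: float, params: FailureParams,
    refine: int = 8,
) -> np.ndarray:
    """Cumulative trapezoid of f(tau)(1 - P_rep(tau)) on the output grid.

    Quadrature runs on a ``refine``-times finer internal grid and is sampled
    back onto the output points; the first fine cell is integrated analytically
    because the density carries a weak t^(k/m - 1) singularity at zero.
    """
    if not np.isfinite(t_fail):
        return np.zeros_like(times)
    out = np.zeros_like(times)
    if times.size < 2:
        return out
    fine = np.linspace(times[0], times[-1], refine * (times.size - 1) + 1)
    dt = fine[1] - fine[0]
    integrand = failure_pdf(fine, v, t_fail, params) * (
        1.0 - repair_probability(fine, params)
    )
    cum = np.zeros_like(fine)
    cum[1] = failure_probability(fine[1], v, t_fail, params) * (
        1.0 - repair_probability(0.5 * fine[1], params)
    )
    if fine.size > 2:
        steps = 0.5 * dt * (integrand[1:-1] + integrand[2:])
        cum[2:] = cum[1] + np.cumsum(steps)
    out[:] = cum[::refine]
    # the continuum integral is bounded by the no-repair CDF (the integrand is
    # the failure density thinned by 1 - P_rep <= 1); trapezoid overshoot in
    # the convex tail is truncated against that exact bound
    out = np.minimum(out, failure_probability(times, v, t_fail, params))
    return np.minimum(out, 1.0)


def failure_with_repair(
    times: np.ndarray,
    v: float,
    t_fail: float,
    params: FailureParams | None = None,
    check_convergence: bool = True,
) -> np.ndarray:
    """Failure probability with repair on the given uniform time grid.

    When ``check_convergence`` is set, the endpoint is recomputed at half the
    step; a shift >= 1e-3 raises (insufficient resolution), and the halved-grid
    value is used only for the check, not returned.
    """
    params = params or FailureParams()
    params.validate()
    times = np.asarray(times, dtype=float)
    out = _with_repair_on_grid(times, v, t_fail, params)
    if check_convergence and times.size >= 2 and np.isfinite(t_fail):
        fine = np.linspace(times[0], times[-1], 2 * (times.size - 1) + 1)
        ref = _with_repair_on_grid(fine, v, t_fail, params)
        if abs(ref[-1] - out[-1]) >= 1e-3:
            raise RuntimeError(
                "repair quadrature not converged: endpoint shifts "
                f"{abs(ref[-1] - out[-1]):.2e} on halving dt"
            )
    return out


def failure_curve(
    v: float, t_fail: float, params: FailureParams | None = None
) -> FailureCurve:
    """Both probability series on the uniform 0..horizon grid."""
    params = params or FailureParams()
    params.validate()
    n = int(round(params.horizon / params.dt))
    times = np.linspace(0.0, params.horizon, n + 1)
    if np.isfinite(t_fail):
        p = failure_probability(times, v, t_fail, params)
        p_rep = failure_with_repair(times, v, t_fail, params)
    else:
        p = np.zeros_like(times)
        p_rep = np.zeros_like(times)
    return FailureCurve(times=times, p_fail=p, p_fail_repair=p_rep, t_fail=t_fail)


def participant_failure(profile, solution, params: FailureParams | None = None) -> FailureCurve:
    """Wire a participant's contact solution into the failure model.

    Uses the peak-force strain and stressed volume (held constant over the
    horizon) and the participant's stride length for the daily cycle count.
    """
    params = params or FailureParams()
    eps = solution.peak_strain
    if eps == 0:
        n = int(round(params.horizon / params.dt))
        times = np.linspace(0.0, params.horizon, n + 1)
        return FailureCurve(times, np.zeros_like(times), np.zeros_like(times),
                            float("inf"))
    t_fail = time_to_failure(eps, profile.stride_length, params)
    return failure_curve(solution.stressed_volume, t_fail, params)


def curve_frame(curve: FailureCurve):
    import pandas as pd

    return pd.DataFrame(
        {
            "time_years": curve.times,
            "p_fail": curve.p_fail,
            "p_fail_repair": curve.p_fail_repair,
        }
    )


def sensitivity_analysis(
    geometry,
    target_force: float,
    flexion_deg: float,
    parameter_ranges: dict[str, np.ndarray],
    force_range: np.ndarray | None = None,
):
    """One-at-a-time sweep of contact-model parameters; output is peak strain.

    Each parameter is swept over its range while all others stay at their
    modelled values. Numeric ``ContactGeometry`` fields and the dotted
    ``moduli.<region>`` keys are sweepable; ``target_force`` and ``flexion``
    may be swept via ``force_range`` / a ``"flexion"`` entry. Solver failures
    at extreme values are recorded as NaN rather than aborting the sweep.
    """
    import pandas as pd

    from .contact import build_element_grid, solve_contact

    rows = []

    def run(param: str, value: float) -> float:
        geo = replace(geometry)
        force, flex = target_force, flexion_deg
        if param == "target_force":
            force = value
        elif param == "flexion":
            flex = value
        elif param.startswith("moduli."):
            geo = replace(geometry, moduli=dict(geometry.moduli))
            geo.moduli[param.split(".", 1)[1]] = value
        else:
            if not hasattr(geo, param):
                raise ValueError(f"unknown sensitivity parameter {param!r}")
            geo = replace(geometry, **{param: value})
        try:
            sol = solve_contact(build_element_grid(geo), geo, force, flex)
            return sol.peak_strain
        except (RuntimeError, ValueError):
            return float("nan")

    ranges = dict(parameter_ranges)
    if force_range is not None:
        ranges["target_force"] = force_range
    for param, values in ranges.items():
        for value in np.asarray(values, dtype=float):
            rows.append(
                {"parameter": param, "value": float(value),
                 "peak_strain": run(param, float(value))}
            )
    return pd.DataFrame(rows)
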