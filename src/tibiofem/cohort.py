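"""Synthetic gait-cohort generation.

Replaces the motion-capture / musculoskeletal-simulation stage of the study
design with a statistical emulator: each participant receives anthropometrics,
spatiotemporal gait parameters, a peak medial tibiofemoral contact force and a
smooth stance-phase force waveform whose peak equals that force. Group-level
distribution parameters (means/SDs of mass, stature, velocity, stride length,
net peak force, vasti forces) are supplied through :class:`GroupSpec`; the
defaults in :mod:`tibiofem.config` carry the study's two groups
(healthy weight, BMI < 25 kg/m^2, and obese, BMI > 30 kg/m^2).

Sampling is truncated-normal per variable (only means and SDs are known).
With ``enforce_exact_means`` the sampled deviations are mean-centred so that
every sample mean equals its specified mean exactly, which is what makes the
downstream group contrasts reproduce printed mean differences to the digit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

G = 9.81  # m/s^2, body-weight normalization

_REJECTION_CAP = 100_000


@dataclass
class WaveformShape:
    """Two-bump stance-phase force profile (weight acceptance + push-off).

    The profile is a sum of two Gaussian bumps plus a broad mid-stance
    component whose amplitude is solved so the mid-stance trough sits at
    ``trough_ratio`` of the peak. The second bump is slightly smaller than the
    first so the waveform has a unique global maximum.
    """

    bump_times: tuple[float, float] = (25.0, 75.0)  # % stance
    bump_widths: tuple[float, float] = (10.0, 10.0)  # % stance
    bump_weights: tuple[float, float] = (1.0, 0.93)
    trough_ratio: float = 0.65  # trough value / peak value
    broad_width: float = 18.0  # % stance
    n_points: int = 101

    def validate(self) -> None:
        if not 0.0 < self.trough_ratio < 1.0:
            raise ValueError("trough_ratio must be in (0, 1)")
        if self.n_points < 3:
            raise ValueError("waveform needs at least 3 points")
        if any(w <= 0 for w in self.bump_widths) or self.broad_width <= 0:
            raise ValueError("waveform widths must be positive")


@dataclass
class ForceWaveform:
    """Stance-phase (0-100 %) medial compartment force series in newtons."""

    grid: np.ndarray  # % stance, uniform 0..100
    values: np.ndarray  # N

    @property
    def peak(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class GroupSpec:
    """Distribution parameters for one study group.

    Every ``*_mean``/``*_sd`` pair parameterizes a truncated normal (lower
    bound at zero). The net peak medial force is the sampled force variable;
    the normalized (BW) value is derived per participant so that
    ``peak_force_bw == peak_force_n / (mass * g)`` holds exactly.
    ``bmi_mean`` is optional; when present together with
    ``enforce_exact_means`` the sample-mean BMI is recentred onto it (see
    :func:`generate_cohort`).
    """

    label: str
    n: int
    mass_mean: float
    mass_sd: float
    stature_mean: float
    stature_sd: float
    velocity_mean: float
    velocity_sd: float
    stride_length_mean: float
    stride_length_sd: float
    peak_force_n_mean: float
    peak_force_n_sd: float
    vasti_bw_means: tuple[float, float, float] = (0.5, 0.45, 0.4)
    vasti_bw_sds: tuple[float, float, float] = (0.2, 0.18, 0.16)
    flexion_mean: float = 15.0  # deg; unconstrained by the study, config-exposed
    flexion_sd: float = 4.0
    bmi_mean: float | None = None
    bmi_bounds: tuple[float, float] = (10.0, 60.0)
    enforce_exact_means: bool = False
    waveform: WaveformShape = field(default_factory=WaveformShape)

    def validate(self) -> None:
        if self.label not in ("healthy_weight", "obese"):
            raise ValueError(f"unknown group label {self.label!r}")
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        lo, hi = self.bmi_bounds
        if not lo < hi:
            raise ValueError("bmi_bounds lower must be < upper")
        if self.label == "healthy_weight" and hi > 25.0:
            raise ValueError("healthy_weight BMI upper bound must be <= 25.0")
        if self.label == "obese" and lo < 30.0:
            raise ValueError("obese BMI lower bound must be >= 30.0")
        for name in (
            "mass_sd", "stature_sd", "velocity_sd", "stride_length_sd",
            "peak_force_n_sd", "flexion_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.vasti_bw_sds):
            raise ValueError("vasti SDs must be >= 0")
        if self.stature_mean <= 0:
            raise ValueError("stature must be positive")
        self.waveform.validate()


@dataclass
class ParticipantProfile:
    """One synthetic (or user-supplied) subject."""

    id: str
    group: str
    mass: float  # kg
    stature: float  # m
    velocity: float  # m/s
    stride_length: float  # m
    peak_force_n: float  # N
    flexion_at_peak: float  # deg
    vasti_peaks_bw: tuple[float, float, float]
    stance_waveform: ForceWaveform

    @property
    def bmi(self) -> float:
        return self.mass / self.stature**2

    @property
    def peak_force_bw(self) -> float:
        return self.peak_force_n / (self.mass * G)

    @property
    def vasti_peaks_n(self) -> tuple[float, float, float]:
        return tuple(v * self.mass * G for v in self.vasti_peaks_bw)


def synth_stance_waveform(
    peak_force: float,
    shape: WaveformShape | None = None,
) -> ForceWaveform:
    """Build a smooth two-bump stance waveform with ``max(values) == peak_force``.

    The shape is normalized to unit peak and then scaled, so the constraint
    holds exactly (bitwise) for any nonnegative peak force.
    """
    if peak_force < 0:
        raise ValueError("peak force must be >= 0")
    shape = shape or WaveformShape()
    shape.validate()
    t = np.linspace(0.0, 100.0, shape.n_points)
    profile = _unit_profile(t, shape)
    return ForceWaveform(grid=t, values=profile * peak_force)


def _unit_profile(t: np.ndarray, shape: WaveformShape) -> np.ndarray:
    (t1, t2), (s1, s2) = shape.bump_times, shape.bump_widths
    a1, a2 = shape.bump_weights
    bumps = a1 * np.exp(-0.5 * ((t - t1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((t - t2) / s2) ** 2
    )
    broad = np.exp(-0.5 * ((t - 50.0) / shape.broad_width) ** 2)

    from scipy.optimize import brentq

    def trough_err(a3: float) -> float:
        f = bumps + a3 * broad
        return f[t.size // 2] / f.max() - shape.trough_ratio

    # amplitude of the broad component solved so the mid-stance trough sits
    # at trough_ratio of the peak; trough_err is increasing in a3
    if trough_err(0.0) >= 0.0:
        a3 = 0.0
    else:
        a3 = brentq(trough_err, 0.0, 50.0, xtol=1e-12)
    f = bumps + a3 * broad
    return f / f.max()


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lower: float = 0.0
) -> np.ndarray:
    """Normal draws rejected below ``lower`` (means here are many SDs above 0)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RuntimeError("truncated-normal rejection failed; check mean/sd")


def _center(x: np.ndarray, mean: float) -> np.ndarray:
    return x - x.mean() + mean


def enforced_mean_samples(
    mean: float,
    sd: float,
    n: int,
    rng: np.random.Generator,
    lower: float | None = None,
) -> np.ndarray:
    """Normal draws whose sample mean equals ``mean`` exactly.

    The sampled deviations are mean-centred after drawing (and after the
    optional lower-bound rejection), the same exact-mean device used by
    :func:`generate_cohort`. Used wherever a printed group mean must be
    reproduced to the digit by a finite sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    x = (
        _truncated_normal(rng, mean, sd, n, lower)
        if lower is not None
        else mean + rng.normal(0.0, sd, n) if sd > 0 else np.full(n, mean)
    )
    return _center(x, mean)


def _fit_masses_to_bmi_constraints(
    mass: np.ndarray,
    stature: np.ndarray,
    mass_mean: float,
    bmi_mean: float,
    bounds: tuple[float, float],
    max_iter: int = 1000,
) -> np.ndarray:
    """Smallest adjustment of the sampled masses so that the sample means of
    both mass and BMI (= m/s^2) are exact while every BMI stays inside the
    group's eligibility bounds.

    Works in BMI space: alternating projections between the affine subspace of
    the two mean constraints (sum b_i = n*bmi_mean, sum b_i*s_i^2 =
    n*mass_mean) and the BMI box. Converges whenever the intersection is
    nonempty; the returned masses keep bmi == mass/stature^2 as an exact
    per-participant identity.
    """
    s2 = stature**2
    n = mass.size
    b = mass / s2
    lo, hi = bounds
    margin = 1e-9 * (hi - lo)
    targets = np.array([n * bmi_mean, n * mass_mean])
    gram = np.array([[n, s2.sum()], [s2.sum(), (s2**2).sum()]])
    for _ in range(max_iter):
        resid = np.array([b.sum(), (b * s2).sum()]) - targets
        lam = np.linalg.solve(gram, resid)
        b = b - (lam[0] + lam[1] * s2)
        if (b > lo + margin).all() and (b < hi - margin).all():
            return b * s2
        b = np.clip(b, lo + 2 * margin, hi - 2 * margin)
    raise RuntimeError(
        "exact-mean BMI constraints are infeasible for these bounds "
        f"(target {bmi_mean} in {bounds} with the sampled spread)"
    )


def generate_cohort(
    spec: GroupSpec, seed: int | np.random.SeedSequence
) -> list[ParticipantProfile]:
    """Sample ``spec.n`` participants; deterministic for a fixed seed.

    BMI is derived from sampled mass and stature (never sampled directly);
    pairs whose BMI falls outside ``spec.bmi_bounds`` are resampled, capped at
    100 000 draws. Under ``enforce_exact_means`` each variable's deviations
    are mean-centred after sampling, and when ``bmi_mean`` is given the masses
    are additionally recentred so the sample-mean BMI is exact as well.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.n
    lo, hi = spec.bmi_bounds

    mass = _truncated_normal(rng, spec.mass_mean, spec.mass_sd, n)
    stature = _truncated_normal(rng, spec.stature_mean, spec.stature_sd, n, 0.5)

    # eligibility screen: resample pairs whose BMI falls outside the bounds
    draws = n
    while True:
        bad = (mass / stature**2 <= lo) | (mass / stature**2 >= hi)
        if not bad.any():
            break
        k = int(bad.sum())
        draws += k
        if draws > _REJECTION_CAP:
            raise RuntimeError(
                f"BMI rejection cap exceeded for group {spec.label!r}: "
                "bounds are likely infeasible for the given mean/SD"
            )
        mass[bad] = _truncated_normal(rng, spec.mass_mean, spec.mass_sd, k)
        stature[bad] = _truncated_normal(rng, spec.stature_mean, spec.stature_sd, k, 0.5)

    if spec.enforce_exact_means and n > 1:
        stature = _center(stature, spec.stature_mean)
        mass = _center(mass, spec.mass_mean)
        if spec.bmi_mean is not None:
            mass = _fit_masses_to_bmi_constraints(
                mass, stature, spec.mass_mean, spec.bmi_mean, spec.bmi_bounds
            )
        elif ((mass / stature**2 <= lo) | (mass / stature**2 >= hi)).any():
            # centring nudged a screened pair across a bound; pull the BMIs
            # back inside while keeping the mass mean exact
            mass = _fit_masses_to_bmi_constraints(
                mass, stature, spec.mass_mean,
                float((mass / stature**2).mean()), spec.bmi_bounds,
            )
    elif spec.enforce_exact_means:
        mass = np.full(n, spec.mass_mean)
        stature = np.full(n, spec.stature_mean)

    velocity = _truncated_normal(rng, spec.velocity_mean, spec.velocity_sd, n)
    stride = _truncated_normal(rng, spec.stride_length_mean, spec.stride_length_sd, n)
    force = _truncated_normal(rng, spec.peak_force_n_mean, spec.peak_force_n_sd, n)
    flexion = _truncated_normal(rng, spec.flexion_mean, spec.flexion_sd, n, -1e-9)
    vasti = [
        _truncated_normal(rng, m_, s_, n)
        for m_, s_ in zip(spec.vasti_bw_means, spec.vasti_bw_sds)
    ]
    if spec.enforce_exact_means:
        velocity = _center(velocity, spec.velocity_mean)
        stride = _center(stride, spec.stride_length_mean)
        force = _center(force, spec.peak_force_n_mean)
        flexion = _center(flexion, spec.flexion_mean)
        vasti = [_center(v, m_) for v, m_ in zip(vasti, spec.vasti_bw_means)]

    profiles = []
    for i in range(n):
        profiles.append(
            ParticipantProfile(
                id=f"{spec.label}_{i + 1:03d}",
                group=spec.label,
                mass=float(mass[i]),
                stature=float(stature[i]),
                velocity=float(velocity[i]),
                stride_length=float(stride[i]),
                peak_force_n=float(force[i]),
                flexion_at_peak=float(flexion[i]),
                vasti_peaks_bw=tuple(float(v[i]) for v in vasti),
                stance_waveform=synth_stance_waveform(float(force[i]), spec.waveform),
            )
        )
    return profiles


def cohort_frame(profiles: list[ParticipantProfile]):
    """Cohort as a tidy one-row-per-participant DataFrame."""
    import pandas as pd

    rows = []
    for p in profiles:
        vi, vl, vm = p.vasti_peaks_bw
        ni, nl, nm = p.vasti_peaks_n
        rows.append(
            {
                "id": p.id,
                "group": p.group,
                "mass_kg": p.mass,
                "stature_m": p.stature,
                "bmi": p.bmi,
                "velocity_m_s": p.velocity,
                "stride_length_m": p.stride_length,
                "peak_force_bw": p.peak_force_bw,
                "peak_force_n": p.peak_force_n,
                "flexion_deg": p.flexion_at_peak,
                "vastus_intermedius_bw": vi,
                "vastus_lateralis_bw": vl,
                "vastus_medialis_bw": vm,
                "vastus_intermedius_n": ni,
                "vastus_lateralis_n": nl,
                "vastus_medialis_n": nm,
            }
        )
    return pd.DataFrame(rows)


def waveform_frame(profiles: list[ParticipantProfile]):
    """All stance waveforms in long format (id, pct_stance, force_n)."""
    import pandas as pd

    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "id": p.id,
                    "pct_stance": p.stance_waveform.grid,
                    "force_n": p.stance_waveform.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
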