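"""Elastic-foundation contact model of the medial tibiofemoral compartment.

Cartilage is a bed of independent compressive columns on the tibial plateau.
The femoral condyle is two sagittal arcs (anterior 35.0 mm, posterior 18.9 mm;
the arc in contact is selected by the knee flexion angle) and a single frontal
arc; the tibial plateau is concave in the frontal plane (21.0 mm) and flat
sagittally. Each column of unloaded height h = 5.0 mm carries

    eps   = compression / h                      (engineering strain)
    sigma = -E_eff * ln(1 - eps)                 (nonlinear elastic law)

where E_eff combines the femoral, tibial (meniscus-covered or uncovered) and
meniscal moduli of the element's column. The axial height of the flexion axis
is lowered (penetration) until the summed element forces match the prescribed
peak joint force — a bracketing + bisection solve, since total force is
strictly increasing in penetration.

By default the moduli are converted to confined-compression (aggregate) form,
E * (1-nu) / ((1+nu)(1-2*nu)) with nu = 0.45, appropriate for laterally
confined foundation columns; the flag ``confined_modulus_correction`` turns
this off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactGeometry",
    "ElementGrid",
    "ContactSolution",
    "build_element_grid",
    "effective_modulus",
    "element_strain",
    "stress_from_strain",
    "solve_contact",
]


@dataclass
class ContactGeometry:
    """Geometry, moduli and solver configuration of the contact model.

    The frontal femoral radius is not a measured quantity of the study; the
    default (21.0 mm, congruent with the tibial frontal arc as in the
    foundation model this geometry follows) is a modelling choice and is
    config-exposed.
    """

    r_fem_ant_sag: float = 35.0  # mm
    r_fem_post_sag: float = 18.9  # mm
    r_tib_front: float = 21.0  # mm (concave)
    r_fem_front: float = 21.0  # mm (convex; <= r_tib_front)
    cartilage_height: float = 5.0  # mm unloaded
    poisson: float = 0.45
    moduli: dict = field(
        default_factory=lambda: {
            "femoral": 8.6,
            "tibial_uncovered": 4.0,
            "tibial_covered": 10.1,
            "meniscus": 1.3,
        }
    )  # MPa
    meniscus_coverage: float = 0.46
    element_spacing: float = 0.5  # mm
    footprint: tuple[float, float] = (32.5, 55.0)  # (frontal width, sagittal depth) mm
    tangency_angle_deg: float = 25.0  # flexion at which the posterior arc takes over
    modulus_rule: str = "series"  # or "arithmetic"
    confined_modulus_correction: bool = True
    strain_cap: float = 0.95
    volume_mode: str = "strain_integrated"  # or "full_column"
    volume_strain_threshold: float = 0.0  # for full_column mode
    max_iterations: int = 200

    def validate(self) -> None:
        for name in ("r_fem_ant_sag", "r_fem_post_sag", "r_tib_front", "r_fem_front"):
            r = getattr(self, name)
            if not (r > 0 or np.isinf(r)):
                raise ValueError(f"{name} must be positive")
        if self.cartilage_height <= 0:
            raise ValueError("cartilage height must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if not 0 < self.meniscus_coverage < 1:
            raise ValueError("meniscus coverage must be in (0, 1)")
        if self.element_spacing <= 0:
            raise ValueError("element spacing must be positive")
        if min(self.footprint) < self.element_spacing:
            raise ValueError("footprint smaller than one element spacing")
        if self.modulus_rule not in ("series", "arithmetic"):
            raise ValueError(f"unknown modulus rule {self.modulus_rule!r}")
        if self.volume_mode not in ("strain_integrated", "full_column"):
            raise ValueError(f"unknown volume mode {self.volume_mode!r}")
        if not 0 < self.strain_cap < 1:
            raise ValueError("strain cap must be in (0, 1)")
        if not (np.isinf(self.r_fem_front) or np.isinf(self.r_tib_front)) and (
            self.r_fem_front > self.r_tib_front
        ):
            raise ValueError(
                "frontal femoral radius must not exceed the concave tibial radius"
            )

    @property
    def confinement_factor(self) -> float:
        nu = self.poisson
        if not self.confined_modulus_correction:
            return 1.0
        return (1 - nu) / ((1 + nu) * (1 - 2 * nu))

    def sagittal_radius(self, flexion_deg: float) -> float:
        """Anterior arc below the tangency angle, posterior arc above it."""
        if flexion_deg <= self.tangency_angle_deg:
            return self.r_fem_ant_sag
        return self.r_fem_post_sag


@dataclass
class ElementGrid:
    """Uniform element grid over the plateau footprint (inclusive endpoints)."""

    x: np.ndarray  # frontal coordinates, mm, per element
    y: np.ndarray  # sagittal coordinates, mm, per element
    covered: np.ndarray  # bool, meniscus-covered
    element_area: float  # mm^2

    @property
    def count(self) -> int:
        return self.x.size

    @property
    def covered_fraction(self) -> float:
        return float(self.covered.mean())


@dataclass
class ContactSolution:
    penetration: float  # mm
    strain_field: np.ndarray
    stress_field: np.ndarray  # MPa
    peak_stress: float  # MPa
    peak_strain: float
    contact_area: float  # mm^2
    stressed_volume: float  # mm^3
    matched_force: float  # N
    target_force: float  # N
    iterations: int


def build_element_grid(geometry: ContactGeometry) -> ElementGrid:
    """Inclusive-endpoint grid; meniscus-covered elements form a peripheral
    band holding ``meniscus_coverage`` of the elements (rounded to the nearest
    element, partial outer ring filled in a fixed deterministic order)."""
    geometry.validate()
    sp = geometry.element_spacing
    wx, wy = geometry.footprint
    nx = int(round(wx / sp)) + 1
    ny = int(round(wy / sp)) + 1
    xs = (np.arange(nx) - (nx - 1) / 2) * sp
    ys = (np.arange(ny) - (ny - 1) / 2) * sp
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ring = np.minimum(np.minimum(I, nx - 1 - I), np.minimum(J, ny - 1 - J))
    k = int(round(geometry.meniscus_coverage * X.size))
    order = np.lexsort((J.ravel(), I.ravel(), ring.ravel()))
    covered = np.zeros(X.size, dtype=bool)
    covered[order[:k]] = True
    return ElementGrid(
        x=X.ravel(), y=Y.ravel(), covered=covered, element_area=sp * sp
    )


def effective_modulus(region: str, geometry: ContactGeometry) -> float:
    """Per-element modulus of the column under the documented composition rule.

    ``series`` (default): reciprocal of the mean compliance of the stacked
    tissues (femoral + tibial for uncovered columns; femoral + covered tibial
    + meniscus for covered ones). ``arithmetic``: plain mean of the moduli.
    The confined-compression factor is *not* applied here; the solver applies
    it uniformly.
    """
    m = geometry.moduli
    if region == "uncovered":
        stack = (m["femoral"], m["tibial_uncovered"])
    elif region == "covered":
        stack = (m["femoral"], m["tibial_covered"], m["meniscus"])
    else:
        raise ValueError(f"unknown region {region!r}")
    if geometry.modulus_rule == "arithmetic":
        return float(np.mean(stack))
    if any(e == 0 for e in stack):
        return 0.0
    return float(len(stack) / sum(1.0 / e for e in stack))


def element_strain(compression, geometry: ContactGeometry):
    """Engineering strain of a column: compression / unloaded height, capped."""
    comp = np.asarray(compression, dtype=float)
    if np.any(comp < 0):
        raise ValueError("compression must be >= 0")
    eps = np.minimum(comp / geometry.cartilage_height, geometry.strain_cap)
    return eps if eps.ndim else float(eps)


def stress_from_strain(strain, modulus: float):
    """sigma = -E * ln(1 - eps); natural log, strictly increasing and convex."""
    eps = np.asarray(strain, dtype=float)
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    if np.any(eps < 0):
        raise ValueError("strain must be >= 0")
    if np.any(eps >= 1):
        raise ValueError("strain must be < 1 (log singularity)")
    sig = -modulus * np.log1p(-eps)
    return sig if sig.ndim else float(sig)


def _gap_field(grid: ElementGrid, geometry: ContactGeometry, flexion_deg: float):
    """Unloaded femur-tibia surface separation per element (mm).

    Additive composition of the sagittal femoral arc profile and the frontal
    femoral-minus-tibial arc relief; elements beyond an arc's reach get an
    effectively infinite gap.
    """
    far = 1e12

    def convex(r: float, c: np.ndarray) -> np.ndarray:
        if np.isinf(r):
            return np.zeros_like(c)
        out = np.full_like(c, far)
        inside = np.abs(c) < r
        out[inside] = r - np.sqrt(r * r - c[inside] ** 2)
        return out

    g_sag = convex(geometry.sagittal_radius(flexion_deg), grid.y)
    g_front = convex(geometry.r_fem_front, grid.x) - convex(
        geometry.r_tib_front, grid.x
    )
    return np.minimum(g_sag + np.maximum(g_front, 0.0), far)


def solve_contact(
    grid: ElementGrid,
    geometry: ContactGeometry,
    target_force: float,
    flexion_deg: float = 0.0,
    tolerance: float | None = None,
) -> ContactSolution:
    """Lower the flexion axis until the summed element forces match the target.

    Total force is strictly increasing in penetration, so the root is found by
    geometric bracket growth followed by bisection. Raises on saturation (the
    target exceeds the force available at the strain cap) or non-convergence.
    """
    geometry.validate()
    if target_force < 0:
        raise ValueError("target force must be >= 0")
    h = geometry.cartilage_height
    factor = geometry.confinement_factor
    e_field = np.where(
        grid.covered,
        effective_modulus("covered", geometry),
        effective_modulus("uncovered", geometry),
    ) * factor
    gap = _gap_field(grid, geometry, flexion_deg)
    area = grid.element_area
    tol = tolerance if tolerance is not None else max(0.5, 1e-4 * target_force)

    def fields(pen: float):
        eps = np.minimum(np.maximum(pen - gap, 0.0) / h, geometry.strain_cap)
        sig = -e_field * np.log1p(-eps)
        return eps, sig, float((sig * area).sum())

    if target_force == 0.0:
        eps, sig, f = fields(0.0)
        return _solution(grid, geometry, 0.0, eps, sig, f, target_force, 0)

    # saturation: supremum of the force with every reachable element at the cap
    reachable = gap < 1e9
    f_sat = float(
        (-e_field[reachable] * np.log1p(-geometry.strain_cap) * area).sum()
    )
    if target_force > f_sat - tol:
        raise RuntimeError(
            f"saturation: target {target_force:.1f} N exceeds the "
            f"{f_sat:.1f} N available at the strain cap"
        )
    # bracket
    iters = 0
    hi = 0.25 * h
    pen_max = float(gap[reachable].max()) + geometry.strain_cap * h
    _, _, f_hi = fields(hi)
    while f_hi < target_force:
        iters += 1
        hi = min(hi * 1.6, pen_max)
        _, _, f_hi = fields(hi)
        if iters > geometry.max_iterations:
            raise RuntimeError("bracketing failed to enclose the target force")
    lo = 0.0
    for _ in range(geometry.max_iterations):
        iters += 1
        mid = 0.5 * (lo + hi)
        eps, sig, f = fields(mid)
        if abs(f - target_force) <= tol:
            return _solution(grid, geometry, mid, eps, sig, f, target_force, iters)
        if f < target_force:
            lo = mid
        else:
            hi = mid
    # interval collapsed to float precision: accept if within tolerance
    eps, sig, f = fields(hi)
    if abs(f - target_force) <= tol:
        return _solution(grid, geometry, hi, eps, sig, f, target_force, iters)
    raise RuntimeError(
        f"contact solve did not converge: |{f:.3f} - {target_force:.3f}| > {tol:g}"
    )


def _solution(grid, geometry, pen, eps, sig, force, target, iters) -> ContactSolution:
    area = grid.element_area
    h = geometry.cartilage_height
    loaded = eps > 0
    if geometry.volume_mode == "full_column":
        thr = geometry.volume_strain_threshold
        volume = float((eps > thr).sum()) * area * h
    else:
        volume = float((eps * area * h).sum())
    return ContactSolution(
        penetration=float(pen),
        strain_field=eps,
        stress_field=sig,
        peak_stress=float(sig.max()) if sig.size else 0.0,
        peak_strain=float(eps.max()) if eps.size else 0.0,
        contact_area=float(loaded.sum()) * area,
        stressed_volume=volume,
        matched_force=force,
        target_force=float(target),
        iterations=iters,
    )


def single_element_grid(area: float = 0.25) -> ElementGrid:
    """Degenerate flat one-element grid (for closed-form verification)."""
    return ElementGrid(
        x=np.zeros(1), y=np.zeros(1), covered=np.zeros(1, bool),
        element_area=float(area),
    )


def flat_geometry(modulus: float, **kwargs) -> ContactGeometry:
    """Flat-surface geometry with one uniform modulus and no confinement
    correction; pairs with :func:`single_element_grid` for analytic checks."""
    geo = ContactGeometry(
        r_fem_ant_sag=np.inf,
        r_fem_post_sag=np.inf,
        r_tib_front=np.inf,
        r_fem_front=np.inf,
        moduli={
            "femoral": modulus,
            "tibial_uncovered": modulus,
            "tibial_covered": modulus,
            "meniscus": modulus,
        },
        confined_modulus_correction=False,
    )
    return replace(geo, **kwargs) if kwargs else geo


def solution_summary(sol: ContactSolution) -> dict:
    return {
        "peak_stress_mpa": sol.peak_stress,
        "peak_strain": sol.peak_strain,
        "contact_area_mm2": sol.contact_area,
        "stressed_volume_mm3": sol.stressed_volume,
        "penetration_mm": sol.penetration,
        "matched_force_n": sol.matched_force,
    }


def field_frame(grid: ElementGrid, sol: ContactSolution):
    """Per-element fields in long format for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_mm": grid.x,
            "y_mm": grid.y,
            "region": np.where(grid.covered, "covered", "uncovered"),
            "strain": sol.strain_field,
            "stress_mpa": sol.stress_field,
        }
    )
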