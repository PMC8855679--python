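"""Condition selection on a fitted surface via worst-case error propagation.

Pipetting errors in the reagent volumes propagate into the absorbance
through the fitted surface R(x).  To first order the worst case — all
errors adding, none cancelling — gives the relative-error objective

    |ΔR/R| ≈ |1/R| · Σ_i |(∂R/∂x_i) · Δx_i|,

with analytic partials of the polynomial surface and coded perturbation
magnitudes Δx_i (default 0.05 coded units, i.e. ~1% of a 50 µl volume
on a typical coding).  Two searches are provided: maximize the
predicted signal over a coded box, and minimize the worst-case relative
error subject to protocol constraints (minimum total reaction volume,
factors pinned to fixed coded levels).  Both are seeded multi-start
local searches; quadratic surfaces have few basins, so a modest number
of starts suffices and results are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sciopt

from .doe import FactorSpec, axial_distance
from .rsm import RSMFit, build_design_matrix

__all__ = [
    "PerturbationSpec",
    "ConditionResult",
    "surface_gradient",
    "worst_case_relative_error",
    "find_max_response",
    "find_precise_condition",
]

N_STARTS = 32  # multi-start count for the seeded local searches


class InfeasibleConstraintsError(ValueError):
    """The requested constraints admit no point in the search box."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-factor coded perturbation magnitudes for error propagation."""

    deltas: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.deltas):
            raise ValueError("perturbation deltas must be >= 0")

    @classmethod
    def uniform(cls, k: int, delta: float = 0.05) -> "PerturbationSpec":
        return cls(tuple(float(delta) for _ in range(k)))


@dataclass
class ConditionResult:
    """A selected assay condition with its objective and active constraints."""

    coded_point: np.ndarray
    predicted_response: float
    objective_value: float
    constraints_active: list[str] = field(default_factory=list)


def surface_gradient(fit: RSMFit, coded_point) -> np.ndarray:
    """Analytic gradient of the fitted polynomial surface at a coded point."""
    x = np.asarray(coded_point, dtype=float)
    k = fit.terms.k
    grad = np.zeros(k)
    for beta, term in zip(fit.beta, fit.terms):
        for i, e in enumerate(term):
            if e == 0:
                continue
            d = float(e) * x[i] ** (e - 1)
            for j, ej in enumerate(term):
                if j != i and ej > 0:
                    d *= x[j] ** ej
            grad[i] += beta * d
    return grad


def _response(fit: RSMFit, x: np.ndarray) -> float:
    return float(build_design_matrix(np.asarray(x, float), fit.terms)[0] @ fit.beta)


def worst_case_relative_error(
    fit: RSMFit, coded_point, perturbation: PerturbationSpec
) -> float:
    """First-order worst-case relative absorbance error at a condition.

    Returns ``|1/R| * sum_i |dR/dx_i * delta_i|`` with analytic partials
    of the quadratic form.  Scale-invariant in R, monotone in each
    delta, and zero at stationary points of the surface.
    """
    r = _response(fit, coded_point)
    if r == 0.0:
        raise ZeroDivisionError(
            "relative error undefined: fitted response is 0 at this point"
        )
    grad = surface_gradient(fit, coded_point)
    deltas = np.asarray(perturbation.deltas, dtype=float)
    return float(np.sum(np.abs(grad * deltas)) / abs(r))


def _starts(bounds: np.ndarray, seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    pts = rng.uniform(lo, hi, size=(n, len(lo)))
    pts[0] = (lo + hi) / 2.0  # always try the box center
    return pts


def _default_bounds(k: int) -> np.ndarray:
    a = axial_distance(k)
    return np.array([[-a, a]] * k)


def find_max_response(
    fit: RSMFit, bounds=None, seed: int = 0
) -> ConditionResult:
    """Maximize the predicted response over a coded box.

    Seeded multi-start L-BFGS-B; for a concave quadratic part the
    interior stationary point is found, otherwise the maximizer sits on
    the box boundary (on this assay's surface, near the extremes of all
    three volumes).
    """
    bounds = _default_bounds(fit.terms.k) if bounds is None else np.asarray(bounds, float)
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise InfeasibleConstraintsError("empty bounds box")
    best_x, best_val = None, -np.inf
    for x0 in _starts(bounds, seed, N_STARTS):
        res = sciopt.minimize(
            lambda x: -_response(fit, x),
            x0,
            jac=lambda x: -surface_gradient(fit, x),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if -res.fun > best_val + 1e-12:
            best_val, best_x = -res.fun, res.x
    active = [
        f"x{i + 1}={'lower' if near_lo else 'upper'}"
        for i, (near_lo, near_hi) in enumerate(
            zip(
                np.isclose(best_x, bounds[:, 0], atol=1e-6),
                np.isclose(best_x, bounds[:, 1], atol=1e-6),
            )
        )
        if near_lo or near_hi
    ]
    return ConditionResult(
        coded_point=best_x,
        predicted_response=best_val,
        objective_value=best_val,
        constraints_active=active,
    )


def find_precise_condition(
    fit: RSMFit,
    perturbation: PerturbationSpec,
    min_total_volume: float | None = None,
    factors: list[FactorSpec] | None = None,
    fixed: dict[int, float] | None = None,
    sample_volume: float = 0.0,
    bounds=None,
    seed: int = 0,
) -> ConditionResult:
    """Minimize worst-case relative error subject to protocol constraints.

    Constraints supported: coded factors pinned to fixed values
    (``fixed`` maps factor index to coded level, e.g. water at -1.682 =
    0 µl), and a minimum total reaction volume, which needs the coding
    map (``factors``) to express sum of decoded volumes (plus any fixed
    ``sample_volume``) >= ``min_total_volume``.  Seeded multi-start
    SLSQP; ties within tolerance break toward the lower response-
    gradient norm.
    """
    k = fit.terms.k
    fixed = dict(fixed or {})
    bounds = _default_bounds(k) if bounds is None else np.asarray(bounds, float)
    free = [i for i in range(k) if i not in fixed]
    deltas = np.asarray(perturbation.deltas, float)
    degenerate = bool(np.all(deltas == 0))
    if degenerate:
        warnings.warn(
            "all perturbation deltas are zero: objective is identically 0; "
            "returning the feasible point with the smallest response gradient",
            UserWarning,
            stacklevel=2,
        )

    def embed(xf: np.ndarray) -> np.ndarray:
        x = np.empty(k)
        for i, v in fixed.items():
            x[i] = v
        x[free] = xf
        return x

    def objective(xf: np.ndarray) -> float:
        x = embed(xf)
        if degenerate:
            return float(np.linalg.norm(surface_gradient(fit, x)))
        return worst_case_relative_error(fit, x, perturbation)

    constraints = []
    if min_total_volume is not None:
        if factors is None:
            raise ValueError(
                "min_total_volume constraint needs the factor coding map"
            )

        def total_volume(xf: np.ndarray) -> float:
            x = embed(xf)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vols = [f.decode(xi) for f, xi in zip(factors, x)]
            return float(sum(vols)) + sample_volume - min_total_volume

        constraints.append({"type": "ineq", "fun": total_volume})

    fbounds = bounds[free]
    if len(free) == 0:
        x = embed(np.empty(0))
        for c in constraints:
            if c["fun"](np.empty(0)) < -1e-9:
                raise InfeasibleConstraintsError("fixed point violates constraints")
        obj = 0.0 if degenerate else worst_case_relative_error(fit, x, perturbation)
        return ConditionResult(
            coded_point=x,
            predicted_response=_response(fit, x),
            objective_value=obj,
            constraints_active=[f"x{i + 1}=fixed" for i in fixed],
        )

    best = None  # (objective, grad_norm, x_free)
    for x0 in _starts(fbounds, seed, N_STARTS):
        res = sciopt.minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=fbounds,
            constraints=constraints,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if not res.success and not np.isfinite(res.fun):
            continue
        feasible = all(c["fun"](res.x) >= -1e-7 for c in constraints)
        if not feasible:
            continue
        gnorm = float(np.linalg.norm(surface_gradient(fit, embed(res.x))))
        cand = (float(res.fun), gnorm, res.x)
        if best is None or cand[0] < best[0] - 1e-10 or (
            abs(cand[0] - best[0]) <= 1e-10 and cand[1] < best[1]
        ):
            best = cand
    if best is None:
        raise InfeasibleConstraintsError(
            "no feasible point found under the given constraints"
        )
    x = embed(best[2])
    active = [f"x{i + 1}=fixed" for i in fixed]
    for j, i in enumerate(free):
        if np.isclose(best[2][j], fbounds[j, 0], atol=1e-6):
            active.append(f"x{i + 1}=lower")
        elif np.isclose(best[2][j], fbounds[j, 1], atol=1e-6):
            active.append(f"x{i + 1}=upper")
    if constraints and abs(constraints[0]["fun"](best[2])) < 1e-6:
        active.append("total_volume=min")
    obj = 0.0 if degenerate else best[0]
    return ConditionResult(
        coded_point=x,
        predicted_response=_response(fit, x),
        objective_value=obj,
        constraints_active=active,
    )
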