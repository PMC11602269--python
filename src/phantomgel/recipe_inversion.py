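"""Invert mixing models: from target relaxation times to gel compositions.

Given target ``(T1, T2)`` at one field, a recipe is a nonnegative composition
``(G, N)`` solving the two rate equations ``R1(G, N) = 1/T1`` and
``R2(G, N) = 1/T2`` within configured concentration bounds.  The system is
solved numerically by a multi-start Newton-type iteration seeded from a
coarse grid; when several in-bounds roots exist the one with minimal salt
concentration is returned (ties broken by minimal agarose) and flagged.

Targets with no joint solution fall back down a ladder: match T1 alone, then
T2 alone, then — when the target relaxes more slowly than pure water, so no
doped gel can reach it — recommend plain water; otherwise the target is
infeasible within the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import brentq, root
from scipy.spatial import Delaunay

from .mixing_model import (
    ConcentrationPair,
    MixingModel,
    evaluate_rate,
    evaluate_rate_grid,
    default_limits,
    predict_times,
)

__all__ = [
    "TargetSpec",
    "Recipe",
    "ConcentrationLimits",
    "solve_recipe",
    "solve_single_target",
    "feasible_region",
    "FeasibleRegion",
]

#: Relative tolerance on rates for accepting a root.
RATE_RTOL = 1e-8


@dataclass(frozen=True)
class TargetSpec:
    """Target relaxation times (seconds) at a field strength."""

    t1_s: float | None = None
    t2_s: float | None = None
    field_T: float = 0.064
    label: str = ""

    def __post_init__(self) -> None:
        if self.t1_s is None and self.t2_s is None:
            raise ValueError("target must specify at least one of t1_s, t2_s")
        for name, v in (("t1_s", self.t1_s), ("t2_s", self.t2_s)):
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class ConcentrationLimits:
    """Inversion search box: agarose in [0, agarose_max], salt in [0, salt_max]."""

    agarose_max: float = 4.0
    salt_max: float = 25.0

    def __post_init__(self) -> None:
        if self.agarose_max < 0 or self.salt_max < 0:
            raise ValueError("limits must be nonnegative")

    @classmethod
    def for_salt(cls, salt: str) -> "ConcentrationLimits":
        cfg = default_limits()
        return cls(agarose_max=cfg["agarose_max"], salt_max=cfg["salt_max"][salt])


@dataclass(frozen=True)
class Recipe:
    """An inversion result: composition, status, and forward-model predictions."""

    conc: ConcentrationPair | None
    status: str  # exact | t1_only | t2_only | water_fallback | infeasible
    predicted_t1_s: float | None
    predicted_t2_s: float | None
    model_key: tuple[str, float]
    multiple_roots: bool = False
    label: str = ""


def _rates(model: MixingModel, G, N):
    return (evaluate_rate_grid(model.t1_coeffs, G, N),
            evaluate_rate_grid(model.t2_coeffs, G, N))


def _check_model(model: MixingModel) -> None:
    if all(c == 0 for c in model.t1_coeffs) or all(c == 0 for c in model.t2_coeffs):
        raise ValueError("degenerate mixing model: an all-zero rate surface cannot be inverted")


def _recipe(model, conc, status, multiple=False, label=""):
    t1 = t2 = None
    if conc is not None:
        t1, t2 = predict_times(model, conc)
    return Recipe(conc=conc, status=status, predicted_t1_s=t1, predicted_t2_s=t2,
                  model_key=model.key, multiple_roots=multiple, label=label)


def _find_roots(model: MixingModel, r1: float, r2: float,
                limits: ConcentrationLimits, n_grid: int = 21) -> list[tuple[float, float]]:
    """All distinct nonnegative in-bounds roots of the 2x2 rate system."""
    gmax, nmax = limits.agarose_max, limits.salt_max
    c1 = np.asarray(list(model.t1_coeffs))
    c2 = np.asarray(list(model.t2_coeffs))

    def fun(x):
        G, N = x
        terms = np.array([1.0, G, G * G, N, N * N, G * N, G * G * N, G * N * N, G * G * N * N])
        return [terms @ c1 - r1, terms @ c2 - r2]

    def jac(x):
        G, N = x
        dG = np.array([0.0, 1.0, 2 * G, 0.0, 0.0, N, 2 * G * N, N * N, 2 * G * N * N])
        dN = np.array([0.0, 0.0, 0.0, 1.0, 2 * N, G, G * G, 2 * G * N, 2 * G * N * N])
        return np.array([[dG @ c1, dN @ c1], [dG @ c2, dN @ c2]])

    Gs = np.linspace(0.0, gmax, n_grid) if gmax > 0 else np.array([0.0])
    Ns = np.linspace(0.0, nmax, n_grid) if nmax > 0 else np.array([0.0])
    GG, NN = np.meshgrid(Gs, Ns)
    R1, R2 = _rates(model, GG, NN)
    resid = ((R1 - r1) / max(r1, 1e-30))**2 + ((R2 - r2) / max(r2, 1e-30))**2

    # start Newton from every local minimum of the coarse residual surface
    # (one per root basin), plus the globally best grid points
    padded = np.pad(resid, 1, constant_values=np.inf)
    local_min = np.ones_like(resid, dtype=bool)
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        local_min &= resid <= padded[1 + dr:1 + dr + resid.shape[0],
                                     1 + dc:1 + dc + resid.shape[1]]
    starts = set(map(int, np.flatnonzero(local_min.ravel())))
    starts.update(map(int, np.argsort(resid.ravel())[:8]))

    roots: list[tuple[float, float]] = []
    slack_g = max(gmax, 1.0)
    slack_n = max(nmax, 1.0)
    for idx in sorted(starts, key=lambda i: resid.ravel()[i]):
        x0 = np.array([GG.ravel()[idx], NN.ravel()[idx]])
        sol = root(fun, x0, jac=jac, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        G, N = sol.x
        # snap tiny negatives from the unconstrained iteration back to zero
        if -1e-9 * slack_g < G < 0:
            G = 0.0
        if -1e-9 * slack_n < N < 0:
            N = 0.0
        if not (0 <= G <= gmax * (1 + 1e-9) and 0 <= N <= nmax * (1 + 1e-9)):
            continue
        G, N = min(G, gmax), min(N, nmax)
        f1, f2 = fun((G, N))
        if abs(f1) > RATE_RTOL * r1 or abs(f2) > RATE_RTOL * r2:
            continue
        if any(abs(G - g0) <= 1e-7 * slack_g and abs(N - n0) <= 1e-7 * slack_n
               for g0, n0 in roots):
            continue
        roots.append((G, N))
    roots.sort(key=lambda gn: (gn[1], gn[0]))
    return roots


def solve_recipe(model: MixingModel, target: TargetSpec,
                 limits: ConcentrationLimits | None = None) -> Recipe:
    """Composition matching both target times, with the fallback ladder.

    The ladder on failure: match T1 alone, then T2 alone, then plain water
    when the target out-relaxes water (both target rates at or below the
    intercepts), else infeasible.
    """
    _check_model(model)
    if target.t1_s is None or target.t2_s is None:
        which = "T1" if target.t1_s is not None else "T2"
        time_s = target.t1_s if target.t1_s is not None else target.t2_s
        return solve_single_target(model, which, time_s, limits=limits, label=target.label)
    if limits is None:
        limits = ConcentrationLimits.for_salt(model.salt)

    r1, r2 = 1.0 / target.t1_s, 1.0 / target.t2_s
    roots = _find_roots(model, r1, r2, limits)
    if roots:
        G, N = roots[0]
        return _recipe(model, ConcentrationPair(G, N), "exact",
                       multiple=len(roots) > 1, label=target.label)

    for which, time_s, status in (("T1", target.t1_s, "t1_only"),
                                  ("T2", target.t2_s, "t2_only")):
        single = solve_single_target(model, which, time_s, limits=limits, label=target.label)
        if single.status != "infeasible":
            return Recipe(conc=single.conc, status=status,
                          predicted_t1_s=single.predicted_t1_s,
                          predicted_t2_s=single.predicted_t2_s,
                          model_key=model.key, label=target.label)

    a1 = model.t1_coeffs[0]
    b1 = model.t2_coeffs[0]
    if r1 <= a1 * (1 + RATE_RTOL) and r2 <= b1 * (1 + RATE_RTOL):
        return _recipe(model, ConcentrationPair(0.0, 0.0), "water_fallback", label=target.label)
    return Recipe(conc=None, status="infeasible", predicted_t1_s=None,
                  predicted_t2_s=None, model_key=model.key, label=target.label)


def _quadratic_root(c_lin: float, c_quad: float, c0: float, rate: float,
                    upper: float) -> float | None:
    """Smallest root in [0, upper] of ``c_quad*x**2 + c_lin*x + (c0 - rate) = 0``.

    The surface is nondecreasing, so a bracketed root is unique.
    """
    def f(x):
        return c0 + c_lin * x + c_quad * x * x - rate
    f0, fu = f(0.0), f(upper)
    if abs(f0) <= RATE_RTOL * rate:
        return 0.0
    if abs(fu) <= RATE_RTOL * rate:
        return upper
    if f0 > 0 or fu < 0:
        return None  # below water rate or above the reachable maximum
    if upper == 0:
        return None
    return float(brentq(f, 0.0, upper, xtol=1e-14, rtol=8.9e-16))


def solve_single_target(model: MixingModel, which: str, time_s: float,
                        strategy: str = "salt_first",
                        limits: ConcentrationLimits | None = None,
                        label: str = "") -> Recipe:
    """Composition matching one relaxation time only.

    The one-target problem has a one-dimensional solution family; the default
    strategy returns the salt-only member (``G = 0``) when attainable — salt
    is the dominant, more precisely dispensable lever — else the agarose-only
    member, else infeasible.
    """
    _check_model(model)
    if not (np.isfinite(time_s) and time_s > 0):
        raise ValueError(f"target time must be positive and finite, got {time_s}")
    if which not in ("T1", "T2"):
        raise ValueError(f"which must be 'T1' or 'T2', got {which!r}")
    if strategy not in ("salt_first", "agarose_first"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if limits is None:
        limits = ConcentrationLimits.for_salt(model.salt)

    c = list(model.coeffs(which))
    rate = 1.0 / time_s
    status = "t1_only" if which == "T1" else "t2_only"

    salt_sol = _quadratic_root(c[3], c[4], c[0], rate, limits.salt_max)
    agar_sol = _quadratic_root(c[1], c[2], c[0], rate, limits.agarose_max)
    ordered = [(0.0, salt_sol, "salt"), (agar_sol, 0.0, "agarose")]
    if strategy == "agarose_first":
        ordered.reverse()
    for G, N, axis in ordered:
        sol = N if axis == "salt" else G
        if sol is not None:
            return _recipe(model, ConcentrationPair(G if axis == "agarose" else 0.0,
                                                    N if axis == "salt" else 0.0),
                           status, label=label)
    return Recipe(conc=None, status="infeasible", predicted_t1_s=None,
                  predicted_t2_s=None, model_key=model.key, label=label)


@dataclass(frozen=True)
class FeasibleRegion:
    """The attainable (T1, T2) cloud of a model over a concentration box."""

    t1_s: np.ndarray
    t2_s: np.ndarray
    agarose: np.ndarray
    salt: np.ndarray
    _hull: Delaunay | None = field(default=None, repr=False, compare=False)

    def contains(self, t1_s: float, t2_s: float) -> bool:
        """Point-in-region test on the convex hull of the sampled cloud."""
        if self._hull is None:
            # degenerate cloud (single point or collinear): nearest-sample test
            d = np.hypot(self.t1_s - t1_s, self.t2_s - t2_s)
            return bool(d.min() <= 1e-12 * max(1.0, abs(t1_s), abs(t2_s)))
        return bool(self._hull.find_simplex([t1_s, t2_s]) >= 0)


def feasible_region(model: MixingModel, limits: ConcentrationLimits | None = None,
                    grid_resolution: int = 40) -> FeasibleRegion:
    """Forward-evaluate the model on a concentration grid.

    Returns the attainable (T1, T2) pairs with their compositions and a
    convex-hull membership test used as a feasibility pre-check.
    """
    if grid_resolution < 1:
        raise ValueError("grid_resolution must be >= 1")
    _check_model(model)
    if limits is None:
        limits = ConcentrationLimits.for_salt(model.salt)
    Gs = np.linspace(0.0, limits.agarose_max, grid_resolution) \
        if limits.agarose_max > 0 else np.array([0.0])
    Ns = np.linspace(0.0, limits.salt_max, grid_resolution) \
        if limits.salt_max > 0 else np.array([0.0])
    GG, NN = np.meshgrid(Gs, Ns)
    R1, R2 = _rates(model, GG, NN)
    t1 = (1.0 / R1).ravel()
    t2 = (1.0 / R2).ravel()
    pts = np.column_stack([t1, t2])
    hull = None
    if len(pts) >= 4 and np.linalg.matrix_rank(pts - pts[0]) >= 2:
        try:
            hull = Delaunay(pts)
        except Exception:  # pragma: no cover - qhull degeneracies
            hull = None
    return FeasibleRegion(t1_s=t1, t2_s=t2, agarose=GG.ravel(), salt=NN.ravel(), _hull=hull)
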