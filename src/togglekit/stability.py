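"""Equilibria and bistability analysis of the resource-coupled toggle switch.

Fixed points of the switch are intersections of the two nullclines; they also
satisfy the one-dimensional constraint

    a * z / (1 + z^2) = y / (1 + y^2),        a = alpha_y / alpha_z,

which for a balanced switch (a = 1) degenerates into the union of the diagonal
y = z and the hyperbola y z = 1.  :func:`find_fixed_points` exploits this:
the constraint is solved for y branch-wise given z, reducing equilibrium
finding to bracketed scalar root finding along each branch — deterministic and
exhaustive for the Hill-coefficient-2 switch, which has at most three
equilibria.  A Monte-Carlo classifier (:func:`bistable_numeric`) integrating
many random initial conditions and clustering endpoints provides an
independent route to the same mono/bistable label.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import jacobian, rhs, settle
from .params import (
    ParameterDomainError,
    ReducedParams,
    ToggleParams,
    toggle_from_reduced,
)

_HYPERBOLICITY_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Root refinement failed on a bracket; carries the bracket report."""


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the switch with its linear classification."""

    y: float
    z: float
    eigenvalues: tuple[complex, complex]
    klass: str  # "stable" | "unstable"

    @property
    def stable(self) -> bool:
        return self.klass == "stable"


@dataclass(frozen=True)
class StabilityResult:
    fixed_points: tuple[FixedPoint, ...]
    label: str  # "monostable" | "bistable" | "other"
    method: str  # "analytic-roots" | "mc-clustering"
    seed: int | None = None
    n_unconverged: int = 0

    @property
    def n_stable(self) -> int:
        return sum(fp.stable for fp in self.fixed_points)

    @property
    def stable_points(self) -> tuple[FixedPoint, ...]:
        return tuple(fp for fp in self.fixed_points if fp.stable)


def constraint_residual(y, z, a):
    """Residual of the fixed-point constraint a*z/(1+z^2) - y/(1+y^2).

    Vanishes exactly on the fixed-point manifold; for ``a = 1`` it vanishes on
    the diagonal y = z and on the hyperbola y z = 1.
    """
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    r = a * z / (1.0 + z * z) - y / (1.0 + y * y)
    return float(r) if r.ndim == 0 else r


def nullclines(params: ToggleParams, axis: str, coordinate_grid) -> list[np.ndarray]:
    """Sample one nullcline over a coordinate grid.

    For ``axis="y"`` (the dy/dt = 0 nullcline) the grid values are z
    coordinates and, for each, all nonnegative real y roots of the cleared
    cubic are returned; symmetric for ``axis="z"``.
    """
    if axis not in ("y", "z"):
        raise ValueError("axis must be 'y' or 'z'")
    grid = np.asarray(coordinate_grid, dtype=float)
    if np.any(grid < 0):
        raise ParameterDomainError("coordinate grid must be nonnegative")
    if axis == "y":
        alpha, b_own, b_other = params.alpha_y, params.beta_y, params.beta_z
    else:
        alpha, b_own, b_other = params.alpha_z, params.beta_z, params.beta_y
    out = []
    for s in grid:
        u = 1.0 / (1.0 + s * s)
        A = 1.0 + b_own * u + params.beta_c
        # A x^3 - alpha u x^2 + (A + b_other) x - alpha u = 0
        roots = np.roots([A, -alpha * u, A + b_other, -alpha * u])
        real = roots[np.abs(roots.imag) < 1e-9].real
        out.append(np.sort(real[real >= -1e-12].clip(min=0.0)))
    return out


# ---------------------------------------------------------------------------
# analytic (deterministic) equilibrium finding
# ---------------------------------------------------------------------------

def _branch_y(z: float, a: float, upper: bool) -> float:
    """Solve y/(1+y^2) = c with c = a*z/(1+z^2) for the requested branch."""
    c = a * z / (1.0 + z * z)
    if c <= 0.0:
        return math.inf if upper else 0.0
    disc = 1.0 - 4.0 * c * c
    if disc < 0.0:
        return math.nan
    s = math.sqrt(disc)
    if upper:
        return (1.0 + s) / (2.0 * c)
    return 2.0 * c / (1.0 + s)


def _fz(y: float, z: float, p: ToggleParams) -> float:
    uy = 1.0 / (1.0 + z * z)
    uz = 1.0 / (1.0 + y * y)
    den = 1.0 + p.beta_y * uy + p.beta_z * uz + p.beta_c
    return p.alpha_z * uz / den - z


def _classify(y: float, z: float, params: ToggleParams) -> FixedPoint:
    ev = np.linalg.eigvals(jacobian((y, z), params))
    re = np.real(ev)
    if np.all(re < -_HYPERBOLICITY_TOL):
        klass = "stable"
    elif np.any(re > _HYPERBOLICITY_TOL):
        klass = "unstable"
    else:
        warnings.warn(
            f"near non-hyperbolic equilibrium at ({y:.6g}, {z:.6g})", stacklevel=3
        )
        klass = "unstable"
    return FixedPoint(y=y, z=z, eigenvalues=(complex(ev[0]), complex(ev[1])), klass=klass)


def _label(points: list[FixedPoint]) -> str:
    n_stable = sum(fp.stable for fp in points)
    if n_stable == 2:
        return "bistable"
    if n_stable == 1:
        return "monostable"
    return "other"


def find_fixed_points(
    params: ToggleParams,
    n_grid: int = 1200,
    residual_tol: float = 1e-9,
) -> StabilityResult:
    """All equilibria in the nonnegative quadrant, deterministically.

    The constraint manifold is parametrized by z on a log-spaced grid; on each
    of its two y-branches the remaining scalar nullcline residual is bracketed
    by sign changes and refined by Brent's method.
    """
    ay, az = params.alpha_y, params.alpha_z
    points: list[tuple[float, float]] = []

    if ay == 0.0 and az == 0.0:
        points.append((0.0, 0.0))
    elif ay == 0.0 or az == 0.0:
        # one side silent: the system is a single self-decaying gene
        if az == 0.0:
            sw = params.swap()
            res = find_fixed_points(sw, n_grid=n_grid, residual_tol=residual_tol)
            pts = [FixedPoint(fp.z, fp.y, fp.eigenvalues, fp.klass)
                   for fp in res.fixed_points]
            return StabilityResult(tuple(pts), res.label, "analytic-roots")
        # ay == 0: y -> 0; solve the z-nullcline cubic at y = 0
        for zr in nullclines(params, "z", [0.0])[0]:
            points.append((0.0, float(zr)))
    else:
        a = ay / az
        alpha0 = params.alpha0
        z_hi = 1.1 * max(az, 1.0)
        den_max = 1.0 + params.beta_y + params.beta_z + params.beta_c
        z_lo = max(1e-10, 0.5 * az / ((1.0 + ay * ay) * den_max))
        # z-domains where the constraint has real y-branches
        if a <= 1.0:
            segments = [(z_lo, z_hi)]
        else:
            r = math.sqrt(a * a - 1.0)
            segments = []
            if a - r > z_lo:
                segments.append((z_lo, a - r))
            segments.append((max(a + r, z_lo), max(z_hi, (a + r) * 1.5)))
        for upper in (False, True):
            for (lo, hi) in segments:
                zs = np.geomspace(lo, hi, n_grid)
                g = np.empty(n_grid)
                for i, zv in enumerate(zs):
                    yv = _branch_y(zv, a, upper)
                    g[i] = _fz(yv, zv, params) if math.isfinite(yv) else math.nan
                for i in range(n_grid - 1):
                    g0, g1 = g[i], g[i + 1]
                    if not (math.isfinite(g0) and math.isfinite(g1)):
                        continue
                    if g0 == 0.0:
                        points.append((_branch_y(zs[i], a, upper), zs[i]))
                    elif g0 * g1 < 0.0:
                        try:
                            zr = brentq(
                                lambda zv: _fz(_branch_y(zv, a, upper), zv, params),
                                zs[i], zs[i + 1], xtol=1e-14, rtol=1e-15,
                            )
                        except Exception as exc:  # pragma: no cover
                            raise ConvergenceError(
                                f"bracket [{zs[i]:.6g}, {zs[i+1]:.6g}] "
                                f"(branch upper={upper}): {exc}"
                            ) from exc
                        points.append((_branch_y(zr, a, upper), zr))

    # dedupe and validate
    unique: list[tuple[float, float]] = []
    for (y, z) in points:
        if not (math.isfinite(y) and math.isfinite(z)):
            continue
        if any(abs(y - uy) < 1e-6 and abs(z - uz) < 1e-6 for uy, uz in unique):
            continue
        fy, fz = rhs((max(y, 0.0), max(z, 0.0)), params)
        if abs(fy) > residual_tol or abs(fz) > residual_tol:
            continue
        unique.append((y, z))

    fps = [_classify(y, z, params) for (y, z) in unique]
    fps.sort(key=lambda fp: fp.y)
    return StabilityResult(tuple(fps), _label(fps), "analytic-roots")


# ---------------------------------------------------------------------------
# Monte-Carlo endpoint-clustering classifier
# ---------------------------------------------------------------------------

def _cluster(points: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Greedy distance-threshold clustering; returns cluster centers."""
    centers: list[np.ndarray] = []
    counts: list[int] = []
    for p in points:
        for i, c in enumerate(centers):
            if np.linalg.norm(p - c) < threshold:
                counts[i] += 1
                centers[i] = c + (p - c) / counts[i]  # running mean
                break
        else:
            centers.append(p.copy())
            counts.append(1)
    return centers


def bistable_numeric(
    params: ToggleParams,
    n_traj: int = 100,
    seed: int = 0,
    ic_domain: tuple[float, float] | None = None,
    t_max: float = 200.0,
    dt: float = 0.02,
) -> StabilityResult:
    """Mono/bistable label from trajectory-endpoint clustering.

    ``n_traj`` random initial conditions are drawn uniformly from
    ``[0, ic_domain[0]] x [0, ic_domain[1]]`` (default ``[0, alpha_y] x
    [0, alpha_z]``), integrated to steady state, and the endpoints clustered
    with Euclidean threshold ``0.05 * max(1, alpha0)`` — stable equilibria of
    a bistable switch are separated by O(alpha0).  Reproducible given ``seed``.
    """
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    rng = np.random.default_rng(seed)
    hi_y, hi_z = ic_domain if ic_domain is not None else (params.alpha_y, params.alpha_z)
    hi_y = max(hi_y, 1e-6)
    hi_z = max(hi_z, 1e-6)
    y0 = rng.uniform(0.0, hi_y, n_traj)
    z0 = rng.uniform(0.0, hi_z, n_traj)
    y, z, _, conv = settle(params, y0, z0, t_max=t_max, dt=dt)
    n_unconv = int(np.sum(~conv))
    pts = np.column_stack([y[conv], z[conv]])
    threshold = 0.05 * max(1.0, params.alpha0)
    centers = _cluster(pts, threshold) if len(pts) else []
    fps = [_classify(float(c[0]), float(c[1]), params) for c in centers]
    n_stable = sum(fp.stable for fp in fps)
    if n_stable == 1:
        label = "monostable"
    elif n_stable == 2:
        label = "bistable"
    else:
        label = "other"
    return StabilityResult(tuple(fps), label, "mc-clustering", seed=seed,
                           n_unconverged=n_unconv)


# ---------------------------------------------------------------------------
# analytic conditions
# ---------------------------------------------------------------------------

def balanced_threshold(beta0: float) -> float:
    """Critical mean expression strength for a balanced switch (a = 1).

    A balanced switch is bistable iff ``alpha0 > 2 sqrt(beta0)``, independent
    of the sequestration asymmetry ``b``: on the y z = 1 equilibrium branch the
    fixed points solve ``(1+beta_y) y^2 - alpha0 y + (1+beta_z) = 0`` whose
    discriminant is ``alpha0^2 - 4 beta0``.
    """
    if beta0 < 1.0:
        raise ParameterDomainError("beta0 = (1+beta_y)(1+beta_z) is >= 1")
    return 2.0 * math.sqrt(beta0)


def sufficient_monostable(reduced: ReducedParams) -> bool:
    """One-sided certificate of monostability (never fires for a bistable switch).

    Two conditions must both hold:

    * the closed-form bound ``alpha0 <= 2 sqrt(beta0)`` — the exact threshold
      below which the balanced switch (a = 1, any b) loses its pair of
      cross-repression states; expression asymmetry only weakens that channel
      further; and
    * the deterministic root analysis (:func:`find_fixed_points`) counts a
      unique equilibrium.

    The second condition is not redundant: heavy sequestration concentrated on
    the weaker gene (b well below 1 at large beta0) can open a second,
    resource-mediated bistability channel — repressing the loaded gene frees
    machinery for the repressor, a positive feedback that supports two stable
    states on the same side of the diagonal even below the balanced threshold.
    The closed-form bound alone would wrongly certify such systems, so the
    certificate is deliberately conservative: it may stay silent (False) for a
    monostable switch, but a True is backed by an exhaustive equilibrium count.
    """
    if not reduced.realizable:
        raise ParameterDomainError("reduced parameters not realizable")
    if reduced.alpha0 > balanced_threshold(reduced.beta0):
        return False
    params = toggle_from_reduced(
        ReducedParams(reduced.alpha0, reduced.a, reduced.beta0, reduced.b)
    )
    return find_fixed_points(params).label == "monostable"


# ---------------------------------------------------------------------------
# phase-diagram sweeps
# ---------------------------------------------------------------------------

_REDUCED_AXES = ("alpha0", "a", "beta0", "b")


def stability_diagram(
    x: str,
    y: str,
    x_values,
    y_values,
    fixed: dict[str, float],
    method: str = "mc-clustering",
    n_traj: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mono/bistable phase diagram over two reduced-parameter axes.

    ``x`` and ``y`` name two of ``alpha0, a, beta0, b``; the remaining two must
    appear in ``fixed``.  Unrealizable (beta0, b) combinations are labeled
    ``"unrealizable"``.  Returns a long-format frame with columns
    (x, y, label, n_stable, seed).
    """
    if x not in _REDUCED_AXES or y not in _REDUCED_AXES or x == y:
        raise ValueError(f"axes must be two distinct of {_REDUCED_AXES}")
    missing = [k for k in _REDUCED_AXES if k not in (x, y) and k not in fixed]
    if missing:
        raise ValueError(f"fixed values required for {missing}")
    rows = []
    for i, xv in enumerate(np.asarray(x_values, dtype=float)):
        for j, yv in enumerate(np.asarray(y_values, dtype=float)):
            kw = dict(fixed)
            kw[x] = float(xv)
            kw[y] = float(yv)
            cell_seed = seed + 1009 * i + j
            try:
                red = ReducedParams(alpha0=kw["alpha0"], a=kw["a"],
                                    beta0=kw["beta0"], b=kw["b"])
                params = toggle_from_reduced(red)
            except ParameterDomainError:
                rows.append({x: xv, y: yv, "label": "unrealizable",
                             "n_stable": 0, "seed": cell_seed})
                continue
            if method == "analytic-roots":
                res = find_fixed_points(params)
            else:
                res = bistable_numeric(params, n_traj=n_traj, seed=cell_seed)
            rows.append({x: xv, y: yv, "label": res.label,
                         "n_stable": res.n_stable, "seed": cell_seed})
    return pd.DataFrame(rows)
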