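"""Functional balancedness of the switch and its optimization via competition.

A perfectly balanced bistable switch sends every initial condition to the
stable state of its initially dominant coordinate: the separatrix is the
diagonal.  Unbalancedness bends the separatrix, so a region of initial
conditions ends up "misclassified" — initial and final dominant coordinates
disagree.  The misclassification-area fraction

    e_psi = area{ (y0, z0) in [0, alpha_y] x [0, alpha_z] :
                  (y0 - z0)(y_inf - z_inf) < 0 } / (alpha_y * alpha_z)

measures this functional error (0 for balanced switches; reported as a
percentage in exports).  Because the sequestration constants (beta_y, beta_z)
also bend the separatrix, deliberately chosen resource competition can undo
the asymmetry of unequal production strengths: :func:`optimize_competition`
grid-searches the (beta_y, beta_z) plane for the bistable pair minimizing
e_psi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import settle
from .params import ToggleParams
from .stability import StabilityResult, find_fixed_points


@dataclass(frozen=True)
class BalanceResult:
    """Misclassification error of one switch (optionally after optimization).

    ``e_psi`` is a fraction in [0, 1] and is NaN unless ``label`` is
    "bistable"; ``mask`` flags the mismatched initial-condition cells.
    """

    params: ToggleParams
    label: str                       # "bistable" | "monostable" | "other"
    e_psi: float
    mask: np.ndarray | None
    n_grid: int
    beta_opt: tuple[float, float] | None = None

    @property
    def e_psi_percent(self) -> float:
        return 100.0 * self.e_psi

    @property
    def applicable(self) -> bool:
        return self.label == "bistable"


class NoBistableCandidateError(RuntimeError):
    """The competition search region contains no bistable parameter pair."""


def final_state_map(
    params: ToggleParams,
    n_grid: int = 101,
    t_max: float = 200.0,
    dt: float = 0.02,
    stability: StabilityResult | None = None,
):
    """Sign of ``y_inf - z_inf`` for a grid of initial conditions.

    Initial conditions are the nodes of an ``n_grid x n_grid`` lattice on
    ``[0, alpha_y] x [0, alpha_z]``.  Returns ``(y0, z0, sign, stability)``
    where ``sign`` is +1/-1 per node (0 where the endpoint is on the
    diagonal); for a non-bistable switch ``sign`` is None — the final-state
    map is then not applicable.
    """
    if stability is None:
        stability = find_fixed_points(params)
    y_axis = np.linspace(0.0, params.alpha_y, n_grid)
    z_axis = np.linspace(0.0, params.alpha_z, n_grid)
    y0, z0 = np.meshgrid(y_axis, z_axis, indexing="ij")
    if stability.label != "bistable":
        return y0, z0, None, stability
    yf, zf, _, _ = settle(params, y0, z0, t_max=t_max, dt=dt)
    return y0, z0, np.sign(yf - zf).astype(np.int8), stability


def mismatch_error(
    params: ToggleParams,
    n_grid: int = 101,
    t_max: float = 200.0,
    dt: float = 0.02,
    stability: StabilityResult | None = None,
) -> BalanceResult:
    """Misclassification-area fraction e_psi of a bistable switch.

    Counts lattice initial conditions whose initial and final dominant
    coordinates disagree; exact-diagonal nodes (y0 = z0) are excluded from
    the area (they have no dominant coordinate).  Not applicable (NaN) for
    non-bistable parameters.
    """
    y0, z0, sign, stability = final_state_map(
        params, n_grid=n_grid, t_max=t_max, dt=dt, stability=stability
    )
    if sign is None:
        return BalanceResult(params=params, label=stability.label,
                             e_psi=math.nan, mask=None, n_grid=n_grid)
    off_diag = y0 != z0
    mismatch = ((y0 - z0) * sign < 0) & off_diag
    e_psi = float(mismatch.sum()) / float(off_diag.sum())
    return BalanceResult(params=params, label="bistable", e_psi=e_psi,
                         mask=mismatch, n_grid=n_grid)


def _candidate(alpha_y, alpha_z, by, bz) -> ToggleParams:
    return ToggleParams(alpha_y=alpha_y, alpha_z=alpha_z,
                        beta_y=by, beta_z=bz)


def optimize_competition(
    alpha_y: float,
    alpha_z: float,
    beta_max: float = 5.0,
    coarse_step: float = 0.25,
    refine_factor: int = 4,
    search_grid: int = 41,
    n_grid: int = 101,
    t_max: float = 200.0,
    dt: float = 0.02,
) -> BalanceResult:
    """Sequestration pair (beta_y, beta_z) minimizing e_psi, subject to bistability.

    Exhaustive coarse-to-fine grid search: ``beta_y, beta_z`` on a lattice of
    step ``coarse_step`` over ``[0, beta_max]``, then one refinement at step
    ``coarse_step/refine_factor`` around the best cell.  Candidates are
    screened for bistability analytically before the (more expensive) e_psi
    evaluation on a ``search_grid``-resolution lattice; the winner is
    re-evaluated at ``n_grid`` resolution.  Deterministic.
    """

    def eval_epsi(by: float, bz: float, n: int) -> tuple[float, StabilityResult]:
        p = _candidate(alpha_y, alpha_z, by, bz)
        stab = find_fixed_points(p)
        if stab.label != "bistable":
            return math.inf, stab
        res = mismatch_error(p, n_grid=n, t_max=t_max, dt=dt, stability=stab)
        return res.e_psi, stab

    def sweep(values_y, values_z, n) -> tuple[float, float, float]:
        best = (math.inf, math.nan, math.nan)
        for by in values_y:
            for bz in values_z:
                e, _ = eval_epsi(by, bz, n)
                if e < best[0]:
                    best = (e, by, bz)
        return best

    coarse = np.arange(0.0, beta_max + 1e-9, coarse_step)
    e_best, by_best, bz_best = sweep(coarse, coarse, search_grid)
    if not math.isfinite(e_best):
        raise NoBistableCandidateError(
            f"no bistable (beta_y, beta_z) in [0, {beta_max}]^2 for "
            f"alpha=({alpha_y}, {alpha_z})"
        )
    fine_step = coarse_step / refine_factor
    fy = np.clip(np.arange(by_best - coarse_step, by_best + coarse_step + 1e-9,
                           fine_step), 0.0, beta_max)
    fz = np.clip(np.arange(bz_best - coarse_step, bz_best + coarse_step + 1e-9,
                           fine_step), 0.0, beta_max)
    e_best, by_best, bz_best = sweep(np.unique(fy), np.unique(fz), search_grid)

    final_params = _candidate(alpha_y, alpha_z, by_best, bz_best)
    final = mismatch_error(final_params, n_grid=n_grid, t_max=t_max, dt=dt)
    return BalanceResult(
        params=final_params, label=final.label, e_psi=final.e_psi,
        mask=final.mask, n_grid=n_grid, beta_opt=(float(by_best), float(bz_best)),
    )
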