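"""Deterministic vector field, Jacobian, and integrators for the toggle switch.

The dimensionless dynamics of two mutually repressing genes competing for a
shared pool of transcription/translation machinery are

    dy/dt = (alpha_y / (1 + z^2)) / Delta - y
    dz/dt = (alpha_z / (1 + y^2)) / Delta - z

with the shared resource denominator

    Delta = 1 + beta_y / (1 + z^2) + beta_z / (1 + y^2) + beta_c.

With beta_y = beta_z = beta_c = 0 this reduces to the classical Hill-repression
toggle switch; the beta terms deflate both effective production rates in a
state-dependent, coupled way.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .params import ParameterDomainError, State, ToggleParams


def _coords(state) -> tuple:
    if isinstance(state, State):
        return state.y, state.z
    y, z = state[0], state[1]
    return y, z


def rhs(state, params: ToggleParams):
    """Time derivatives (dy/dt, dz/dt) of the resource-coupled switch.

    ``state`` may be a :class:`~togglekit.params.State`, a (y, z) pair, or a
    pair of equal-shaped arrays (evaluated elementwise).
    """
    y, z = _coords(state)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(y < 0) or np.any(z < 0):
        raise ParameterDomainError("state must lie in the nonnegative quadrant")
    uy = 1.0 / (1.0 + z * z)
    uz = 1.0 / (1.0 + y * y)
    den = 1.0 + params.beta_y * uy + params.beta_z * uz + params.beta_c
    fy = params.alpha_y * uy / den - y
    fz = params.alpha_z * uz / den - z
    if fy.ndim == 0:
        return float(fy), float(fz)
    return fy, fz


def jacobian(state, params: ToggleParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of :func:`rhs` at ``state``."""
    y, z = _coords(state)
    if y < 0 or z < 0:
        raise ParameterDomainError("state must lie in the nonnegative quadrant")
    u = 1.0 / (1.0 + z * z)   # repression of y by z
    v = 1.0 / (1.0 + y * y)   # repression of z by y
    W = 1.0 + params.beta_y * u + params.beta_z * v + params.beta_c
    du_dz = -2.0 * z * u * u
    dv_dy = -2.0 * y * v * v
    # fy = alpha_y u / W - y
    dfy_dy = -params.alpha_y * u * params.beta_z * dv_dy / (W * W) - 1.0
    dfy_dz = params.alpha_y * du_dz * (W - params.beta_y * u) / (W * W)
    # fz = alpha_z v / W - z
    dfz_dz = -params.alpha_z * v * params.beta_y * du_dz / (W * W) - 1.0
    dfz_dy = params.alpha_z * dv_dy * (W - params.beta_z * v) / (W * W)
    return np.array([[dfy_dy, dfy_dz], [dfz_dy, dfz_dz]])


def integrate_trajectory(
    params: ToggleParams,
    y0: float,
    z0: float,
    t_max: float = 200.0,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    t_eval=None,
):
    """Integrate one deterministic trajectory with an adaptive RK45 solver.

    Returns the scipy ``OdeResult`` (fields ``t``, ``y`` with rows y and z).
    """

    def f(_t, x):
        uy = 1.0 / (1.0 + x[1] * x[1])
        uz = 1.0 / (1.0 + x[0] * x[0])
        den = 1.0 + params.beta_y * uy + params.beta_z * uz + params.beta_c
        return [params.alpha_y * uy / den - x[0], params.alpha_z * uz / den - x[1]]

    return solve_ivp(f, (0.0, t_max), [y0, z0], rtol=rtol, atol=atol, t_eval=t_eval)


def settle(
    params: ToggleParams,
    y0: np.ndarray,
    z0: np.ndarray,
    t_max: float = 200.0,
    dt: float = 0.02,
    ftol: float = 1e-7,
    accumulate_potential: bool = False,
):
    """Relax an ensemble of initial conditions to steady state (fixed-step RK4).

    Parameters
    ----------
    y0, z0 : arrays of initial coordinates (flattened internally).
    t_max : integration horizon in dimensionless time.
    dt : RK4 step; the relaxation rates of the switch are O(1) so 0.02 is
        comfortably stable for the shipped parameter ranges.
    ftol : per-point early-stop threshold on the vector-field norm.
    accumulate_potential : if True also accumulate the quasi-potential drop
        (fy^2 + fz^2) dt along each path (see :mod:`togglekit.potential`).

    Returns
    -------
    (y, z, v, converged) arrays with the shape of ``y0``; ``v`` is zero unless
    ``accumulate_potential`` is set.
    """
    y0 = np.asarray(y0, dtype=float)
    shape = y0.shape
    y0 = y0.ravel()
    z0 = np.asarray(z0, dtype=float).ravel()
    if np.any(y0 < 0) or np.any(z0 < 0):
        raise ParameterDomainError("initial conditions must be nonnegative")
    y, z, v, conv = _kernels.settle_ensemble(
        y0, z0,
        params.alpha_y, params.alpha_z,
        params.beta_y, params.beta_z, params.beta_c,
        dt, t_max, ftol, accumulate_potential,
    )
    return (y.reshape(shape), z.reshape(shape), v.reshape(shape),
            conv.reshape(shape))
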