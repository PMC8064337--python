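"""Collective behavior of N resource-coupled toggle switches.

Every switch deployed in the same cell draws on the same transcription/
translation machinery, so each switch i experiences a context load equal to
the instantaneous sequestration of all the other switches,

    beta_c,i = sum_{j != i} ( beta_y,j / (1 + z_j^2) + beta_z,j / (1 + y_j^2) ),

entering its shared denominator exactly like the intrinsic beta terms.  For N
identical switches sitting at the same state this collapses to a single
switch with (N beta_y, N beta_z) — the symmetric reduction — which makes the
critical number ``N_crit`` (the largest N for which the collective dynamics
remain bistable) cheap to compute; the full 2N-dimensional simulation with
endpoint clustering is the general route and the cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .params import ParameterDomainError, ToggleParams
from .stability import find_fixed_points


@dataclass(frozen=True)
class MultiswitchSystem:
    """N toggle switches coupled through the shared resource pool."""

    params: tuple[ToggleParams, ...]

    def __post_init__(self) -> None:
        if len(self.params) < 1:
            raise ParameterDomainError("need at least one switch")
        if any(p.beta_c != 0 for p in self.params):
            raise ParameterDomainError(
                "per-switch beta_c must be zero: the context load is generated "
                "by the other switches"
            )

    @property
    def n(self) -> int:
        return len(self.params)

    def _arrays(self):
        ay = np.array([p.alpha_y for p in self.params])
        az = np.array([p.alpha_z for p in self.params])
        by = np.array([p.beta_y for p in self.params])
        bz = np.array([p.beta_z for p in self.params])
        return ay, az, by, bz


def coupled_rhs(state_vector, params_list) -> np.ndarray:
    """Derivative of the coupled system; state is ((y1,z1),...,(yN,zN)) flat.

    With a single switch this is identical to :func:`togglekit.dynamics.rhs`.
    """
    system = MultiswitchSystem(tuple(params_list))
    x = np.asarray(state_vector, dtype=float).ravel()
    if x.shape[0] != 2 * system.n:
        raise ParameterDomainError(
            f"state length {x.shape[0]} does not match 2N = {2 * system.n}"
        )
    if np.any(x < 0):
        raise ParameterDomainError("states must be nonnegative")
    ay, az, by, bz = system._arrays()
    y = x[0::2]
    z = x[1::2]
    uy = 1.0 / (1.0 + z * z)
    uz = 1.0 / (1.0 + y * y)
    total = np.sum(by * uy + bz * uz)
    den = 1.0 + total
    out = np.empty_like(x)
    out[0::2] = ay * uy / den - y
    out[1::2] = az * uz / den - z
    return out


def collective_stability(
    n_switches: int,
    params: ToggleParams,
    n_ic: int = 100,
    seed: int = 0,
    t_max: float = 400.0,
    dt: float = 0.02,
    dominance_margin: float | None = None,
) -> str:
    """Collective mono/bistable label of N identical switches.

    ``n_ic`` random initial conditions are drawn with every switch's (y, z)
    pair uniform on ``[0, alpha0]^2``, the 2N-dimensional system is relaxed,
    and each switch's resting state is classified by its dominant coordinate.
    The collective is labeled bistable iff, across the whole ensemble,
    switches are found resting in both y-dominated and z-dominated states —
    i.e. distinct switch-level memories can still coexist; monostable iff all
    rest on one side.  Endpoints within ``dominance_margin`` of the diagonal
    (default ``0.02 * alpha0``) count as neither and yield "other" if nothing
    else is observed.
    """
    if n_switches < 1:
        raise ParameterDomainError("n_switches must be >= 1")
    system = MultiswitchSystem((params,) * n_switches)
    rng = np.random.default_rng(seed)
    alpha0 = params.alpha0
    if dominance_margin is None:
        dominance_margin = 0.02 * max(1.0, alpha0)
    states0 = rng.uniform(0.0, alpha0, size=(n_ic, 2 * n_switches))
    ay, az, by, bz = system._arrays()
    x, conv = _kernels.settle_multiswitch(states0, ay, az, by, bz, dt, t_max, 1e-7)
    y = x[:, 0::2].ravel()
    z = x[:, 1::2].ravel()
    d = y - z
    has_y = bool(np.any(d > dominance_margin))
    has_z = bool(np.any(d < -dominance_margin))
    if has_y and has_z:
        return "bistable"
    if has_y or has_z:
        return "monostable"
    return "other"


def symmetric_reduction(n_switches: int, params: ToggleParams) -> ToggleParams:
    """Single-switch equivalent of N identical switches at a common state."""
    return ToggleParams(
        alpha_y=params.alpha_y, alpha_z=params.alpha_z,
        beta_y=n_switches * params.beta_y, beta_z=n_switches * params.beta_z,
    )


@dataclass(frozen=True)
class MultiswitchResult:
    n_crit: int
    labels: dict[int, str]     # per-N collective label
    method: str                # "full" | "symmetric"
    seed: int | None
    lower_bound: bool = False  # True if n_max reached while still bistable


def find_ncrit(
    params: ToggleParams,
    n_max: int = 64,
    n_ic: int = 100,
    seed: int = 0,
    method: str = "full",
) -> MultiswitchResult:
    """Largest number of identical switches that remains collectively bistable.

    Incremental search in N; one more switch than ``n_crit`` renders the
    collective monostable.  ``method="symmetric"`` uses the exact identical-
    switch reduction (a single switch with N-scaled sequestration, classified
    by deterministic root finding); ``method="full"`` simulates the full
    2N-dimensional ensemble.  A switch that is already monostable alone has
    ``n_crit = 0``.
    """
    if method not in ("full", "symmetric"):
        raise ValueError("method must be 'full' or 'symmetric'")
    labels: dict[int, str] = {}
    n_crit = 0
    for n in range(1, n_max + 1):
        if method == "symmetric":
            label = find_fixed_points(symmetric_reduction(n, params)).label
        else:
            label = collective_stability(n, params, n_ic=n_ic, seed=seed + n)
        labels[n] = label
        if label == "bistable":
            n_crit = n
        else:
            return MultiswitchResult(n_crit=n_crit, labels=labels, method=method,
                                     seed=seed if method == "full" else None)
    return MultiswitchResult(n_crit=n_crit, labels=labels, method=method,
                             seed=seed if method == "full" else None,
                             lower_bound=True)


def ncrit_sweep(
    alpha0_values,
    a_values,
    beta0: float,
    b: float,
    n_max: int = 64,
    method: str = "symmetric",
    n_ic: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """N_crit over an (alpha0, a) grid at fixed sequestration (beta0, b)."""
    from .params import ReducedParams, toggle_from_reduced

    rows = []
    for alpha0 in alpha0_values:
        for a in a_values:
            try:
                p = toggle_from_reduced(
                    ReducedParams(alpha0=float(alpha0), a=float(a),
                                  beta0=beta0, b=b))
            except ParameterDomainError:
                rows.append({"alpha0": alpha0, "a": a, "beta0": beta0,
                             "b": b, "ncrit": math.nan})
                continue
            res = find_ncrit(p, n_max=n_max, method=method, n_ic=n_ic, seed=seed)
            rows.append({"alpha0": alpha0, "a": a, "beta0": beta0, "b": b,
                         "ncrit": res.n_crit})
    return pd.DataFrame(rows)
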