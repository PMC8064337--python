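"""Langevin simulation of the noisy switch and Kramers-type switching rates.

The deterministic flow is perturbed by additive zero-mean Gaussian white noise
of intensity ``eps`` in both coordinates (increment std ``sqrt(2 eps dt)`` per
Euler–Maruyama step), with reflection at the axes since the state is a pair of
concentrations.  Noise occasionally carries trajectories over the potential
barrier separating the two metastable states; by the Eyring–Kramers picture
the mean dwell time in a basin grows exponentially with (barrier height)/eps.

Per-generation switching probabilities follow from exponentially distributed
waiting times: a cell doubling every ``td = ln(2)/gamma`` switches out of the
y-dominated state before its next division with probability
``py = 1 - exp(-td/tau_y)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import ParameterDomainError, ToggleParams
from .stability import StabilityResult, find_fixed_points
from .potential import NoBarrierError, _order_stable


@dataclass(frozen=True)
class LangevinRun:
    """A seeded Euler–Maruyama realization with dwell bookkeeping.

    ``samples`` holds strided (t, y, z) snapshots; ``event_times`` /
    ``event_basins`` record each entry into a capture disc (basin 0 = the
    y-dominated state, 1 = the z-dominated state) under the hysteresis rule:
    a transition is scored only on reaching the disc around the opposite
    stable fixed point, never on mere separatrix crossings.
    """

    params: ToggleParams
    eps: float
    dt: float
    horizon: float
    seed: int
    samples: np.ndarray        # (n, 3): t, y, z
    event_times: np.ndarray
    event_basins: np.ndarray
    capture_radius: float
    xy: tuple[float, float]
    xz: tuple[float, float]
    truncated_events: bool = False

    @property
    def n_transitions(self) -> int:
        """Number of basin changes (excluding the first capture)."""
        if len(self.event_basins) == 0:
            return 0
        return int(np.sum(np.diff(self.event_basins) != 0))


def simulate_langevin(
    params: ToggleParams,
    eps: float,
    dt: float = 0.005,
    horizon: float = 1000.0,
    seed: int = 0,
    initial_state: tuple[float, float] | None = None,
    sample_stride: int = 200,
    capture_radius: float | None = None,
    stability: StabilityResult | None = None,
    max_events: int = 2_000_000,
) -> LangevinRun:
    """Simulate the Langevin switch with Euler–Maruyama.

    With ``eps = 0`` the path coincides with deterministic integration.  The
    run starts at ``initial_state`` (default: the y-dominated stable fixed
    point) and is reproducible given ``seed``.
    """
    if eps < 0:
        raise ParameterDomainError("noise intensity eps must be >= 0")
    if dt > 0.01:
        raise ParameterDomainError(
            "dt must be <= 0.01 for a stable deterministic part"
        )
    if stability is None:
        stability = find_fixed_points(params)
    if stability.label == "bistable":
        fp_y, fp_z = _order_stable(stability)
        xy = (fp_y.y, fp_y.z)
        xz = (fp_z.y, fp_z.z)
    elif stability.stable_points:
        only = stability.stable_points[0]
        xy = xz = (only.y, only.z)
    else:
        raise NoBarrierError("no stable state to simulate around")
    if capture_radius is None:
        sep = math.hypot(xy[0] - xz[0], xy[1] - xz[1])
        capture_radius = 0.1 * sep if sep > 0 else 0.5
    y0, z0 = initial_state if initial_state is not None else xy
    n_steps = int(round(horizon / dt))
    ys, zs, ts, ev_t, ev_b, n_ev = _kernels.langevin_em(
        float(y0), float(z0),
        params.alpha_y, params.alpha_z, params.beta_y, params.beta_z,
        params.beta_c, float(eps), float(dt), n_steps, int(seed) % (2**32),
        xy[0], xy[1], xz[0], xz[1], capture_radius, sample_stride, max_events,
    )
    return LangevinRun(
        params=params, eps=eps, dt=dt, horizon=horizon, seed=seed,
        samples=np.column_stack([ts, ys, zs]),
        event_times=ev_t.copy(), event_basins=ev_b.copy(),
        capture_radius=capture_radius, xy=xy, xz=xz,
        truncated_events=n_ev >= max_events,
    )


@dataclass(frozen=True)
class DwellEstimate:
    tau_y: float
    tau_z: float
    se_y: float
    se_z: float
    n_y: int        # completed dwell segments in the y-basin
    n_z: int
    lower_bound: bool  # True if zero transitions: tau is only a lower bound


def dwell_times(run: LangevinRun, bootstrap: int = 200, seed: int = 0) -> DwellEstimate:
    """Mean dwell times per basin from the run's capture events.

    A dwell in the y-basin is the time from an entry into the y-capture disc
    to the next entry into the z-capture disc (hysteresis rule).  Standard
    errors are bootstrap estimates over the completed segments.  With zero
    transitions the horizon is returned as a lower bound, flagged.
    """
    times = run.event_times
    basins = run.event_basins
    # compress to alternating basin-change events
    seg_y, seg_z = [], []
    if len(times):
        cur_b = basins[0]
        cur_t = times[0]
        for t, b in zip(times[1:], basins[1:]):
            if b != cur_b:
                (seg_y if cur_b == 0 else seg_z).append(t - cur_t)
                cur_b = b
                cur_t = t
    if not seg_y and not seg_z:
        return DwellEstimate(run.horizon, run.horizon, math.inf, math.inf,
                             0, 0, lower_bound=True)
    rng = np.random.default_rng(seed)

    def mean_se(seg):
        if not seg:
            return run.horizon, math.inf
        arr = np.asarray(seg)
        boots = [np.mean(rng.choice(arr, len(arr))) for _ in range(bootstrap)]
        return float(np.mean(arr)), float(np.std(boots))

    ty, sy = mean_se(seg_y)
    tz, sz = mean_se(seg_z)
    return DwellEstimate(ty, tz, sy, sz, len(seg_y), len(seg_z), lower_bound=False)


@dataclass(frozen=True)
class SwitchingRates:
    """Mean dwell times mapped to per-generation switching probabilities."""

    tau_y: float
    tau_z: float
    td: float
    py: float
    pz: float
    prefactor: float = 1.0


def kramers_time(barrier: float, eps: float, prefactor: float = 1.0) -> float:
    """Eyring–Kramers mean transition time ``prefactor * exp(barrier/eps)``."""
    if eps <= 0:
        return math.inf
    return prefactor * math.exp(barrier / eps)


def switching_probabilities(
    tau_y: float,
    tau_z: float,
    gamma: float,
    prefactor: float = 1.0,
) -> SwitchingRates:
    """Per-generation switching probabilities from mean dwell times.

    ``tau_y`` and ``tau_z`` are dimensionless dwell times (units of 1/gamma);
    the doubling time is ``td = ln(2)/gamma``.  In the exponential-waiting
    approximation ``py = 1 - exp(-td/tau_y)`` with both times on the same
    clock, so gamma cancels and py depends only on ln(2)/tau_y.  py increases
    with the doubling time and decreases with tau_y (py -> 0 as tau_y -> inf).
    """
    if tau_y <= 0 or tau_z <= 0 or gamma <= 0:
        raise ParameterDomainError("tau and gamma must be positive")
    td = math.log(2.0) / gamma
    py = 1.0 - math.exp(-math.log(2.0) / tau_y)
    pz = 1.0 - math.exp(-math.log(2.0) / tau_z)
    return SwitchingRates(tau_y=tau_y, tau_z=tau_z, td=td, py=py, pz=pz,
                          prefactor=prefactor)
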