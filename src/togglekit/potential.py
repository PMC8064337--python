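"""Quasi-potential landscapes and barrier heights of the bistable switch.

The switch is not a gradient system, so a path-based quasi-potential is
accumulated along deterministic trajectories: over one integration step the
potential changes by

    dV = -(fy^2 + fz^2) dt,

which equals -f . dx along the trajectory and therefore coincides with the
potential drop of a gradient system whenever the flow is (locally) gradient.
V decreases strictly along every trajectory away from equilibria (a Lyapunov
surface): trajectories flow downhill into the two metastable states.  Each
basin's surface is anchored at its stable fixed point (V = 0 there) and the
two sides are aligned through the saddle — the potential drop from the saddle
into each basin is computed by integrating along the unstable manifold, which
pins the saddle height seen from either side.

Barrier heights are then minimax (bottleneck) path costs on the grid graph:
``hy`` is the smallest, over all grid paths from the y-dominated state into
the opposite basin, of the highest potential met on the way, measured above
the y-state's own potential.  In two dimensions the optimal path crosses the
saddle, so ``V(saddle) - V(xy)`` is an independent cross-check.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import jacobian, settle
from .params import ToggleParams
from .stability import StabilityResult, find_fixed_points


class NoBarrierError(RuntimeError):
    """Barrier heights are undefined for a monostable landscape."""


@dataclass(frozen=True)
class PotentialGrid:
    """Quasi-potential surface on a rectangular grid.

    ``basin`` codes: 0 for the basin of the y-dominated state ``xy``, 1 for
    the z-dominated state ``xz``, -1 for unresolved nodes.  ``saddle_drop``
    holds the potential drop (d_y, d_z) from the saddle into each basin,
    obtained by trajectory integration along the unstable manifold.
    """

    y_axis: np.ndarray
    z_axis: np.ndarray
    V: np.ndarray          # shape (len(y_axis), len(z_axis)), aligned
    basin: np.ndarray      # same shape, int8
    xy: tuple[float, float]
    xz: tuple[float, float]
    saddle: tuple[float, float] | None
    saddle_drop: tuple[float, float] | None
    stability: StabilityResult

    @property
    def bistable(self) -> bool:
        return self.stability.label == "bistable"

    def node_near(self, point: tuple[float, float]) -> tuple[int, int]:
        i = int(np.argmin(np.abs(self.y_axis - point[0])))
        j = int(np.argmin(np.abs(self.z_axis - point[1])))
        return i, j

    def to_frame(self) -> pd.DataFrame:
        yy, zz = np.meshgrid(self.y_axis, self.z_axis, indexing="ij")
        return pd.DataFrame({
            "y": yy.ravel(), "z": zz.ravel(),
            "V": self.V.ravel(), "basin": self.basin.ravel(),
        })


@dataclass(frozen=True)
class BarrierResult:
    hy: float
    hz: float
    saddle: tuple[float, float]
    path: np.ndarray          # (n, 2) node coordinates of the minimax path
    normalization: float = 1.0

    @property
    def hy_normalized(self) -> float:
        return self.hy / self.normalization

    @property
    def hz_normalized(self) -> float:
        return self.hz / self.normalization


def _order_stable(res: StabilityResult) -> tuple:
    """(xy, xz): y-dominated first."""
    s = sorted(res.stable_points, key=lambda fp: fp.y - fp.z, reverse=True)
    return s[0], s[-1]


def quasipotential(
    params: ToggleParams,
    grid_spec: int | tuple[int, int] = 81,
    dt: float = 0.01,
    t_max: float = 400.0,
    domain_factor: float = 1.2,
    stability: StabilityResult | None = None,
) -> PotentialGrid:
    """Accumulate the trajectory quasi-potential from every grid node.

    The grid covers ``[0, domain_factor*alpha_y] x [0, domain_factor*alpha_z]``.
    Every node is integrated to steady state while accumulating the potential
    drop, giving the node's height above its attractor; nodes whose
    trajectories fail to converge within ``t_max`` are marked unresolved.
    """
    if stability is None:
        stability = find_fixed_points(params)
    n_y, n_z = (grid_spec, grid_spec) if isinstance(grid_spec, int) else grid_spec
    y_axis = np.linspace(0.0, domain_factor * max(params.alpha_y, 1.0), n_y)
    z_axis = np.linspace(0.0, domain_factor * max(params.alpha_z, 1.0), n_z)
    yy, zz = np.meshgrid(y_axis, z_axis, indexing="ij")
    yf, zf, v, conv = settle(params, yy, zz, t_max=t_max, dt=dt,
                             ftol=1e-8, accumulate_potential=True)

    stables = stability.stable_points
    basin = np.full(yf.shape, -1, dtype=np.int8)
    if stability.label == "bistable":
        fp_y, fp_z = _order_stable(stability)
        anchors = [(fp_y.y, fp_y.z), (fp_z.y, fp_z.z)]
    elif stables:
        only = stables[0]
        anchors = [(only.y, only.z)]
    else:
        anchors = []
    tol = 0.05 * max(1.0, params.alpha0)
    for code, (ay_, az_) in enumerate(anchors):
        near = (np.hypot(yf - ay_, zf - az_) < tol) & conv
        basin[near] = code

    saddle_xy = None
    drops = None
    V = v.copy()
    if stability.label == "bistable":
        unstable = [fp for fp in stability.fixed_points if not fp.stable]
        if unstable:
            sp = unstable[0]
            saddle_xy = (sp.y, sp.z)
            drops = _saddle_drops(params, sp, anchors, dt)
            if drops is not None:
                d_y, d_z = drops
                # anchor each basin at its fixed point, lift the z-basin so the
                # saddle has the same height seen from both sides
                V = np.where(basin == 1, v + (d_y - d_z), v)
        xy_pt, xz_pt = anchors
    else:
        xy_pt = anchors[0] if anchors else (math.nan, math.nan)
        xz_pt = xy_pt
    return PotentialGrid(
        y_axis=y_axis, z_axis=z_axis, V=V, basin=basin,
        xy=xy_pt, xz=xz_pt, saddle=saddle_xy,
        saddle_drop=drops, stability=stability,
    )


def _saddle_drops(params, saddle, anchors, dt) -> tuple[float, float] | None:
    """Potential drop from the saddle into each basin along its unstable manifold."""
    J = jacobian((saddle.y, saddle.z), params)
    w, vecs = np.linalg.eig(J)
    k = int(np.argmax(w.real))
    if w[k].real <= 0:  # not a saddle after all
        return None
    direction = np.real(vecs[:, k])
    direction /= np.linalg.norm(direction)
    eta = 1e-6 * max(1.0, params.alpha0)
    starts = np.array([
        [saddle.y + eta * direction[0], saddle.z + eta * direction[1]],
        [saddle.y - eta * direction[0], saddle.z - eta * direction[1]],
    ]).clip(min=0.0)
    yf, zf, v, conv = settle(params, starts[:, 0], starts[:, 1],
                             t_max=1000.0, dt=dt, ftol=1e-9,
                             accumulate_potential=True)
    out = [None, None]
    for i in range(2):
        if not conv[i]:
            return None
        for code, (ay_, az_) in enumerate(anchors):
            if math.hypot(yf[i] - ay_, zf[i] - az_) < 0.05 * max(1.0, params.alpha0):
                out[code] = float(v[i])
    if out[0] is None or out[1] is None:
        return None
    return out[0], out[1]


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def minimax_path(V: np.ndarray, valid: np.ndarray, start: tuple[int, int],
                 goal: tuple[int, int]) -> tuple[float, list[tuple[int, int]]]:
    """Bottleneck shortest path: minimize the maximum node value along the path.

    Dijkstra variant on the 8-connected grid graph restricted to ``valid``
    nodes.  Returns (bottleneck value, node index path).
    """
    n, m = V.shape
    best = np.full((n, m), np.inf)
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    si, sj = start
    best[si, sj] = V[si, sj]
    heap = [(V[si, sj], start)]
    while heap:
        cost, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            break
        if cost > best[i, j]:
            continue
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < n and 0 <= nj < m and valid[ni, nj]:
                c = max(cost, V[ni, nj])
                if c < best[ni, nj]:
                    best[ni, nj] = c
                    prev[(ni, nj)] = (i, j)
                    heapq.heappush(heap, (c, (ni, nj)))
    if not np.isfinite(best[goal]):
        raise NoBarrierError("no grid path between the two states")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return float(best[goal]), path


def compute_barriers(grid: PotentialGrid) -> BarrierResult:
    """Barrier heights ``hy`` and ``hz`` from the aligned potential surface.

    Runs the bottleneck minimax path between the two stable states on the
    8-connected grid graph; the barrier out of a state is the bottleneck
    height above that state's own potential.  The saddle is the argmax node on
    the optimal path.
    """
    if not grid.bistable:
        raise NoBarrierError("monostable landscape has no barrier")
    valid = grid.basin >= 0
    start = grid.node_near(grid.xy)
    goal = grid.node_near(grid.xz)
    bottleneck, path = minimax_path(grid.V, valid, start, goal)
    v_xy = grid.V[start]
    v_xz = grid.V[goal]
    hy = bottleneck - v_xy
    hz = bottleneck - v_xz
    k = int(np.argmax([grid.V[p] for p in path]))
    saddle_node = (float(grid.y_axis[path[k][0]]), float(grid.z_axis[path[k][1]]))
    coords = np.array([[grid.y_axis[i], grid.z_axis[j]] for i, j in path])
    return BarrierResult(hy=float(hy), hz=float(hz), saddle=saddle_node, path=coords)


def barrier_sweep(
    variants,
    grid_spec: int | tuple[int, int] = 81,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Barriers for a list of parameter variants, under one shared normalization.

    ``variants`` is an iterable of :class:`ToggleParams` (or (name, params)
    pairs).  Monostable variants are reported with NaN barriers.  All barriers
    are divided by one global constant so the maximum across the sweep is 1.
    """
    rows = []
    for item in variants:
        name, params = item if isinstance(item, tuple) else (None, item)
        row = {
            "name": name,
            "alpha_y": params.alpha_y, "alpha_z": params.alpha_z,
            "beta_y": params.beta_y, "beta_z": params.beta_z,
            "hy": math.nan, "hz": math.nan, "label": None,
        }
        stab = find_fixed_points(params)
        row["label"] = stab.label
        if stab.label == "bistable":
            pg = quasipotential(params, grid_spec=grid_spec, dt=dt, stability=stab)
            bars = compute_barriers(pg)
            row["hy"] = bars.hy
            row["hz"] = bars.hz
        rows.append(row)
    df = pd.DataFrame(rows)
    norm = np.nanmax(df[["hy", "hz"]].to_numpy())
    df["hy_norm"] = df["hy"] / norm
    df["hz_norm"] = df["hz"] / norm
    df.attrs["normalization"] = float(norm)
    return df
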