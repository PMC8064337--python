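"""Exact population-level distribution of cell fates over generations.

Each generation consists of two steps applied to every cell independently:
first, a cell in the y-dominated state switches to the z-dominated state with
probability ``py`` (and vice versa with ``pz``) — noise-induced switching
completes during growth; second, every cell doubles deterministically into two
daughters that inherit its state.  Starting from a single seed cell, the
population after ``i`` generations has exactly ``2^i`` cells, and the number
``Y_i`` of y-dominated cells follows an exact branching recursion: conditioned
on the previous count, the pre-doubling count ``Y_i'`` is the sum of two
independent binomials (survivors among the previous y-cells with keep
probability ``1 - py``, plus switchers among the previous z-cells with
probability ``pz``), and ``Y_i = 2 Y_i'``.

``q_i`` denotes the distribution of ``Y_i`` for a z-dominated seed
(``Y_0 = 0``) and ``r_i`` for a y-dominated seed (``Y_0 = 1``); the z-count
distribution is the exact mirror, ``Pr[Z_i = k] = Pr[Y_i = 2^i - k]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .params import ParameterDomainError

#: Exact distribution vectors grow as 2^i; beyond this cap use Monte Carlo.
MAX_GENERATIONS = 20


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ParameterDomainError(f"{name} must lie in [0, 1], got {p}")
    return p


@dataclass(frozen=True)
class GenerationDistribution:
    """Distribution of the y-dominated cell count in one generation.

    ``probs[k] = Pr[Y_i = k | Y_0 = seed_state]`` for k = 0..2^i.
    """

    generation: int
    seed_state: int  # 0: z-dominated seed, 1: y-dominated seed
    probs: np.ndarray

    @property
    def n_cells(self) -> int:
        return 2 ** self.generation

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.n_cells + 1)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    @property
    def mean_fraction(self) -> float:
        """Expected fraction of the population in the y-dominated state."""
        return self.mean / self.n_cells

    def z_probs(self) -> np.ndarray:
        """Distribution of the z-dominated count: the exact mirror image."""
        return self.probs[::-1].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "generation": self.generation,
            "count": self.support,
            "probability": self.probs,
            "seed_state": self.seed_state,
        })


@dataclass(frozen=True)
class SwitchCounts:
    """Bookkeeping of one switching step (before a doubling).

    Among ``n_y + m_y`` previous y-dominated cells, ``n_y`` preserve their
    state and ``m_y`` switch; symmetric for the z side.  The pre-doubling
    y-count is ``y_prime = n_y + m_z`` and doubling gives ``2 * y_prime``.
    """

    n_y: int
    n_z: int
    m_y: int
    m_z: int

    @property
    def y_prime(self) -> int:
        return self.n_y + self.m_z

    @property
    def y_prev(self) -> int:
        return self.n_y + self.m_y

    @property
    def z_prev(self) -> int:
        return self.n_z + self.m_z


def generation_kernel(y_prev: int, i: int, py: float, pz: float) -> np.ndarray:
    """Transition law of the pre-doubling count Y_i' given Y_{i-1} = y_prev.

    Returns the probability vector over ``Y_i' = 0..2^(i-1)``: the convolution
    of Binomial(y_prev, 1 - py) survivors with Binomial(2^(i-1) - y_prev, pz)
    switchers; binomial terms outside their natural range are zero.
    """
    _check_prob("py", py)
    _check_prob("pz", pz)
    n_prev = 2 ** (i - 1)
    if not 0 <= y_prev <= n_prev:
        raise ParameterDomainError(f"y_prev must lie in [0, {n_prev}]")
    keep = _binom_pmf(y_prev, 1.0 - py)
    gain = _binom_pmf(n_prev - y_prev, pz)
    out = np.convolve(keep, gain)
    # guard against pmf round-off; the kernel is a probability vector
    return out / out.sum()


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial pmf over k = 0..n, robust down to subnormal p."""
    if n == 0:
        return np.ones(1)
    if p <= 0.0:
        out = np.zeros(n + 1)
        out[0] = 1.0
        return out
    if p >= 1.0:
        out = np.zeros(n + 1)
        out[n] = 1.0
        return out
    k = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                  + k * math.log(p) + (n - k) * math.log1p(-p))
    return np.exp(logpmf)


def evolve(
    py: float,
    pz: float,
    generations: int,
    seed_state: int,
) -> list[GenerationDistribution]:
    """Exact distributions of Y_i for generations 0..``generations``.

    ``seed_state`` is 0 (z-dominated seed, the ``q`` family) or 1
    (y-dominated seed, the ``r`` family).  Cost grows as 4^i; generations
    beyond ``MAX_GENERATIONS`` are rejected.
    """
    _check_prob("py", py)
    _check_prob("pz", pz)
    if seed_state not in (0, 1):
        raise ParameterDomainError("seed_state must be 0 or 1")
    if not 0 <= generations <= MAX_GENERATIONS:
        raise ParameterDomainError(
            f"generations must lie in [0, {MAX_GENERATIONS}] "
            "(exact vectors grow as 2^i; use monte_carlo_population beyond)"
        )
    dist = np.zeros(2)
    dist[seed_state] = 1.0
    out = [GenerationDistribution(0, seed_state, dist.copy())]
    for i in range(1, generations + 1):
        n_prev = 2 ** (i - 1)
        prev = out[-1].probs
        half = np.zeros(n_prev + 1)  # distribution of Y_i'
        for y_prev in range(n_prev + 1):
            if prev[y_prev] == 0.0:
                continue
            half[: y_prev + (n_prev - y_prev) + 1] += prev[y_prev] * generation_kernel(
                y_prev, i, py, pz
            )
        # doubling: Y_i = 2 Y_i' (even counts only)
        probs = np.zeros(2 ** i + 1)
        probs[::2] = half
        out.append(GenerationDistribution(i, seed_state, probs))
    return out


def stationary_composition(py: float, pz: float) -> float:
    """Equilibrium fraction of y-dominated cells, ``pz / (py + pz)``.

    Closed-form fixed point of the mean recursion
    ``f_i = f_{i-1} (1 - py) + (1 - f_{i-1}) pz``; independent of the seed
    cell's state.  Undefined when ``py = pz = 0`` (the composition then stays
    frozen at the seed).
    """
    _check_prob("py", py)
    _check_prob("pz", pz)
    if py + pz == 0.0:
        raise ParameterDomainError(
            "stationary composition undefined for py = pz = 0 (frozen at seed)"
        )
    return pz / (py + pz)


def mean_fraction_recursion(py: float, pz: float, generations: int,
                            seed_state: int) -> np.ndarray:
    """Expected y-dominated fraction per generation (exact, O(generations))."""
    f = float(seed_state)
    out = [f]
    for _ in range(generations):
        f = f * (1.0 - py) + (1.0 - f) * pz
        out.append(f)
    return np.array(out)


def generations_to_steady(
    py: float,
    pz: float,
    seed_state: int,
    tol: float = 0.001,
    max_generations: int = 10_000,
) -> int:
    """First generation whose expected composition is within ``tol`` (relative)
    of the stationary value and remains so.

    The mean fraction approaches its fixed point geometrically with ratio
    ``1 - py - pz``, so once inside the band it never leaves; the scan is over
    the O(1) mean recursion, not the full distributions.
    """
    target = stationary_composition(py, pz)
    f = float(seed_state)
    ratio = abs(1.0 - py - pz)
    for i in range(max_generations + 1):
        if abs(f - target) <= tol * target:
            return i
        f = f * (1.0 - py) + (1.0 - f) * pz
    raise RuntimeError("did not reach steady state within max_generations")


def monte_carlo_population(
    py: float,
    pz: float,
    generations: int,
    seed_state: int,
    replicates: int = 10_000,
    rng_seed: int = 0,
) -> GenerationDistribution:
    """Empirical distribution of Y at ``generations`` from simulated colonies.

    Each replicate simulates the two-step process exactly: independent
    Bernoulli switching of every cell, then deterministic doubling.  Cell
    counts (not individual cells) are tracked, so a replicate costs O(i)
    binomial draws.
    """
    _check_prob("py", py)
    _check_prob("pz", pz)
    if replicates < 1:
        raise ParameterDomainError("replicates must be >= 1")
    if seed_state not in (0, 1):
        raise ParameterDomainError("seed_state must be 0 or 1")
    rng = np.random.default_rng(rng_seed)
    n_final = 2 ** generations
    y = np.full(replicates, seed_state, dtype=np.int64)
    n_cells = 1
    for _ in range(generations):
        keep = rng.binomial(y, 1.0 - py)
        gain = rng.binomial(n_cells - y, pz)
        y = 2 * (keep + gain)
        n_cells *= 2
    probs = np.bincount(y, minlength=n_final + 1) / replicates
    return GenerationDistribution(generations, seed_state, probs)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two distributions on the same support."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
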