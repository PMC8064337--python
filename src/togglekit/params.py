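"""Parameterizations of the resource-coupled genetic toggle switch.

Three views of the same switch are used throughout the package:

* :class:`BiophysicalParams` — mechanistic constants (transcription/translation
  rates, dissociation constants, DNA concentration) that lump into effective
  production and sequestration constants.
* :class:`ToggleParams` — the dimensionless parameterization (``alpha_y``,
  ``alpha_z``, ``beta_y``, ``beta_z``, context load ``beta_c``) in which all
  analyses are carried out.
* :class:`ReducedParams` — the four-parameter reduction (``alpha0``, ``a``,
  ``beta0``, ``b``) separating mean expression strength and overall resource
  sequestration from their asymmetries.

Conventions: ``alpha0 = sqrt(alpha_y * alpha_z)`` is the geometric-mean
expression strength and ``a = alpha_y / alpha_z >= 1`` the expression asymmetry
(relabeling y and z if needed, recorded in ``swapped``), so that
``alpha_y = alpha0 * sqrt(a)`` and ``alpha_z = alpha0 / sqrt(a)``.  The
sequestration reduction is ``beta0 = (1 + beta_y) * (1 + beta_z)`` and
``b = (1 + beta_y) / (1 + beta_z)``, realizable with nonnegative betas iff
``1/beta0 <= b <= beta0``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path


class ParameterDomainError(ValueError):
    """A parameter lies outside its admissible domain."""


class UnrealizableParametersError(ParameterDomainError):
    """A reduced parameterization requires a negative sequestration constant."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ParameterDomainError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ToggleParams:
    """Dimensionless toggle-switch parameters.

    Parameters
    ----------
    alpha_y, alpha_z : float
        Dimensionless production constants (typical range 1–100).
    beta_y, beta_z : float
        Dimensionless resource-sequestration constants (typical range 0.1–10);
        zero means abundant resources / no competition.
    beta_c : float
        Resource load imposed by the genetic context (other modules sharing the
        transcription/translation machinery); default 0.
    theta : float
        Hill coefficient of repression.  Fixed at 2 (dimeric repressors) in all
        shipped analyses; stored as a field only as a generalization hook.
    """

    alpha_y: float
    alpha_z: float
    beta_y: float = 0.0
    beta_z: float = 0.0
    beta_c: float = 0.0
    theta: float = 2.0

    def __post_init__(self) -> None:
        for name in ("alpha_y", "alpha_z", "beta_y", "beta_z", "beta_c"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.alpha_y < 0 or self.alpha_z < 0:
            raise ParameterDomainError("production constants must be nonnegative")
        if self.beta_y < 0 or self.beta_z < 0 or self.beta_c < 0:
            raise ParameterDomainError("sequestration constants must be nonnegative")
        if self.theta != 2.0:
            raise ParameterDomainError(
                "only theta=2 (dimeric repressors) is supported in shipped analyses"
            )

    # -- convenience views -------------------------------------------------

    @property
    def alpha0(self) -> float:
        return math.sqrt(self.alpha_y * self.alpha_z)

    @property
    def beta0(self) -> float:
        return (1.0 + self.beta_y) * (1.0 + self.beta_z)

    def swap(self) -> "ToggleParams":
        """Relabel the two sides (y <-> z)."""
        return replace(
            self,
            alpha_y=self.alpha_z,
            alpha_z=self.alpha_y,
            beta_y=self.beta_z,
            beta_z=self.beta_y,
        )

    def to_dict(self) -> dict:
        return {
            "alpha_y": self.alpha_y,
            "alpha_z": self.alpha_z,
            "beta_y": self.beta_y,
            "beta_z": self.beta_z,
            "beta_c": self.beta_c,
            "theta": self.theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToggleParams":
        known = {k: d[k] for k in ("alpha_y", "alpha_z", "beta_y", "beta_z", "beta_c", "theta") if k in d}
        return cls(**known)


@dataclass(frozen=True)
class ReducedParams:
    """Reduced (alpha0, a, beta0, b) parameterization of the switch.

    ``swapped`` records whether the y/z labels were exchanged to enforce the
    ``a >= 1`` convention; it is carried so downstream reports can refer to the
    original labeling.
    """

    alpha0: float
    a: float
    beta0: float = 1.0
    b: float = 1.0
    swapped: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha0", "a", "beta0", "b"):
            _require_finite(name, getattr(self, name))
        if self.alpha0 <= 0:
            raise ParameterDomainError("alpha0 must be positive")
        if self.a < 1.0:
            raise ParameterDomainError("a must be >= 1 (relabel so the stronger side is y)")
        if self.beta0 < 1.0:
            raise ParameterDomainError("beta0 = (1+beta_y)(1+beta_z) is >= 1 by construction")
        if self.b <= 0:
            raise ParameterDomainError("b must be positive")

    @property
    def realizable(self) -> bool:
        """True iff nonnegative (beta_y, beta_z) exist for this (beta0, b)."""
        return 1.0 / self.beta0 - 1e-12 <= self.b <= self.beta0 + 1e-12

    def to_dict(self) -> dict:
        return {"alpha0": self.alpha0, "a": self.a, "beta0": self.beta0, "b": self.b,
                "swapped": self.swapped}


@dataclass(frozen=True)
class State:
    """Dimensionless state (y, z) of the switch at dimensionless time ``t``."""

    y: float
    z: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.y < 0 or self.z < 0:
            raise ParameterDomainError("concentrations must be nonnegative")

    def dimensional(self, K_y: float, K_z: float, gamma: float) -> tuple[float, float, float]:
        """Convert back to dimensional concentrations (Y, Z) and time."""
        return self.y * K_y, self.z * K_z, self.t / gamma


#: Default dilution/growth rate used for nondimensionalization, 1/h
#: (doubling time of 30 min).
DEFAULT_GAMMA = math.log(2.0) / 0.5


@dataclass(frozen=True)
class BiophysicalParams:
    """Per-gene mechanistic constants of one repressor's expression cassette.

    Units follow the conventions of the mechanistic resource-competition model:
    rates in 1/h, DNA concentration ``D`` and repressor dissociation constant
    ``K`` in nM, machinery dissociation constants ``kappa`` (RNAP) and ``k``
    (ribosome) in uM.
    """

    lam_tx: float  # transcription rate constant, 1/h
    lam_tl: float  # translation rate constant, 1/h
    D: float       # DNA (gene copy) concentration, nM
    delta: float   # mRNA decay rate constant, 1/h
    kappa: float   # RNAP dissociation constant, uM
    k: float       # ribosome dissociation constant, uM
    gamma: float = DEFAULT_GAMMA  # growth/dilution rate, 1/h
    K: float = 0.1                # repressor dissociation constant, nM

    def __post_init__(self) -> None:
        for name in ("lam_tl", "D", "delta", "kappa", "k", "gamma", "K"):
            if getattr(self, name) <= 0:
                raise ParameterDomainError(f"{name} must be strictly positive")
        if self.lam_tx < 0:
            raise ParameterDomainError("lam_tx must be nonnegative")


def lump_constants(p: BiophysicalParams) -> dict:
    """Lump mechanistic constants into effective production/sequestration constants.

    Returns a dict with the dimensional lumped constants ``alpha_dim`` (effective
    production rate) and ``beta_dim`` (resource sequestration, dimensionless),
    plus the dimensionless ``alpha`` and ``beta`` obtained with the growth rate
    ``gamma`` and repressor dissociation constant ``K`` of ``p``.

    DNA concentration is given in nM while the machinery dissociation constants
    are in uM; the ratio ``D/kappa`` is converted accordingly.  Only the orders
    of magnitude (alpha in 1–100, beta in 0.1–10 for typical constants) are
    anchored to measured parameter ranges; the absolute dimensionless alpha
    additionally depends on the user-supplied ``gamma`` and ``K``.
    """
    d_um = p.D / 1000.0  # nM -> uM, same unit as kappa and k
    alpha_dim = p.lam_tx * p.lam_tl * d_um / (p.delta * p.kappa * p.k)
    beta_dim = (d_um / p.kappa) * (1.0 + p.lam_tx / (p.delta * p.k))
    alpha = alpha_dim / (p.gamma * (p.K / 1000.0))
    return {
        "alpha_dim": alpha_dim,
        "beta_dim": beta_dim,
        "alpha": alpha,
        "beta": beta_dim,  # beta is already dimensionless
    }


# ---------------------------------------------------------------------------
# reduction <-> expansion
# ---------------------------------------------------------------------------

def reduce_parameters(
    alpha_y: float,
    alpha_z: float,
    beta_y: float = 0.0,
    beta_z: float = 0.0,
) -> ReducedParams:
    """Reduce (alpha_y, alpha_z, beta_y, beta_z) to (alpha0, a, beta0, b).

    The labels are exchanged if necessary so that ``a >= 1`` (the stronger
    repressor is the y-side); ``swapped`` records the exchange and the
    sequestration asymmetry ``b`` is computed after the same relabeling.
    """
    for name, v in (("alpha_y", alpha_y), ("alpha_z", alpha_z),
                    ("beta_y", beta_y), ("beta_z", beta_z)):
        _require_finite(name, v)
    if alpha_y <= 0 or alpha_z <= 0:
        raise ParameterDomainError("production constants must be positive to reduce")
    if beta_y < 0 or beta_z < 0:
        raise ParameterDomainError("sequestration constants must be nonnegative")

    swapped = alpha_y < alpha_z
    if swapped:
        alpha_y, alpha_z = alpha_z, alpha_y
        beta_y, beta_z = beta_z, beta_y
    return ReducedParams(
        alpha0=math.sqrt(alpha_y * alpha_z),
        a=alpha_y / alpha_z,
        beta0=(1.0 + beta_y) * (1.0 + beta_z),
        b=(1.0 + beta_y) / (1.0 + beta_z),
        swapped=swapped,
    )


def expand_parameters(reduced: ReducedParams) -> tuple[float, float, float, float]:
    """Invert :func:`reduce_parameters`.

    Returns ``(alpha_y, alpha_z, beta_y, beta_z)``.  If ``swapped`` is set the
    labels are exchanged back, making the round trip with
    :func:`reduce_parameters` an exact identity.
    """
    if not reduced.realizable:
        raise UnrealizableParametersError(
            f"b={reduced.b:g} outside [1/beta0, beta0]=[{1/reduced.beta0:g}, "
            f"{reduced.beta0:g}]: would require a negative beta"
        )
    sqrt_a = math.sqrt(reduced.a)
    alpha_y = reduced.alpha0 * sqrt_a
    alpha_z = reduced.alpha0 / sqrt_a
    beta_y = max(math.sqrt(reduced.beta0 * reduced.b) - 1.0, 0.0)
    beta_z = max(math.sqrt(reduced.beta0 / reduced.b) - 1.0, 0.0)
    if reduced.swapped:
        alpha_y, alpha_z = alpha_z, alpha_y
        beta_y, beta_z = beta_z, beta_y
    return alpha_y, alpha_z, beta_y, beta_z


def toggle_from_reduced(reduced: ReducedParams, beta_c: float = 0.0) -> ToggleParams:
    """Build :class:`ToggleParams` from a reduced parameterization."""
    ay, az, by, bz = expand_parameters(reduced)
    return ToggleParams(alpha_y=ay, alpha_z=az, beta_y=by, beta_z=bz, beta_c=beta_c)


def context_rescale(params: ToggleParams) -> ToggleParams:
    """Fold the context load ``beta_c`` into rescaled switch parameters.

    With ``alpha' = alpha/(1+beta_c)`` and ``beta' = beta/(1+beta_c)`` the
    rescaled switch with ``beta_c = 0`` generates the identical vector field,
    so every context-free result applies verbatim under context load.
    """
    s = 1.0 + params.beta_c
    return ToggleParams(
        alpha_y=params.alpha_y / s,
        alpha_z=params.alpha_z / s,
        beta_y=params.beta_y / s,
        beta_z=params.beta_z / s,
        beta_c=0.0,
        theta=params.theta,
    )


# ---------------------------------------------------------------------------
# flat config I/O (JSON and TOML)
# ---------------------------------------------------------------------------

_CONFIG_KEYS = ("alpha_y", "alpha_z", "beta_y", "beta_z", "beta_c", "theta")


def save_params(params: ToggleParams, path: str | Path) -> None:
    """Write parameters as a flat key-value config (.json or .toml)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix == ".toml":
        lines = [f"{k} = {v!r}" for k, v in d.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def load_params(path: str | Path) -> ToggleParams:
    """Read parameters from a flat key-value config (.json or .toml).

    A config with reduced keys (alpha0, a, beta0, b) is expanded automatically.
    """
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        d = tomllib.loads(path.read_text())
    else:
        d = json.loads(path.read_text())
    if "alpha0" in d and "alpha_y" not in d:
        red = ReducedParams(
            alpha0=d["alpha0"], a=d.get("a", 1.0),
            beta0=d.get("beta0", 1.0), b=d.get("b", 1.0),
            swapped=bool(d.get("swapped", False)),
        )
        return toggle_from_reduced(red, beta_c=d.get("beta_c", 0.0))
    return ToggleParams.from_dict({k: d[k] for k in _CONFIG_KEYS if k in d})
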