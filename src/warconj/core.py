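"""Model definitions: parameters, state, and right-hand sides.

The system follows three bacterial populations in a well-mixed batch
environment — an attacker strain ``C1`` carrying a toxin/immunity plasmid, a
toxin-sensitive target strain ``C2``, and transconjugants ``C3`` (former
targets that received the plasmid and now produce toxin and are immune) —
together with a diffusible toxin pool ``T`` and up to three nutrient pools.
Growth is Monod-limited consumer-resource dynamics; killing of targets by
toxin follows a Hill function with coefficient 1 (functionally a second
Monod term); conjugation from donors (attackers and transconjugants) into
targets is gated by the donor's nutrient-uptake factor, so transfer stops
when nutrients run out.

Two right-hand sides are defined:

* :func:`rhs_default` — a single shared nutrient ``N1``; all strains compete
  for it (``N2`` and ``N3`` are carried in the state but held constant).
* :func:`rhs_metabolic` — adds private nutrients: ``N2`` usable only by the
  attacker, ``N3`` only by the target lineage (target + transconjugant),
  modelling niche separation. Growth, toxin production and conjugation all
  scale with the sum of the accessible Monod terms. With ``N2 = N3 = 0``
  this reduces exactly to the default model.

States and derivatives are ordered ``(C1, C2, C3, N1, N2, N3, T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from enum import Enum
from typing import Iterator, NamedTuple

import numpy as np

__all__ = [
    "STATE_FIELDS",
    "NEGATIVE_TOLERANCE",
    "ModelParams",
    "SystemState",
    "ModelVariant",
    "Derivatives",
    "monod",
    "rhs_default",
    "rhs_metabolic",
    "rhs_for_variant",
    "rhs_array",
    "default_initial_state",
]

#: Canonical ordering of state components throughout the package.
STATE_FIELDS = ("C1", "C2", "C3", "N1", "N2", "N3", "T")

#: Adaptive integrators may overshoot zero slightly; state components in
#: [-NEGATIVE_TOLERANCE, 0) are treated as 0, anything more negative is an
#: error in the public RHS functions.
NEGATIVE_TOLERANCE = 1e-9


class ModelVariant(str, Enum):
    """Which right-hand side (and initial-nutrient convention) to use.

    ``DEFAULT``
        Single shared nutrient; complete niche overlap.
    ``METABOLIC_DIVERSITY``
        Shared nutrient plus both private nutrients (``N2(0) = N3(0) = 1``
        by default).
    ``TWO_NUTRIENT``
        Same equations as ``METABOLIC_DIVERSITY`` but only the target
        lineage has a private pool: ``N2(0) = 0`` and ``N3(0) = 0.25``
        (chosen so maximum realized growth rates stay comparable across
        strains).
    """

    DEFAULT = "default"
    METABOLIC_DIVERSITY = "metabolic_diversity"
    TWO_NUTRIENT = "two_nutrient"


@dataclass(frozen=True)
class ModelParams:
    """Rate, affinity and investment constants.

    All quantities are on a single dimensionless mass scale (the model is
    phenomenological; no unit conversions are applied anywhere).

    Parameters
    ----------
    rC1, rC2, rC3 : float
        Maximum intrinsic growth rate of each strain (1/time). Default 1.
    KN1, KN2, KN3 : float
        Monod saturation constant for uptake of each nutrient (nutrient
        mass). Default 5.
    E : float
        Toxin killing efficiency (potency), scaling target death per unit
        of bound toxin (1/(toxin mass x time)). Default 10.
    b : float
        Conjugation rate: per-donor-biomass rate of plasmid transfer into
        targets, gated by the donor's nutrient-uptake factor
        (1/(cell biomass x time)). Default 0.25.
    gamma : float
        Fraction of a producer's growth diverted into toxin production,
        in [0, 1]. Default 0.15.
    KC2T : float
        Half-saturation affinity of the toxin for the target strain (toxin
        mass). Default 1.0.
    """

    rC1: float = 1.0
    rC2: float = 1.0
    rC3: float = 1.0
    KN1: float = 5.0
    KN2: float = 5.0
    KN3: float = 5.0
    E: float = 10.0
    b: float = 0.25
    gamma: float = 0.15
    KC2T: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {f.name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {f.name!r} must be >= 0, got {value!r}")
        if self.gamma > 1:
            raise ValueError(f"parameter 'gamma' must be <= 1, got {self.gamma!r}")
        for name in ("KN1", "KN2", "KN3", "KC2T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {getattr(self, name)!r}")

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class SystemState:
    """Instantaneous biomasses and resource pools.

    ``C1``/``C2``/``C3`` are attacker, target and transconjugant biomass;
    ``N1`` the shared nutrient, ``N2``/``N3`` the attacker- and
    target-lineage-private nutrients (identically 0 and inert in the
    default model variant); ``T`` the free toxin pool.
    """

    C1: float = 0.01
    C2: float = 0.01
    C3: float = 0.0
    N1: float = 1.0
    N2: float = 0.0
    N3: float = 0.0
    T: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"state component {name!r} must be finite, got {value!r}")
            if value < -NEGATIVE_TOLERANCE:
                raise ValueError(f"state component {name!r} must be >= 0, got {value!r}")
            if value < 0:  # tiny integrator overshoot: clamp
                object.__setattr__(self, name, 0.0)

    def replace(self, **changes: float) -> "SystemState":
        return replace(self, **changes)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_FIELDS),):
            raise ValueError(f"expected state vector of shape ({len(STATE_FIELDS)},), got {y.shape}")
        return cls(**dict(zip(STATE_FIELDS, (float(v) for v in y))))

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in STATE_FIELDS}

    @property
    def total_biomass(self) -> float:
        return self.C1 + self.C2 + self.C3

    def __iter__(self) -> Iterator[float]:
        return (getattr(self, n) for n in STATE_FIELDS)


class Derivatives(NamedTuple):
    """Time derivative of each state component, in state order."""

    C1: float
    C2: float
    C3: float
    N1: float
    N2: float
    N3: float
    T: float

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def monod(pool: float, K: float) -> float:
    """Saturating uptake factor ``pool / (pool + K)``.

    Parameters
    ----------
    pool : float
        Available resource mass, >= 0.
    K : float
        Half-saturation constant, > 0.

    Returns
    -------
    float
        Value in ``[0, 1)``; 0 for an empty pool, 0.5 at ``pool == K``.
    """
    if K <= 0:
        raise ValueError(f"Monod saturation constant must be > 0, got {K!r}")
    if not pool >= 0:  # also catches NaN
        raise ValueError(f"nutrient pool must be >= 0, got {pool!r}")
    return pool / (pool + K)


def default_initial_state(variant: ModelVariant | str = ModelVariant.DEFAULT) -> SystemState:
    """Standard initial condition for a variant.

    All variants start at C1 = C2 = 0.01, C3 = 0, N1 = 1.0, T = 0. The
    private pools depend on the variant: absent (0) in the default model,
    N2 = N3 = 1.0 with full metabolic diversity, and N2 = 0, N3 = 0.25 in
    the two-nutrient convention.
    """
    variant = ModelVariant(variant)
    if variant is ModelVariant.DEFAULT:
        n2, n3 = 0.0, 0.0
    elif variant is ModelVariant.METABOLIC_DIVERSITY:
        n2, n3 = 1.0, 1.0
    else:
        n2, n3 = 0.0, 0.25
    return SystemState(C1=0.01, C2=0.01, C3=0.0, N1=1.0, N2=n2, N3=n3, T=0.0)


# ---------------------------------------------------------------------------
# Right-hand sides.
#
# The scalar cores below are deliberately plain-float arithmetic: they are
# called hundreds of thousands of times by the fixed-step reference
# integrator, where numpy's per-call overhead on length-7 vectors dominates.


def _core_default(
    C1: float, C2: float, C3: float, N1: float, T: float, p: ModelParams
) -> tuple[float, float, float, float, float, float, float]:
    M1 = N1 / (N1 + p.KN1)
    tox = T / (T + p.KC2T)
    conj = p.b * C2 * (C1 * M1 + C3 * M1)
    dC1 = C1 * p.rC1 * M1 * (1.0 - p.gamma)
    dC2 = C2 * p.rC2 * M1 - conj - p.E * C2 * tox
    dC3 = C3 * p.rC3 * M1 * (1.0 - p.gamma) + conj
    dN1 = -M1 * (C1 + C2 + C3)
    dT = p.gamma * C1 * M1 + p.gamma * C3 * M1 - C2 * tox
    return dC1, dC2, dC3, dN1, 0.0, 0.0, dT


def _core_metabolic(
    C1: float, C2: float, C3: float, N1: float, N2: float, N3: float, T: float, p: ModelParams
) -> tuple[float, float, float, float, float, float, float]:
    M1 = N1 / (N1 + p.KN1)
    M2 = N2 / (N2 + p.KN2)
    M3 = N3 / (N3 + p.KN3)
    G1 = M1 + M2  # attacker uptake factor
    G2 = M1 + M3  # target-lineage uptake factor
    tox = T / (T + p.KC2T)
    conj = p.b * C2 * (C1 * G1 + C3 * G2)
    dC1 = C1 * p.rC1 * G1 * (1.0 - p.gamma)
    dC2 = C2 * p.rC2 * G2 - conj - p.E * C2 * tox
    dC3 = C3 * p.rC3 * G2 * (1.0 - p.gamma) + conj
    dN1 = -M1 * (C1 + C2 + C3)
    dN2 = -M2 * C1
    dN3 = -M3 * (C2 + C3)
    dT = p.gamma * C1 * G1 + p.gamma * C3 * G2 - C2 * tox
    return dC1, dC2, dC3, dN1, dN2, dN3, dT


def _validated_components(state: SystemState) -> tuple[float, ...]:
    # SystemState's own constructor enforces finiteness and the negative
    # tolerance; anything that got here is already clean.
    return tuple(state)


def rhs_default(state: SystemState, params: ModelParams) -> Derivatives:
    """Time derivative under the single-shared-nutrient model.

    The attacker and transconjugant divert a fraction ``gamma`` of Monod
    growth into toxin; targets are killed at rate ``E * T/(T + KC2T)`` and
    absorb toxin at the same saturating rate (without the ``E`` factor);
    conjugation converts targets to transconjugants at rate
    ``b * C2 * (C1 + C3) * M1`` where ``M1`` is the shared-nutrient uptake
    factor. ``N2`` and ``N3`` are inert (zero derivative).
    """
    C1, C2, C3, N1, _, _, T = _validated_components(state)
    return Derivatives(*_reorder(_core_default(C1, C2, C3, N1, T, params)))


def rhs_metabolic(state: SystemState, params: ModelParams) -> Derivatives:
    """Time derivative under the metabolic-diversity (private nutrient) model.

    Each lineage's growth, toxin production and conjugation scale with the
    sum of its accessible Monod terms (shared + private). With
    ``N2 = N3 = 0`` the result equals :func:`rhs_default` exactly.
    """
    C1, C2, C3, N1, N2, N3, T = _validated_components(state)
    return Derivatives(*_reorder(_core_metabolic(C1, C2, C3, N1, N2, N3, T, params)))


def _reorder(core: tuple[float, ...]) -> tuple[float, ...]:
    # scalar cores return (dC1, dC2, dC3, dN1, dN2, dN3, dT) which is
    # already STATE_FIELDS order
    return core


def rhs_for_variant(variant: ModelVariant | str):
    """Return the ``(state, params) -> Derivatives`` function for a variant."""
    variant = ModelVariant(variant)
    if variant is ModelVariant.DEFAULT:
        return rhs_default
    return rhs_metabolic


def rhs_array(variant: ModelVariant | str):
    """Return a lenient array-in/array-out RHS ``f(y, params) -> tuple``.

    Intended for use *inside* integrators only: adaptive trial steps may
    transiently overshoot zero, so negative components are evaluated as 0
    rather than raising (the strict ``NEGATIVE_TOLERANCE`` rule applies to
    the public :func:`rhs_default` / :func:`rhs_metabolic` and to every
    stored state).
    """
    variant = ModelVariant(variant)
    use_default = variant is ModelVariant.DEFAULT

    def f(y, params: ModelParams):
        C1, C2, C3, N1, N2, N3, T = (v if v > 0.0 else 0.0 for v in y)
        if use_default:
            return _core_default(C1, C2, C3, N1, T, params)
        return _core_metabolic(C1, C2, C3, N1, N2, N3, T, params)

    return f
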