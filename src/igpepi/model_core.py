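"""Model parameters, state containers and right-hand sides.

The model couples two species in an intraguild-predation (IGP)
relationship: species 1 (the predator) and species 2 (the prey) compete
by interference while species 1 additionally consumes species 2 with a
Holling type-I (linear) functional response.  Without disease the
abundances ``(N1, N2)`` follow

    dN1/dt = r1*N1*(1 - (N1 + p*N2)/k1) + epsilon*a*N1*N2
    dN2/dt = r2*N2*(1 - (N2 + q*N1)/k2) - a*N1*N2

With disease, each species hosts its own susceptible-infected (SI)
pathogen with density-dependent transmission ``beta_i*S_i*I_i``, and the
birth/death split ``r_i = b_i - d_i`` is made explicit so that vital
dynamics route all newborns into the susceptible class without altering
the total-abundance dynamics.  Summing the susceptible and infected
equations of either species recovers the disease-free system exactly.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "EcoState",
    "EpiState",
    "rhs_eco",
    "rhs_epi",
    "totals",
    "canonical_parameters",
]

#: Exactly the accepted serialization keys, in canonical order.
PARAM_FIELDS = (
    "b1", "d1", "k1",
    "b2", "d2", "k2",
    "p", "q", "a", "epsilon",
    "beta1", "beta2",
)


class EcoState(NamedTuple):
    """Abundance phase-space point ``(N1, N2)`` of the disease-free model."""

    n1: float
    n2: float


class EpiState(NamedTuple):
    """Compartment phase-space point ``(S1, I1, S2, I2)`` of the SI model."""

    s1: float
    i1: float
    s2: float
    i2: float


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """The twelve model constants, with derived rates cached as properties.

    Parameters
    ----------
    b1, b2 : float
        Per-capita birth rates [1/time]; must be positive.
    d1, d2 : float
        Per-capita death rates [1/time]; must satisfy ``d_i < b_i`` so the
        intrinsic growth rates ``r_i = b_i - d_i`` are positive (both
        species grow logistically in isolation).
    k1, k2 : float
        Carrying capacities [individuals]; positive.
    p : float
        Interspecific pressure of the prey on the predator (dimensionless).
    q : float
        Interspecific pressure of the predator on the prey (dimensionless).
    a : float
        Predation efficiency [1/(individuals*time)].
    epsilon : float
        Conversion efficiency of consumed prey into predator births.
    beta1, beta2 : float
        Transmission rates of the predator and prey diseases
        [1/(individuals*time)].

    Notes
    -----
    ``r_i`` is never accepted as an independent input: supplying it
    separately from ``(b_i, d_i)`` could silently alter the epidemic
    dynamics, so it is always derived.  The composite interaction
    coefficients are ``alpha1 = r1*p/k1 - epsilon*a`` (net pressure of
    prey on predator: competition minus predation benefit; either sign)
    and ``alpha2 = r2*q/k2 + a`` (net pressure of predator on prey;
    always positive).
    """

    b1: float
    d1: float
    k1: float
    b2: float
    d2: float
    k2: float
    p: float
    q: float
    a: float
    epsilon: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value!r}")
        for i in ("1", "2"):
            b, d, k = (getattr(self, s + i) for s in ("b", "d", "k"))
            if b <= 0:
                raise ValueError(f"b{i} must be > 0")
            if k <= 0:
                raise ValueError(f"k{i} must be > 0")
            if b <= d:
                raise ValueError(
                    f"b{i} <= d{i} gives non-positive intrinsic growth r{i}; "
                    "the model assumes logistic growth of both species"
                )

    # -- derived rates -------------------------------------------------

    @property
    def r1(self) -> float:
        """Intrinsic growth rate of the predator, ``b1 - d1``."""
        return self.b1 - self.d1

    @property
    def r2(self) -> float:
        """Intrinsic growth rate of the prey, ``b2 - d2``."""
        return self.b2 - self.d2

    @property
    def alpha1(self) -> float:
        """Net prey-on-predator pressure ``r1*p/k1 - epsilon*a``."""
        return self.r1 * self.p / self.k1 - self.epsilon * self.a

    @property
    def alpha2(self) -> float:
        """Net predator-on-prey pressure ``r2*q/k2 + a``; always > 0."""
        return self.r2 * self.q / self.k2 + self.a

    # -- construction / serialization ---------------------------------

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        unknown = sorted(set(mapping) - set(PARAM_FIELDS))
        if unknown:
            raise ValueError(
                f"unknown parameter keys {unknown}; derived quantities such as "
                "'r1' or 'alpha1' are computed and must not be supplied"
            )
        missing = sorted(set(PARAM_FIELDS) - set(mapping))
        if missing:
            raise ValueError(f"missing parameter keys {missing}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of parameters")
        return cls.from_dict(data)


def canonical_parameters() -> ParameterSet:
    """The package's documented example parameter set.

    A mild-interaction coexistence scenario used throughout the docs and
    tests: both species near carrying capacity 100, weak reciprocal
    competition, weak predation, and a predator disease just above
    threshold.  Chosen for readability of the resulting numbers, not
    taken from any external study.
    """
    return ParameterSet(
        b1=1.2, d1=0.2, k1=100.0,
        b2=1.5, d2=0.5, k2=100.0,
        p=0.2, q=0.2, a=0.005, epsilon=0.5,
        beta1=0.02, beta2=0.02,
    )


def endemic_demo_parameters() -> ParameterSet:
    """The canonical scenario with the prey disease pushed above threshold.

    Identical to :func:`canonical_parameters` except ``beta2 = 0.1``, so
    both diseases are endemic at coexistence (the fully endemic fixed
    point exists and is stable).  This is the package's base regime for
    the dilution/amplification sweep demonstration.
    """
    return canonical_parameters().replace(beta2=0.1)


# -- right-hand sides ---------------------------------------------------

def _eco_deriv(n1: float, n2: float, pr: ParameterSet) -> tuple[float, float]:
    dn1 = pr.r1 * n1 * (1.0 - (n1 + pr.p * n2) / pr.k1) + pr.epsilon * pr.a * n1 * n2
    dn2 = pr.r2 * n2 * (1.0 - (n2 + pr.q * n1) / pr.k2) - pr.a * n1 * n2
    return dn1, dn2


def _epi_deriv(
    s1: float, i1: float, s2: float, i2: float, pr: ParameterSet
) -> tuple[float, float, float, float]:
    n1 = s1 + i1
    n2 = s2 + i2
    crowd1 = (pr.r1 / pr.k1) * (n1 + pr.p * n2)
    crowd2 = (pr.r2 / pr.k2) * (n2 + pr.q * n1)
    ds1 = pr.b1 * n1 - pr.d1 * s1 - crowd1 * s1 + pr.epsilon * pr.a * n1 * n2 - pr.beta1 * s1 * i1
    di1 = -pr.d1 * i1 - crowd1 * i1 + pr.beta1 * s1 * i1
    ds2 = pr.b2 * n2 - pr.d2 * s2 - crowd2 * s2 - pr.a * s2 * n1 - pr.beta2 * s2 * i2
    di2 = -pr.d2 * i2 - crowd2 * i2 - pr.a * i2 * n1 + pr.beta2 * s2 * i2
    return ds1, di1, ds2, di2


def _validate_state(values: Iterable[float], dim: int) -> np.ndarray:
    arr = np.asarray(tuple(values), dtype=float)
    if arr.shape != (dim,):
        raise ValueError(f"expected a state of {dim} components, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state has non-finite components: {arr}")
    if np.any(arr < 0):
        raise ValueError(f"state has negative components: {arr}")
    return arr


def rhs_eco(state, params: ParameterSet) -> np.ndarray:
    """Rate of change ``(dN1/dt, dN2/dt)`` of the disease-free model.

    Pure function; rejects negative or non-finite abundances.
    """
    n1, n2 = _validate_state(state, 2)
    return np.array(_eco_deriv(n1, n2, params))


def rhs_epi(state, params: ParameterSet) -> np.ndarray:
    """Rate of change ``(dS1, dI1, dS2, dI2)/dt`` of the SI model."""
    s1, i1, s2, i2 = _validate_state(state, 4)
    return np.array(_epi_deriv(s1, i1, s2, i2, params))


def totals(state) -> EcoState:
    """Species totals ``N_i = S_i + I_i`` of an epidemiological state."""
    s1, i1, s2, i2 = _validate_state(state, 4)
    return EcoState(s1 + i1, s2 + i2)
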