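"""Basic reproductive numbers of the two diseases.

Each species hosts its own SI pathogen, so each disease has a basic
reproductive number at every disease-free equilibrium of the community:

* at the competitive-exclusion equilibria the winner sits at its carrying
  capacity and ``R0^(1,1) = beta1*k1/b1`` (predator disease at ``E1``),
  ``R0^(1,2) = beta2*k2/b2`` (prey disease at ``E2``);
* at the disease-free coexistence point ``(N1*, N2*)``,

      R0^(2,1) = k1*beta1*N1* / (d1*k1 + p*r1*N2* + r1*N1*)
      R0^(2,2) = (beta2*k2/b2) * (N2*/k2)

``ngm_oracle`` recomputes any of these from scratch as the spectral
radius of a next-generation matrix assembled by linearizing the infected
subsystem of the model's right-hand side at the given disease-free
equilibrium; it never touches the closed forms above, which makes it an
independent cross-check.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .model_core import ParameterSet, _epi_deriv

__all__ = ["R0Report", "r0_boundary", "r0_coexistence", "ngm_oracle", "r0_report"]


@dataclasses.dataclass(frozen=True)
class R0Report:
    """The four basic reproductive numbers with their defining context.

    ``r0_21``/``r0_22`` are ``None`` when the disease-free coexistence
    equilibrium does not exist (they are defined only there).
    """

    r0_11: float
    r0_12: float
    r0_21: Optional[float]
    r0_22: Optional[float]
    context: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r0_11": self.r0_11,
            "r0_12": self.r0_12,
            "r0_21": self.r0_21,
            "r0_22": self.r0_22,
            "context": dict(self.context),
        }


def r0_boundary(params: ParameterSet) -> tuple[float, float]:
    """``(R0^(1,1), R0^(1,2))`` at the competitive-exclusion equilibria."""
    return params.beta1 * params.k1 / params.b1, params.beta2 * params.k2 / params.b2


def r0_coexistence(
    params: ParameterSet, n1_star: float, n2_star: float
) -> tuple[float, float]:
    """``(R0^(2,1), R0^(2,2))`` at the disease-free coexistence point.

    Parameters
    ----------
    n1_star, n2_star : float
        The coexistence abundances, e.g. from
        :func:`igpepi.equilibria.coexistence_solve`.
    """
    if not (n1_star > 0 and n2_star > 0):
        raise ValueError(
            "coexistence reproductive numbers are defined only at a feasible "
            f"coexistence point; got ({n1_star}, {n2_star})"
        )
    denom = params.d1 * params.k1 + params.p * params.r1 * n2_star + params.r1 * n1_star
    r0_21 = params.k1 * params.beta1 * n1_star / denom
    r0_22 = (params.beta2 * params.k2 / params.b2) * (n2_star / params.k2)
    return r0_21, r0_22


def ngm_oracle(params: ParameterSet, dfe_state) -> tuple[float, float]:
    """Per-disease R0 via the next-generation matrix at a disease-free point.

    The infected subsystem ``(I1, I2)`` is split into new infections
    ``F(x) = (beta1*S1*I1, beta2*S2*I2)`` and transitions
    ``V(x) = F(x) - (dI1/dt, dI2/dt)`` (deaths, crowding drag, predation
    on infected prey).  Both are linearized with respect to ``(I1, I2)``
    at the equilibrium by central differences — exact here because the
    right-hand side is quadratic — and R0 per disease is the spectral
    radius of the corresponding block of ``F V^{-1}``.  The two blocks
    decouple because the diseases share no hosts.
    """
    s1, i1, s2, i2 = (float(v) for v in dfe_state)
    if i1 != 0.0 or i2 != 0.0:
        raise ValueError("next-generation matrix requires I1 = I2 = 0 at the equilibrium")

    def infected_rhs(i_vec: np.ndarray) -> np.ndarray:
        d = _epi_deriv(s1, i_vec[0], s2, i_vec[1], params)
        return np.array([d[1], d[3]])

    def new_infections(i_vec: np.ndarray) -> np.ndarray:
        return np.array(
            [params.beta1 * s1 * i_vec[0], params.beta2 * s2 * i_vec[1]]
        )

    def transitions(i_vec: np.ndarray) -> np.ndarray:
        return new_infections(i_vec) - infected_rhs(i_vec)

    h = 1e-6 * max(params.k1, params.k2)
    F = np.empty((2, 2))
    V = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        F[:, j] = (new_infections(e) - new_infections(-e)) / (2 * h)
        V[:, j] = (transitions(e) - transitions(-e)) / (2 * h)

    k_matrix = F @ np.linalg.inv(V)
    rho_1 = float(np.max(np.abs(np.linalg.eigvals(k_matrix[:1, :1]))))
    rho_2 = float(np.max(np.abs(np.linalg.eigvals(k_matrix[1:, 1:]))))
    return rho_1, rho_2


def r0_report(params: ParameterSet) -> R0Report:
    """All four reproductive numbers of a parameter set.

    Convenience wrapper: evaluates the boundary values always and the
    coexistence values when the disease-free coexistence equilibrium of
    the community exists.
    """
    from .equilibria import coexistence_solve  # local import avoids a cycle

    r0_11, r0_12 = r0_boundary(params)
    star = coexistence_solve(params)
    context = {"r0_11": "E1 (predator at k1)", "r0_12": "E2 (prey at k2)"}
    if star is None:
        return R0Report(r0_11, r0_12, None, None, context)
    r0_21, r0_22 = r0_coexistence(params, star.n1, star.n2)
    context["r0_21"] = context["r0_22"] = (
        f"E5 (disease-free coexistence at ({star.n1:.6g}, {star.n2:.6g}))"
    )
    return R0Report(r0_11, r0_12, r0_21, r0_22, context)
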