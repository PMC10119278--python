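"""Closed-form equilibria of the disease-free and SI models.

Disease-free model (four fixed points):

=========  ==================  ==========================================
label      state               existence
=========  ==================  ==========================================
E0         (0, 0)              always
E1         (k1, 0)             always
E2         (0, k2)             always
Estar_eco  (N1*, N2*)          alpha1*k2 < r1, alpha2*k1 < r2 and
                               alpha1*alpha2 < (r1/k1)*(r2/k2)
=========  ==================  ==========================================

``(N1*, N2*)`` solves the linear system obtained by zeroing the bracketed
factors of the disease-free equations:

    (r1/k1)*N1 + alpha1*N2 = r1
    alpha2*N1 + (r2/k2)*N2 = r2

SI model (nine fixed points): the four above lifted to the disease-free
slice, plus endemic variants gated by the reproductive-number thresholds
(``E3``/``E4`` endemic exclusion, ``E6``/``E7``/``Estar`` endemic
coexistence).  The endemic susceptible densities follow from the
infected nullclines combined with the coexistence relations:

    S1* = (b1 + epsilon*a*N2*)/beta1,   I1* = N1* - S1*
    S2* = b2/beta2,                     I2* = N2* - b2/beta2

so that ``I1* > 0`` iff ``R0^(2,1) > 1`` and ``I2* > 0`` iff
``R0^(2,2) > 1``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from .model_core import EcoState, ParameterSet, rhs_eco, rhs_epi
from .reproduction import r0_boundary, r0_coexistence

__all__ = [
    "Equilibrium",
    "coexistence_solve",
    "eco_equilibria",
    "epi_equilibria",
    "catalogue_to_json",
]

ECO_LABELS = ("E0", "E1", "E2", "Estar_eco")
EPI_LABELS = ("E0e", "E1e", "E2e", "E3", "E4", "E5", "E6", "E7", "Estar")

#: relative margin under which a threshold quantity counts as degenerate
_MARGIN = 1e-12
#: relative closeness of an R0 to 1 flagged as a marginal (boundary) case
_R0_MARGINAL = 1e-9


class DegenerateSystemError(ValueError):
    """The coexistence linear system is numerically singular."""


@dataclasses.dataclass
class Equilibrium:
    """A labelled fixed point with its existence bookkeeping.

    ``state`` is ``None`` when the fixed point does not exist for the
    parameter set (``exists=False``); ``conditions`` records every named
    existence predicate that was evaluated.  ``marginal`` marks fixed
    points sitting exactly on a threshold (they coincide with a boundary
    equilibrium).
    """

    label: str
    model: str  # "eco" | "epi"
    state: Optional[np.ndarray]
    exists: bool
    conditions: dict[str, bool] = dataclasses.field(default_factory=dict)
    source: str = "closed_form"
    marginal: bool = False

    def residual(self, params: ParameterSet) -> float:
        """Max absolute right-hand side at the state, scaled by carrying capacity."""
        if self.state is None:
            raise ValueError(f"{self.label} does not exist; no residual")
        rhs = rhs_eco if self.model == "eco" else rhs_epi
        scale = (
            np.array([params.k1, params.k2])
            if self.model == "eco"
            else np.array([params.k1, params.k1, params.k2, params.k2])
        )
        return float(np.max(np.abs(rhs(self.state, params)) / scale))

    def to_json_dict(self, params: Optional[ParameterSet] = None) -> dict:
        out = {
            "label": self.label,
            "model": self.model,
            "state": None if self.state is None else [float(v) for v in self.state],
            "exists": self.exists,
            "conditions": dict(self.conditions),
            "source": self.source,
            "marginal": self.marginal,
        }
        if params is not None and self.state is not None:
            out["residual"] = self.residual(params)
        return out


def _coexistence_conditions(params: ParameterSet) -> dict[str, bool]:
    r1, r2, k1, k2 = params.r1, params.r2, params.k1, params.k2
    a1, a2 = params.alpha1, params.alpha2
    return {
        "alpha1*k2 < r1": a1 * k2 < r1 - _MARGIN * r1,
        "alpha2*k1 < r2": a2 * k1 < r2 - _MARGIN * r2,
        "alpha1*alpha2 < (r1/k1)*(r2/k2)": a1 * a2
        < (r1 / k1) * (r2 / k2) * (1.0 - _MARGIN),
    }


def coexistence_solve(params: ParameterSet) -> Optional[EcoState]:
    """Disease-free coexistence abundances ``(N1*, N2*)`` or ``None``.

    Solves the 2x2 linear nullcline system when the three existence
    inequalities hold and the solution is strictly positive; returns
    ``None`` otherwise.

    Raises
    ------
    DegenerateSystemError
        If the first two inequalities hold but the determinant
        ``(r1/k1)*(r2/k2) - alpha1*alpha2`` vanishes numerically.
    """
    conds = _coexistence_conditions(params)
    r1, r2, k1, k2 = params.r1, params.r2, params.k1, params.k2
    det_scale = (r1 / k1) * (r2 / k2)
    det = det_scale - params.alpha1 * params.alpha2
    if conds["alpha1*k2 < r1"] and conds["alpha2*k1 < r2"] and abs(det) < 1e-12 * det_scale:
        raise DegenerateSystemError(
            "coexistence nullclines are numerically parallel (determinant ~ 0)"
        )
    if not all(conds.values()):
        return None
    matrix = np.array([[r1 / k1, params.alpha1], [params.alpha2, r2 / k2]])
    n1, n2 = np.linalg.solve(matrix, np.array([r1, r2]))
    if not (n1 > 0 and n2 > 0):
        return None
    return EcoState(float(n1), float(n2))


def eco_equilibria(params: ParameterSet) -> list[Equilibrium]:
    """The four fixed points of the disease-free model, in Table order."""
    k1, k2 = params.k1, params.k2
    always = {"always": True}
    out = [
        Equilibrium("E0", "eco", np.zeros(2), True, dict(always)),
        Equilibrium("E1", "eco", np.array([k1, 0.0]), True, dict(always)),
        Equilibrium("E2", "eco", np.array([0.0, k2]), True, dict(always)),
    ]
    conds = _coexistence_conditions(params)
    star = coexistence_solve(params)
    out.append(
        Equilibrium(
            "Estar_eco",
            "eco",
            None if star is None else np.array(star, dtype=float),
            star is not None,
            conds,
        )
    )
    return out


def endemic_slice_1(params: ParameterSet, n1_star: float, n2_star: float) -> tuple[float, float]:
    """Endemic predator split ``(S1*, I1*)`` on the coexistence slice."""
    s1 = (params.b1 + params.epsilon * params.a * n2_star) / params.beta1
    return s1, n1_star - s1


def epi_equilibria(params: ParameterSet) -> list[Equilibrium]:
    """The nine fixed points of the SI model, in Table order.

    Endemic exclusion equilibria require the corresponding boundary
    reproductive number to exceed one; the coexistence family
    additionally requires the disease-free coexistence conditions (its
    species totals must sit at the eco coexistence point).
    """
    k1, k2, b1, b2, beta1, beta2 = (
        params.k1, params.k2, params.b1, params.b2, params.beta1, params.beta2,
    )
    r0_11, r0_12 = r0_boundary(params)
    always = {"always": True}
    out = [
        Equilibrium("E0e", "epi", np.zeros(4), True, dict(always)),
        Equilibrium("E1e", "epi", np.array([k1, 0.0, 0.0, 0.0]), True, dict(always)),
        Equilibrium("E2e", "epi", np.array([0.0, 0.0, k2, 0.0]), True, dict(always)),
    ]

    # endemic competitive exclusion
    c3 = {"R0_11 > 1": r0_11 > 1.0}
    # at the exact threshold the endemic state coincides with the boundary one;
    # report it, flagged marginal
    exists3 = beta1 > 0 and r0_11 >= 1.0
    out.append(
        Equilibrium(
            "E3",
            "epi",
            np.array([b1 / beta1, k1 - b1 / beta1, 0.0, 0.0]) if exists3 else None,
            exists3,
            c3,
            marginal=exists3 and abs(r0_11 - 1.0) <= _R0_MARGINAL,
        )
    )
    c4 = {"R0_12 > 1": r0_12 > 1.0}
    exists4 = beta2 > 0 and r0_12 >= 1.0
    out.append(
        Equilibrium(
            "E4",
            "epi",
            np.array([0.0, 0.0, b2 / beta2, k2 - b2 / beta2]) if exists4 else None,
            exists4,
            c4,
            marginal=exists4 and abs(r0_12 - 1.0) <= _R0_MARGINAL,
        )
    )

    # coexistence family
    coex_conds = _coexistence_conditions(params)
    star = coexistence_solve(params)
    if star is None:
        for label, extra in (
            ("E5", {}),
            ("E6", {"R0_21 > 1": False}),
            ("E7", {"R0_22 > 1": False}),
            ("Estar", {"R0_21 > 1": False, "R0_22 > 1": False}),
        ):
            out.append(Equilibrium(label, "epi", None, False, {**coex_conds, **extra}))
        return out

    n1s, n2s = star
    r0_21, r0_22 = r0_coexistence(params, n1s, n2s)
    out.append(
        Equilibrium("E5", "epi", np.array([n1s, 0.0, n2s, 0.0]), True, dict(coex_conds))
    )

    endemic1 = beta1 > 0 and r0_21 >= 1.0
    endemic2 = beta2 > 0 and r0_22 >= 1.0
    if endemic1:
        s1s, i1s = endemic_slice_1(params, n1s, n2s)
    if endemic2:
        s2s, i2s = b2 / beta2, n2s - b2 / beta2

    out.append(
        Equilibrium(
            "E6",
            "epi",
            np.array([s1s, i1s, n2s, 0.0]) if endemic1 else None,
            endemic1,
            {**coex_conds, "R0_21 > 1": r0_21 > 1.0},
            marginal=endemic1 and abs(r0_21 - 1.0) <= _R0_MARGINAL,
        )
    )
    out.append(
        Equilibrium(
            "E7",
            "epi",
            np.array([n1s, 0.0, s2s, i2s]) if endemic2 else None,
            endemic2,
            {**coex_conds, "R0_22 > 1": r0_22 > 1.0},
            marginal=endemic2 and abs(r0_22 - 1.0) <= _R0_MARGINAL,
        )
    )
    both = endemic1 and endemic2
    out.append(
        Equilibrium(
            "Estar",
            "epi",
            np.array([s1s, i1s, s2s, i2s]) if both else None,
            both,
            {**coex_conds, "R0_21 > 1": r0_21 > 1.0, "R0_22 > 1": r0_22 > 1.0},
            marginal=both
            and (abs(r0_21 - 1.0) <= _R0_MARGINAL or abs(r0_22 - 1.0) <= _R0_MARGINAL),
        )
    )
    return out


def catalogue_to_json(params: ParameterSet, path=None) -> str:
    """Serialize the full eco + epi catalogue (with residuals) to JSON."""
    payload = {
        "parameters": params.to_dict(),
        "eco": [e.to_json_dict(params) for e in eco_equilibria(params)],
        "epi": [e.to_json_dict(params) for e in epi_equilibria(params)],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
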