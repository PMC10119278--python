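"""Local stability, two independent ways.

Every equilibrium is classified (i) numerically, from the eigenvalues of
the analytic Jacobian, and (ii) analytically, from the tabulated
inequality conditions of the model:

disease-free model
    ``E0`` always unstable; ``E1`` stable iff ``r2 < alpha2*k1``;
    ``E2`` stable iff ``r1 < alpha1*k2``; coexistence stable whenever it
    exists.

SI model
    the same ecological conditions combined with the reproductive-number
    thresholds, e.g. ``E1e`` stable iff ``r2 < alpha2*k1`` and
    ``R0^(1,1) < 1``; the coexistence family is gated purely by the signs
    of ``R0^(2,1) - 1`` and ``R0^(2,2) - 1``.

The two verdicts are compared (``agree``); disagreement on a decisively
non-marginal spectrum would falsify either the Jacobian code or the
condition table, so the test-suite cross-validates them on large sampled
ensembles.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .equilibria import Equilibrium, coexistence_solve
from .model_core import ParameterSet
from .reproduction import r0_boundary, r0_coexistence

__all__ = ["StabilityVerdict", "jacobian", "classify", "EIG_TOL"]

#: dimensionless eigenvalue tolerance; compared against max Re(lambda) after
#: scaling time by the fastest intrinsic growth rate
EIG_TOL = 1e-8


@dataclasses.dataclass
class StabilityVerdict:
    label: str
    eigenvalues: np.ndarray
    eig_verdict: str  # "stable" | "unstable" | "marginal"
    condition_verdict: str  # "stable" | "unstable" | "not_covered"
    conditions: dict[str, bool]
    agree: Optional[bool]  # None when the spectrum is marginal

    @property
    def eig_real_parts(self) -> np.ndarray:
        return self.eigenvalues.real

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "eig_real_parts": [float(v) for v in self.eig_real_parts],
            "eig_verdict": self.eig_verdict,
            "condition_verdict": self.condition_verdict,
            "conditions": dict(self.conditions),
            "agree": self.agree,
        }


def jacobian(params: ParameterSet, state, model: str) -> np.ndarray:
    """Analytic Jacobian of the chosen model at ``state``.

    ``model`` is ``"eco"`` (2x2 in ``(N1, N2)``) or ``"epi"`` (4x4 in
    ``(S1, I1, S2, I2)``).
    """
    pr = params
    if model == "eco":
        n1, n2 = (float(v) for v in state)
        return np.array(
            [
                [
                    pr.r1 * (1.0 - (2.0 * n1 + pr.p * n2) / pr.k1) + pr.epsilon * pr.a * n2,
                    -pr.r1 * pr.p * n1 / pr.k1 + pr.epsilon * pr.a * n1,
                ],
                [
                    -pr.r2 * pr.q * n2 / pr.k2 - pr.a * n2,
                    pr.r2 * (1.0 - (2.0 * n2 + pr.q * n1) / pr.k2) - pr.a * n1,
                ],
            ]
        )
    if model != "epi":
        raise ValueError(f"model must be 'eco' or 'epi', got {model!r}")

    s1, i1, s2, i2 = (float(v) for v in state)
    n1, n2 = s1 + i1, s2 + i2
    g1, g2 = pr.r1 / pr.k1, pr.r2 / pr.k2
    crowd1 = g1 * (n1 + pr.p * n2)
    crowd2 = g2 * (n2 + pr.q * n1)
    ea = pr.epsilon * pr.a
    return np.array(
        [
            [
                pr.b1 - pr.d1 - crowd1 - g1 * s1 + ea * n2 - pr.beta1 * i1,
                pr.b1 - g1 * s1 + ea * n2 - pr.beta1 * s1,
                -g1 * pr.p * s1 + ea * n1,
                -g1 * pr.p * s1 + ea * n1,
            ],
            [
                (pr.beta1 - g1) * i1,
                -pr.d1 - crowd1 - g1 * i1 + pr.beta1 * s1,
                -g1 * pr.p * i1,
                -g1 * pr.p * i1,
            ],
            [
                -(g2 * pr.q + pr.a) * s2,
                -(g2 * pr.q + pr.a) * s2,
                pr.b2 - pr.d2 - crowd2 - g2 * s2 - pr.a * n1 - pr.beta2 * i2,
                pr.b2 - g2 * s2 - pr.beta2 * s2,
            ],
            [
                -(g2 * pr.q + pr.a) * i2,
                -(g2 * pr.q + pr.a) * i2,
                (pr.beta2 - g2) * i2,
                -pr.d2 - crowd2 - g2 * i2 - pr.a * n1 + pr.beta2 * s2,
            ],
        ]
    )


def _condition_map(params: ParameterSet, label: str) -> tuple[dict[str, bool], str]:
    """Tabulated stability conditions for one labelled equilibrium."""
    pr = params
    eco1 = pr.r2 < pr.alpha2 * pr.k1  # exclusion of the prey is favoured
    eco2 = pr.r1 < pr.alpha1 * pr.k2  # exclusion of the predator is favoured
    r0_11, r0_12 = r0_boundary(pr)

    if label in ("E0", "E0e"):
        return {"always unstable": True}, "unstable"
    if label == "E1":
        conds = {"r2 < alpha2*k1": eco1}
    elif label == "E2":
        conds = {"r1 < alpha1*k2": eco2}
    elif label == "Estar_eco":
        conds = {"stable if it exists": True}
    elif label == "E1e":
        conds = {"r2 < alpha2*k1": eco1, "R0_11 < 1": r0_11 < 1.0}
    elif label == "E2e":
        conds = {"r1 < alpha1*k2": eco2, "R0_12 < 1": r0_12 < 1.0}
    elif label == "E3":
        conds = {"r2 < alpha2*k1": eco1, "R0_11 > 1": r0_11 > 1.0}
    elif label == "E4":
        conds = {"r1 < alpha1*k2": eco2, "R0_12 > 1": r0_12 > 1.0}
    elif label in ("E5", "E6", "E7", "Estar"):
        star = coexistence_solve(pr)
        if star is None:
            return {"coexistence exists": False}, "not_covered"
        r0_21, r0_22 = r0_coexistence(pr, star.n1, star.n2)
        want = {
            "E5": (False, False),
            "E6": (True, False),
            "E7": (False, True),
            "Estar": (True, True),
        }[label]
        conds = {
            f"R0_21 {'>' if want[0] else '<'} 1": (r0_21 > 1.0) == want[0],
            f"R0_22 {'>' if want[1] else '<'} 1": (r0_22 > 1.0) == want[1],
        }
    else:
        return {}, "not_covered"
    return conds, "stable" if all(conds.values()) else "unstable"


def classify(params: ParameterSet, equilibrium: Equilibrium) -> StabilityVerdict:
    """Classify local asymptotic stability of an existing equilibrium.

    The eigenvalue verdict uses the analytic Jacobian with tolerance
    ``EIG_TOL`` on real parts after scaling time by ``max(r1, r2)``; a
    dominant real part inside the tolerance band yields ``"marginal"``
    and the agreement flag is left undetermined (``None``).
    """
    if not equilibrium.exists or equilibrium.state is None:
        raise ValueError(f"{equilibrium.label} does not exist for these parameters")
    jac = jacobian(params, equilibrium.state, equilibrium.model)
    eigs = np.linalg.eigvals(jac)
    tol = EIG_TOL * max(params.r1, params.r2)
    max_re = float(np.max(eigs.real))
    if max_re < -tol:
        eig_verdict = "stable"
    elif max_re > tol:
        eig_verdict = "unstable"
    else:
        eig_verdict = "marginal"

    conditions, condition_verdict = _condition_map(params, equilibrium.label)
    if eig_verdict == "marginal":
        agree: Optional[bool] = None
    elif condition_verdict == "not_covered":
        agree = True
    else:
        agree = eig_verdict == condition_verdict
    return StabilityVerdict(
        equilibrium.label, eigs, eig_verdict, condition_verdict, conditions, agree
    )
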