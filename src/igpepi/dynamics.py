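"""Time integration and equilibrium matching.

Trajectories are produced with the adaptive Dormand-Prince Runge-Kutta
4(5) pair (scipy's ``RK45``) at tight default tolerances
(``rtol=1e-8``, ``atol=1e-10``) so that convergence-to-equilibrium tests
are sharp.  The model is strictly forward-invariant on the nonnegative
orthant; tiny negative undershoots produced by the integrator are
clipped to zero in the reported trajectory, while anything larger aborts
with a diagnostic.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium
from .model_core import ParameterSet, _eco_deriv, _epi_deriv, rhs_eco, rhs_epi

__all__ = [
    "Trajectory",
    "simulate",
    "detect_convergence",
    "settling_time",
    "IntegrationError",
    "AmbiguousMatchError",
]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid ``(t, state)`` pair."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


class AmbiguousMatchError(RuntimeError):
    """More than one catalogued equilibrium matches the final state."""


@dataclasses.dataclass
class Trajectory:
    """An integrated orbit: strictly increasing times and matching states."""

    t: np.ndarray
    y: np.ndarray  # shape (len(t), dim)
    model: str  # "eco" | "epi"
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.y[-1]

    def to_dataframe(self):
        import pandas as pd

        cols = ("N1", "N2") if self.model == "eco" else ("S1", "I1", "S2", "I2")
        frame = pd.DataFrame(self.y, columns=list(cols))
        frame.insert(0, "time", self.t)
        return frame


def _state_scale(params: ParameterSet, model: str) -> np.ndarray:
    if model == "eco":
        return np.array([params.k1, params.k2])
    return np.array([params.k1, params.k1, params.k2, params.k2])


def simulate(
    params: ParameterSet,
    init,
    t_end: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 400,
) -> Trajectory:
    """Integrate the model from ``init`` over ``[0, t_end]``.

    The model is chosen from the dimension of ``init`` (2 components:
    disease-free; 4 components: SI).  ``t_end`` defaults to
    ``50/min(r1, r2)`` so that ecological transients have decayed across
    a wide range of rates; slow near-threshold regimes may need a longer
    horizon (see :func:`settling_time`).
    """
    init = np.asarray(init, dtype=float)
    model = {2: "eco", 4: "epi"}.get(init.shape[0] if init.ndim == 1 else -1)
    if model is None:
        raise ValueError(f"initial state must have 2 or 4 components, got {init!r}")
    # validate via the public rhs (rejects negative / non-finite inputs)
    (rhs_eco if model == "eco" else rhs_epi)(init, params)
    if t_end is None:
        t_end = 50.0 / min(params.r1, params.r2)
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")

    deriv = _eco_deriv if model == "eco" else _epi_deriv

    def fun(_t: float, y: np.ndarray) -> np.ndarray:
        return np.array(deriv(*y, params))

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        fun, (0.0, t_end), init, method="RK45", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else 0.0
        y_last = sol.y[:, -1] if sol.t.size else init
        raise IntegrationError(f"integration failed: {sol.message}", t_last, y_last)

    y = sol.y.T.copy()
    undershoot = -1e-9 * max(1.0, params.k1, params.k2)
    worst = float(y.min(initial=0.0))
    if worst < undershoot:
        idx = int(np.argmax(np.any(y < undershoot, axis=1)))
        raise IntegrationError(
            f"state went negative beyond the undershoot tolerance ({worst:.3e})",
            float(sol.t[idx]),
            y[idx],
        )
    np.clip(y, 0.0, None, out=y)
    meta = {
        "method": "RK45 (Dormand-Prince)",
        "rtol": rtol,
        "atol": atol,
        "n_steps": int(sol.t.size),
        "nfev": int(sol.nfev),
        "t_end": float(t_end),
    }
    return Trajectory(sol.t, y, model, meta)


def detect_convergence(
    traj: Trajectory,
    catalogue: Sequence[Equilibrium],
    params: ParameterSet,
    tol: float = 1e-3,
) -> Optional[str]:
    """Label of the catalogued equilibrium the trajectory has settled at.

    A match requires the final state within ``tol`` of the equilibrium
    (max-norm, states scaled by carrying capacity) and the last 10% of
    the trajectory within ``2*tol`` of it (so transients and slow drifts
    are not mistaken for convergence).  Returns ``None`` when nothing
    matches; raises :class:`AmbiguousMatchError` when more than one
    catalogue entry matches the final state.
    """
    scale = _state_scale(params, traj.model)
    dim = scale.size
    final = traj.final_state
    matches = [
        eq
        for eq in catalogue
        if eq.exists
        and eq.state is not None
        and eq.state.shape == (dim,)
        and np.max(np.abs(final - eq.state) / scale) <= tol
    ]
    if len(matches) > 1:
        raise AmbiguousMatchError(
            "final state is within tolerance of "
            + ", ".join(m.label for m in matches)
            + "; refine tol"
        )
    if not matches:
        return None
    eq = matches[0]
    tail = traj.y[traj.t >= traj.t[-1] - 0.1 * (traj.t[-1] - traj.t[0])]
    if np.max(np.abs(tail - eq.state) / scale) > 2.0 * tol:
        return None
    return eq.label


def settling_time(
    params: ParameterSet, equilibrium: Equilibrium, log_reduction: float = 15.0
) -> float:
    """Integration horizon for convergence to a stable equilibrium.

    Returns ``log_reduction / |max Re(lambda)|`` for the dominant (least
    negative) eigenvalue of the Jacobian at the equilibrium — the time
    over which a linear perturbation shrinks by ``e**log_reduction``.

    Raises if the equilibrium is not locally stable.
    """
    from .stability import jacobian  # deferred: stability builds on equilibria

    eigs = np.linalg.eigvals(jacobian(params, equilibrium.state, equilibrium.model))
    max_re = float(np.max(eigs.real))
    if max_re >= 0:
        raise ValueError(
            f"{equilibrium.label} is not locally stable (max Re eigenvalue {max_re:.3e})"
        )
    return log_reduction / abs(max_re)
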