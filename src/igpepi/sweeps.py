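"""Competition/predation parameter sweeps and the dilution/amplification scan.

For a base parameter set, the sweep varies the interference pressures
``(q, p)`` over a rectangular grid (default ``[0.1, 0.6]^2`` at 51x51
resolution) under several predation efficiencies ``a``, and records at
every cell the coexistence reproductive numbers ``R0^(2,1)``,
``R0^(2,2)`` and the endemic infected densities ``I1*``, ``I2*``
(floored at zero below threshold).  Cells where disease-free coexistence
fails are masked (NaN).

``monotonicity_report`` then summarizes the finite-difference signs of
each metric along ``p``, ``q`` and ``a`` and checks the headline
dilution/amplification claims: predation amplifies the predator disease
(``R0^(2,1)``, ``I1*`` nondecreasing in ``a``) while diluting the prey
disease (``R0^(2,2)``, ``I2*`` nonincreasing in ``a``), and the
interspecific competition *received* by a host species dilutes its
disease (``R0^(2,1)``, ``I1*`` nonincreasing in ``p``; ``R0^(2,2)``,
``I2*`` nonincreasing in ``q``).  Note the pairing: pressure exerted on
a host's competitor releases the host and can increase its infections,
so no claim is made for ``I1`` along ``q`` or ``I2`` along ``p``.  The
claims are demonstrated properties of a regime, not theorems; the
report is a scan that lists counterexample cells where a claim fails.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .equilibria import coexistence_solve, endemic_slice_1
from .model_core import ParameterSet
from .reproduction import r0_coexistence

__all__ = ["SweepGrid", "sweep", "monotonicity_report", "DEFAULT_PQ_AXIS"]

DEFAULT_PQ_AXIS = np.linspace(0.1, 0.6, 51)

METRICS = ("r0_21", "r0_22", "i1_star", "i2_star")

#: the directional claims checked by the report: metric, axis, direction
CLAIMS = (
    ("r0_21", "p", "nonincreasing"),
    ("i1_star", "p", "nonincreasing"),
    ("r0_22", "q", "nonincreasing"),
    ("i2_star", "q", "nonincreasing"),
    ("r0_21", "a", "nondecreasing"),
    ("i1_star", "a", "nondecreasing"),
    ("r0_22", "a", "nonincreasing"),
    ("i2_star", "a", "nonincreasing"),
)


@dataclasses.dataclass
class SweepGrid:
    """Metric surfaces over ``(a, q, p)``; arrays have shape (n_a, n_q, n_p)."""

    base: ParameterSet
    p_axis: np.ndarray
    q_axis: np.ndarray
    a_values: np.ndarray
    r0_21: np.ndarray
    r0_22: np.ndarray
    i1_star: np.ndarray
    i2_star: np.ndarray
    coexists: np.ndarray  # boolean

    def metric(self, name: str) -> np.ndarray:
        if name not in METRICS:
            raise KeyError(f"unknown metric {name!r}; choose from {METRICS}")
        return getattr(self, name)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per ``(a, q, p)`` cell."""
        aa, qq, pp = np.meshgrid(
            self.a_values, self.q_axis, self.p_axis, indexing="ij"
        )
        return pd.DataFrame(
            {
                "a": aa.ravel(),
                "q": qq.ravel(),
                "p": pp.ravel(),
                "r0_21": self.r0_21.ravel(),
                "r0_22": self.r0_22.ravel(),
                "i1_star": self.i1_star.ravel(),
                "i2_star": self.i2_star.ravel(),
                "coexists": self.coexists.ravel(),
            }
        )

    def plot_heatmaps(self, path=None, metric_names: Sequence[str] = METRICS):
        """Heatmap figure, one row per metric, one column per ``a`` value."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_rows, n_cols = len(metric_names), len(self.a_values)
        fig, axes = plt.subplots(
            n_rows, n_cols, figsize=(3.2 * n_cols, 2.8 * n_rows), squeeze=False
        )
        extent = (
            self.q_axis[0], self.q_axis[-1], self.p_axis[0], self.p_axis[-1],
        )
        for i, name in enumerate(metric_names):
            surfaces = self.metric(name)
            for j, a in enumerate(self.a_values):
                ax = axes[i][j]
                im = ax.imshow(
                    surfaces[j].T, origin="lower", extent=extent, aspect="auto"
                )
                fig.colorbar(im, ax=ax, shrink=0.85)
                ax.set_xlabel("q")
                ax.set_ylabel("p")
                ax.set_title(f"{name}, a = {a:.4g}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def sweep(
    params_base: ParameterSet,
    p_axis: Optional[Sequence[float]] = None,
    q_axis: Optional[Sequence[float]] = None,
    a_values: Optional[Sequence[float]] = None,
) -> SweepGrid:
    """Evaluate the coexistence disease metrics over a ``(q, p)`` grid.

    ``a_values`` defaults to the base predation efficiency scaled by
    ``(0.5, 1, 2)`` — a weaker/base/stronger predation scenario family.
    Axes must be sorted ascending.
    """
    p_axis = np.asarray(DEFAULT_PQ_AXIS if p_axis is None else p_axis, dtype=float)
    q_axis = np.asarray(DEFAULT_PQ_AXIS if q_axis is None else q_axis, dtype=float)
    if a_values is None:
        a_values = params_base.a * np.array([0.5, 1.0, 2.0])
    a_values = np.asarray(a_values, dtype=float)
    for name, axis in (("p_axis", p_axis), ("q_axis", q_axis), ("a_values", a_values)):
        if axis.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if np.any(np.diff(axis) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
        if np.any(axis < 0):
            raise ValueError(f"{name} must be nonnegative")

    shape = (a_values.size, q_axis.size, p_axis.size)
    grids = {name: np.full(shape, np.nan) for name in METRICS}
    coexists = np.zeros(shape, dtype=bool)
    for ia, a in enumerate(a_values):
        for iq, q in enumerate(q_axis):
            for ip, p in enumerate(p_axis):
                pr = params_base.replace(p=float(p), q=float(q), a=float(a))
                star = coexistence_solve(pr)
                if star is None:
                    continue
                coexists[ia, iq, ip] = True
                r0_21, r0_22 = r0_coexistence(pr, star.n1, star.n2)
                grids["r0_21"][ia, iq, ip] = r0_21
                grids["r0_22"][ia, iq, ip] = r0_22
                if pr.beta1 > 0:
                    _, i1 = endemic_slice_1(pr, star.n1, star.n2)
                    grids["i1_star"][ia, iq, ip] = max(i1, 0.0)
                else:
                    grids["i1_star"][ia, iq, ip] = 0.0
                if pr.beta2 > 0:
                    grids["i2_star"][ia, iq, ip] = max(star.n2 - pr.b2 / pr.beta2, 0.0)
                else:
                    grids["i2_star"][ia, iq, ip] = 0.0
    return SweepGrid(params_base, p_axis, q_axis, a_values, coexists=coexists, **grids)


def _axis_number(axis: str) -> int:
    return {"a": 0, "q": 1, "p": 2}[axis]


def _diff_signs(surface: np.ndarray, axis: str, rel_tol: float) -> np.ndarray:
    """Signed finite differences along an axis; NaN where either cell is masked."""
    d = np.diff(surface, axis=_axis_number(axis))
    scale = np.nanmax(np.abs(surface)) if np.any(np.isfinite(surface)) else 0.0
    tol = rel_tol * max(scale, 1e-300)
    signs = np.where(np.abs(d) <= tol, 0.0, np.sign(d))
    signs[~np.isfinite(d)] = np.nan
    return signs


def monotonicity_report(grid: SweepGrid, rel_tol: float = 1e-9) -> dict:
    """Directional summary of every metric along ``p``, ``q`` and ``a``.

    For each metric/axis pair the report gives a qualitative sign
    ("nonincreasing", "nondecreasing", "flat", "mixed" or "undefined")
    over all unmasked adjacent cell pairs, and for each headline
    dilution/amplification claim whether it holds at every such pair,
    with up to ten counterexample cell indices when it does not.
    Differences below ``rel_tol`` times the metric's magnitude count as
    flat.
    """
    for name in ("p_axis", "q_axis"):
        if getattr(grid, name).size < 2:
            raise ValueError(f"monotonicity needs >= 2 points on {name}")
    signs_summary: dict[str, dict[str, str]] = {}
    signs_cache: dict[tuple[str, str], np.ndarray] = {}
    axes = ("p", "q") + (("a",) if grid.a_values.size >= 2 else ())
    for metric in METRICS:
        surface = grid.metric(metric)
        signs_summary[metric] = {}
        for axis in axes:
            signs = _diff_signs(surface, axis, rel_tol)
            signs_cache[(metric, axis)] = signs
            finite = signs[np.isfinite(signs)]
            if finite.size == 0:
                verdict = "undefined"
            elif np.all(finite == 0):
                verdict = "flat"
            elif np.all(finite <= 0):
                verdict = "nonincreasing"
            elif np.all(finite >= 0):
                verdict = "nondecreasing"
            else:
                verdict = "mixed"
            signs_summary[metric][axis] = verdict

    claims: dict[str, dict] = {}
    for metric, axis, direction in CLAIMS:
        if axis not in axes:
            continue
        signs = signs_cache[(metric, axis)]
        bad = signs > 0 if direction == "nonincreasing" else signs < 0
        bad &= np.isfinite(signs)
        cells = [tuple(int(v) for v in idx) for idx in np.argwhere(bad)[:10]]
        claims[f"{metric}_{direction}_in_{axis}"] = {
            "holds": not bool(bad.any()),
            "n_violations": int(bad.sum()),
            "counterexamples": cells,
        }
    return {"signs": signs_summary, "claims": claims}
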