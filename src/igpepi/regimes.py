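"""Parameter-regime generator.

The SI model has nine equilibria whose existence and stability are
delimited by explicit inequalities (ecological exclusion/coexistence
conditions and reproductive-number thresholds).  This module
rejection-samples parameter sets that land decisively inside the region
of any chosen target equilibrium, together with an initial state
perturbed off that equilibrium, so that end-to-end behaviour (simulate,
converge, classify) is testable for every regime without external data.

Every strict inequality is enforced with a 5% relative margin by
default: accepted regimes are well inside their region, which keeps
dominant eigenvalues bounded away from zero and convergence horizons
finite, and keeps reproductive numbers outside the ambiguous band
around 1.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np

from .equilibria import Equilibrium, coexistence_solve, epi_equilibria
from .model_core import EpiState, ParameterSet
from .reproduction import r0_boundary, r0_coexistence

__all__ = [
    "RegimeSpec",
    "DEFAULT_BOUNDS",
    "SUITE_LABELS",
    "sample_regime",
    "regime_suite",
    "sample_ensemble",
    "RegimeSamplingError",
]

#: Uniform sampling intervals per parameter.  Chosen so that every regime is
#: reachable with modest rejection counts: demographic rates of order one,
#: populations of tens to hundreds of individuals, weak-to-strong interference
#: and predation, and transmission spanning both sides of the R0 = 1 threshold.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "b1": (0.5, 2.0),
    "d1": (0.05, 0.5),
    "k1": (50.0, 500.0),
    "b2": (0.5, 2.0),
    "d2": (0.05, 0.5),
    "k2": (50.0, 500.0),
    "p": (0.05, 0.8),
    "q": (0.05, 0.8),
    "a": (0.001, 0.05),
    "epsilon": (0.1, 0.9),
    "beta1": (0.001, 0.1),
    "beta2": (0.001, 0.1),
}

#: the eight non-trivial SI equilibria (the origin is always unstable and is
#: therefore never a target)
SUITE_LABELS = ("E1e", "E2e", "E3", "E4", "E5", "E6", "E7", "Estar")


class RegimeSamplingError(RuntimeError):
    """Rejection sampling exhausted; message lists the blocking predicates."""


@dataclasses.dataclass(frozen=True)
class RegimeSpec:
    """A sampling request for one target equilibrium regime.

    ``margin`` is the relative slack applied to every strict inequality;
    ``perturbation`` the relative size of the initial-state displacement
    (compartments that are zero at the equilibrium are seeded at up to
    ``perturbation`` of the carrying capacity instead).
    """

    target_label: str
    seed: int
    bounds: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_draws: int = 200_000
    margin: float = 0.05
    perturbation: float = 0.05

    def __post_init__(self) -> None:
        if self.target_label not in SUITE_LABELS:
            raise ValueError(
                f"target must be one of {SUITE_LABELS}; the trivial equilibrium "
                "is always unstable and cannot be a target"
            )
        if self.max_draws < 1:
            raise ValueError("max_draws must be >= 1")
        if set(self.bounds) != set(DEFAULT_BOUNDS):
            raise ValueError("bounds must cover exactly the twelve parameters")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bounds for {name!r} must be strictly positive")


def _lt(x: float, y: float, m: float) -> bool:
    """``x < y`` with relative margin ``m`` (sign-aware on the threshold)."""
    return x < y - m * abs(y)


def regime_predicates(
    params: ParameterSet, label: str, margin: float = 0.0
) -> dict[str, bool]:
    """Existence-and-stability predicates of a target regime.

    With ``margin = 0`` these are exactly the tabulated conditions; a
    positive margin shrinks the admissible region away from its
    boundaries.
    """
    pr = params
    m = margin
    r0_11, r0_12 = r0_boundary(pr)
    preds: dict[str, bool] = {}

    def coexistence() -> Optional[tuple[float, float]]:
        preds["alpha1*k2 < r1"] = _lt(pr.alpha1 * pr.k2, pr.r1, m)
        preds["alpha2*k1 < r2"] = _lt(pr.alpha2 * pr.k1, pr.r2, m)
        preds["alpha1*alpha2 < (r1/k1)*(r2/k2)"] = _lt(
            pr.alpha1 * pr.alpha2, (pr.r1 / pr.k1) * (pr.r2 / pr.k2), m
        )
        if not all(preds.values()):
            return None
        star = coexistence_solve(pr)
        if star is None:  # positivity failed despite the inequalities
            preds["N* > 0"] = False
            return None
        return star

    if label in ("E1e", "E3"):
        preds["r2 < alpha2*k1"] = _lt(pr.r2, pr.alpha2 * pr.k1, m)
        if label == "E1e":
            preds["R0_11 < 1"] = r0_11 < 1.0 - m
        else:
            preds["R0_11 > 1"] = r0_11 > 1.0 + m
    elif label in ("E2e", "E4"):
        preds["r1 < alpha1*k2"] = _lt(pr.r1, pr.alpha1 * pr.k2, m)
        if label == "E2e":
            preds["R0_12 < 1"] = r0_12 < 1.0 - m
        else:
            preds["R0_12 > 1"] = r0_12 > 1.0 + m
    else:
        star = coexistence()
        if star is None:
            return preds
        r0_21, r0_22 = r0_coexistence(pr, star[0], star[1])
        want_1, want_2 = {
            "E5": (False, False),
            "E6": (True, False),
            "E7": (False, True),
            "Estar": (True, True),
        }[label]
        preds["R0_21 > 1" if want_1 else "R0_21 < 1"] = (
            r0_21 > 1.0 + m if want_1 else r0_21 < 1.0 - m
        )
        preds["R0_22 > 1" if want_2 else "R0_22 < 1"] = (
            r0_22 > 1.0 + m if want_2 else r0_22 < 1.0 - m
        )
    return preds


def _draw_params(rng: np.random.Generator, bounds: Mapping[str, tuple[float, float]]):
    values = {name: rng.uniform(lo, hi) for name, (lo, hi) in bounds.items()}
    if values["b1"] <= values["d1"] or values["b2"] <= values["d2"]:
        return None
    return ParameterSet(**values)


def _perturbed_initial(
    rng: np.random.Generator, params: ParameterSet, eq: Equilibrium, size: float
) -> EpiState:
    scale = np.array([params.k1, params.k1, params.k2, params.k2])
    state = np.array(eq.state, dtype=float)
    out = np.empty(4)
    for j in range(4):
        if state[j] > 0:
            out[j] = state[j] * (1.0 + rng.uniform(-size, size))
        else:
            # seed absent compartments at 1%..size of carrying capacity
            out[j] = scale[j] * rng.uniform(0.2, 1.0) * size
    return EpiState(*out)


def sample_regime(spec: RegimeSpec) -> tuple[ParameterSet, EpiState]:
    """Draw one parameter set inside the target regime, plus an initial state.

    Uniform rejection sampling within ``spec.bounds``; deterministic for
    a given seed.  The returned initial state is a small all-positive
    perturbation of the target equilibrium.

    Raises
    ------
    RegimeSamplingError
        If ``max_draws`` draws never satisfied every predicate; the
        message reports how often each predicate rejected.
    """
    rng = np.random.default_rng(spec.seed)
    reject_counts: dict[str, int] = {}
    for _ in range(spec.max_draws):
        params = _draw_params(rng, spec.bounds)
        if params is None:
            reject_counts["b_i > d_i"] = reject_counts.get("b_i > d_i", 0) + 1
            continue
        preds = regime_predicates(params, spec.target_label, spec.margin)
        failed = [name for name, ok in preds.items() if not ok]
        if failed:
            for name in failed:
                reject_counts[name] = reject_counts.get(name, 0) + 1
            continue
        eq = next(
            e for e in epi_equilibria(params) if e.label == spec.target_label
        )
        return params, _perturbed_initial(rng, params, eq, spec.perturbation)
    ranked = sorted(reject_counts.items(), key=lambda kv: -kv[1])
    raise RegimeSamplingError(
        f"no parameter set for {spec.target_label} in {spec.max_draws} draws; "
        "most frequent rejections: "
        + ", ".join(f"{name} ({count})" for name, count in ranked[:4])
    )


def regime_suite(
    seed: int, **spec_overrides
) -> dict[str, tuple[ParameterSet, EpiState]]:
    """One accepted (parameters, initial state) pair per non-trivial regime.

    Per-label seeds are derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(SUITE_LABELS))
    return {
        label: sample_regime(
            RegimeSpec(label, int(child_seeds[j]), **spec_overrides)
        )
        for j, label in enumerate(SUITE_LABELS)
    }


def sample_ensemble(
    seed: int, n: int, labels: tuple[str, ...] = SUITE_LABELS, **spec_overrides
) -> list[tuple[str, ParameterSet, EpiState]]:
    """``n`` regime-sampled parameter sets, cycling through ``labels``."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for j in range(n):
        label = labels[j % len(labels)]
        params, init = sample_regime(
            RegimeSpec(label, int(child_seeds[j]), **spec_overrides)
        )
        out.append((label, params, init))
    return out
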