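# Methods

## Model

Two species interact through intraguild predation: interference
competition in both directions plus consumption of species 2 by
species 1 with a linear (Holling type-I) functional response. The
abundance model is

    dN1/dt = r1 N1 (1 − (N1 + p N2)/k1) + ε a N1 N2
    dN2/dt = r2 N2 (1 − (N2 + q N1)/k2) − a N1 N2.

Assumptions: both species grow logistically in isolation (the predator
is a generalist, so it persists without this prey), `r_i = b_i − d_i > 0`,
and all interactions are density-dependent with constant coefficients.

Each species hosts its own SI pathogen. Births (all susceptible) and
deaths are made explicit, transmission is density-dependent
(`β_i S_i I_i`), and infection alters neither demography nor
competitive/predatory performance — the "healthy reservoir" setting.
Consequently the compartment model is exactly compatible with the
abundance model: summing the `S_i` and `I_i` equations recovers it, and
every property proved on totals carries over. There is no recovery and
no disease-induced mortality; with vital dynamics this still yields
nontrivial endemic levels instead of total infection.

Composite coefficients used throughout:
`α1 = r1 p/k1 − ε a` (net prey→predator pressure, either sign; negative
when the predation benefit outweighs competition) and
`α2 = r2 q/k2 + a > 0` (net predator→prey pressure).

## Parameters

| name | meaning | units | demo value |
| --- | --- | --- | --- |
| `b_i`, `d_i` | birth / death rate | 1/time | 1.2/0.2, 1.5/0.5 |
| `k_i` | carrying capacity | individuals | 100, 100 |
| `p`, `q` | interference pressures | — | 0.2, 0.2 |
| `a` | predation efficiency | 1/(ind·time) | 0.005 |
| `ε` | conversion efficiency | — | 0.5 |
| `β_i` | transmission rate | 1/(ind·time) | 0.02, 0.1 |

`r_i` and `α_i` are always derived, never inputs: supplying `r_i`
separately from `(b_i, d_i)` could silently change the epidemic
dynamics while leaving the abundance dynamics intact, so the
serialization layer rejects such keys outright.

The demo values define the package's canonical scenario
(`canonical_parameters`, predator disease endemic) and, with
`β2 = 0.1`, the base sweep regime (`endemic_demo_parameters`, both
diseases endemic). They were chosen once for readable magnitudes —
populations of order 100, rates of order one, weak interactions — not
fitted to anything.

## Equilibria

The abundance model has `E0(0,0)`, `E1(k1,0)`, `E2(0,k2)` always, and a
coexistence point `E*` solving the linear nullcline system

    (r1/k1) N1 + α1 N2 = r1,     α2 N1 + (r2/k2) N2 = r2,

feasible iff `α1 k2 < r1`, `α2 k1 < r2` and
`α1 α2 < (r1/k1)(r2/k2)` (the last makes the determinant positive and
the solution a genuine attractor). Strict inequalities are tested with
relative margin 1e−12; if the first two hold while the determinant is
below 1e−12 of its leading scale the system is reported degenerate
rather than divided through.

The SI model lifts these to the disease-free slice and adds endemic
variants gated by reproductive numbers: `E3/E4` (endemic disease in the
winning excluder, e.g. `E3 = (b1/β1, k1 − b1/β1, 0, 0)` iff
`R0^(1,1) ≥ 1`) and the coexistence family `E5/E6/E7/E*`. The endemic
coexistence susceptible densities follow from the infected nullclines
combined with the coexistence relations:

    β1 S1* = d1 + (r1/k1)(N1* + p N2*) = b1 + ε a N2*
    β2 S2* = d2 + (r2/k2)(N2* + q N1*) + a N1* = b2,

hence `S1* = (b1 + εaN2*)/β1` and `S2* = b2/β2`; each infected density
is positive exactly when the matching `R0 > 1`. Every equilibrium
reported as existing is verified by residual (max |rhs|/k ≤ 1e−9;
observed ~1e−15). The coexistence family's existence includes the
disease-free coexistence inequalities — its totals must sit at `E*` of
the abundance model. Equilibria exactly on a threshold (`R0 = 1`)
coincide with their infection-free counterpart and are flagged
`marginal`.

## Reproductive numbers

Closed forms: `R0^(1,1) = β1k1/b1` and `R0^(1,2) = β2k2/b2` at the
exclusion equilibria; at disease-free coexistence

    R0^(2,1) = k1 β1 N1* / (d1 k1 + p r1 N2* + r1 N1*)
    R0^(2,2) = (β2 k2 / b2)(N2*/k2).

Algebraic consequences used as cross-checks: `R0^(2,1) = N1*/S1*` and
`R0^(2,2) = R0^(1,2) · N2*/k2 ≤ R0^(1,2)` when `N2* ≤ k2`.

The independent oracle assembles the next-generation matrix by
linearizing the infected subsystem of the implemented right-hand side at
the given disease-free equilibrium, using the standard splitting: new
infections `F = ∂(β_i S_i I_i)/∂I_j`, transitions `V = F − ∂(dI_i/dt)/∂I_j`
(deaths, crowding drag, predation on infected prey). Derivatives are
central differences, which are exact here because the right-hand side is
quadratic in the state; R0 per disease is the spectral radius of the
corresponding block of `F V⁻¹` (the blocks decouple since the diseases
share no hosts). Agreement with the closed forms is required to 1e−8
relative and observed at ~1e−15.

## Stability

Jacobians are analytic (verified against central finite differences to
1e−6 relative in tests); eigenvalues come from `numpy.linalg.eigvals`.
A spectrum is called stable/unstable when the dominant real part is
beyond `±1e−8·max(r1, r2)`; inside that band the verdict is `marginal`
and no agreement is asserted. The analytic verdicts implement the
condition tables: `E1` stable iff `r2 < α2 k1`, `E2` iff `r1 < α1 k2`,
abundance coexistence stable whenever it exists (its Jacobian has
negative trace and, by the third existence inequality, positive
determinant); the SI equilibria add the matching `R0 ≶ 1` conditions,
with the coexistence family gated purely by the quadrant of
`(R0^(2,1), R0^(2,2))` relative to (1, 1). On 500-set sampled ensembles
the two routes agree on every non-marginal case. Bistability between the
two exclusion branches is possible (both `r2 < α2k1` and `r1 < α1k2`);
within the coexistence family at most one equilibrium is stable because
the quadrant conditions are mutually exclusive.

## Dynamics

`simulate` uses the Dormand–Prince RK45 pair with `rtol=1e−8`,
`atol=1e−10` — much tighter than typical defaults so that
equilibrium-matching tests are sharp. The default horizon is
`50/min(r1, r2)`; for convergence studies `settling_time` instead
returns `15/|Re λ_max|` at the target equilibrium, which covers slow
near-threshold modes. The orthant is forward-invariant; integrator
undershoots in `(−1e−9·max(1, k), 0)` are clipped to zero in reported
output, anything larger aborts with the offending state.
`detect_convergence` matches the final state against the catalogue at
tolerance 1e−3 (scaled by carrying capacity), requires the last 10% of
the trajectory within twice that, and raises rather than guessing when
two catalogue entries both match.

## Regime generator

The generator emulates "data" for this analysis: parameter sets
guaranteed to land in each of the nine equilibrium regimes. It
rejection-samples uniformly within bounds
`b_i ∈ [0.5, 2]`, `d_i ∈ [0.05, 0.5]` (with `b_i > d_i`),
`k_i ∈ [50, 500]`, `p, q ∈ [0.05, 0.8]`, `a ∈ [0.001, 0.05]`,
`ε ∈ [0.1, 0.9]`, `β_i ∈ [0.001, 0.1]`, accepting a draw when the
target's existence **and** stability predicates hold with a 5% relative
margin on every strict inequality. The margin keeps accepted regimes
decisively inside their region: reproductive numbers stay outside
`[0.95, 1.05]` (the band excluded by the threshold-behaviour checks) and
dominant eigenvalues stay bounded away from zero, so convergence
horizons remain practical. Initial states perturb the target equilibrium
by ±5% and seed absent compartments at 1–5% of the carrying capacity.
Sampling is deterministic per seed (`numpy` PCG64; per-label seeds
derived from the master seed). Failures report which predicate rejected
most often.

What the generator does **not** emulate: demographic or environmental
stochasticity, observation error, parameter correlations of real
communities, or seasonal forcing. Passing tests therefore certify the
deterministic model analysis — formulas, thresholds, stability
structure — not the fit of the model to field data.

## Sweeps and the dilution/amplification scan

`sweep` re-solves coexistence and the endemic densities on a
`(q, p) ∈ [0.1, 0.6]²` grid (51×51 by default; the range is standard for
this analysis, the resolution is the package's choice) under predation
scenarios `a × {0.5, 1, 2}` (scenario family declared, not inferred).
Cells without coexistence are masked; in unmasked cells
`I1* = max(N1* − S1*, 0)` and `I2* = max(N2* − b2/β2, 0)`, so
`I_i* > 0 ⇔ R0^(2,i) > 1` holds cell-by-cell.

The monotonicity report checks the directional claims with the axes
paired to the *receiving* host: prey-on-predator pressure `p` dilutes
the predator disease (`R0^(2,1)`, `I1*` nonincreasing in `p`);
predator-on-prey pressure `q` dilutes the prey disease (`R0^(2,2)`,
`I2*` nonincreasing in `q`); predation amplifies the predator disease
and dilutes the prey disease (`R0^(2,1)`, `I1*` nondecreasing and
`R0^(2,2)`, `I2*` nonincreasing in `a`). No claim is made for `I1`
along `q` or `I2` along `p`: suppressing a host's competitor releases
the host and generally *increases* its infections, and sampled regimes
confirm this. The predation-amplification direction for the predator
disease is itself regime-dependent (non-monotone cells occur in some
sampled coexistence regimes); the claims are therefore asserted only on
the shipped base regime, where all eight hold in every unmasked cell,
and reported as a scan (counterexample cells listed, never suppressed)
elsewhere.

## Verification battery

`scripts/acceptance.py --seed S --out results.json` recomputes, from
scratch at seed `S`: the worst scaled equilibrium residual and worst
NGM-vs-closed-form relative error over a 500-set ensemble; the
percentage agreement of the two stability routes and the percentage of
existing coexistence points that are spectrally stable; the worst
compartments-vs-abundance trajectory deviation (per unit of carrying
capacity) and the R0-threshold pass rate over the eight-regime suite;
and the dilution/amplification claim rate plus the base regime's
`R0^(2,·)` and endemic infected densities. Problem sizes (500 sets,
eight regimes, 51×51×3 grid) are the package's standard verification
sizes; the whole battery takes well under a minute on one core.

A separate check compares the implemented R0 formulas against the
published reference values of eight simulation panels; the generating
parameter sets are published only in the originating study's
supplementary material and are not redistributed here, so that check
requires a user-supplied `data/reference_panels.yaml` and fails with an
explanatory message otherwise.

## Known limitations

* Linear functional response only; no saturation (type II/III), so very
  large `a·N` products are extrapolations.
* No disease-induced mortality, recovery, or behaviour change; both
  pathogens are host-specialists with no cross-infection.
* Stability is local; basins of attraction and global dynamics are only
  probed empirically by the perturbation simulations. No limit cycles
  were observed in sampled regimes, and none are handled specially.
* The printed form of the endemic predator susceptible density in the
  source condition table is dimensionally inconsistent
  (`1/β1 + εaN2*/β1`); this package uses the nullcline-derived
  `(b1 + εaN2*)/β1`, which passes the fixed-point residual check.
* Exact-threshold parameter sets (`R0 = 1`) are measure-zero and
  reported as marginal boundary cases rather than analysed by
  centre-manifold methods.
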