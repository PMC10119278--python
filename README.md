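# igpepi — intraguild predation eco-epidemiology

`igpepi` analyses a two-species eco-epidemiological model in which the
species compete by interference **and** one preys on the other
(intraguild predation, IGP), while each species hosts its own
susceptible–infected (SI) disease. It is aimed at theoretical ecologists
and disease modellers studying how predation and competition produce
**dilution** (less transmission/prevalence) or **amplification** (more)
of wildlife diseases — e.g. for zoonotic reservoirs whose dynamics are
unaffected by infection.

## The model

Abundances `N1` (predator) and `N2` (prey) follow Lotka–Volterra
competition with a Holling type-I predation term:

```
dN1/dt = r1 N1 (1 − (N1 + p N2)/k1) + ε a N1 N2
dN2/dt = r2 N2 (1 − (N2 + q N1)/k2) − a N1 N2
```

with intrinsic growth `r_i = b_i − d_i > 0`, carrying capacities `k_i`,
interference pressures `p` (prey→predator) and `q` (predator→prey),
predation efficiency `a` and conversion efficiency `ε`. Splitting each
species into susceptibles and infecteds (`N_i = S_i + I_i`, all births
susceptible, transmission `β_i S_i I_i`, infection changing neither
demography nor interaction) gives a four-compartment system whose
pairwise sums recover the abundance model exactly.

The package provides, in closed form and numerically cross-checked:

* the **4 + 9 equilibria** of the two systems with their existence
  conditions (e.g. the fully endemic state has
  `S1* = (b1 + εaN2*)/β1`, `S2* = b2/β2`);
* **local stability** both from analytic Jacobian eigenvalues and from
  the tabulated inequality conditions, with agreement bookkeeping;
* the four **basic reproductive numbers**
  `R0^(1,1) = β1k1/b1`, `R0^(1,2) = β2k2/b2`,
  `R0^(2,1) = k1β1N1*/(d1k1 + p r1 N2* + r1 N1*)`,
  `R0^(2,2) = (β2k2/b2)(N2*/k2)`,
  plus an independent next-generation-matrix oracle;
* **simulation** (adaptive Dormand–Prince RK45) with convergence
  detection against the catalogue;
* **(q, p) × a sweeps** of `R0^(2,·)` and the endemic infected
  densities, with a monotonicity report that scans the
  dilution/amplification directions;
* a **regime generator** that rejection-samples parameter sets landing
  decisively in any of the nine equilibrium regimes.

## Worked example

```python
>>> import igpepi as ig
>>> pr = ig.endemic_demo_parameters()   # both diseases endemic at coexistence
>>> ig.coexistence_solve(pr)
EcoState(n1=101.44927536231884, n2=28.985507246376805)
>>> rep = ig.r0_report(pr)
>>> (rep.r0_21, rep.r0_22)
(1.5945330296127562, 1.9323671497584538)
>>> cat = {e.label: e for e in ig.epi_equilibria(pr)}
>>> cat["Estar"].state
array([63.62318841, 37.82608696, 15.        , 13.98550725])
>>> ig.classify(pr, cat["Estar"]).eig_verdict
'stable'
```

Disease-free coexistence sits at `N1* ≈ 101.4` predators and
`N2* ≈ 29.0` prey. Both coexistence reproductive numbers exceed one
(`R0^(2,1) ≈ 1.59`, `R0^(2,2) ≈ 1.93`), so both diseases invade: the
fully endemic equilibrium carries ≈ 37.8 infected predators and ≈ 14.0
infected prey and is locally asymptotically stable — trajectories
started nearby return to it (`ig.simulate`, `ig.detect_convergence`).

The same pipeline is scriptable from the shell:

```sh
igpepi regimes --seed 1 -o regimes/          # one config per regime
igpepi simulate -c regimes/regime_Estar.yaml -o trajectory.csv
igpepi sweep -c regimes/regime_Estar.yaml -o sweep.csv --report report.json
```

## Layout

| module | contents |
| --- | --- |
| `igpepi.model_core` | `ParameterSet`, state types, right-hand sides |
| `igpepi.equilibria` | closed-form equilibrium catalogue |
| `igpepi.stability` | Jacobians, eigenvalue + condition verdicts |
| `igpepi.reproduction` | closed-form R0s and the NGM oracle |
| `igpepi.dynamics` | RK45 simulation, convergence detection |
| `igpepi.sweeps` | (q, p) × a grids, monotonicity report, heatmaps |
| `igpepi.regimes` | per-regime rejection sampler |
| `igpepi.cli` | `igpepi` command with six subcommands |

See `docs/methods.md` for the mathematical background, numerical
choices and known limitations.
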