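# mabkin

Kinetic modelling and multistep particle-swarm parameter estimation for
hybridoma monoclonal-antibody (mAb) batch cultures.

## The problem

Murine hybridoma cells grown in batch culture secrete IgG while consuming
glucose, glutamine and supplemented amino acids.  A practical dynamic model
of such a culture tracks 11 extracellular metabolites — glucose (GLC),
glutamine (GLN), glutamate (GLU), asparagine (ASN), aspartate (ASP), lactate
(LAC), alanine (ALA), proline (PRO), antibody (MAb), biomass (BM) and
ammonia (NH₃) — coupled through nine lumped macroreactions, plus viable (X)
and dead (X_d) cell densities:

```
dξ/dt  = K · φ(ξ)                       (batch: no exchange with environment)
φ_i    = φ_i* · X · ∏_j  S_j / (K_Sj,i + S_j)     (compound Monod kinetics)
dX/dt  = μX − k_d X X_d   (t <  t_exp)
dX/dt  =     − k_d X X_d  (t ≥ t_exp)
dX_d/dt = k_d X X_d
```

`K` is the signed 11×9 stoichiometric matrix, `φ_i*` the per-cell maximum
rate of macroreaction *i* (pmol/(cell·h)), `K_Sj,i` a half-saturation
constant (mM), and the viable-cell equation switches from exponential growth
to decline at `t_exp = 54 h` of the 147 h batch.

The model has **23 kinetic parameters** (9 maximum rates, 12 half-saturation
constants, μ, k_d) that must be estimated from only 7 sparse concentration
samples per variable.  `mabkin` implements the full estimation machinery:

- shape-preserving cubic-Hermite (PCHIP) densification of the sparse
  measurements on a 0.1 h grid;
- a particle swarm optimizer with three coefficient regimes (scheduled
  inertia, Clerc constriction, time-varying acceleration coefficients);
- the **multistep scheme**: nine sequential PSO subproblems P1–P9, each
  minimizing a summed squared one-step-ahead explicit-Euler prediction
  error for a single balance equation, with parameters frozen forward
  (P1 biomass → P2 antibody → P3 proline → P4 alanine → P5 glutamine →
  P6 asparagine → P7 aspartate → P8 glucose → P9 cell dynamics);
- a Monte Carlo robustness study: Gaussian perturbation of every measured
  point by its reported standard deviation, re-estimation per replicate,
  exclusive-median quartile-fence outlier removal, and per-parameter
  spread reported as percent of the mean;
- a synthetic-data generator with a ground truth whose half-saturation
  constants lie inside the observed substrate ranges, so recovery of
  individual parameters (not just lumped slopes) can be tested.

It is intended for bioprocess modellers who need a reproducible, testable
implementation of this estimation workflow, with the batch measurement
table and three literature parameter sets bundled as fixtures.

## Worked example

Fit the model to the bundled measurements with the desk-scale profile
(50 particles, 100 iterations; `--full` gives 150×300) and simulate it:

```bash
mabkin fit --data bundled --seed 1 --out fit_out
mabkin simulate --params fit_out/params.yaml --out sim_out
```

The fit logs one line per subproblem and ends with

```
total objective 1540.88; parameters written to fit_out/params.yaml
```

`params.yaml` holds the assembled 23-parameter set, e.g. `mu: 0.0451`,
`kd: 0.0627` (1/h and per (10⁶ cells/mL)/h): the culture doubles roughly
every 15 h during the exponential phase.  `sim_out/trajectory.csv` contains
the 13-state trajectory; the overlay plot shows glutamine depleting to below
0.1 mM, a biomass plateau, and the viable-cell rise to ~0.9×10⁶ cells/mL at
54 h followed by decline.  Most half-saturation constants are not
individually identifiable from 7 samples (only slopes φ*/K are pinned
down), which the Monte Carlo study quantifies:

```bash
mabkin montecarlo --data bundled --n-reps 30 --seed 1 --out mc_out
```

`mc_out/summary.csv` lists each parameter's mean and SD%; μ comes out an
order of magnitude more stable (SD% ≈ 9) than half-saturation constants
such as K_S2,8 or K_S5,6 (SD% in the hundreds).

Synthetic data from the identifiable ground truth:

```bash
mabkin synth --noise cv --cv 0.01 --seed 3 --out synthetic.csv
mabkin fit --data synthetic.csv --seed 3 --out recovery_out
```

recovers μ and k_d to within a few percent.

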