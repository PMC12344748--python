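# coverdyn

Short-term (transient) versus long-term (asymptotic) stability of
cover-class-structured grassland communities under precipitation change.

## The problem

Grassland plots surveyed once a year yield coarse data: per species, a
percent cover between 0 and 100. Classical community models collapse each
functional group to a single abundance number and ask only whether the
equilibrium is asymptotically stable (eigenvalues of the community matrix
inside the unit circle). That view misses transient behaviour: a community
whose equilibrium is asymptotically stable can still *amplify* a
disturbance for years before it decays, because community matrices are
non-normal. `coverdyn` implements the full chain from raw cover tables to
that transient-stability verdict, for three functional groups (grasses,
legumes, non-leguminous forbs) under irrigation / control / drought
treatments.

## The model

Treat every **species as an individual** and its log percent cover
`x ∈ [0, log 100]` as its "size". Each functional group *k* then has
community analogues of vital rates, with the logged group totals
`u = (log N_g, log(N_l + e⁻¹), log N_f)` as covariates:

* **persistence** `s_k(x)` — Bernoulli, logit-linear in
  `{x, x², u_g, u_l, u_f}`;
* **expansion** `g_k(x, y)` — Gaussian in next year's log cover `y`, with
  mean and standard deviation each linear in the same terms;
* **colonisation** `f_k(y)` — Gaussian in the colonist's log cover, linear
  in the abundance terms only.

Each rate is selected from an all-subsets candidate family (2⁵ = 32 models
for persistence and expansion, 2³ = 8 for colonisation) by AICc within two
units, subject to a biological-plausibility screen (no runaway growth).
The selected rates define an annual integral projection model (IPM) per
group,

    n_k(y, t+1) = ∫ [s_k(x) g_k(x, y)] n_k(x, t) dx + c_k f_k(y),

discretised by the midpoint rule on m = 100 cover classes. The three IPMs
are coupled through the totals `N_k = ∫ eˣ n_k(x) dx` and iterated 300
years to equilibrium (all `|Δ log N_k| < 10⁻⁶` over the last 10 steps).

The **cover-class-structured community matrix** `C` (3m × 3m) is the
Jacobian of that coupled map at equilibrium. Its eigenvalues decide
asymptotic stability; its ε-**pseudospectra** decide transient stability:
with `ρ_ε(C)` the pseudospectral radius, the transient index

    T_ε = (ρ_ε(C) − 1) / ε,      sup_{ε>0} T_ε

lower-bounds the peak of `‖Cᵗ‖`. `sup T_ε > 1` with all eigenvalues inside
the unit circle means some perturbations grow before they decay —
transient instability under asymptotic stability.

No field data are bundled: a synthetic-survey generator runs the same
vital-rate models forward (5 blocks × 4 plots × 8 annual censuses, covers
recorded to ±0.5%), so every stage is testable by parameter and structure
recovery, and a fitted-coefficient CSV can be supplied to skip fitting and
run the IPM/stability stages on external estimates.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_generate_survey.py --seed 1
python analysis/02_fit_vital_rates.py
python analysis/03_simulate_equilibria.py
python analysis/04_assemble_community_matrices.py
python analysis/05_pseudospectral_stability.py
```

Output of the last three steps (seed 1):

```
irrigation : converged=True (step 92), equilibrium covers {'grass': 36.9, 'legume': 3.2, 'forb': 7.2} -> grass > forb > legume
control    : converged=True (step 46), equilibrium covers {'grass': 17.5, 'legume': 6.2, 'forb': 14.7} -> grass > forb > legume
drought    : converged=True (step 233), equilibrium covers {'grass': 5.4, 'legume': 33.8, 'forb': 54.5} -> forb > legume > grass

irrigation : 90x90 matrix, spectral radius 0.9789, finite-difference deviation 8.27e-10
control    : 90x90 matrix, spectral radius 0.7779, finite-difference deviation 6.20e-10
drought    : 90x90 matrix, spectral radius 0.9580, finite-difference deviation 2.23e-09

irrigation : rho=0.9789  sup T_eps=2.934 (eps=0.1)    peak ||C^t||=6.124 at t=1  -> transiently_unstable_asymptotically_stable
control    : rho=0.7779  sup T_eps=1.306 (eps=0.562)  peak ||C^t||=2.652 at t=1  -> transiently_unstable_asymptotically_stable
drought    : rho=0.9580  sup T_eps=1.989 (eps=0.178)  peak ||C^t||=4.033 at t=1  -> transiently_unstable_asymptotically_stable
```

Reading this: grasses dominate the watered equilibria while legumes and
forbs dominate under drought; every spectral radius is below 1, so all
three equilibria are asymptotically stable; yet every `sup T_ε` exceeds 1,
so each community transiently amplifies some perturbations (up to ~6-fold
under irrigation) before they dissipate. The finite-difference deviation
column is the independent cross-check of the analytic Jacobian.

The same pipeline is available as a CLI (`coverdyn synth | fit | simulate
| stability | run`) and as a library (`coverdyn.pipeline.run_pipeline`).

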