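# Methods

## Data model

A survey record is one species × plot × year percent-cover observation in
(0, 100]; absence is encoded by the absence of a row, and an explicit zero
is rejected as a recording error. Species covers are summed within each of
three functional groups (grasses, legumes, non-leguminous forbs) to the
totals `N_g, N_l, N_f`; because canopies overlap, totals may exceed 100%.
Procedural- and ambient-control labels are merged to a single `control`
level by the reader (on by default).

All modelling happens on natural-log cover, bounded by `L = log 1 = 0` and
`U = log 100 ≈ 4.605`. Legume totals can be exactly zero, so the legume
covariate is `log(N_l + e⁻¹)`; the offset makes the covariate's lower
bound exactly −1. Grass and forb totals enter as plain logs; plot-year
pairs in which either is zero are dropped from the regression data with a
logged count (inventing an offset there would change the stated model).
During kernel evaluation — where a simulated group may collapse — grass
and forb totals are floored at `e⁻¹` percent, the same magnitude as the
legume offset and below the 0.5% recording resolution; this is a numerical
guard against log(0) extrapolation, not part of the fitted model.

Transitions are formed from every pair of consecutive calendar years
within a plot (the model's time step is annual; gapped years form no
pairs). A species present at *t* contributes a persistence row (and, if
still present at *t* + 1, an expansion row); a species absent at *t* and
present at *t* + 1 contributes a colonisation row with covariates taken at
*t*. A reappearance after a gap counts as a fresh colonisation. Covers
below 1% (possible at the 0.5% recording step) are clamped to `L` with a
logged count.

## Vital-rate models and selection

Persistence is a Bernoulli GLM with logit link, linear in
`{x, x², u_g, u_l, u_f}` (fitted with statsmodels). Expansion is a
Gaussian in next year's log cover with *mean and standard deviation each
linear* in the same terms; colonisation is the same family in the
abundance terms only. The heteroscedastic Gaussian roles are fitted by
joint maximum likelihood with an analytic gradient (BFGS); standard errors
come from a finite-difference observed information matrix. Evaluated
standard deviations are floored at `σ_floor = 10⁻³` on the log-cover
scale during optimisation and kernel construction. Joint ML (rather than
two-stage residual regression) is used because it makes the likelihood —
and hence AICc — well defined; the mean and SD sub-models share one
included-term subset per candidate, keeping the candidate counts at
2⁵ = 32 (persistence, expansion) and 2³ = 8 (colonisation).

Selection: candidates within two AICc units of the minimum
(`AICc = −2 logL + 2k + 2k(k+1)/(n−k−1)`, k counting every estimated
coefficient including SD-model terms) are considered in order of (AICc,
parameter count, canonical term order), and the first *biologically
plausible* one wins; if none in the window passes, the window widens to
all candidates with a logged warning. Perfect separation (flagged by
statsmodels warnings or exploding coefficients/SEs) and non-convergence
exclude a candidate.

**Plausibility screen.** "No runaway growth" is operationalised as a
300-year single-group projection from the observed initial abundances
(other groups' totals held at their observed values) that must (i) stay
finite, (ii) keep total cover below a cap of 10⁴ percent, (iii) not pile
more than half its density against the mesh boundaries, and (iv) lose less
than 10% density-weighted mass past the bounds per year at its final state.
Conditions (iii)–(iv) catch growth models whose divergence the bounded
mesh would otherwise mask: runaway expansion shows up as mass stacked at,
or constantly evicted through, the upper bound. Because an implausible
choice in one role (typically expansion) can poison the screen for every
candidate of another role, roles are selected greedily — expansion, then
colonisation, then persistence — and a role whose selection fails outright
is retried after the others are pinned down. Cells with fewer than four
colonisation events (AICc undefined for every candidate) fall back to the
sample mean/SD of colonist sizes; with no events the colonisation rate is
zero and the size model is irrelevant.

## The coupled IPMs

Each group's kernel `K_k(x, y) = s_k(x) g_k(x, y) + f_k(y)` is discretised
by the midpoint rule (the standard IPM discretisation) on m = 100 cells
over `[0, log 100]`; Gaussian terms are evaluated as densities in y and
truncated at the bounds without mass return (eviction tolerance 1%, with a
per-column warning). Total cover is the cover-weighted integral
`N_k = ∫ eˣ n_k(x) dx` — a species at log cover x contributes eˣ percent —
chosen because the totals are defined as summed percent covers, not
species counts. Updates are synchronous: all three kernels are rebuilt at
the current totals, all densities advanced, then the totals recomputed, so
group order cannot matter.

**Colonisation placement.** The kernel sum places `f_k(y)` inside the
integral, which makes colonist inflow proportional to the current number
of resident species; taken literally it also makes total extinction
absorbing and lets the sparsest group be competitively excluded. The
package's default instead adds `c_k f_k(y)` as a density-independent
inflow each year — colonisation treated as independent of resident
abundance, which matches how the colonisation model is specified (no
dependence on resident cover), and makes the estimated rate `c_k`
(colonisation events per plot-year pair) dimensionally coherent with the
inflow. The literal in-integral placement remains available behind
`col_mode="density"`, where the fitted rate is instead scaled per resident
species-year. The community-matrix assembly and all tests cover both
modes.

Simulations start from the observed first-census species log covers binned
onto the mesh (averaged over the treatment's plots) and run T = 300 annual
steps; equilibrium means every group's log total changes by less than
10⁻⁶ per step over the final 10 steps. A realisation that is still
drifting at T = 300 is given further 300-step extensions (up to 10× total)
rather than a weakened criterion; runs with T below the convergence window
are never extended.

## The structured community matrix

With `v = (n_g, n_l, n_f)` the stacked mesh densities, the coupled map is
`F_k(v) = h K_k(N(v)) n_k (+ c_k f_k)` with `N_j = w_jᵀ n_j` and
`w_j[i] = e^{x_i} h`. The community matrix is its Jacobian at equilibrium:

    C_kj = δ_kj h K_k(N*) + [ h (∂K_k/∂N_j) n_k* (+ c_k ∂f_k/∂N_j) ] w_jᵀ

The kernel sensitivities are evaluated analytically through the logistic
and Gaussian forms (terms whose SD evaluation sits on the σ-floor have
zero derivative there); each feedback correction is an outer product, so
cross-group blocks have rank one, and with all cross-group coefficients
zero the matrix is exactly block-diagonal. A central finite-difference
Jacobian of one simulation step (step size 10⁻⁶·N_j per coordinate) is
kept as an independent oracle; the test suite requires agreement to 10⁻⁶
relative at 20 cover classes, and observed agreement is ~10⁻⁹. Asymptotic
stability is judged against the unit circle (discrete-time convention).

## Pseudospectral analysis

All norms are spectral 2-norms, the norm under which the pseudospectrum
equals a smallest-singular-value sublevel set and the normal-matrix closed
form `ρ_ε = ρ + ε` holds. `σ_min(zI − M)` is evaluated after a one-time
complex Schur reduction (orthogonal similarity leaves singular values
unchanged; tests assert agreement with the direct dense SVD to 10⁻⁸).

The pseudospectral radius is located by polar search: a uniform angle grid
(180 directions by default; half-plane only for real matrices, whose
pseudospectra are conjugate-symmetric) always augmented with the
eigenvalue directions, per-angle radial descent, and bisection to relative
tolerance 10⁻⁶. Two exact prunings keep this cheap: the ε-pseudospectrum
lies within the ε-neighbourhood of the numerical range, whose support
function (64 Hermitian eigenvalue problems) bounds each ray; and σ_min is
1-Lipschitz in z, so a radial step of `σ_min − ε` can never jump across a
boundary crossing. The supremum of `T_ε = (ρ_ε − 1)/ε` is taken over a
log-spaced grid (10⁻⁶…10², 49 points by default), processed in ascending
order so each radius seeds the next search; an argmax on a grid endpoint
triggers a too-narrow-grid warning. Classification: spectral radius above
1 + 10⁻⁸ → asymptotically unstable; otherwise `sup T_ε > 1 + 10⁻⁸` →
transiently unstable but asymptotically stable; otherwise stable, with a
borderline flag when `sup T_ε` sits within tolerance of 1.

## Synthetic surveys

The generator runs the fitted model family forward as a simulator: per
plot and year, each species persists with probability `s_k(x)`; survivors
redraw log cover from the expansion Gaussian truncated to `[0, log 100]`;
each group gains Poisson(`c_k`) colonists per plot-year with truncated
Gaussian sizes; covers are rounded to the 0.5% recording step and floored
at one step. Each plot owns a counter-based random stream (Philox keyed by
seed and plot index), so enlarging the design never perturbs existing
plots and a fixed seed reproduces the table bit for bit.

The default design mirrors a blocked precipitation experiment — 5 blocks ×
{1 irrigation, 2 control, 1 drought} plots, 8 annual censuses — with
initial richness 6/3/6 species (grass/legume/forb) per 1 m² quadrat and
initial log covers around 1–2 (≈ 2–7% cover), typical of species-rich
calcareous grassland. The default vital rates are self-limiting (each
group's own-total coefficient, −0.8 on the logit scale, dominates the
cross-group terms, −0.15 to −0.20) so the three groups coexist; under
irrigation all interactions are competitive and grasses are released,
under drought grasses are suppressed and the broad-leaved groups receive
small positive (facilitative) coefficients. Colonisation rates (0.3–0.9
species per plot-year per group) put colonisation near 10% of
species-years. These choices make the generator's equilibria land in the
tens of percent per group and produce the qualitative regime the analysis
studies — asymptotically stable equilibria with transient amplification.

What the generator does *not* emulate: observation error beyond rounding,
within-year phenology, block or year random effects (the fitted models
exclude them too), spatially explicit competition, and species identities
beyond labels. Passing recovery tests therefore show the estimators are
consistent for data generated by the model family itself — not that the
family is adequate for any particular field system.

**Truncation caveat.** The generator truncates Gaussian draws at the mesh
bounds (matching the IPM's no-eviction assumption), but the fitters assume
untruncated Gaussians; parameter recovery is therefore exact only when the
generating means sit well inside the bounds. The recovery experiment uses
such a parameter set (colonist mean 3.3 SD from the bound, expansion means
≥ 2 SD inside for the occupied range) with one merged treatment, 36 plots
× 8 years and ≈ 2,300 transition rows per group, and requires every
coefficient within 3 estimated SE in ≥ 95% of 200 replicates.

## Problem sizes

Library defaults follow the study design (m = 100, T = 300, 49-point ε
grid, 180 angles). The analysis scripts run m = 30 (90 × 90 community
matrices, 33 ε points, 90 angles) and the acceptance script m = 20 with 25
ε points, 60 angles and 25 recovery replicates — sizes at which the
midpoint rule is already within 1% of the refined-mesh equilibria (asserted
in the tests) and every reported quantity is stable to the grid choices.

## Known limitations

* The worked analysis is entirely on synthetic data; field estimates can
  be ingested through the fitted-coefficient CSV but none are bundled.
* The plausibility screen examines one group at a time with the other
  totals frozen; a trio of individually plausible models can still
  interact badly in the coupled run (the pipeline then reports the
  non-converged trajectory rather than silently proceeding).
* `sup T_ε` is a grid supremum; a maximiser between grid points is missed
  by at most the local curvature of `T_ε`, and endpoint maxima are warned
  about rather than extrapolated.
* The ε-pseudospectra are unstructured: perturbations `E` range over all
  matrices with `‖E‖₂ ≤ ε`, not only ecologically realisable ones, so
  `sup T_ε > 1` is a possibility statement about worst-case perturbation
  directions.
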