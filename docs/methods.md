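# Methods

## Mechanistic models

The core object is a `KineticScheme`: an ordered species list plus
elementary mass-action reactions, compiled to a stoichiometry matrix with
an analytic Jacobian and integrated with LSODA (`scipy.integrate.solve_ivp`,
relative tolerance 1e-8, absolute tolerance 1e-6 nM; both configurable).
Concentrations are in nM, time in s, second-order rates in nM⁻¹s⁻¹
throughout; μM appears only at I/O boundaries with explicit conversion.

**Single-nucleotide incorporation (scheme 1).**  Free enzyme binds
substrate DNA (k₁/k₋₁), the binary complex binds nucleotide (k₂/k₋₂), and
an irreversible chemistry step (k₃ = k_pol) produces the extended complex.
Product DNA exchanges with enzyme using the same k₁/k₋₁ as substrate DNA —
the two binding steps are asserted to share constants, as in the mechanism
the presets were measured under.  Pyrophosphate is not tracked (it appears
only as an irreversible product), and exonucleolytic excision is modelled
separately (below), not inside scheme 1: the chemistry step is treated as
irreversible.  The observable `product26` = [E·D₂₆] + [D₂₆] matches the
quantified product band.

Assumptions: ground-state nucleotide binding is an elementary reversible
step; translocation and PPi release are fast and folded into k₃; no
misincorporation (only the correct nucleotide is present).

**Processive polymerization (scheme 2).**  A ladder of sequential
irreversible incorporations `E·D_L → E·D_(L+1)` at per-position rates
kpol_i, with every intermediate exchanging with free enzyme.  The data only
determine the equilibrium K_d,DNA, so the association rate is fixed at a
diffusion-like default (k_on = 0.002 nM⁻¹s⁻¹, the value implied by the
wild-type K_d,DNA ≈ 9.9 nM and k_off ≈ 0.02 s⁻¹) and k_off = K_d·k_on is
derived.  Rebinding after dissociation is allowed (full mass action); a
`trap` flag disables it for trap experiments.  Observables are per-length
total DNA (`band_L` = [E·D_L] + [D_L]), matching the gel convention of
fractional band intensity × total DNA.  The per-position rates are
*effective* rates at the experiment's fixed 5 μM dNTPs; nucleotide binding
is not resolved in this scheme.

**Closed-form assays.**  Burst kinetics:
`[P](t) = A(1−e^(−k_obs t)) + k_ss·t`, with the steady-state DNA off-rate
k_off = k_ss/A.  Mismatch excision: `A₀e^(−k_exo t) + C`.

**Pre-incubation.**  Experiments pre-incubate enzyme and DNA before mixing
with nucleotide.  Rather than simulating the incubation, the initial state
partitions enzyme and DNA at the one-site binding equilibrium
(quadratic solution at the current K_d,DNA).  Crucially, this partitioning
is recomputed from the *current* parameter values at every objective
evaluation during fitting, so the pre-equilibrium is part of the model —
this is what makes a DNA-titration series informative about k₁ and k₋₁.

## Global fitting

`fit_global` minimizes the unweighted sum of squared residuals over all
courses of one or more `ExperimentSet`s simultaneously (per-point weights
are optional; the noise model of gel quantification is not known well
enough to justify a default weighting).  k₂ is fixed at its
diffusion-limited value of 0.5 nM⁻¹s⁻¹ unless overridden.

Numerical choices:

- Free parameters are optimized as log₁₀(rate): rates are positive and
  span five decades, and the log transform is what lets a trust-region
  least-squares method (lmfit/`least_squares`) converge to machine
  precision on noiseless data.  Reported standard errors are transformed
  back to native units.
- The finite-difference step is 1e-4 (in log units) so numerical
  derivatives stay above the ODE integration noise floor.
- Bounds default to [1e-6, 1e6] in native units.
- Multi-start: restarts perturb the starting guesses log-uniformly within
  one decade (seeded); the best of `n_starts` runs is returned with all
  start χ² values recorded.  Default 5 starts for exploratory fits; the
  replicated recovery studies use 2 starts from neutral guesses.
- Non-convergence is returned flagged (`success=False`), never silently.
  Identifiability diagnostics (missing covariance, >1.5-decade standard
  errors, |correlation| > 0.995, and the structural degeneracy of fitting
  k₋₂ and k₃ to a single nucleotide concentration) are recorded in
  `FitResult.warnings`.

Which parameters to free depends on the experiment.  A nucleotide
titration determines k₋₂ and k₃; the recovery studies therefore fix the
DNA-binding constants at their independently measured values (they are set
by the DNA-titration and burst experiments).  Freeing k₋₁ from a dNTP
titration alone leaves a k₃/K_d,app/k₋₁ compensation ridge on which
occasional noise draws place the global optimum far from the generating
values — a property of the design, not of the optimizer.  The combined
dNTP + DNA titration dataset constrains all four rate constants and is the
configuration used for contour analysis.

## Confidence contours

For a parameter pair, χ² is evaluated on a log-spaced grid (21×21 by
default) centred on the best fit; at each node the pinned pair is held and
all remaining free parameters are re-optimized, warm-started from the
nearest solved neighbour (sweeping outward from the centre).  The surface
is reported as normalized χ² = χ²_min/χ² ∈ (0, 1], and the confidence
region at threshold f is {χ² ≤ (1+f)·χ²_min}, i.e. normalized χ² ≥ 1/(1+f);
the default f = 0.10 reproduces the 10%-increase criterion.  Per-parameter
limits are the extreme values on that contour, log-interpolated between
grid nodes; the grid auto-expands (continuing its log spacing) up to six
times per side until the profile falls below threshold, after which a side
is flagged open (unbounded).  Nodes whose re-optimization fails are flagged,
never interpolated.  Node refits are capped at 40 residual evaluations
(warm starts make longer runs unnecessary).  A cheaper 1-D profile
(`profile_1d`) provides per-parameter limits without a partner.

The threshold is a χ²-increase construction, not a calibrated coverage
probability; the test suite reports empirical coverage on synthetic
replicates but none is assumed.

## Synthetic data

Generators emulate each experiment class at its standard design:

- single-turnover dNTP titration: 100 nM enzyme pre-incubated with 75 nM
  DNA, dATP grids 0.05–17 μM (S305R) or 0.2–10 μM (P1073L);
- DNA titration: 55 nM enzyme, DNA 10–300 nM, 100 μM dATP;
- burst: 100 nM enzyme, 350 nM DNA, 50 μM dATP;
- excision: 75 nM mismatched DNA, first-order decay;
- processive ladder: 150 nM enzyme, 75 nM DNA, 5- or 10-step ladders.

Noise is Gaussian with per-course σ = 5% of the course maximum + 0.5 nM
additive — typical scatter of quantified gel bands — and fully
configurable.  Zero-noise output is exactly the deterministic forward
model, and identical (design, seed) pairs are byte-identical on disk.

Sampling times default to log-spaced points spanning three half-lives of
the fastest phase, extended to cover a slower phase (DNA re-equilibration)
when present, 12 points per course; published figures show times only
graphically, so these are declared package defaults.  The burst window is
capped where the depletion-free burst equation would exceed the total DNA
present (product cannot exceed substrate); without the cap the of-maximum
noise convention would be set by an unphysical region of the curve.

What the generators do *not* emulate: radiolabel imaging physics,
gel-migration artifacts, base- or sequence-context-dependent rate
variation within a titration, enzyme inactivation over the time course,
and any misincorporation.  Passing recovery tests therefore demonstrate
estimator correctness and identifiability under the declared noise model,
not robustness to every artifact of real gel data.

## Degenerate inputs and tie-breaks

- Rates of exactly zero are valid in simulation (chemistry off, binding
  off) but derived parameters require positive denominators and raise
  otherwise.
- Burst fits raise a degeneracy error when no curvature is resolvable
  (amplitude or rate collapsing to zero); exponential fits of
  non-decaying data return k_exo ≈ 0 with a warning instead, since a flat
  excision course is a meaningful negative result.
- A perfect (χ² = 0) fit has no finite confidence contour; the normalized
  surface is defined as 1 at the optimum and 0 elsewhere in that case.

## Limitations

- The contour construction assumes the re-optimized surface is unimodal
  near the fit; far-off secondary minima would need a global search.
- Scheme 1 shares k₁/k₋₁ between substrate and product DNA; mechanisms
  with length-dependent binding need scheme 2.
- The processive model's K_d,DNA is identified mostly through the
  pre-incubation partition when dissociation is slow relative to the
  ladder; its uncertainty is correspondingly asymmetric.
- Replicated recovery studies use 20 replicates and 12 points per course,
  the sizes used throughout the test suite and acceptance script.
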