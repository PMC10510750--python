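# Methods

This note documents the models, numerical choices, and design decisions
behind emuflux, and states precisely what the synthetic-data tests do and
do not establish.

## Network model and total fluxes

Reactions carry atom maps (lowercase letters per molecule instance, unique
within an instance, coefficient-weighted balanced across the arrow unless
flagged `nocheck` for biomass-type pseudo-reactions). Molecular symmetry
(succinate, fumarate) is expressed by listing the same product twice with
two atom maps at coefficient ½ each; the EMU balances then average over the
two orientations automatically. Stoichiometric coefficients are stored as
exact rationals.

Each reversible reaction contributes two nonnegative total fluxes `r_f`,
`r_b` with net flux `r_f − r_b` and exchange flux `min(r_f, r_b)`; the
stoichiometric matrix S runs over balanced metabolites × total fluxes, and
the backward column is the negation of the forward one. Metabolite roles
are inferred from topology — never produced ⇒ labeling substrate, never
consumed ⇒ excreted — and can be overridden.

## EMU decomposition

Backward traversal from the target (measured) EMUs: for every EMU, each
atom-mapped reaction instance producing its metabolite maps the EMU's atoms
onto the reactant molecules; atoms landing on different reactants make a
condensation (convolution) node. Traversal is memoized per EMU and results
are sorted by canonical name, so decomposition is deterministic. Reactions
without atom maps are invisible to the traversal; an EMU with no atom-mapped
producer raises (unreachable from any substrate).

## Balance assembly

For size n, the internal EMUs split into *dynamic* rows (balanced
metabolites, which have pools and obey ODEs) and *output* rows (excreted
metabolites, whose MDV is the instantaneous flux-weighted average of their
producers — they are never sources themselves). The diagonal of A
accumulates each EMU's **total influx** rather than its metabolite's
consumption; the two coincide whenever S·v = 0, which every simulation and
fitting path guarantees by construction (and the simulator checks at
entry, tolerance 1e-6 relative). This keeps row sums exactly zero, which in
turn conserves MDV normalization both in the linear solve and along the
ODE integration.

Dilution of a pool P by metabolically inactive material (G-value, the
labeled fraction) is realized as a source substitution: every appearance of
P's EMUs as a labeling source is replaced by `G·x_P + (1−G)·natural`;
inside a convolution the mixture distributes over the product (bilinear),
doubling the variants per diluted constituent. For *measured* diluted pools
the same mixture is applied at the measurement model instead. Both scopes
are exposed (`DilutionSpec(met, "pool"|"measurement")`).

## INST integration (first-order hold)

Per size, `diag(c)·dX/dt = A·X + B·Y(t)` with X(0) at natural abundance
(cells grown unlabeled; the tracer switches at t = 0). The inhomogeneity
Y(t) is constant for substrate rows and time-varying for convolution rows
(computed at internal-grid resolution from the smaller sizes, which are
solved first). Each step holds Y linear and advances with the exact
solution via one augmented matrix exponential, cached per (size, step):
this is unconditionally stable and second-order in the step size (verified:
error ratios ≈ 4 under step halving). Two grid policies:

* **simulation** (default): step ≤ min pool turnover time / 20, uniform per
  output interval. τ/5 was tried first and left ~3e-6 endpoint error with
  multi-position tracers, violating the 1e-6 consistency target; τ/20
  costs 4× and reaches ~1e-7.
* **fitting** (`n_substeps`, default 8 per measurement interval): a fixed,
  parameter-independent grid. A turnover-adaptive grid makes the objective
  discontinuous in the pool parameters (the grid jumps), which breaks
  finite-difference gradients; the fixed grid keeps Φ smooth at a
  discretization error (~1e-5 in MDV units) far below the 1 mol%
  measurement noise.

If the normalization of any trajectory drifts beyond 1e-6 the grid is
refined geometrically and the integration repeated (at most 6 times).

Relaxation horizons: bidirectional exchange creates system modes slower
than any single pool's turnover, so "50× the largest c/v" does *not*
guarantee isotopic stationarity; consistency checks use 50× the *sum* of
turnover times (a transit-time bound, validated empirically on the toy
worlds).

## Constraint-based layer

FBA/FVA are plain LPs (HiGHS) over total fluxes with default bounds
[0, 1000]; degenerate optima are broken by a 1e-9 lexicographic secondary
objective. Feasible-flux sampling is coordinate hit-and-run on the null
space of S (burn-in 1000, thinning 10); directions are restricted to leave
coordinates pinned by equal bounds untouched, and the start is a
Chebyshev-style interior point that maximizes slack over the *non-pinned*
coordinates only (otherwise the LP is degenerate and returns a vertex the
walk cannot leave).

## Estimation

Parameters θ: null-space coordinates of the **net** stoichiometric matrix
(scaled by the measured-flux magnitude so all coordinates are O(1)),
exchange fluxes via `xch = 100·tan(πw/2)`, `w ∈ [0, 0.98]` (covers
exchange up to ~3000 on the uptake = 100 scale), G-values in [0, 1], pools
as log10. Every θ maps to an exactly balanced flux vector; box feasibility
(irreversibility, user bounds, measurement windows of mean ± 5 sd) enters
as linear inequality constraints.

The optimizer is SLSQP on **log Φ** — raw Φ spans ~10 orders of magnitude
between a random start and a noise-free optimum, which stalls SQP line
searches; the log makes the objective self-scaling, and `ftol` becomes a
tolerance on the relative change of Φ (default 1e-9, max 500 iterations).
Gradients are forward differences of Φ with per-parameter relative steps of
1e-6. Where a trial point leaves the feasible polytope and simulation
fails, the objective returns a graded penalty sloping back toward
feasibility instead of a flat cliff. Initial points: hit-and-run samples of
the FVA-bounded net-flux polytope; defaults 10 starts (steady state), 5
(INST). MDV standard deviations below 0.001 are floored at 0.001.

The residual Jacobian at the optimum is computed by forward differences
(relative step 1e-6) and feeds all statistics; the Gauss–Newton Hessian is
2JᵀJ. Reported quantities (net fluxes, exchange fluxes, G-values, pools)
are delta-method propagations of θ through their analytic transforms.

Monte-Carlo CIs refit `n_runs` datasets perturbed entrywise by N(0, sd²),
warm-started from the base optimum (single start — the perturbed optimum
is a small displacement of the base one), in parallel via joblib when
requested, with empirical quantile intervals; >20% failed runs is an error.

## Statistics

* χ²: two-sided acceptance band [χ²_{α/2,dof}, χ²_{1−α/2,dof}],
  dof = residuals − parameters; a suspiciously small Φ (overstated sds or
  overfitting) is rejected just like a poor fit.
* Normality: Shapiro–Wilk statistic plus normal-probability-plot quantile
  pairs.
* Covariance: pseudo-inverse of JᵀJ with singular values below 1e-8 of the
  maximum treated as null directions; quantities with a component along a
  null direction (e.g. both members of an unconstrained futile cycle) are
  flagged unidentifiable and reported with infinite intervals.
* Sensitivity: ∂(estimate)/∂(measurement) = D(JᵀJ)⁺Jᵀ/sd (first order);
  contribution matrix C_ij = S_ij²sd_j² / Σ_j S_ij²sd_j², row-normalized
  (rows with zero total variance are left as NaN rather than normalized).

## The synthetic world

`toynet1()` is a five-reaction network chosen as the smallest structure
exercising every code path: a cleavage, a condensation, a reversible
interconversion, and flux-dependent target MDVs. Conventions, fixed before
any test thresholds were evaluated:

* uptake 100 (all fluxes normalized to uptake = 100); other fluxes bounded
  by 300; pools B = 5, C = 3, D = 8 in units where turnover times are
  ~0.02–0.04 time units; INST sampling grid (0, 0.02, 0.05, 0.1, 0.2, 0.4).
* steady-state tracer: pure [1-¹³C]A. Measured fragments F_123, D_123,
  C_12 and E_1 — without E_1 the problem has an exactly unidentifiable
  one-dimensional flux family (verified: Φ = 0 at wrong fluxes), because
  both cleavage routes send B's labeled atom to E.
* INST tracer: 60% [1-¹³C] + 40% [U-¹³C] A at purity 0.997. A
  single-position tracer leaves atoms 2–3 of every metabolite at natural
  abundance for all time, so pool C would be structurally unidentifiable
  and the first-order hold would never be exercised (its Y(t) would be
  constant).
* noise: 1 mol% Gaussian per MDV entry, then clipped at 0 and renormalized
  (the generator can skip renormalization for exact-noise-model studies,
  e.g. χ² calibration, where the declared sd must be the true sd);
  declared sd = the noise level, floored at 0.001. The uptake measurement
  carries sd = max(1% of its value, the noise level).
* `random_toy_network(seed)` draws randomized atom-map permutations and
  cleavage positions around the same skeleton (parallel cleavage/
  condensation and isomerization routes), giving distinct labeling
  topologies per seed for the oracle cross-checks.

The exhaustive isotopomer simulator (`brute_force_*`) is the independent
oracle: it enumerates all 2ⁿ labeling states per metabolite (capped at 4096
total), solves the steady state by Gauss–Seidel fixed point (tolerance
1e-14) or integrates the full isotopomer ODE with adaptive LSODA
(rtol 1e-10), and marginalizes to MDVs. It shares no code path with the
EMU engine beyond the tracer definition.

**What a green test establishes:** the EMU cascade reproduces the exact
isotopomer physics (≤1e-9), the estimator recovers the generating
parameters in its own forward model under the declared noise, and the
uncertainty statistics are calibrated against that noise model. **What it
does not:** real MS data have correlated, non-Gaussian errors, imperfect
natural-abundance correction, fragment misannotation, and model
misspecification (missing reactions, compartmentation); none of these are
emulated. Real networks are supported through the readers (TSV dialect,
spreadsheet layout) but are not bundled.

## Known limitations

* Pools and fluxes are constant during the labeling experiment (the
  standard INST assumption); no time-varying fluxes.
* Nominal mass-shift MDVs only — no tandem-MS or positional isotopomer
  data.
* Local and Monte-Carlo uncertainty only; no profile-likelihood CIs, no
  global-optimization heuristics (gradient-based multi-start can miss the
  global optimum in strongly multimodal problems).
* Genome-scale (SBML) import and automatic atom mapping are out of scope:
  the engine targets atom-mapped core networks.
* The sensitivity matrix is first-order; its finite-difference validation
  is limited by refit termination noise (~0.1% relative on influential
  entries).
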