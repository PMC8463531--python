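# Methods

This note documents the models implemented in `microscape`, the
assumptions behind them, the defaults and why they were chosen, and
the limits of what the synthetic-data experiments demonstrate.

## Landscape chain

### Dissimilarity

Samples are rows of a non-negative abundance table. Profiles are
renormalized to relative abundance before any comparison; an all-zero
sample is an error (its frequency profile is undefined), never
silently dropped. The dissimilarity is the Jensen–Shannon divergence
with base-2 entropy and the convention 0·log 0 = 0, so values are
bounded in [0, 1]. The divergence itself — not its square root, which
would be a metric — is used throughout: no downstream step requires
the triangle inequality, and the bounded scale simplifies cover
construction. Computation delegates to
`scipy.spatial.distance.jensenshannon` (squared, base 2).

### Ordination

Classical scaling: B = −½ J (D∘D) J with J the centering matrix, then
an eigendecomposition of the symmetrized B. Axes with eigenvalue
≤ 1e-10 × the largest are dropped; coordinates are eigenvectors scaled
by √λ; *relative eigenvalues* are each retained λ divided by the sum of
all positive eigenvalues. JSD matrices are generally non-Euclidean, so
negative eigenvalues can occur; they are excluded from both the
embedding and the normalizing sum. All-zero distance matrices are
rejected as degenerate.

### Mapper cover and preimage clustering

The filter is exactly the first two principal coordinates; further
axes are reported but unused. Each axis is covered by
`intervals_per_axis` = 15 closed intervals of length
L = range/(k − (k−1)·overlap) with 70% overlap between consecutive
windows; the first and last window edges coincide with the data
min/max (with a 1e-12-relative guard against float round-off), and a
point on a shared boundary belongs to every window covering it —
deterministic membership. A zero-range axis degenerates to a single
all-covering window.

Every nonempty cover cell's preimage is clustered in the **original
JSD restricted to its members**, not in filter space: Mapper's
clustering step is conventionally done in the source metric, and the
low-dimensional filter discards exactly the information the clusters
should respect. Single-linkage merge heights, together with the
preimage diameter d_max, are histogrammed into 10 equal-width bins
over [0, d_max]; the cut is the left edge of the first *empty bin that
follows a populated one*, and the clusters are the single-linkage
components at that cut. Empty bins below the smallest merge height
carry no gap information and are ignored — otherwise a preimage of two
distant samples would always shatter. Without a qualifying gap the
preimage is one cluster.

### Attractors and basins

Singleton nodes (one member sample) are removed before attractor
detection, together with incident edges; their samples may end up
unassigned. Each sample's density surrogate is the distance to its
k-th nearest neighbour over **all** samples (default
k = ⌈√n⌉, clipped to [1, n−1]): large where the landscape is sparse,
small in dense regions. A node's potential is the mean over its member
samples. The density literature behind this construction modifies the
raw kNN values into a potential in an unspecified way; this package
takes the identity as the default modification and exposes one round
of neighbour-average smoothing as an explicit option (off by default)
rather than guessing further.

An attractor is a maximal connected set of equal-potential nodes none
of whose members has a strictly lower-potential neighbour (equality at
a 1e-12 relative tolerance, i.e. plateaus merge). Basins follow
steepest descent: repeatedly move to the adjacent node of minimal
potential, ties broken by the smallest node id — the tie-break makes
runs deterministic. A sample belonging to several nodes inherits the
basin of its lowest-potential node. Samples in no node (pruned
singletons) are unassigned and appear as their own category in
occupancy summaries.

### Behaviour on planted archetypes

On cross-sectional mixtures of K well-separated archetypes (see the
generator below), the chain recovers exactly K attractors for K = 3
and K = 4, with every assigned sample in the basin of its own
archetype. **K = 2 over-counts**: with two archetypes the second
filter axis carries only within-cloud noise, each cloud stretches
across the full 15-window cover on that axis, and occasional 2–3
sample preimage clusters survive singleton pruning with noisy mean-kNN
potentials that dip below their neighbours, creating spurious descent
sinks (typically 3–5 attractors instead of 2, each still pure, so
basin-assignment accuracy is unaffected). The effect is intrinsic to
the cover geometry: it persists across sample sizes (30–150 per
group), noise concentrations (200–5000; the cover is anchored to the
per-axis data range, so tightening the clouds is scale-invariant) and
neighbourhood sizes (k = 11–40). Interpret attractor *counts* on
quasi-one-dimensional configurations with care; basin purity is the
robust output.

## Community simulator

Both models act on I sites, each empty or holding one individual of
one of S metacommunity species. Defaults mirror the study conditions:
S = 50, I = 500, 600 timesteps, 450 replicates per parameter
combination, per-species migration probabilities drawn once per
combination from U(0, 1), positive-edge percentage of the interaction
matrix capped at 30% by random sign switching, interaction values
uniform on (−1, 1), diagonal self-limitation −0.5. Death and growth
rates are not part of the study's stated conditions; the package's
conventions are extinction_prob = 0.1 (per site per step) and
growth_prob = 0.5 (per reproduction event), both configurable.

**SOI** (self-organized instability) runs three phases per timestep in
fixed order: (1) *immigration* — each species, with its migration
probability, fills one uniformly chosen empty site; (2) *interaction/
growth* — I events, each drawing a uniformly random occupied site a
(species i) and a uniformly random other site b: an empty b is
colonized by i with probability growth_prob; an occupied b (species
j ≠ i) resolves by the asymmetry Δ = A[i,j] − A[j,i], the winner
overwriting the loser with probability min(1, |Δ|); (3) *extinction*
— every occupied site is vacated independently with probability
extinction_prob. Connectivity 0 means no interactions, and the
experiment driver dispatches that case to the neutral model.

**Hubbell** is zero-sum: every site stays occupied. Per timestep,
d = max(1, round(extinction_prob·I)) distinct individuals die and are
each replaced immediately — by an immigrant with probability
m̄ = mean(migration probabilities), species drawn proportionally to
those probabilities, otherwise by the offspring of a uniformly chosen
surviving individual.

Randomness is counter-based: one experiment seed spawns independent
streams per combination (matrix, fixed individuals, migration vector)
and per replicate, so reruns are bit-for-bit identical and no global
state is touched. Symmetric interaction matrices (Δ ≡ 0) provably
reduce to the zero-interaction dynamics, and with equal per-species
parameters the models are exchangeable under species relabeling — both
properties are exercised in the test suite.

## Beta-diversity statistics

The **Morisita overlap** uses the classic unbiased form,
λ_x = Σx(x−1)/(X(X−1)), so C may exceed 1 and the dissimilarity
d = 1 − C may be negative whenever within-community aggregation is
lower than cross-community overlap (alpha diversity exceeding beta
diversity) — the regime the simulations actually produce. The
Morisita–Horn simplification cannot produce C > 1 and is deliberately
not used. Each community needs total abundance ≥ 2 for λ to exist;
pairs violating this (extinct communities) are dropped with a warning.

Replicates are paired by a uniformly random perfect matching within
each parameter combination, each replicate used exactly once. Because
the gamma family needs a strictly positive response, the default
transform reflects the dissimilarity (y = −d) when all values are
negative, falls back to y = d when all are positive, then to the raw
overlap y = C; the choice actually taken is always returned and logged
with the run.

The **gamma GLM with inverse link** (μ = 1/η) is fitted by IRLS
authored in the package: working weights μ², working response
z = η − (y − μ)η², convergence when the relative deviance change drops
below 1e-8 (at most 50 iterations), initialization from the linear
least-squares fit of 1/y, and step-halving to keep the linear
predictor positive. Likelihood conventions follow R's `logLik.glm` for
the gamma family: dispersion φ̂ = residual deviance/n, log-likelihood
Σ log Gamma(y; shape 1/φ̂, scale μφ̂), and a parameter count of
coefficients + 1 for the dispersion — these conventions reproduce the
published AICc values from their printed log-likelihoods. Covariates
enter numerically (one slope each plus the product interaction), which
matches the published degrees of freedom (2, 3, 3, 4, 5 for the five
candidate models). The best-vs-complete comparison uses the scaled
deviance (dev_nested − dev_full)/φ̂_Pearson against a chi-square with
the coefficient-count difference as df; its size is well calibrated
(measured rejection rate ≈ 0.04 at nominal 0.05 over 1000 null
replications in the acceptance suite).

A known property of this (entirely standard) selection procedure:
when only connectivity has a true effect, AICc still picks a larger
model whenever the spurious likelihood gain of an extra slope exceeds
its ≈2-point penalty, so the connectivity-only model wins only ≈80% of
replications regardless of effect size — the familiar
P(χ²₁ < 2) · P(χ²₂ < 4) overfitting rate of AIC-type criteria with
numeric covariates. Categorical covariates would raise the penalty and
the selection rate, but would not match the published model
dimensions.

## Synthetic data generator

Archetypes are disjoint dominant-feature blocks blended toward the
uniform composition by the `separation` parameter (1 = fully disjoint
blocks, pairwise JSD ≈ 1; 0 = all uniform). Observed samples are
Dirichlet draws with parameter concentration·archetype + 0.05 (the
floor keeps zero-block features strictly positive, as JSD requires
nothing but it reflects that real functional profiles are rarely
exactly zero). Defaults — K = 3 archetypes, F = 100 features, 30
samples per group, concentration 300 (within-cloud JSD ≈ 0.06 against
between-cloud ≈ 0.96, i.e. ≥ 10× separation) — describe a strongly
metastable, cleanly sampled world.

Longitudinal trajectories start from mode-specific sparse compositions
and contract toward a target archetype by a fixed fraction
(`convergence_rate`, default 0.4) per timepoint, plus Dirichlet noise:
the succession-to-shared-attractor structure. Generational lineages
keep or switch archetypes with probability `drift` per generation:
drift 0 is perfect functional persistence, drift > 0 the observed
divergence. Proportions are emitted; a multinomial `to_counts` step
(default depth 10 000) produces integer counts for Morisita work.

What the generator does **not** emulate: compositional correlation
between functions (features are exchangeable within blocks),
overdispersion beyond Dirichlet, sequencing depth variation, partially
overlapping archetypes, and sample dependence within subjects beyond
the mean trajectory. Passing the recovery experiments therefore shows
the chain is correct and well-behaved under its own assumptions, not
that real functional tables are this clean.

## Numerical conventions and degenerate inputs

- Row sums are validated to 1 ± 1e-9 for relative tables; distance
  matrices to symmetry within 1e-12 and zero diagonal.
- PCoA axis retention threshold: 1e-10 relative to the top eigenvalue.
- Potential equality (plateaus): 1e-12 relative tolerance.
- Empty Mapper graph (everything pruned) yields an empty partition,
  with all samples unassigned — valid, not an error.
- TSV is the only on-disk format: tab separator, "." decimal, full
  float precision on write (round trips reproduce values to 1e-12).

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full grid at reduced
scale — communities of 40–200 sites, 40–150 timesteps, 12–40
replicates per combination, and the null/power studies at the study's
n = 2025 response rows — chosen so the whole battery completes in a
few minutes on one CPU while exercising every code path at the study's
design shape (3 × 3 grid, five candidate models, 225-pair arithmetic
at full scale where it is instant).
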