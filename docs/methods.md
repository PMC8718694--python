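# Methods

## Problem and model

Whole-cell models emit one flux time series per metabolic reaction per
simulated cell cycle.  After a gene knockout, some reactions leave the
behavioural range seen in wild-type cells; which reactions do so, and how
consistently, characterises the knockout's phenotype.  `wcflux` implements
the full interpretation pipeline:

1. **Features.** Each series is summarised by an ordinary least-squares
   line fit of flux on time: intercept β₀, gradient β₁, coefficient of
   determination R² = 1 − SS_res/SS_tot, and mean squared residual
   MSE = SS_res/n.  The four features capture level, trend, linearity and
   roughness.  A constant series has SS_tot = 0; the flat line fits it
   exactly, so R² is defined as 1 and the gradient as exactly 0.
2. **Feature PCA.** Per reaction, the pooled wild-type + knockout feature
   matrix is z-standardised (intercept and MSE live on incomparable
   scales; without standardisation MSE dominates) and projected on its top
   two principal components.  Loading signs are fixed by making each
   column's largest-magnitude entry positive, so scores are reproducible
   across linear-algebra backends.
3. **Weak labelling.** Three axis-aligned boxes around the wild-type
   scores act as labelling functions: the exact bounding box (extrema) and
   per-axis empirical percentile boxes at [0.5, 99.5] and [2.5, 97.5].
   Boxes are closed — a point on the edge is normal, since only points
   *outside* the wild-type range are abnormal.  The three binary label
   columns are combined by an agreement-weighted vote: each function's
   weight is its mean pairwise agreement with the others (a cheap accuracy
   proxy), the row's label is the side with more weighted mass, and the
   reported probability is that side's share of the total mass (hence in
   [0.5, 1]; unanimous rows get 1).  This is a deliberately transparent
   stand-in for a full generative label model; any backend satisfying the
   same contract can be slotted in.
4. **Classification.** One multilayer perceptron per reaction (four hidden
   layers, softmax output, Adam), fed the trajectory resampled to a fixed
   length (default 500 points) and min-max scaled per series, trained on
   the weak labels with a stratified 80/20 holdout.  The canonical
   hyperparameter grid is epochs {5, 10, 15} × batch {50, 100, 150} ×
   width {750, 1500, 2250}; brute-force grid search is available
   (`use_grid_search`) with ties broken toward fewer epochs, smaller
   width, larger batch.  Stratified k-fold cross-validation (default
   k = 10 when enabled) serves as the overfitting check.  Reactions whose
   holdout accuracy is below 0.70, or whose weak labels contain one class,
   are dropped.
5. **Flux profiles.** Each simulation becomes a binary vector over the
   retained reactions (1 = abnormal), the profile.
6. **Profile PCA.** Knockout profiles are reduced to two components by
   centred PCA without standardisation (bits share a scale).
7. **Network analysis.** The stoichiometric matrix S (metabolites ×
   reactions) is binarised and A = SᵀS, binarised with zero diagonal, is
   the reaction graph: an edge means two reactions share a metabolite.
   Driver nodes are the nodes unmatched by a matching; the default
   strategy is maximum-cardinality matching (minimal, iteration-order
   independent driver count), with a deterministic greedy alternative
   (single pass over lexicographically sorted edges) that reproduces the
   classic greedy maximal-matching approach and never yields fewer
   drivers.  Wild-type abnormality frequencies are fitted by a
   maximum-likelihood exponential (rate λ = 1/mean); the 95% quantile
   −ln(0.05)/λ is the noise threshold, and reactions whose group frequency
   strictly exceeds it form the per-class affected sub-network.
8. **Markers.** For each driver reaction with a retained classifier, a
   linear SVM (C = 1) on the 2-D profile scores is trained against that
   reaction's normal/abnormal split; training-set accuracy > 0.95 counts
   as linearly separable (the question is separability of the plotted
   cloud, not generalisation).  Association with each phenotype class is
   the phi coefficient of the 2×2 table (rows: reaction normal/abnormal;
   columns: in/out of class), φ = (ad − bc)/√((a+b)(c+d)(a+c)(b+d)).
   Under this orientation a marker whose *abnormality* tags a class has
   negative φ; the report selects the best class by |φ| and keeps the
   sign.

Phenotype classes are assigned from production flags (DNA, RNA, protein,
growth, division).  The slow-growing and septum-disruption classes share
the same printed flag row and are separated by an auxiliary
`division_initiated` flag (slow-growing cells start dividing near the end
of the cycle but do not finish; completed division implies initiation).
The DNA-disruption row is implemented exactly as printed
(no DNA production, RNA/protein/growth present, no division).  Unlisted
flag combinations raise rather than guess.

## Synthetic data

The generator emulates the qualitative variety of whole-cell-model fluxes,
not their mechanism: per reaction an archetype (steady, ramp, oscillation,
step, or Poisson-timed bursts) with Gaussian observation noise, and
per-simulation ±10% uniform jitter of the archetype parameters to mimic
the stochastic model's run-to-run variability.  Time grids default to a
50,000 s cell cycle sampled every 100 s (500 points) — full-cycle length
at desk resolution.  Knockout ensembles perturb a chosen reaction subset
(trend shift, amplitude shift, offset shift, or collapse to exactly zero
flux) with a dimensionless effect size in units of the wild-type
parameter's own scale, and record exactly those reactions as abnormal.
Negative fluxes are allowed (reversible reactions); nothing is clipped.

What the generator does **not** reproduce: mass-balance between reactions
(series are independent given their archetypes), realistic flux
magnitudes, regime switches mid-cycle, or correlated failures cascading
through the network.  Passing recovery tests therefore demonstrates that
the pipeline detects departures from a wild-type envelope under realistic
noise — not that it would reach the same accuracy on real whole-cell-model
output.

The reference study (`wcflux.benchmark`) fixes the conditions used by the
tests and the acceptance script: 20 reactions (four of each archetype),
60 wild-type simulations, four knockout classes × 50 simulations
(metabolic, RNA, protein, non-essential), effect size 6 with one
collapse-to-zero, and one marker reaction perturbed only in the metabolic
class.  Its stoichiometric network is a chain with the marker isolated
(an isolated node is always a driver) plus three transport reactions.
Perturbation modes in the reference study are trend shifts/collapses
rather than pure offset shifts: the classifier input is min-max scaled per
series, which deliberately removes absolute level, so a pure offset is a
weak-labelling signal (intercept feature) but invisible to the network.

## Numerical choices and edge cases

- Boundaries need ≥ 3 wild-type points; empirical percentiles use linear
  interpolation (numpy default).  Nesting ci95 ⊆ ci99 ⊆ extrema holds by
  construction.
- The label vote floors weights at 1e−6 so a fully disagreeing function
  cannot zero the vote; with two label values the winner's probability is
  always ≥ 0.5, and ties break toward normal.
- All stochastic stages (ensemble generation, train/holdout splits,
  network initialisation, shuffling, k-fold) take explicit seeds;
  per-reaction seeds are derived from the run seed by a fixed affine map
  modulo 2³¹.  Identical config + seed reproduces every reported number.
- An all-zero wild-type frequency vector makes the exponential fit
  degenerate: the threshold is 0 and a warning is emitted.  Identical
  flux profiles make profile PCA degenerate: zero scores, warning.
- The SᵀS diagonal is zeroed (self-adjacency carries no matching
  information).  Boundary metabolites are ordinary matrix rows, so two
  transport reactions sharing a boundary species are adjacent.
- Training-set sizes below the configured batch size shrink the batch to
  the training-set size.

## Design choices where the ground was open

- **Network input representation.** The trajectory itself (resampled,
  per-series min-max scaled) rather than derived features, matching the
  wide hidden layers; `classifier_input: features` switches to the 4-D
  regression features.
- **Default matching strategy** is maximum-cardinality matching: the
  driver count is then the structural minimum and independent of edge
  iteration order; the greedy variant is retained as a documented option
  because its result depends on edge order, which we fix lexicographically.
- **Exponential threshold reading.** The rate is the MLE from wild-type
  frequencies and the threshold is the 95% quantile of that fitted
  distribution; "consistently abnormal" uses strict inequality.
- **Desk-scale defaults.** The bundled configs train one grid point
  (width 750, epochs 15, batch 50 — the most gradient updates among the
  canonical grid values at reference-study sample sizes) instead of the
  full 27-point search; tiny demo ensembles use narrower, longer-trained
  networks, since a few dozen simulations give an MLP very few updates per
  epoch.

## Known limitations

- The weak-label vote cannot model correlation between the two percentile
  labelling functions; points in the percentile tails of the wild-type
  envelope are systematically flagged abnormal, so per-reaction weak-label
  accuracy against ground truth has a floor set by envelope coverage
  (~4/(n_wt+1) of unperturbed points fall marginally outside a 2-D
  bounding box built from n_wt reference points, for any continuous
  feature distribution).  Detection of genuinely perturbed simulations is
  unaffected.
- Driver-node analysis treats the reaction graph as undirected and says
  nothing about directed controllability.
- SVM separability is a descriptive statistic of the fitted cloud, not a
  validated classifier.
- Pathway annotation requires an offline reaction → pathway table; there
  is no live database lookup.
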