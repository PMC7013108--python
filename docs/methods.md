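# Methods

This note records the models, estimators, default parameters and numerical
choices behind `greganet`, and what the synthetic-data tests do and do not
establish about real tracking data.

## From antenna reads to residence intervals

The raw input is a stream of `(timestamp, tag_id, box_id, reader_id,
direction)` antenna reads. Field systems drop reads, so interval
reconstruction is deliberately conservative and auditable:

* Per animal, reads are scanned chronologically. An `in` at box *b* opens
  an interval; the next event closes it — an `out` at *b* closes it as
  `paired`, while any read at a different box closes it at that read's
  timestamp as `imputed_end` (an animal is in at most one box at once).
  `out` reads with no open interval are discarded and counted as orphans.
* Reads with `direction = unknown` are treated as enter/exit alternation
  within a box; a read at a different box while one is open acts as a
  handover (close + reopen).
* Any imputed closure, and any interval still open at the end of the data,
  is capped at `open + max_residence` (default **12 h**: long enough to
  span a sleep bout, short enough that a missed exit read cannot fabricate
  a multi-day residence).
* Every anomaly (orphan reads, zero-length intervals, unclosed intervals)
  is counted and reported, never silently dropped.

Intervals are half-open `[t_start, t_end)`; touching endpoints do not
overlap. This makes zero-measure contacts unambiguous.

## Co-location networks and degree

Two animals are connected within a 24 h window when, in some box, an
interval of one intersects an interval of the other for at least
`min_overlap` seconds (default **1 s**, i.e. any measurable co-residence;
exposed as a parameter). Qualifying intersection seconds are summed over
interval pairs and boxes into the edge weight. Windows are consecutive
24 h spans anchored at a configurable local clock time (default midnight);
intervals crossing a boundary are split and contribute to both windows.
Edges are found by a per-box sweep over start-sorted intervals; tests hold
this exactly equal to the all-pairs brute force on hundreds of random
instances. An animal's **degree** is its number of distinct partners in
the window; animals observed in the window with no partner get degree 0.

## Phenotype classification

The population distribution pools every animal-day degree over the
reference days (default the first **5** windows; per-animal means are
available by flag since the pooling convention is a genuine design
choice). Mean and sample SD (n−1; configurable) set the thresholds at
mean ± 1 SD. An animal is **high** (**low**) gregariousness when its
daily degree reached the high (low) threshold — inclusive, reading
"at least 1 SD" literally — on at least `n_required = 3` distinct days;
its score is the mean degree over the 3 most recent qualifying days
(first-3 and all-qualifying are options). Animals seen on fewer than 3
days can never classify and are reported with a reason code, as are
degenerate distributions (SD = 0) and the pathological both-sides case.

When a sex × phenotype cell has fewer strict qualifiers than the target
cohort size *k*, `relaxed_rank_selection` fills the remaining slots with
the animals whose mean degree most closely approaches the threshold from
the correct side of the population mean (for *high*: above the mean,
highest first), ties broken by lexicographically lower tag — a
deterministic version of "targeting the animals that most approached the
threshold" when a population cannot supply enough extremes.

## Assay processing

* **qPCR.** `R0 = (1+E)^(−Ct)` converts a cycle threshold to a relative
  starting-template concentration given the per-gene amplification
  efficiency `E ∈ (0, 1]` (E = 1 is perfect doubling; percent inputs are
  converted with a warning). Duplicate wells of one (sample, region, gene)
  are collapsed by mean Ct before conversion. Expression is normalized per
  sample and region to the β-Actin R0; samples lacking a housekeeping well
  are flagged and excluded from statistics rather than guessed.
* **Replicate QC.** Per sample × analyte: replicate mean and intra-assay
  %CV using the sample SD of the duplicates (the vendor convention is not
  standardized, so the convention is fixed and documented here);
  single-replicate rows report %CV as undefined, not zero. Means below the
  analyte's detection limit (serum defaults: 3.05 IFN-γ, 0.81 IL-1β,
  4.02 TNF-α, 16.9 corticosterone, pg/mL) are retained and flagged;
  substitution policies are deliberately not applied by default.
* **Outlier screen.** A value is flagged when it is at least
  `fold_threshold` (default **10**) times the overall mean of its analyte
  — a screen for the single runaway sample that dominates a small serum
  panel. Downstream ANOVAs are reported both with and without flagged
  samples; neither run is privileged.
* **Boxplot summaries** use type-7 (linear interpolation) quartiles, and
  whiskers at the most extreme point within `k × IQR` of the box ends.
  Upper and lower `k` are separate parameters (default 1.5 each) because
  published fence conventions for the lower whisker vary.

## Rank-based factorial ANOVA

The response is fit by rank regression: minimize Jaeckel's dispersion
`D(β) = Σ a(R(eᵢ)) eᵢ` with Wilcoxon scores `a(i) = √12 (i/(n+1) − ½)`,
mid-ranks on ties. `D` ignores the intercept, which is recovered as the
median of the residuals. The estimator has bounded influence in the
response and 0.955 asymptotic efficiency under Gaussian errors — suited to
small field samples with heavy tails, where least squares is fragile.

For the 2 × 2 sex × phenotype layout the full interaction model is coded
sum-to-zero (±1 columns plus their product); each term is tested by
dropping its column and measuring the dispersion increase:

    F_φ = [(D_reduced − D_full)/q] / (τ̂/2),  referred to F(q, n − p − 1),

with `p` the number of non-intercept parameters of the full model. With
near-balanced cells this drop-one-term scheme coincides with the usual
factorial decomposition; the coding is configurable. Empty cells are a
hard error naming the cell.

τ̂ is the Koul–Sievers–McKean window estimator of
`τ = [√12 ∫f²]⁻¹`: the density of pairwise residual differences at zero is
estimated in a window `t = q_δ(|eᵢ−eⱼ|)/√n` (δ = 0.80, or 0.95 for very
small n/p; the p smallest differences, degenerate by the fit, are
discarded), then inflated by the `√(n/(n−p−1))` degrees-of-freedom
correction and a Huber-type correction from the fraction of residuals
within 2 robust SDs of the median. The estimator is validated two ways:
consistency at the normal model (τ̂ → √(π/3) ≈ 1.023) and Monte-Carlo
type-I error calibration at the study's exact cell sizes (7/7/8/7), where
each term's null rejection rate at α = 0.05 must fall in [0.035, 0.065]
over 2000 replicates.

### Numerical choices

`D` is convex and piecewise linear, and — at factorial-cohort sizes — can
be *flat over a small face*: distinct slope vectors attain the same
minimal dispersion, and τ̂ computed from their residuals differs by a few
percent. A reproducible estimator therefore needs a canonical minimizer.
The `auto` solver solves the equivalent linear program exactly (L1
regression on the n(n−1)/2 pairwise differences, HiGHS) for n ≤ 60, which
returns a deterministic vertex to machine precision; above that, where
the LP becomes expensive, it switches to a subgradient-guided BFGS descent
finished by exact line minimizations (weighted medians of pairwise slopes)
along coordinates, the subgradient direction and a few deterministic
random directions. The descent route reaches the optimum to ~1e−6
relative dispersion (it can stall on a kink); the two routes are
cross-checked against each other in the tests, and every solution is
verified to be a local minimum under ±ε coordinate perturbations.
Perfect fits (zero residual spread) leave τ̂ undefined and are reported as
NaN rather than a fabricated scale.

Spearman correlations are mid-rank Pearson correlations with the
t-approximation p-value on n − 2 degrees of freedom, reported as `r_s(df)`;
they are invariant to monotone transformations of either variable.
No multiple-testing correction is applied anywhere — deliberately, so that
per-test behaviour stays interpretable; callers who need familywise
control must apply it themselves.

## The synthetic barn

`greganet.simulate` emulates the tracked population end to end with one
integer seed controlling everything (identical configurations give
byte-identical files):

* Each animal carries a latent class (**high**/**low** sociability,
  default half and half, stratified within sex) and a Dirichlet box
  preference over the 40 boxes — concentration 0.3 for low-class animals
  (a few favourite boxes), 10× flatter for high-class. Visits follow an
  inhomogeneous Poisson process with a cosine nocturnal peak at 02:00
  (amplitude 0.8), at 40 (high) vs 16 (low) visits/day with exponential
  durations of mean 45 min, truncated so an animal occupies one box at a
  time. These rates were fixed once so the pooled degree distribution
  resembles a dense barn population (≈ 26 ± 8 partners/day) with the
  class means separated by ≈ 2.5 within-class SDs, and were not adjusted
  afterwards.
* Every visit emits an `in` and an `out` read, each dropped independently
  with `miss_prob` (default 0.02; the real system's read-failure rate is
  unknown, so this is a plausible small value, and 0 is used wherever the
  tests need exact ground-truth reproduction).
* Ground truth (true classes, visit spans, daily edge sets by brute
  force, daily degrees) is recorded *before* read dropping, so the
  reconstruction can be scored against it.
* Assay values follow `baseline + sex_effect·1[M] + phenotype_effect·1[high]
  + N(0, noise_sd)`, truncated at 0, with multiplicative duplicate noise at
  the assay's intra-assay %CV. The default effect table plants: sex and
  phenotype elevations in serum TNF-α, a female elevation in serum
  corticosterone plus a rise of 12 pg/mL per minute of simulated handling
  time (expected Spearman with time-to-euthanasia ≈ 0.57), sex effects on
  hair testosterone/progesterone with a phenotype effect on progesterone,
  and null cytokines otherwise.
* qPCR wells follow `Ct = −ln(c)/ln(1+E) + N(0, 0.15)` where `c` is the
  relative expression times a per-sample input-RNA scale (log2 SD 0.5,
  median 2⁻¹²); the scale cancels in normalization, and with noise off the
  R0 pipeline recovers planted concentration ratios exactly.

**What passing on synthetic data shows — and what it does not.** The
generator exercises the pipeline's logic (interval pairing under read
loss, window splitting, thresholding, normalization, test calibration)
with known truth. It does not model spatial movement between boxes,
demography, social-group structure beyond shared box preference,
tag loss, antenna dead time, or correlated read failures; recovery rates
measured here are therefore upper bounds on what messy field data allows,
and the immune-endocrine effect sizes are plausible plants, not estimates.

## Problem sizes used by the tests and the acceptance script

Sweep-vs-brute-force agreement: 500 random instances (≤ 200 intervals,
≤ 20 animals, ≤ 10 boxes). Phenotype recovery: cohorts of 60 animals,
5 days, no read loss — 500 replicates in the test suite, 300 in the
acceptance script. Null calibration: 2000 replicates at n = 29 (7/7/8/7).
Estimator-vs-OLS efficiency: 25 replicates at n = 200. Power of the
planted TNF-α effects: 30 seeded cohort pipelines. These sizes are the
package's validation settings; all are parameters in the corresponding
functions.

## Known limitations

* The interval-pairing rules are heuristics; different hardware dialects
  (explicit dual-antenna direction vs undirected reads) are both
  supported, but systematically missing `out` reads bias residence times
  toward `max_residence`.
* The descent solver's ~1e−6 dispersion accuracy translates to F-statistic
  changes in the 4th significant figure at typical scales — negligible for
  inference, but the exact LP route is preferred (and default) at cohort
  sizes.
* The drop-in-dispersion F is asymptotic; its small-sample calibration is
  demonstrated at the 7/7/8/7 layout only, and other designs should be
  re-checked by simulation before trusting α.
* `relaxed_rank_selection` makes the sampled cohort partly
  *non-extreme* by construction; the sampled-cohort label is then a
  selection label, not a strict phenotype, exactly as in the field
  protocol it mirrors.
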