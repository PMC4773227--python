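# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic-data generator, and the numerical conventions used throughout
`cardiopanel`, in the spirit of the model documentation of statsmodels or
msprime: what is assumed, what is tunable, and what the tests do and do
not demonstrate.

## Differential-expression model

Expression values are log2-scale, probes × samples, assumed already
normalised.  For probe *g* with `n₁` cases and `n₀` controls, the
two-group fit gives means, their difference `d_g`, and the pooled residual
variance `s²_g` on `df = n₁ + n₀ − 2` degrees of freedom.

The gene-variance hierarchy is the standard empirical-Bayes one: the true
variances follow a scaled inverse-chi-square prior with degrees of freedom
`d₀` and scale `s₀²`, so the marginal distribution of `s²_g` is
`s₀²·F(df, d₀)`.  The hyper-parameters are estimated by moment matching on
`z = log s²`:

- `Var(z) = ψ′(df/2) + ψ′(d₀/2)` — the excess of the observed spread of
  `z` over `ψ′(df/2)` identifies `d₀` through trigamma inversion (solved by
  bisection in log space; non-positive excess ⇒ `d₀ = ∞`, i.e. no evidence
  of variance heterogeneity).
- `E(z) = log s₀² + ψ(df/2) − ψ(d₀/2) − log(df/2) + log(d₀/2)` then gives
  `s₀²`.

The moderated statistic is `t_g = d_g / sqrt(s²_post (1/n₁ + 1/n₀))` with
`s²_post = (d₀ s₀² + df s²_g)/(d₀ + df)`, referred to `t(d₀+df)` (normal
when `d₀ = ∞`).  At `d₀ = 0` this is exactly the ordinary pooled t — a limit
the tests exploit as an oracle.  The implementation is cross-checked against
Bioconductor limma on a small fixture and agrees to ~1e-8 in the
t-statistics and in the estimated prior.

Multiple testing uses Benjamini–Hochberg step-up (via statsmodels), checked
against a literal brute-force implementation of the step-up definition.

**Discovery Method 1** keeps probes with BH-adjusted p < α (default 0.05),
ranked by ascending p, capped at a configurable list length (default 636 —
a convention, not a constant of the method).  **Discovery Method 2** leaves
each sample out in turn, recomputes Method-1 significance on the remainder
(the full pipeline including re-estimation of the prior per fold), and
ranks probes by appearance count over the n folds.  The per-fold criterion
is the same BH α rather than a fixed per-fold top-K; probes never
significant in any fold are dropped.  Ties in every ranking are broken by
(statistic, then probe id lexicographically) so runs are reproducible.

## KNN evaluation protocol

Classification is k-nearest-neighbour with k = 3 and Euclidean distance on
the provided log2 values over the selected panel — no rescaling beyond
upstream normalisation, because the expression measures themselves are the
features.  With binary labels and odd k the majority vote never ties;
distance ties at the k-th neighbour are broken by training-sample order
(stable sort).  LOOCV classifies each sample against the remaining n−1.

Fold outcomes are coded 0 (wrong) / 100 (right); SR is their mean.  The
95% CI of any proportion metric applies `mean ± 1.96·sd/√n` (sample sd,
n−1 divisor, bounds rounded to integers) to the fold outcomes of the
samples in that metric's denominator — all samples for SR, true cases for
sensitivity, true controls for specificity, predicted positives/negatives
for PPV/NPV.  Bounds are deliberately not clipped to [0, 100]: a small
cohort with a middling SR genuinely produces a negative lower bound, and
clipping would hide how uninformative the estimate is.

Unbalanced cohorts are evaluated by repeated balanced subsampling (default
15 repeats): the majority class is subsampled without replacement to the
minority size, LOOCV is run, and point estimates and CI bounds are averaged
over repeats.  Repeat seeds derive from the master seed by repeat index.
Blind validation merges the training and test cohorts, adjusts for batch =
dataset-of-origin (see below), and classifies every test sample against the
full training set.

## Panel optimisation

All three optimisers score panels by LOOCV SR on the training cohort and
record ΔSR = SR_new − SR_previous per feature.  An incremental scorer
caches each feature's pairwise squared-difference matrix, so evaluating a
panel ± one feature is an O(n²) update; this is what makes wrapper search
over hundreds of features affordable.

**Greedy (Optimisation 1).**  Start from the top two ranked features
(never eliminated; no ΔSR defined for them), walk down the list adding one
feature at a time; ΔSR < 0 ⇒ permanent elimination, ΔSR ≥ 0 ⇒ retention.
The accepted-SR trace is non-decreasing by construction, which the tests
assert on every run.

**Random crossover (Optimisation 2).**  The ranked list is partitioned
into consecutive subsets of fixed size (default 53; the last subset may be
short).  Within each subset, members are scored sequentially; the first
member's ΔSR is taken against the chance-level baseline (the
majority-class success rate) — the natural "empty panel" reference — and
negative-ΔSR members are excluded from subsequent within-subset
cross-validations while keeping their position in the subset.  Each
generation, adjacent subset pairs exchange a random two-point segment (cut
positions shared by the pair, drawn within the shorter member's length; an
odd trailing subset sits out), and the population is re-scored.
Elimination marks reset each generation; after the final generation all
members are ranked globally by ΔSR (ties: original discovery rank, then
id) and the top m = 25 form the optimised list, returned with its joint
LOOCV SR.  A per-generation record marks subsets whose SR reaches the best
seen so far.

**Fittest-member crossover (Optimisation 3).**  Identical except for the
exchange: each subset replaces its q (default 5) lowest-ΔSR members with
the q globally best-ΔSR members from other subsets; donors keep their own
copies, a member already present is skipped for the next-best donor, and a
single-subset population makes the exchange a no-op.

The subset size matters: small subsets (≈20) let noise features in
signal-free subsets accumulate spuriously positive ΔSR from a low
baseline, diluting the global ranking; at the default 53 the planted-signal
recovery simulations recover ≥ 8/10 (typically 10/10) planted probes.  The
final classifier length is not forced to m; downstream selection may prefer
a shorter candidate.

## Batch adjustment and diagnostics

The adjustment is the parametric empirical-Bayes location/scale model:
genes are standardised against a design containing batch indicators plus
the class label (protecting the label keeps case/control signal out of the
batch estimates when cohorts are class-unbalanced — important here because
merged cohorts rarely share a class mix); per-batch additive effects get a
normal prior across genes and multiplicative effects an inverse-gamma
prior, with method-of-moments hyper-parameters and iterative refinement of
the posterior estimates (tolerance 1e-4, ≤ 100 iterations).  Zero-variance
genes are floored at 1e-8 with a logged warning.  The implementation
agrees with Bioconductor `sva::ComBat` (parametric, covariate-protected)
to ~1e-6 on a fixture, and adjusting already-adjusted data changes it by
< 1% in Frobenius norm.

Diagnostics: classical (Torgerson) multidimensional scaling — double-centred
Gram matrix of squared Euclidean distances, top eigenpairs; coordinates
defined up to rotation/reflection; exact for genuinely low-rank inputs —
with an option to embed only the n least differential probes (smallest
|moderated t|), the right panel for checking that residual structure is not
class-driven.  Quantile normalisation replaces each column's sorted values
by the across-column mean of sorted values, with average-rank interpolation
for ties.  QC summaries are per-chip five-number statistics.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, directly on the
log2 scale (no probe-level intensity simulation — every computation in the
pipeline operates post-normalisation):

- probe baselines `μ_g ~ N(8, 2)` (typical microarray log2 levels);
- gene variances `σ²_g ~ d₀·s₀²/χ²(d₀)` with defaults `d₀ = 4`,
  `s₀² = 0.25` (residual SD ≈ 0.5, typical for blood arrays) — the same
  scaled inverse-chi-square family the moderated-t model assumes, so prior
  recovery by the discovery module is a closed-loop test;
- the first `n_de` probes shifted by `effect_size` (default 2 log2 units)
  in cases; default cohort 15 + 15 samples, 1,000 probes, 50 differential;
- optional per-batch distortions: additive `N(0, sd)` offsets and
  multiplicative `exp(N(0, disp))` factors per gene acting on gene-centred
  residuals — matching the location/scale model the adjustment estimates;
  the batch-free matrix is retained so recovery can be scored;
- platform masking: each probe independently kept with probability
  `keep_fraction`, with an emitted source→target mapping table listing
  dropped probes as unmapped;
- multi-cohort generation shares the gene-level truth (baselines,
  variances, planted effects) across the discovery/selection/validation
  triplet while drawing independent sampling noise.

What this does **not** emulate: correlated gene modules, heavy-tailed or
intensity-dependent noise, probe cross-hybridisation, or any real GEO
cohort's distribution.  Passing tests therefore demonstrate that the
machinery is correct and recovers planted structure under the model's own
assumptions — not that any particular published accuracy would be
reproduced on real data.

## Problem sizes and determinism

The test suite and acceptance script use deliberately compact problem
sizes chosen to exercise every code path with comfortable margins:
1,000-gene cohorts for discovery, 200-feature ranked lists over 5 seeds for
optimiser recovery, 300-gene × 10-seed simulations for batch recovery,
10,000 simulated variances for prior recovery, and 5 independent
1,000-gene triplets end to end.  Every stochastic component takes an
explicit seed (child seeds derived by index via `SeedSequence`), and the
pipeline manifest records parameters and input hashes; identical config +
seed reproduces identical outputs bit for bit.

## Known limitations and open choices

- Only the parametric batch-adjustment variant is implemented; a
  nonparametric density-based variant exists in the literature but is not
  needed for this pipeline's contract.
- Discovery Method 2's per-fold criterion (BH α, not top-K) is one of two
  defensible readings; the alternative is a constructor flag away in
  `discovery_method2` if a rank cut-off is preferred.
- The ΔSR baseline for the first member of a subset (chance-level SR) and
  the reset of elimination marks each generation are documented choices
  where the procedure is genuinely underdetermined.
- CI bounds for sensitivity/specificity/PPV/NPV follow the same
  fold-outcome rule as SR applied to the metric's denominator samples;
  alternative conventions (e.g. Wilson intervals) would be better-behaved
  near 0/100% but are not what this protocol specifies.
- Wrapper selection with LOOCV SR on small cohorts overfits by
  construction; the pipeline's defence is the held-out selection cohort and
  the independent validation stage, not the optimiser itself.
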