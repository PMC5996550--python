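# Methods

`oligonet` re-implements, on synthetic cohorts, a network-based procedure
for prioritizing candidate cancer genes inside a recurrent chromosomal
co-deletion. The motivating setting is the 1p/19q co-deletion of
oligodendrogliomas: hundreds of genes on the two arms lose one copy at
once and are down-regulated together, so ordinary differential-expression
statistics cannot separate drivers from passengers. The procedure instead
asks which co-deleted genes, through a learned gene regulatory network,
exert unusually strong influence on cancer-relevant pathway genes —
unusual relative to random networks of the same complexity.

## Synthetic cohorts

Real tumor data is replaced by a generator that emulates the statistical
structure the analysis assumes.

**Genome.** `n_genes` genes in a fixed genome order, partitioned into
contiguous chromosome arms (default 300 genes over 1p, 19q, the eight
rarely mutated arms 4q/9q/13q/15q/18q/7p/7q/11q, and a neutral remainder).
Genome order is the only positional information used anywhere; functional
category flags (TF, kinase, oncogene, tumor suppressor, essential,
signaling, metabolic, ...) are sampled per gene at configurable rates.

**Copy number.** A fixed fraction of tumors (default 0.75, matching a
133-of-178 cohort composition) carries the two-arm co-deletion; both arms
share one per-tumor log2 depth drawn from [-1.0, -0.6]. Rare whole-arm
deletions and duplications are applied independently per tumor at the
frequencies reported for oligodendroglioma cohorts (e.g. 18q deletion
15%, 7p duplication 6%). Gene-level measurement noise is Normal(0, 0.05²);
normal references sit at zero. Co-deletion carrier counts are exact
(rounded fraction of the cohort), not Bernoulli, so fixtures are
deterministic.

**Expression.** A sparse signed ground-truth network is sampled as a DAG:
`n_regulators` genes get outgoing links to downstream genes in a random
topological order, with expected `mean_out_degree` (default 5.5) links
per regulator, coefficient magnitudes uniform on [0.5, 1.5], and 78%
positive (activator) signs. Regulator-target pairs closer than the
±50-gene local window are never linked: the inference stage excludes
local predictors by construction, so a truth with local edges would make
recovery ill-defined. Expression follows the same linear model the
inference stage fits, evaluated in topological order:

    x_g = u_g · cn_g + Σ_{r→g} β_rg · x_r + ε_g,   ε_g ~ N(0, σ²)

with unit copy-number dose u_g and σ = 0.2 by default. A counts mode
(Poisson around a per-gene baseline, `counts ~ Pois(b_g · 2^x)`) exists
only to exercise the CPM filtering path; log-ratio mode is the default.

What the generator deliberately does not model: probe-level aCGH noise,
read-level RNA-seq, tumor purity (the co-deletion depth range stands in
for it), point mutations, and any non-linear regulation. Passing tests
therefore certify the machinery under the model's own assumptions, not
robustness to violations of them.

## Mutation calling and differential expression

Per tumor, the mean copy-number log-ratio r_i over the co-deleted region
anchors adaptive thresholds: a gene is deleted if its log-ratio is below
0.5·r_i and duplicated above −0.5·r_i (the 0.5 scaling absorbs tumor
content and measurement noise). Tumors with r_i ≥ 0 are uncallable and
excluded from source selection rather than failing the run. An arm counts
as deleted/duplicated when ≥ 80% of its genes carry the call (inclusive
boundary); every arm event observed in ≥ 6 co-deleted tumors defines a
subcohort.

Differential expression against the normal references uses a two-sample
moderated t-test: per-gene pooled variances are shrunk toward a common
prior via the standard empirical-Bayes hierarchy, with prior df d0 and
prior variance s0² estimated by moment matching on log s² (digamma /
trigamma closed forms, no iterative fitting); the statistic is referred
to t with d0 + df degrees of freedom. d0 = 0 recovers the ordinary pooled
t-test exactly, and the implementation is cross-checked against the
reference R implementation in one test. Multiple testing uses q-values:
Benjamini-Hochberg scaled by a smoother-extrapolated π0 estimate, with a
BH fallback whenever the estimate leaves (0, 1] or fewer than 20 p-values
are available (the cubic extrapolation is meaningless for tiny families).
Genes at q < 0.05 are called up/down; Fisher's exact test (one-sided,
enrichment) quantifies per-pathway overrepresentation.

## Network inference

Each gene g is modeled from its own copy number plus the expression of
every gene farther than 50 positions away in genome order (the window
always contains g itself, so no self-edge is possible; local neighbors
are excluded because they would mostly re-encode the shared copy-number
state). Columns are standardized and the response centered. The
LARS-lasso path is computed under the objective

    (1/(2n)) ‖y − Xβ‖² + λ‖β‖₁,

so the first knot is max_j |⟨x_j, y⟩|/n. At the knot where predictor j
first enters with previously active set A, the covariance statistic

    T_j = ( ⟨y, Xβ̂(λ_next)⟩ − ⟨y, X_A β̃_A(λ_next)⟩ ) / σ̂²

is computed (restricted fits by exact piecewise-linear interpolation of
the lasso path on X_A), and p_j = exp(−T_j) under the asymptotic
standard-exponential null. σ̂² is the least-squares residual variance on
the largest support reached along the path when at least 10 residual
degrees of freedom remain, otherwise a plug-in from the terminal path
residual (flagged). The path length is capped at min(n−1, 100) steps
(configurable; scaled runs use 15–25 — late entries are never selected
at the cutoffs used). Per target, entry p-values are converted to
q-values with BH (the conservative π0 = 1 choice; the per-target family
is small), predictors at q ≤ 0.01 are retained, and coefficients are
re-estimated by unpenalized least squares on the selected support so that
prediction and propagation work with unshrunken effect sizes. The
copy-number column competes under the same penalty as expression
predictors. An ensemble of 10 networks (3 in scaled runs) is learned on
independent random splits with |train| = round(2n/3).

**What the models mean.** Per-gene predictive regression identifies
Markov-blanket structure, not causal orientation: in the model of a
regulator, its targets are genuinely predictive (they observe the
regulator's noise), and genes sharing ancestors or children also carry
real conditional signal. Recovered networks therefore contain
reverse-oriented and proxy edges whose covariance-test statistics are
honestly enormous. The recovery benchmark scores regulator–target
*pairs* (adjacency) for this reason, with sign agreement evaluated on
pairs recovered in the true orientation; directed precision is reported
alongside. This is the method's intrinsic resolution, not an estimator
defect — a caveat that applies equally to the biological interpretation
of edges learned from observational tumor data.

## Validation and connectivity

Each network predicts every gene in its held-out tumors (one-step, from
measured regulator expression); per-gene Pearson correlations between
predicted and measured expression summarize prediction quality, with
constant predictions stored as undefined and excluded from medians. The
same quantity is computed under degree-preserving random rewirings
(repeated directed double-edge swaps that reject self-loops and
duplicates; edge attributes travel with the source endpoint; 100·|E|
attempted swaps; 25 rewirings per network by default, 10 in scaled runs)
and compared with a one-sided rank-sum test, pooling all random
replicates.

The ensemble connectivity score counts, for each gene, its distinct
outgoing links by the number of networks containing them (count matrix
C), normalizes each nonzero column of C to sum 1, and sums rows. Genes
whose links recur across independently learned networks score high; on
recovery simulations the highest-out-degree truth regulators occupy the
top score decile. One-sided rank-sum tests compare score distributions
between an annotation category and its complement.

## Impact propagation and the permutation null

Impacts flow through M[t, r] = w_t · β_{r→t}, where w_t is target t's
held-out prediction quality clipped to [0, 1] (weighting optional). The
impact of a source on every gene is the truncated all-paths (walk) sum
Σ_{k=1..K} M^k e_source with K = 5, or (I − M)^{-1} M e_source in closed
form when the spectral radius of |M| is below 1. Because degree-
preserving rewiring of a largely feed-forward network creates short
amplifying cycles — and a super-critical |M| turns the truncated walk sum
into a measure of cycle amplification rather than of where flow goes —
M is rescaled to a spectral radius of 0.9 whenever it exceeds it,
identically for learned and permuted networks (relative edge weights
within a network are preserved; Katz-style gain bound).

A source's total impact on a pathway class is Σ_t |v_t| over the class
genes, self-impact excluded. Per source and class, the impacts under the
10 learned networks are compared with the per-network means over that
network's 25 (10 in scaled runs) rewirings by a paired one-sided
signed-rank test (exact for n ≤ 25; zero differences dropped, all-zero
→ p = 1); q-values are computed across sources separately per class, and
high-impact genes are called at q ≤ 0.05 for the co-deletion region and
q ≤ 0.1 for the smaller rare-arm subcohorts. Random networks reuse the
learned networks' quality weights so the null isolates topology.
Per-pathway signed profiles and single-target paired tests use the same
machinery on individual gene sets.

With 3 networks the smallest attainable paired p is 1/8, so scaled
3-network cohort runs cannot flag anything at q ≤ 0.05; the shipped
cohort run is demonstrative, and driver detection is benchmarked at 10
networks where the p floor is 1/1024.

## Benchmarks and their operating characteristics

Four standing evaluations (`oligonet.experiments`, run by
`analysis/06_benchmarks.py`, the acceptance tests and the acceptance
script):

- **Edge recovery** — 300 genes, 60 regulators, |β| ∈ [0.5, 1.5],
  σ = 0.2, 120 training tumors per network, 3 networks × 10 rewirings.
  Pair-level precision ≈ 0.6–0.75 across cohort seeds (directed ≈ 0.5),
  recall ≈ 0.75–0.85, sign agreement ≈ 1.0, held-out median correlation
  ≈ 0.9 and real ≫ random (rank-sum p below 1e-100). Residual false
  pairs are shared-ancestor proxies and collider co-parents (see above).
- **Covariance-test calibration** — global null at n = 50, p = 10: the
  first-entry p-value's type-I error at nominal 0.05 is ≈ 0.070 (the
  Exp(1) null is asymptotic and slightly liberal at this sample size).
- **Planted drivers** — 100 genes; three exogenous co-deleted genes each
  wired with eight β = 1 links into pathway genes placed on the second
  co-deleted arm (so each target's own copy-number predictor absorbs the
  shared dosage and attribution is identifiable); three isolated
  co-deleted passengers; 10 networks × 10 rewirings, 10 repetitions.
  Drivers are flagged at q ≤ 0.05 in ~9/10 repetitions and outrank
  passengers by median impact in 10/10. Passengers occasionally acquire
  stable small-magnitude proxy wiring that the signed-rank test (which
  has no magnitude floor) correctly detects — with dosage-collinear
  sources, "no passenger ever flagged" is not attainable, a limitation
  that carries over to real co-deletion cohorts.
- **Null calibration of the impact test** — an exchangeable null in which
  the "learned" network is itself one extra rewiring of the same base
  network: the flag rate at q ≤ 0.05 is ≈ 0 over 20 repetitions
  (comfortably below 5%).

## Numerical and reproducibility choices

All randomness flows from per-stage seeds derived from one master seed
via `SeedSequence`; rerunning a configuration is byte-identical, and
resumed runs (stages reloaded from disk) reproduce downstream outputs
bit-exactly — matrices are written at %.17g and parsed round-trip, and
correlation computations fix the array memory layout so summation order
cannot wobble the last ulp. Constant predictions are detected by exact
range, not by post-centering residuals. Lasso knot ties (measure-zero
with continuous data) resolve to the engine's internal order. Degenerate
inputs — tumors with non-negative region means, single-edge networks with
no valid swap, empty per-gene models, all-zero impact differences — are
handled as flagged no-ops rather than errors.

Scaled problem sizes used throughout (300-gene genomes, 3-network cohort
ensembles, 10-network driver benchmarks, 10 rewirings) are the package's
default study scale; the full 10-network × 25-rewiring configuration is
a config change (`inference.n_networks`, `validation.n_random`).
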