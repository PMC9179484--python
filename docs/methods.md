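# Methods

This note documents the statistical machinery, the synthetic-data model,
the defaults and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Statistical components

### SAM moderated difference

For two groups with `n₁`, `n₂` samples the per-gene statistic is
`d_g = (x̄₁ − x̄₂)/(s_g + s₀)` with the pooled standard error
`s_g = √[(1/n₁ + 1/n₂)(SS₁ + SS₂)/(n₁ + n₂ − 2)]`. Groups are ordered
lexicographically by label so that relabelling negates every `d` exactly;
callers can fix the orientation explicitly. With `s₀ = 0`, `d` is
identically the pooled-variance two-sample t statistic (asserted to
1e-12 in the tests).

`s₀` is the 5th percentile of the `s_g` distribution by default. The full
coefficient-of-variation minimisation over percentiles adds tuning noise
without changing ranks materially at these panel sizes; the fixed
percentile is deterministic and configurable (0 gives the plain t).

FDR follows the permutation recipe: order observed `d`, average ordered
`d` over label permutations (all distinct assignments when there are at
most 10,000, otherwise seeded uniform draws) to get expected order
statistics, call genes whose deviation exceeds `delta`, derive cut
thresholds from the called set, and estimate FDR as median permutation
false-call count over observed calls, capped at 1 (0 by convention when
nothing is called). Per-gene q is the FDR at the delta that just includes
the gene, monotonised so q never decreases as the call set grows.

### Enrichment engine

The running sum walks the ranking; hits add `|r|^p / Σ_hits |r|^p`,
misses subtract `1/(N − N_h)`; the ES is the running-sum value at the
first index of maximal absolute deviation. `p = 1` is the default
weighting, configurable. If every hit metric is zero (possible in
degenerate rankings) hits fall back to equal weights `1/N_h` so the
statistic stays defined.

The null is gene-set permutation by default (random same-size sets from
the ranked universe): it is cheap, calibrated under the null ranking, and
requires nothing beyond the ranking itself. Phenotype permutation
(relabel samples, re-rank with SAM each time) is implemented and
preferred when group labels with ≥ 7 samples per class are in hand.
Nominal p uses the sign-stratified add-one estimator `(b + 1)/(B + 1)`,
so p ≥ 1/(B + 1) and never 0. NES divides ES by the mean same-sign null
ES; FDR q compares each observed NES with the pooled sign-matched null
NES (null exceedance fraction over observed exceedance fraction, capped
at 1) and is monotonised Benjamini–Hochberg-style: each set's q becomes
the minimum raw q over itself and all less-extreme sets in its sign
stratum. Leading edge: members at ranks ≤ peak for positive ES, ≥ peak
for negative ES, in rank order; an exactly-zero ES yields an empty
leading edge with a warning.

Reversal antisymmetry (unweighted ES flips sign when the ranking is
reversed) holds exactly except when the extreme positive and negative
deviations tie in magnitude; the first-peak tie rule then picks the same
sign in both orientations. |ES| is always preserved.

### Elastic-net pathway selection

Pathway score = mean of per-gene z-scored expression over matched member
genes (pathways matching fewer than `min_genes = 2` are dropped with a
log). This transparent score is oracle-testable by direct summation and
keeps the selection stage independent of the enrichment engine.

Per drug, the continuous response is regressed on standardized pathway
scores with an elastic-net penalty; the alpha grid comes from the
coordinate-descent path, the penalty is chosen by seeded K-fold
cross-validation (folds split over sample-id-sorted lists, so selection
is bit-reproducible) with the 1-SE rule, and a pathway is selected for a
drug iff its coefficient is non-zero at that penalty. Retention requires
selection in at least `ceil(n_drugs/2)` drugs.

The l1/l2 mixing defaults to `l1_ratio = 0.95`. With an equal mix (0.5)
the ridge half shrinks the strongly predictive causal coefficients so
much that cross-validation is forced to a small penalty, at which point
most null pathways acquire small non-zero coefficients and the
non-zero-coefficient selection rule loses all specificity; because the
drugs share a latent sensitivity axis, those chance selections recur
across drugs and survive the majority-retention filter. A mostly-lasso
mix keeps the shrinkage bias small, the 1-SE penalty honest, and the
false-retention rate near zero while never losing the causal pathways in
the recovery benchmark. Pure lasso (1.0) behaves equivalently; 0.95
retains a trace of ridge grouping for correlated pathway scores. The
mixing, CV folds and retention threshold are all config-exposed.

Ridge-only (`l1_ratio = 0`) is rejected with an error for selection: no
coefficient is ever exactly zero, so "selected" would degenerate to all
pathways.

### Signature scoring

The per-sample score is the weighted average: sum of up-gene expression
minus sum of down-gene expression, divided by the total gene count.
Directions come from the sign of the per-gene Welch t (sensitive minus
resistant) on the training panel; genes with t = 0 are excluded.
Expression is per-gene z-scored before summation by default
(`mode="zscore"`): raw log2 summation weights genes by their absolute
expression scale, which is rarely intended; `mode="raw"` preserves the
literal formula and the mode is recorded in every output. Unmatched
signature genes are dropped from numerator and denominator alike, with
coverage logged; cohort validation flags results whose gene coverage
falls below 50%.

When two signatures are combined, a gene carried with opposite
directions is dropped with a warning, preserving the up ∩ down = ∅
invariant.

Associations use Welch's unequal-variance t with Satterthwaite degrees
of freedom; a result is "sensitivity-linked" when the mean score is
higher in the sensitive class. Across a signatures × drugs panel, raw p
is reported together with a Benjamini–Hochberg q per signature row.
Cohort validation scores the cohort with the signature exactly as frozen
from training — directions are never re-derived on the validation data,
which would leak labels.

### Metabolite enrichment

Welch t on log2 abundances per metabolite, fold change as the ratio of
arm medians, significance at unadjusted p < 0.05 by default (a BH-adjusted
mode is provided and labelled). Metabolites with zero variance in both
arms get p = 1 and a flag. Pathway over-representation is the one-sided
hypergeometric tail `P(X ≥ k)` with one pathway per metabolite
(multi-membership would change the universe counting and is excluded);
`fold_enrichment = (k/n)/(K/N)` is reported alongside, and the top-k
report sorts by ascending p, then descending fold enrichment, then
pathway id.

### Response clustering

Samples are clustered on per-treatment z-scored response vectors
(Euclidean distance, Ward linkage, both configurable) and the tree is cut
to `k` clusters (default 4). Linkage is computed by
`scipy.cluster.hierarchy` on the condensed distance matrix; its merge
order is deterministic given the distances, and exact merge-height ties
have probability zero for continuous responses, so partitions are
invariant to sample input order in practice (asserted on tie-free data).
The dendrogram exports as Newick with merge heights as branch lengths.
Cluster–mutation association is the phi coefficient with the two-sided
t approximation for its p-value.

## The synthetic-data model

`simulate_panel` emulates a profiled cell panel screened against a drug
family:

- Background genes are iid N(0,1) on the log2 scale.
- Each pathway has a unit-variance latent factor; member gene expression
  is `sign · factor + N(0, noise_sd²)` with `noise_sd = 1` by default.
  Member signs are +1 with probability 0.8: co-expression modules are
  predominantly positively loaded on their factor, and an unsigned mean
  z-score over a balanced ±1 pathway would cancel the factor entirely,
  leaving nothing for score-based selection to find.
- A per-sample latent sensitivity L ~ N(0,1) drives everything drug- and
  mutation-related. Causal pathway factors load on L with coefficient
  `effect_size / 2.184` (2.184 is the expected top-minus-bottom-tertile
  gap of a standard normal), so the standardized factor shift between the
  sensitive and resistant response tertiles equals `effect_size`; factors
  keep unit variance, and effects beyond ~2.18 saturate.
- Per-drug response latents are L plus drug noise (sd 0.4), mapped to %
  cell death by `100·logistic`; an lnIC50 dialect (`−latent + noise`) is
  available so both response conventions are exercised. Drugs therefore
  share the causal pathways but differ in noise, mirroring one signature
  associating with most — not all — drugs of a family.
- The mutation flag is Bernoulli with probability
  `clip(0.2 + 0.6·logistic(L), 0.05, 0.95)` — a detectable but noisy
  cluster–mutation correlation, not a deterministic marker.
- `simulate_cohort` restricts the generative model to the signature genes
  plus named background genes; responders and non-responders differ by a
  standardized per-gene shift of `effect_size` in the gene's signed
  direction, and degenerate label draws (fewer than two per class) are
  resampled. Cohort size defaults to 13 with responder fraction 0.5.
- `simulate_metabolite_table` draws log-normal abundances (log2 noise sd
  0.25), quadruplicate per arm, with the shifted metabolites packed into
  the first pathways.

What the generator does *not* model: probe/batch effects, heteroscedastic
microarray noise, correlated pathway overlap (pathways are disjoint by
default), copy number, or any mechanistic link between the metabolite
table and the expression panel. Passing tests therefore demonstrate that
the statistics recover planted linear-Gaussian structure at realistic
sizes and stay calibrated under the null — not that the biology of any
real panel would yield the same pathways.

## Benchmark problem sizes

The recovery benchmark runs 20 independent panels of 5,000 genes × 200
samples, 20 pathways × 25 genes (2 causal), 8 drugs, effect 1.5, with a
13-sample cohort per panel — large enough that tertile groups hold ~66
samples and pathway recovery is a property of the method rather than of a
lucky seed, and small enough to run on a laptop in about a minute.
Calibration uses 500 null gene sets / 500 replicate Welch tests / 20 SAM
null panels. Oracle equivalence uses 1,000 random enrichment instances at
N ≤ 50 and exhaustive hypergeometric enumeration at N ≤ 12, both at
1e-12 tolerance.

## Known limitations

- SAM per-gene q is a monotonised point estimate, not the full SAM
  delta-table; local FDR and multi-class variants are out of scope.
- Gene-set permutation p-values are known to be liberal relative to
  phenotype permutation on correlated real expression; on the simulated
  panels, set members are exchangeable under the null, so calibration
  holds. Use phenotype mode for correlated data.
- The elastic-net stage selects pathways, not genes, and makes no
  nested-CV claim about predictive performance.
- Gene identifiers match exactly (case-sensitive); no alias resolution.
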