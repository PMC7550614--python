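# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind pesignet, in the
order the pipeline runs them.

## Rank-product differential expression

For a two-class unpaired contrast with n₁ cases and n₂ controls, each of K
case–control sample pairings yields per-gene log2 differences that are
ranked across genes (rank 1 = largest difference; average ranks on ties).
The rank product `RP_g = (∏_k r_gk)^{1/K}` — computed as the exponential of
the mean log rank — is small for genes consistently upregulated across
pairings; the mirrored ordering gives the downregulation statistic
(`rank_down = G + 1 − rank_up`, exact under average-tie ranking). The
non-parametric statistic tolerates small, heterogeneous cohorts, the regime
this analysis targets.

**Pairing scheme.** All n₁·n₂ pairings are used when that count is at most
10,000 (the `PairingScheme.n_pairs_cap` default); above the cap, the cap's
worth of seeded random pairings is drawn. The pipeline runs with a cap of
800: on a ~50v110 contrast the full 5,000+ pairings multiply runtime
several-fold while leaving planted-gene recovery unchanged (60/60 in the
calibration cohort at either setting).

**Permutation null and pfp.** Class labels are permuted B times (default
B = 100, configurable). Every permutation contributes its RP values under
*both* orderings to a single pooled null of 2·B·G values — the two
orderings are mirror-exchangeable under the null, so pooling estimates the
same distribution with twice the sample, and it makes swapping the class
labels exchange the up/down results exactly on balanced designs (a
per-direction null only matches in distribution, not realization). For a
gene with observed RP_g at position r of the observed ordering:

* permutation p: `(1 + #{null ≤ RP_g}) / (1 + 2·B·G)` — add-one smoothed,
  never exactly zero;
* pfp: `(#{null ≤ RP_g} / (2B)) / r` — expected false positives at the
  gene's cutoff over its rank position, an FDR-like quantity. Stored
  unclipped (it can exceed 1); clip at 1 for display.

Genes are called DE at pfp < 0.05 per direction; the pathological case of a
gene passing both directions is excluded and logged. `rank_product` rounds
its log-mean to 1e-12 before exponentiating: distinct rank multisets differ
by far more than that, accumulated float error by far less, so
mirror-equal statistics compare as exactly equal when counted against the
null.

**Covariate residualization.** `residualize` replaces each gene's values by
ordinary-least-squares residuals on named phenotype columns plus an
intercept — a deliberate stand-in for surrogate-variable-style
heterogeneity adjustment when the nuisance structure is measured rather
than inferred (inferring it is out of scope). The pipeline residualizes
each condition contrast on the other three condition flags; without this,
genes planted in several conditions carry the other conditions' effects as
extra variance (≈ 0.8 SD at default settings) and replication power in
small cohorts collapses.

## Replication, intersection, sensitivity

Replication keeps a discovery gene when its two-sided replication p —
`min(1, 2·min(p_up, p_down))`, the standard two-sided reading of two
one-tailed rank-product p-values — is below α = 0.05 and its replication
direction (the smaller one-tailed p; sign of the mean difference on ties)
matches discovery. Direction concordance is the default and can be lifted
(`require_direction=False`); replication filters on permutation p rather
than pfp, with both exposed where relevant.

Intersection is by gene symbol across exactly four labelled signatures,
with exclusive (UpSet) counts for every non-empty subset; the counts
partition the union. Overlap-gene directions are taken from the PE
signature and cross-signature discordance is reported, not dropped.

The sensitivity contrast compares samples positive for all four conditions
against samples positive for none, calling genes at two-sided permutation
p < 0.05, and reports the percentage of the overlap signature recovered
(rounded to the nearest integer, with the raw count).

## Baseline-table statistics

`chi2_yates` is the Pearson chi-square with Yates continuity correction
(df = 1); `pooled_t_from_summary` is the equal-variance Student t computed
from group means, SDs and sizes. These two — not the uncorrected chi-square
or Welch t — reproduce the published baseline-table p-values this package
checks against (0.047, 0.025, 0.042), so they are the defaults; Welch and
Fisher's exact test are available. Zero-variance t inputs short-circuit
(p = 1 for equal means, p = 0 with a warning otherwise); zero-margin 2×2
tables are redirected to the exact test.

## Interactome modules

Edge lists (geneA, geneB, combined score) are filtered at score > 0.4
(strictly greater), self-loops dropped, reversed duplicates merged keeping
the maximum score. A signature's module is the induced subgraph on its
mapped genes; statistics are computed on the module subgraph: average
internal degree 2E/N, mean local clustering (0 for degree < 2), Brandes
betweenness normalized by (N−1)(N−2)/2, and the largest connected component
with a deterministic tie-break (lexicographically smallest member gene).

**Randomization nulls.** Both the edge-enrichment test and module closeness
draw random node sets of matching size from degree bins: nodes are sorted
by degree and grouped into bins of at least min(100, max(10, n/20)) nodes —
100 for real-interactome scales, shrinking on small synthetic graphs so
upper-tail degrees stay matched (verified within ~1% for planted modules).
Uniform sampling is available by flag. Empirical enrichment p uses add-one
smoothing, `(1 + #{null ≥ observed})/(1 + n_iter)`, so the attainable
minimum is 1/(n_iter+1); echoing a "p < 0.0001" claim requires
n_iter ≥ 10⁴.

**Closeness.** The observed statistic is the mean shortest-path length over
all reachable cross pairs (a gene shared by both modules contributes
distance 0); unreachable pairs are excluded from the mean and their
fraction reported so fragmentation is visible. The all-pairs convention is
the default because the published distance scale (observed ≈ 2.7 against a
random expectation ≈ 2.74) matches a network-average-distance scale rather
than a closest-distance scale; the symmetrized closest-distance convention
is retained as an option. The null repeats the statistic for n_iter
degree-matched random set pairs; z = (d_obs − μ)/σ, with z < −1.65 labelled
"significantly close" (one-sided normal p < 0.05). All-pairs distances are
computed once per interactome with a BFS-based all-pairs shortest-path
pass and cached.

## Ontology: ORA and Wang similarity

Over-representation is the upper-tail hypergeometric test per annotation
term with at least 3 universe genes (configurable), BH-corrected across
tested terms; the universe defaults to all genes on the expression platform
rather than the genome. Annotations are used as given (no ancestor
propagation); with propagated input tables the same machinery applies.

Wang similarity: a term induces S-values over its ancestor closure —
S(term) = 1, and S(ancestor) is the maximum over child edges inside the
closure of w(relation)·S(child), a dynamic program in topological order,
with the method's established contribution factors w_is_a = 0.8 and
w_part_of = 0.6. Term similarity is the shared S-mass over the total;
gene- and set-level similarities aggregate by best-match-average
(row maxima + column maxima over m + n). Similarities are computed within a
namespace; cross-namespace term pairs contribute 0 at the gene level (and
raise when compared directly). S-values are cached per (term, weights) on
the DAG, which makes set-level similarity linear in the number of gene
pairs.

## Cross-tissue replication

The overlap signature is filtered to genes with a non-missing value in
every sample of the second-tissue matrix; DE runs on the *full* matrix so
rank statistics remain genome-wide, then intersects with that subset,
calling genes at two-sided permutation p < α (pfp optional). The called
subset maps onto the interactome for module statistics and LCC size. The
trimester contrasts of a healthy-placenta design reuse this exact operation
with different group flags. Probe-to-gene collapsing keeps the source with
the highest mean expression when an expression matrix is supplied (first
occurrence otherwise, logged).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular array platform:

* **Cohort.** Genes draw a baseline mean ~ U(6, 12) log2 units and a
  biological SD ~ U(0.1, 0.3); samples add Gaussian noise with SD 0.5.
  Condition flags are independent Bernoulli per sample with default
  prevalences 47/157, 63/157, 104/157, 119/157 — the discovery design's
  condition frequencies at N = 157. Each condition plants a signature
  (defaults 60/75/68/49 genes, about 1/16 of the real contrasts' DE
  counts at 1000 genes) containing a common core (default 15 ≈ 238/16);
  outside the core the per-condition sets are disjoint. A planted
  (gene, condition) pair shifts positive samples by ±δ (default
  δ = 1.0 = 2·noise SD; sign random per gene, shared across conditions so
  "upregulated" counts stay coherent), and shifts stack additively across
  conditions. Everything is reproducible bit-for-bit from the seed.
* **Replication cohorts** reuse the discovery truth table with fresh
  samples and are case-enriched to prevalence 0.5 for their target
  condition, mirroring how replication cohorts are actually selected
  (e.g. 14 PE of 30; 10 asthmatic of 24).
* **Interactome.** A powerlaw-cluster (or Erdős–Rényi) background with
  planted modules receiving an extra within-module edge probability
  (default boost 0.3 in the pipeline) and optionally extra edges between
  consecutive planted modules (cross-boost) so planted signatures are both
  locally clustered and mutually close. Background scores are U(0.4, 0.95),
  boosted edges U(0.7, 0.99), all above the confidence filter.
* **Ontology.** A single-rooted DAG of typed is_a/part_of edges with
  configurable depth and a second-parent probability; each gene gets
  exactly `annotations_per_gene` random non-root terms.
* **Placenta.** A two-group matrix over the same genes in which a
  round-half-even `concordance` fraction of the blood core (default 0.41,
  the fraction of the blood overlap observed as DE in term placenta) is
  planted with the blood direction and effect; everything else is null.

What the generator does *not* emulate — batch effects and latent
expression heterogeneity, correlated condition prevalences, probe-level
artifacts, realistic gene–gene correlation, annotation realism — bounds
what passing tests show: they certify the statistical machinery (error
control, recovery, calibration of the randomization nulls) under the
assumed model, not performance on real arrays.

## Problem sizes and defaults

The default pipeline runs 1,000 genes, a 157-sample discovery cohort,
30/24-sample replication cohorts, B = 100 permutations, 999 enrichment
iterations (minimum attainable empirical p = 0.001), 300 closeness
iterations and a pairing cap of 800 — sizes chosen so a full run completes
in well under a minute on one CPU while every downstream stage operates in
its intended regime. Calibration studies in the test suite use 20 null
cohorts of 1,000 genes at 20v20 and a planted 40v40 cohort at δ = 2·noise
SD.

## Known limitations

* The pfp estimator shares one pooled null across genes; genes with
  atypical variance are not separately calibrated (the original method has
  the same property).
* Label-symmetry of the permutation p/pfp is exact only for balanced
  designs; for unbalanced designs the up/down results swap in distribution
  but not realization.
* Empirical closeness z assumes approximate normality of the null distance
  distribution when mapped to a one-sided p; for very small modules the
  null can be visibly discrete.
* The ontology similarity treats annotations as flat sets; no
  evidence-code weighting or information-content alternative is provided.
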