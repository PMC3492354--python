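# Methods

## Problem setting

`methcall` analyses array-based DNA-methylation profiles of the
neuroblastic tumor spectrum (neuroblastoma, NB; ganglioneuroblastoma,
GNB; ganglioneuroma, GN) against normal reference tissues (fetal brain,
FB; adrenal gland, AG).  The measurement unit is the Infinium beta
value — the per-CpG methylation fraction M/(M+U+offset) in [0, 1] —
arranged as a probes x samples matrix with an optional matched
detection-p matrix.  The package identifies probes and genes that gain
(hyperM) or lose (hypoM) methylation in tumors, intersects those calls
across several independent reference sets, and characterises the
resulting gene sets (chromosomal clustering, promoter CpG class,
Polycomb-target status, expression concordance).

## Quality control

Exclusions mirror standard Infinium practice and run before any
analysis:

* gonosomal probes (chrX/chrY per annotation) — removed so sex
  composition cannot masquerade as tumor biology;
* low-quality probes — detection p > 0.01 in more than 5% of samples,
  or more than 20% missing values;
* poor samples — detection p > 0.01 on more than 1% of probes.

All cut-offs are `QCConfig` fields.  The *mechanism* is the
reproducible content; the constants are conventional defaults, exposed
because published studies rarely state them.

## The three-criteria consensus caller

For one case-vs-reference comparison, a probe is differentially
methylated only when three deliberately different views agree
(`DiffMethConfig` defaults in parentheses):

* **A, threshold.** HyperM requires *every* reference beta < 0.25 and
  at least 10% of case samples > 0.75; hypoM is the mirror image.  The
  reference side is a strict all-samples condition — reading it as a
  mean would duplicate criterion B — and the case-side fraction is
  inclusive (>=), computed over non-missing values.
* **B, mean shift.** |mean(case) − mean(reference)| strictly greater
  than 0.25, computed pairwise over non-missing values; the sign fixes
  the direction, which must agree with A.
* **C, test.** Unpaired pooled-variance t statistic per probe
  (Welch selectable), assessed jointly across all probes by
  Westfall–Young free step-down maxT permutation and by
  Benjamini–Hochberg FDR on the raw permutation p-values; the criterion
  is q < 0.05.  When either group has fewer than 3 samples
  (`min_group_for_ttest`) a two-sample test is meaningless, so the
  criterion is marked not-applicable, the call rests on A ∧ B, and the
  output carries a `test_skipped` flag.  This pathway is forced by the
  study design this package emulates: two of the three reference sets
  are single tissues.

Zero-variance probes get t = 0 when the means agree (uninformative) and
a large finite sentinel when they differ; significance is always
settled by the permutation distribution, never by a t reference
distribution.  Testing is two-sided (|t|) throughout, because both
directions are reported.

### Permutation machinery

If the number of distinct two-group relabellings C(n, n_case) is at
most 20 000, all are enumerated (the identity split is one of them, so
p >= 1/B by construction); otherwise `n_perm` (default 10 000) random
relabellings are drawn and the add-one estimator
p = (1 + #{perm >= obs}) / (1 + B) keeps p positive.  Step-down
adjustment: order probes by decreasing |t|, take successive maxima of
the permuted |t| from the least significant probe upward, compare with
the observed values, then enforce monotonicity by a running maximum.
Permutations are processed in chunks of 4096 so memory stays flat, and
tie comparisons carry a 1e-9 relative tolerance so exact permutation
symmetries (complement splits, label swaps) are counted identically on
every BLAS code path.

### Gene aggregation, consensus, ranking

A gene is called when any of its probes is called (the 27K-style design
has ~2 probes per gene, so probe-level voting schemes have no support);
genes whose called probes disagree in direction are flagged ambiguous
and excluded from ranked lists.  NB-specific genes are the per-direction
intersection of gene calls across the reference comparisons (FB, AG,
GN/GNB); every Venn region is reported.  Ranking uses the fraction of
case samples shifted (descending), then the maximum |Δβ| (descending),
then the gene symbol — the last key is only there to make output
deterministic.  For consensus genes the ranking statistics take the
minimum over comparisons: the case samples are shared, so this is the
conservative choice.

### Subgroup contrasts

`ContrastSpec` selects two tumor subsets from the sample sheet (risk
HR/LR, INSS stage, MYCN status, or an age cut-off in months; HR = stage
4 with MYCN amplification, LR = stage 1–3 without it).  The same
calling machinery runs between the subsets; when external reference
tissues are supplied, each call additionally gets a `ref_consistent`
flag — the threshold criterion against those references must agree with
the subgroup direction (three-way consistency).

## Enrichment

All enrichment uses the exact upper-tail hypergeometric probability
P(X >= k), summed in log space (gammaln + logsumexp) for stability.
The background universe is the set of genes that survived QC on the
array, not the genome: the background percentages such analyses quote
are platform-relative.  `enrich_category` reports raw hypergeometric p
per category (BH optional, off by default).  The chromosome view tests
all chromosomes at once and therefore flags significance on the
BH-corrected q — without that correction roughly half of random gene
lists flag some chromosome, which would make the "chromosomal
clustering" readout meaningless; raw p values are still reported.
Within each enriched chromosome the per-major-band share of called
genes is tabulated (e.g. 19p13.2 collapses to 19p13).

The sequence-based promoter classifier is a convenience, not the source
of truth (promoter class and PcG status normally come from the
annotation table).  It scans 500-bp windows (step 5) across the
−700..+200 region around the TSS: HCP if some window reaches GC >= 0.55
and CpG observed/expected >= 0.75, LCP if no window reaches o/e 0.48,
ICP otherwise, with o/e = (#CpG · L) / (#C · #G) and N bases excluded
from all counts.

## Expression concordance

Expression matrices are standardized per gene, z = (x − mean)/SD, over
a configurable population (default: all samples; standardizing against
references only is the right choice when most tumors are expected to
shift, since a majority shift inflates the pooled SD and compresses
z).  Sample SD (ddof=1) is the default convention.  Differential
expression requires both a significant permutation t-test (maxT + BH,
q < 0.01 by default — the adjusted value, with a raw-p option) and
z > 1 in strictly more than half of the case samples (z < −1 for
down-regulation).  Concordance counts hyperM genes with reduced
expression and hypoM genes with increased expression among the genes
that have expression data; percentages are exact rational arithmetic
truncated (not rounded) to one decimal, matching how such tables are
conventionally printed.

## Sample-structure views

PCA treats samples as observations: probe-wise mean centering, no
variance scaling (beta is already bounded and unit-comparable), SVD,
and a deterministic sign convention (the largest-magnitude loading of
each component is made positive).  Hierarchical clustering is
agglomerative with average linkage on Euclidean distance by default;
dendrograms serialize to Newick with branch lengths equal to
merge-height differences.  Missing values are mean-imputed per probe
for these two views only.

## Synthetic data

The generator emulates the statistical structure of a 27K-scale tumor
study so the pipeline can be scored against known truth:

* ~1000 genes at 1–3 probes each (~2000 probes; the 27K design has
  ~1.9 probes/gene), 20 tumors, references FB=1, AG=1, GN=2 + GNB=1 —
  deliberately reproducing the single-tissue references that force the
  test-skipped pathway;
* per-probe baseline states from a 45/45/10 mixture (unmethylated mean
  0.10, methylated mean 0.85, intermediate uniform on 0.3–0.7), shared
  by all samples, with Beta-distributed noise parameterized by
  mean/concentration (concentration 50) — a parameterization that maps
  directly onto the bimodal beta landscape of such arrays;
* planted hyper/hypo genes: baselines forced to the appropriate mode
  and shifted by `effect_delta` (0.6) in a carrier subset of the tumors
  (`planted_case_fraction`, 0.5; carrier counts are exact to ±1
  sample); subgroup signals shift every member of a sample-sheet
  subgroup instead;
* detection p ~ U(0, 0.005) with planted bad samples (5% failing
  probes) and failing probes (10% failing samples);
* a coupled expression matrix: responsive planted genes shift carrier
  samples by a configurable number of per-gene SDs, downward for hyperM
  genes and upward for hypoM genes.

What the generator does **not** emulate: probe cross-hybridization,
SNP-affected probes, copy-number contamination of beta, batch effects,
or tumor purity gradients.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated
statistical structure, not robustness to those artifacts.

## Calibration and detection limits

Two properties of the caller are worth stating plainly, because both
are measured by the acceptance suite:

* **Null calibration.** On no-signal data (200 seeded datasets at the
  default scale) the consensus caller averages far below one call per
  dataset, and the family-wise error of the maxT criterion stays within
  binomial tolerance of its nominal 5%.
* **Partial-penetrance detection limit.** When only half the tumors
  carry a shift, the case group is bimodal.  The two-sample t statistic
  against a small reference set is then modest, and — more
  fundamentally — every relabelling that draws the "reference" group
  from the unshifted-plus-reference values reproduces the observed
  composition, so the permutation p-value is bounded below by roughly
  C(#unshifted, n_ref)/C(n, n_ref) (about 0.1 for 20 tumors vs 3
  references).  After BH correction across thousands of probes the test
  criterion cannot reach q < 0.05, and the three-criteria consensus
  goes silent regardless of effect size or measurement noise.  This is
  a structural property of two-sample testing under partial penetrance,
  not an implementation artifact: at full penetrance (every tumor a
  carrier) the same pipeline recovers planted genes essentially
  perfectly, which the test suite also demonstrates.  Users hunting
  subgroup-specific signals should contrast the subgroups directly
  (`run_subgroup_contrast`) rather than expect the global consensus to
  find them.

## Numerical choices

* Fraction comparisons in criterion A are inclusive with 1e-12 slack;
  criterion B is strict (a delta of exactly 0.25 fails).
* BH q-values use the standard step-up running minimum, stable under
  ties; q is clipped to [0, 1].
* Hypergeometric tails are exact log-space sums over the attainable
  support, so k = 0 (or any k at or below the support floor) returns
  exactly 1.0.
* Pearson correlation requires >= 3 complete pairs and positive
  variance on both sides; violations raise typed errors rather than
  returning NaN.
* All randomness flows from explicit seeds; identical configs produce
  byte-identical outputs, and every output TSV records the config hash
  and seed in header comments.

## Problem sizes used by the test and acceptance suites

Oracle-agreement checks run at enumerable sizes (4+4 samples x 20
features for maxT; every hypergeometric configuration with N <= 25).
Null calibration uses 200 datasets of ~2000 probes in the test suite
and 100 in the acceptance script; parameter recovery uses 25 replicates
of ~3000 probes (1500 genes).  These sizes make the binomial tolerances
meaningful while keeping a full run in the minutes range on one CPU.
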