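# Methods

## Problem setting

Culture collections of gut isolates are most useful when a small, defined
subset of strains ("minimal consortium") reproduces as much as possible of the
functional potential of the community it is meant to model.  This package
works entirely at the level of *binary functional profiles*: a genome or
metagenome is reduced to the set of protein-family identifiers (e.g. Pfam
accessions) detected in it.  Family assignment itself (HMM searches,
annotation pipelines) is upstream and out of scope; profiles are consumed as
strict presence/absence TSV matrices.

## Consortium selection

For a metagenome with family set *M* and a candidate consortium with pooled
family set *C* (the union of its member genomes' families), the score is

    S(C) = |C ∩ M| − λ·|C \ M|,    λ ≥ 0,

i.e. matched families minus λ-weighted mismatches.  Mismatches are counted
only on the consortium side (families the consortium carries that the
metagenome lacks); metagenome families not yet covered are handled by the
coverage objective, not penalised twice.  Selection is greedy: at each step
the genome with the largest marginal gain ΔS joins the consortium, with ties
broken by lexicographic genome id so results are bit-reproducible.  Iteration
stops at an optional cap `max_k`, when the panel is exhausted, or (default)
when no remaining genome has positive gain.  With λ = 0 the procedure is the
classic greedy maximum-coverage algorithm and inherits the (1 − 1/e)
approximation guarantee, which the test-suite verifies by brute force on
small instances.

λ defaults to 1 (matches and mismatches weighted equally).  The linear
trade-off is the simplest scoring consistent with "reward matches, penalise
mismatches"; exposing λ makes the trade-off explicit and lets users recover
pure maximum coverage (λ = 0) or mismatch-averse selection (λ > 1).

### Community sizing (knee point)

The number of species kept per sample comes from the cumulative
functional-coverage curve c₁ ≤ c₂ ≤ … ≤ cₙ (coverage of *M* by the union of
the first *i* picks, plotted against step number).  The knee is the 1-based
index maximising the perpendicular distance from (i, cᵢ) to the chord joining
(1, c₁) and (n, cₙ) — the standard geometric member of the knee/elbow
estimator family.  Ties go to the smaller index; curves shorter than three
points have no interior geometry and are kept whole.

If the maximum chord distance falls below `knee_tolerance` the curve is
declared flat/linear — there is no knee and the whole selection is kept.  The
default tolerance (1e-9) only catches exactly linear curves.  **Choosing the
tolerance:** on real, noisy curves the chord distance of a genuinely linear
curve fluctuates at the scale of the coverage noise, so the tolerance should
be set around that amplitude.  In the planted-recovery experiments shipped
with the package (disjoint genomes of equal size, whose true curve is exactly
linear) we use 0.05 coverage units: a knee shallower than 5% of total
coverage is indistinguishable from noise there.  Curves with a real
saturation bend have chord distances an order of magnitude larger, so this
choice does not mask true knees.

The knee only ever truncates a selection (curves are computed first, the knee
applied afterwards); it never extends one.  A metagenome sharing nothing with
the panel yields zero positive-gain picks; the result is returned empty and
flagged degenerate rather than erroring, so cohort runs survive pathological
samples.

## Cohort aggregation

Per-genome statistics across a cohort: selection prevalence (fraction of
samples whose *knee-truncated community* contains the genome — not the full
greedy ranking; the alternative convention would systematically inflate
prevalence) overall and per group, and the median 1-based picking rank over
exactly those samples where the genome made the community (midpoint
convention for even counts).  The core consortium is the set of genomes with
prevalence strictly above a threshold (default 50%) in at least one group,
ordered by decreasing overall prevalence with lexicographic ties.  Strict
inequality follows the ">50%" reading of the rule; `mode="overall"` applies
the threshold cohort-wide instead and is always a subset of the per-group
mode.

## Group separation

Pairwise Jaccard distances (1 − |A∩B|/|A∪B|; two empty profiles are
identical, distance 0) feed a distance-based pseudo-F:

    F = (SS_between / (a − 1)) / (SS_within / (N − a)),

with SS_total = Σ_{i<j} d²ᵢⱼ/N and SS_within the analogous per-group sums —
the standard PERMANOVA decomposition.  Significance comes from label
permutation with the add-one correction p = (1 + #{F* ≥ F})/(1 + n_perm), so
a sampled p is never 0.  When the number of distinct label arrangements is at
most `n_permutations`, all arrangements are enumerated (a small recursive
multiset-permutation generator) and the p-value is exact, identity included.
All profiles identical is a degenerate case defined as F = 0, p = 1.  The
statistic is checked in the test suite against scikit-bio's PERMANOVA on
random instances; the hand implementation exists because exhaustive
enumeration and the degenerate contract are not exposed there.

## Host ecology

*Cultured fraction*: 100 × the summed relative abundance of the taxa in a
match set (taxa matched to cultured isolates at a stated identity threshold;
the matching itself, e.g. blastn at 97%/95% identity, is consumed as input).
Host comparison uses the tie-corrected Kruskal–Wallis H with per-host medians
and quartiles; identical data across hosts is defined as H = 0, p = 1.

*Host enrichment*: a taxon is enriched in the target host iff (i) it is
detected (relative abundance strictly > 0; no detection floor is applied) in
at least 20% of target-host samples, and (ii) against **every** other host
its target median abundance is strictly greater and the one-sided Wilcoxon
rank-sum test (alternative: target greater, matching the "higher median"
direction of the rule) survives Benjamini–Hochberg correction at α = 0.05.
The BH family pools all taxa × all host comparisons into one correction — the
most conservative of the defensible conventions.  BH itself is the step-up
adjustment via statsmodels.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **Reference panel** — `n_families` families (default 400), a core fraction
  (default 25%) present in every genome, remaining families i.i.d. Bernoulli
  (default 0.3) per genome; default 110 genomes, the scale of a large
  single-host isolate collection.  A disjoint-block variant deals equal-size,
  non-overlapping family sets; planted unions of such genomes produce exactly
  linear coverage curves, the regime where recovery is exactly checkable.
* **Metagenome cohort** — each sample unions a planted community (size drawn
  from an inclusive range, genomes drawn without replacement, optionally with
  skewed weights so archetypal genomes recur across samples), adds its
  group's private family block (which induces within-group functional
  similarity, hence detectable clustering), then flips noise: false-absent
  with probability `fn_rate` on present families, false-present with
  probability `fp_rate` on absent families over the panel universe plus all
  private blocks.
* **Abundance tables** — relative abundances from a zero-inflated log-normal:
  per-taxon baseline log-mean drawn once from N(0, 1), per-sample log-normal
  noise with σ = 0.8, zeros injected with probability 0.1 per entry, rows
  normalised to sum to 1 (all-zero rows are flagged, not renormalised).
  Planted enriched taxa get a 4-fold multiplicative shift in the target host
  and the *typical* (median) baseline: a multiplicative shift on a community
  dominant self-dilutes under row normalisation and does not represent the
  modest-abundance taxa host-enrichment screens are about.  Defaults
  (40 taxa, 3 hosts × 50 samples, σ = 0.8, 10% zero inflation) put a 4-fold
  shift at a rank-test AUC of roughly 0.8 per comparison — strong but not
  trivial signal for n = 50 per host.

All generators take one explicit seed, use a single `numpy` Generator stream,
and are bit-reproducible.

### What the synthetic data does and does not show

The generators emulate the *structure* of the real inputs (shared cores,
accessory variation, union-of-genomes metagenomes, group-specific content,
compositional zero-inflated abundances) but not their full complexity: no
family-abundance weighting, no phylogenetic correlation between genomes, no
read-level errors, no study- or batch-effects, and noise is i.i.d. per
family.  Passing the planted-recovery and calibration suites therefore shows
the algorithms are implemented correctly and behave as designed under the
stated model — not that any particular real cohort will yield communities of
a particular size or a particular core list.

## Problem sizes and numerical choices

The shipped validation experiments use sizes chosen to exercise every code
path while staying desk-scale: oracle comparisons on ≤12 genomes × ≤200
families (exhaustive enumeration is exact there), recovery on 40-genome
disjoint panels over 50 seeds, 500 null datasets × 199 permutations for test
calibration, and 100 seeded abundance cohorts for the enrichment operating
characteristics.  Floating-point ties in the greedy argmax and the knee
argmax are broken deterministically (first maximum / smaller index);
coverage values are ratios of integer counts, so curve monotonicity is exact.
Seeds derived inside experiment drivers stay below 2³¹.

## Known limitations

* The greedy + knee procedure is a heuristic; no optimality is claimed beyond
  the λ = 0 max-coverage bound, and the knee estimator is one member of the
  extremum-distance family (others bend the axes or smooth first).
* Prevalence counts knee-truncated communities; with full rankings the
  numbers would differ (both are computable from the stored results).
* The pseudo-F permutation test assumes exchangeability of samples under the
  null; it inherits PERMANOVA's sensitivity to dispersion differences.
* BH pooling across all taxa × comparisons controls the FDR of the pooled
  test family, not of the final conjunction rule per taxon (which is more
  conservative).
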