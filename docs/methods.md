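# Methods

`herbnet` implements the computational core of a network-pharmacology
target-identification study: starting from a multi-herb formula, it screens
chemical ingredients by ADME properties, assembles the
herb–ingredient–target network, intersects the network's targets with
disease-associated genes and differentially expressed genes, and assesses
the resulting candidate list by hypergeometric over-representation and by
gene set enrichment analysis. This note records the models, the defaults
and the open design choices.

## Ingredient screening

Each herb ingredient carries two TCMSP-style properties: oral
bioavailability (OB, percent scale — 30 means 30%) and drug-likeness (DL,
unitless in [0, 1]). An ingredient is retained iff

    OB ≥ ob_min  and  DL ≥ dl_min        (defaults 30 and 0.18, inclusive)

or its herb is on the exemption list (default `{ML}`; mineral/animal-derived
material whose constituents are inorganic and score low on DL by
construction, so the drug-likeness heuristic is not applicable). The
exemption bypasses *both* criteria and is configuration-driven, never
hard-coded. Duplicate (herb, ingredient) rows are rejected at load rather
than silently deduplicated: provenance tables should be clean. Screening is
idempotent, monotone in both thresholds, and the identity when thresholds
are zero and no herb is exempt.

## Network construction and counting

The network is tripartite: herb → ingredient and ingredient → target edges
only; gene symbols are uppercased and whitespace-stripped at ingestion (no
alias resolution — a documented limitation, since no external identifier
service is consulted). Retained ingredients without a target-map entry are
dropped with a logged count. The graph lives in plain typed adjacency sets;
networkx is used only for GraphML interchange.

Counting rules: per-herb counts are distinct ingredients/targets reachable
from that herb; network totals deduplicate across herbs, so a target shared
by several herbs is counted once. A target's *herb-degree* is the number of
distinct herbs reaching it; the shared-target histogram maps herb-count →
number of targets with exactly that degree (`exact` mode, the default) or
at least that degree (`at_least`). Exact-mode bins always sum to the size
of the target universe. Exports (SIF with `contains`/`targets` relations,
GraphML with a `node_type` attribute, edge-list TSV) are written in
lexicographic order so files are diff-stable.

## Disease genes, differential expression, intersection

Disease-association records carry a relevance score ≥ 0 (GeneCards-style);
the filter keeps genes with score strictly greater than 5 by default
(`strict=False` switches to ≥). Duplicate genes keep the maximum score.

Differential expression between exactly two groups (each ≥ 2 samples) is
tested per gene, two-sided, on log2 values:

* `welch_t` (default): Welch's unequal-variance t.
* `moderated_t`: empirical-Bayes variance moderation — gene-wise pooled
  variances s²_g (df = n₁+n₂−2) are shrunk toward a scaled
  inverse-chi-square prior whose parameters (d₀, s₀²) are estimated by the
  method of moments on log s²_g using digamma/trigamma identities; the
  posterior variance (d₀s₀² + df·s²_g)/(d₀+df) feeds a t statistic on
  df+d₀ degrees of freedom. When the observed dispersion of log-variances
  does not exceed chi-square sampling noise, d₀ = ∞ and all genes share the
  mean variance. This reproduces the limma procedure (cross-checked against
  Bioconductor limma in the test suite to 1e−6) and is offered because
  public two-group microarray contrasts (GEO2R) are computed that way.

Significance defaults to raw P < 0.05; BH-adjusted P is always reported and
can be used for the cut instead (`use_adjusted`). Genes with zero variance
in both groups get p = 1 and a `degenerate` flag rather than an exception.
An optional probe→gene map collapses probe rows to the smallest-p row per
gene after testing. Log fold change is group2 − group1 mean.

The three-set intersection decomposes A (disease genes), B (DEGs) and C
(network targets) into the seven exclusive Venn regions; the triple
intersection is the candidate-target list. Symbols are normalized before
set operations so the three sources agree.

## Over-representation analysis

For background universe of size N (the background intersected with the
collection's annotated genes — unannotated background genes are excluded
before N is computed), query size n (query ∩ universe), term size M within
the universe and overlap m, the P-value is the upper hypergeometric tail

    P = P(X ≥ m) = 1 − Σ_{i=0}^{m−1} C(M,i) C(N−M, n−i) / C(N,n),

the probability of *at least* the observed overlap; m = 0 gives exactly 1.
It is evaluated through the numerically stable survival function and
verified against exact rational-arithmetic enumeration (max |error|
≈ 3e−16 over all N ≤ 40). Terms are tested when M ≥ 3 (configurable) and,
by default, m ≥ 1; zero-overlap terms can be included to widen the
multiple-testing field. BH-FDR runs across all tested terms; significance
is FDR ≤ 0.05, inclusive.

The dual-background mode runs the same query against (a) the full
annotated universe and (b) a focused background (the disease ∩ DEG
intersection), and cross-tabulates each term as significant in
both/a-only/b-only/neither. No ordering between the two runs' p-values is
asserted — enrichment against a focused background can be weaker or
stronger. Under a small focused background most terms fall below the
minimum testable size; the consistency table simply records what was
testable.

## GSEA

Three steps, implemented from first principles:

1. **Ranking.** Genes are ranked by signal-to-noise (default),
   (μ₁−μ₂)/(σ₁+σ₂), with each group SD floored at 0.2·|group mean| (0.2
   when the mean is 0) so flat genes cannot dominate; `t_stat` and
   `log_fc` metrics are also available. Positive metric = up in the first
   group of `group_order`. Ties are broken by gene symbol for
   reproducibility.
2. **Enrichment score.** The weighted Kolmogorov–Smirnov running sum:
   hits advance by |r|^p normalized over the hits' total (p = 1 default),
   misses retreat by 1/(N−N_hit); ES is the signed maximum-magnitude
   deviation. With p = 0 the walk ends exactly at zero. If every hit
   carries zero metric the walk falls back to equal hit weights.
3. **Significance.** Phenotype labels are permuted (seeded); when fewer
   distinct labelings exist than requested, all distinct labelings are
   enumerated and the result flagged exhaustive. Nominal p uses the
   (b+1)/(k+1) pseudo-count over null ES of matching sign, so p is never
   zero and has granularity 1/(n_perm+1). NES divides ES by the mean
   |null ES| of matching sign (positive and negative sides normalized
   separately); the FDR q compares each NES with the pooled,
   per-set-normalized null NES distribution on its own sign side, clipped
   to [0, 1].

Phenotype permutation (not gene-set permutation) is the null because the
intended inputs have enough samples per group; it preserves inter-gene
correlation, so sets of correlated or strongly shifted genes have wider
null ES distributions — NES and p reflect that.

## Synthetic data

Every generator is a pure function of (parameters, seed); a master seed
fans out to fixed per-generator streams (SeedSequence spawn keys), so
changing one generator's draws never perturbs another's. Symbols are
synthetic (`G000001`, …) so nothing can accidentally depend on real
annotations.

* **Herb tables** draw pass/fail per row with probability `frac_passing`;
  passing rows draw OB ~ U(30, 100), DL ~ U(0.18, 1); failing rows miss at
  least one criterion (OB ~ U(0, 30) and/or DL ~ U(0, 0.18)). The expected
  retained fraction is therefore exactly `frac_passing`.
* **Target maps** plant an exact sharing histogram: for each (herb-count
  k, target-count c) entry, c targets are wired to exactly k distinct
  herbs through one random retained ingredient each; leftover universe
  targets get herb-degree 1. A profile that itself plants bin 1 must cover
  the whole universe, otherwise the leftover would contaminate the planted
  bin. Every retained ingredient is guaranteed ≥ 1 target by re-using a
  target its herb already owns, which leaves all herb-degrees unchanged.
* **Expression** is i.i.d. N(8, 1) log2 noise (within-group SD 1);
  planted genes have their group-2 mean shifted by `effect_sd_units`
  within-group SDs. This emulates the two-group structure of a microarray
  contrast, not its realistic covariance, probe effects or heavy tails —
  so calibration results here bound behaviour on idealized data only.
* **Gene sets** are uniform random draws plus one planted term; in the
  full study the random terms are drawn from non-DE genes so the planted
  term is the *unique* truly-enriched set, which is exactly what the truth
  record asserts.
* **The full study** wires the pieces so that the disease genes passing
  the score filter meet the target universe exactly in the planted
  overlap (default 81 genes, sharing histogram {9:2, 8:9, 7:23, 6:30,
  5:65, 4:69} over 10 herbs), and overlap genes carry 5-SD up-shifts in
  group 2. Hence the triple intersection equals the planted set whenever
  all overlap genes are called (their per-gene power at n = 10+10 is
  ≈ 1), and DEG false positives cannot enter the triple because
  (disease ∩ targets) = overlap by construction.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: 10 herbs × 12
ingredients, a 400-target universe inside a 2000-gene expression universe,
10+10 samples, 30 random gene sets plus the planted term, 1000 phenotype
permutations, and exhaustive hypergeometric verification over all N ≤ 40.
These sizes keep a full run in well under a minute per stage while leaving
every statistical check with adequate resolution (e.g. binomial SD of the
null DEG rate at 1000 genes is 0.0069).

Other numerical conventions: thresholds at boundaries are inclusive for
screening (≥) and ORA significance (FDR ≤ 0.05), strict for the disease
score (> 5) and DEG calling (P < 0.05); DEG tables sort by p, then
|log2fc| descending, then symbol; GSEA results sort by |NES| descending
with term-id tie-break; permutation seeds are plain integers fed to numpy
Generators.

## Known limitations

* No gene-identifier alias resolution; sources must share a symbol space.
* Flat gene-set semantics: no GO DAG propagation, no pathway topology.
* The moderated-t option implements the standard two-group limma model
  only (no covariates, no trend/robust variants).
* GSEA FDR uses the pooled signed-null procedure; with few gene sets the
  q-values are coarse.
* The synthetic expression model is Gaussian and independent across genes;
  it does not emulate probe-level artifacts, batch effects or correlated
  modules beyond the planted sets.
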