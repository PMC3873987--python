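# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely open.

## Differential expression without replicates

Counts for gene *i* in library *j* are modelled NB(μ_ij, α_i) with
Var = μ + αμ².  Library depth is normalized by median-of-ratios size
factors: for each gene with positive counts in both libraries, divide each
count by the gene's geometric mean, and take the per-library median of those
ratios.

With a single library per condition there is no within-condition replication,
so dispersion is estimated **blind**:

1. *Moment estimates.*  On normalized counts y₁, y₂ per gene, with
   m = (y₁+y₂)/2 and v = (y₁−y₂)²/2, set α̂ = max(0, (v − m)/m²).  With two
   observations this is extremely noisy (one degree of freedom), and for a
   truly regulated gene it absorbs the treatment effect itself — at a 4-fold
   change α̂ ≈ 2·dev²/m² ≈ 0.7 regardless of expression level.
2. *Trend.*  α_tr(μ) = a₀ + a₁/μ is fitted to (m, α̂) over genes with
   α̂ > 0 by iteratively reweighted least squares with Tukey-bisquare
   down-weighting of outliers and coefficients clipped at zero.  The
   conditioning on α̂ > 0 biases the trend slightly upward relative to the
   generating dispersion; the robust loss keeps regulated genes and the χ²₁
   upper tail from dominating.
3. *MAP.*  Per gene, α maximizes the two-point NB log-likelihood (both
   libraries as replicates at fitted means s_j·m) plus a log-normal prior
   centred at log α_tr(m) with spread σ_prior.  The posterior is profiled on
   a 121-point log-spaced grid on [1e-8, 20] and refined by parabolic
   interpolation in log α; this is robust for a 1-D posterior whose two-point
   likelihood can be nearly flat.

**σ_prior defaults to 0.5.**  With one residual degree of freedom the
log-scale sampling spread of the gene-wise estimate is so large that the
shrinkage prior's width cannot be estimated from data; 0.5 corresponds to
the prior-variance floor (0.25) the DESeq2 family applies in exactly this
regime.  The choice matters: at σ_prior = 1 the gene's own (effect-inflated)
estimate dominates and even 50-fold inductions lose significance, while at
σ_prior = 0.5 strong inductions (≳16-fold) are recovered.  No prior width
rescues moderate (≈4-fold) changes — the blind design is intrinsically
conservative there, since a regulated gene's spread is "explained" by its own
inflated dispersion (in the likelihood-dominated limit the conditional
z-statistic tends to 1 exactly).  Consumers should expect high precision and
modest recall, concentrated in the strongly induced tail.

Testing is an exact conditional NB test: under the null of a common rate
(estimated as the mean of normalized counts), condition on the per-gene
total T and sum the probabilities of all splits (a, T−a) whose probability
does not exceed the observed split's.  A Wald test is ill-posed with one
library per condition; the conditional test is exact at any count.  Genes
with zero counts in both libraries are labelled `no_expression` and never
tested.  The displayed log2 fold change uses a pseudo-count of 0.5 in both
numerator and denominator; p-values never use it.

Independent filtering then drops low-information genes before correction:
candidate cutoffs are the 0–95% percentiles (1% steps) of the mean of
normalized counts over testable genes, truncated at the median of that mean
(so filtering can never discard the upper half of genes to buy rejections),
plus an explicit no-filtering candidate.  The cutoff maximizing BH
rejections at the target FDR (default 0.10) is chosen, ties resolved toward
the least aggressive filter; surviving genes are BH-adjusted and labelled
up/down by adjusted p ≤ FDR and the sign of the fold change.

## Immune catalog

Three evidence tiers, most-curated first: a curated AMP gene list; reciprocal
best blastp hits to the fly, transferring the partner's published immune
class (`amp`, `effector_other`, `recognition`, `signaling`,
`protease_or_inhibitor`); and profile-HMM hits from a battery of immune
family models.  Running N separate profile searches inflates the effective
search space N-fold, so raw e-values are multiplied by N (default 25) and
hits kept only when the corrected value is ≤ 1 (boundary inclusive); a
protein hit by several models keeps the smallest corrected e-value, ties by
model name.  A gene carrying several tiers is counted once under the
highest-precedence tier, which also resolves class conflicts; the summary
reports both raw per-source totals and the deduplicated catalog size so the
overlap is visible rather than hidden.  RBH pairing requires a *unique* best
hit in both directions (minimum e-value, ties broken by bitscore); an exact
tie on both keys disqualifies the pair — conservative, since a tie means the
orthology signal is ambiguous.

## Gene ages

A hit is a detectable homolog when its alignment length covers at least half
of the shorter protein (gaps included, as aligners report) and carries at
least 30% positives; both thresholds inclusive.  Hit tables are assumed
pre-filtered at the upstream blastp e-value cutoff (0.001), which is thus a
precondition, not a re-applied filter.  A gene's stratum is the maximum
(deepest) stratum over the species contributing detectable hits; no hits
means Wasp.  This "deepest detectable homolog" rule is deliberately
conservative about taxonomic restriction: one outgroup hit makes a gene
Metazoan however gappy the pattern, and the Wasp stratum conflates
focal-species-specific genes with genes shared by unsampled wasp relatives.
The panel file, not code, defines stratum membership.

## Paralog families

Edges require both directional self-proteome hits to pass all four criteria:
e-value ≤ 1e-4, positives ≥ 30%, alignment ≥ 50% of the *longer* protein
(stricter than the detectability rule's shorter-protein denominator), and
each directional hit more significant than its own query's best
non-Hymenopteran e-value (vacuous for genes without such a hit).  The last
criterion is evaluated per query and both directions must pass — the
symmetric, conservative reading of an ambiguous rule; it filters edges that
merely reflect a conserved domain older than the Hymenoptera.  An edge's
removal bitscore is the larger of its two directional bitscores (an edge
stands for two hits), configurable.

Families are connected components after iterative bridge removal: among all
bridges inside components larger than two, delete the one with the globally
lowest edge bitscore (ties by lexicographic gene pair), recompute, repeat
until no such bridge remains.  Components of size ≤ 2 are never split, and
each iteration removes one edge so termination is bounded by |E|.  Global
(rather than per-component) selection with recomputation makes the result
independent of edge input order; the test suite checks the final partition
against a brute-force remove-one-edge-and-count oracle on hundreds of random
graphs.

## Effector screen and enrichment statistics

The candidate cascade applies, in order: induced and not in the immune
catalog; protein strictly shorter than 300 aa (longest isoform) **and** a
signal peptide on any isoform; no fly blastp hit at the upstream cutoff (any
hit, not merely an RBH); net charge > 0.  Net charge is (#K + #R) − (#D +
#E) at neutral pH, histidine excluded by default (a flag counts it as +1),
termini ignored — a standard approximation for AMP screening.

Fisher exact tests are two-sided by the minimum-likelihood rule, computed
over genes with significant expression; odds ratios are the sample
(ad)/(bc).  No correction is applied across the battery — each comparison is
reported raw, as is conventional for descriptive enrichment panels.  The
age–length confound (short genes are hard to find homologs for) is handled
two ways: restricting the stratum table to proteins of 134–456 aa inclusive
(the induced class's interquartile range; the empirical IQR is recomputed
and reported next to the configured bounds), and a logistic regression of
youth (1 = not Metazoan, or Wasp-restricted under the alternative
definition) on an induced indicator and raw protein length in aa.  Raw
length is used, matching the restriction analysis; the model is fitted by
Newton/IRLS maximum likelihood with Wald p-values, and separation or
non-convergence is an error rather than a silently unstable estimate.

## Synthetic data

The generator's defaults are the study conditions the package targets:
24,389 gene models; 1.29% induced and 0.43% repressed among analyzable
genes; 12.1% of genes with no expression; baseline mean normalized counts
log-normal with median 7 (the observed median of the mean of normalized
counts is then a few counts, matching the sparse two-library regime);
library size factors 1.16/0.86 (a ~1.35× depth imbalance); |log2fc|
magnitudes log-normal with mean 2 and sdlog 0.8, so the upper tail reaches
the 30–50-fold inductions typical of antimicrobial peptide responses —
the part of the distribution the unreplicated test can recover; NB
dispersion 0.02, the technical/pool scale appropriate for libraries that
are pools of many individuals sequenced once (not the ~0.2 scale of
biological replicates, which would be inconsistent with the pooled design);
~2% immune genes split 32:106:361-style across the AMP-list/RBH/HMM
sources; ages distributed 17/8/8/7/60% from Wasp to Metazoan; geometric
family sizes with p = 0.906 (≈18% of genes in multi-gene families); and
planted associations linking induction to immunity (×4.7), youth (×2.2),
multi-copy membership, short length, signal peptides and positive charge.

Consistency rules make recovery exact where the pipeline is exact: a gene of
planted age X receives detectable hits only to species at strata ≤ X, always
including one at exactly X; deeper species receive only sub-threshold decoy
hits (low coverage or low positives) that exercise the boundary logic;
planted families are cliques of reciprocal self-hits satisfying every edge
criterion, with near-miss decoy pairs each violating exactly one criterion;
fly RBH partners are the unique best hit in both directions yet less
significant than within-family self-hits; HMM decoys fall just past the
corrected-e-value boundary; protein sequences realize the planted length and
net charge exactly.  One pseudo-random substream per output table derives
from the master seed, so all outputs are byte-identical across runs with the
same seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic sequence evolution (hit strengths are
drawn, not computed from sequences); mapping artefacts, 3′ bias, and
multi-mapping; dispersion varying with expression beyond the fitted trend;
annotation errors in gene models or in the curated fly immune lists;
horizontal transfer or gene loss violating the nested-age model; and
correlated errors between evidence tiers.  Exact recovery of ages and
families on generated data validates the rule implementations, not the
biological reliability of the rules.

## Problem sizes and numerical choices

The test suite runs the DE recovery analysis at 10,000 genes with 200
4-fold-planted genes, the oracle comparisons on hundreds of small random
instances, the logistic recovery at 10,000 observations over 30 seeds, and
end-to-end determinism at ~1,000 genes; the acceptance script runs the full
pipeline at the default 24,389 genes.  Dispersion estimation requires at
least 100 genes with positive moment estimates (configurable) and errors
below that.  Exact-test enumeration is linear in each gene's total count.
Ties are broken deterministically everywhere (bitscore, then lexicographic
identifiers), so all outputs are reproducible bit-for-bit given inputs.

## Known limitations

* Power at moderate fold changes is intrinsically low (see the σ_prior
  discussion); the package reports the regime honestly rather than
  inflating sensitivity.
* Only two-library, two-condition designs are supported; no covariates, no
  shrunken fold-change estimation, no outlier (Cook's-distance-style)
  handling.
* The catalog merge precedence (AMP list > fly RBH > HMM) is a curation
  judgement, not a statistical one; the raw per-source totals are reported
  so users can audit the overlap.
* Stratum assignment is only as good as the species panel's coverage;
  unsampled lineages inflate the shallowest stratum.
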