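# Methods

## Signature scores

A gene-expression signature is a named gene set with up to four components:
UP, DOWN, and the presence/absence contrasts "+inf" (detected only under
the perturbation) and "−inf" (detected only in controls). The raw component
score of a sample is the arithmetic mean of **all** matrix features mapping
to the component's gene symbols. Two points deserve emphasis:

* **Probe pooling.** On probe-level platforms, probes are pooled directly
  into the mean rather than first averaged per gene. A gene with three
  probes therefore carries three times the weight of a single-probe gene.
  The per-gene-first alternative gives a different answer (the tests
  demonstrate this on a two-gene toy), and callers who want it can collapse
  probes upstream; pooling is the package's single convention.
* **Composites.** Signatures carrying a DOWN set default to UP − DOWN;
  up-only signatures (including SRC activation scored from its 61 UP genes
  and the 5-gene Dasa-S set EPHA2/CAV1/CAV2/ANXA1/PTRF after dropping the
  non-predictive DOWN gene IGFBP2) default to the UP mean. The full
  composite (UP + (+inf)) − (DOWN + (−inf)) is available per call.

Cohort standardization is (s − median)/IQR with IQR = Q3 − Q1. All
quantiles, here and in quartile assignment, use linearly interpolated
sample quantiles (NumPy's default, "type 7"); one convention applied
uniformly keeps scores and quartiles comparable across modules. The
transform is strictly monotone, so rank statistics (Spearman correlations,
Mann–Whitney, quartile membership) are invariant to it — a property the
tests assert exactly. A column with zero IQR cannot be standardized; it is
flagged degenerate and kept raw, never silently zeroed. Quartile and
quadrant boundaries resolve ties downward/leftward (a value exactly on a
cut point goes to the lower group; a zero standardized score is a
"lower/left" sample), which is deterministic and matches rank intuition.

Cell-line panels are ratio-normalized first: each probe row is divided by
its mean over all samples, because probe intensities of different signature
genes can differ by orders of magnitude and would otherwise dominate the
pooled mean. Division (not subtraction) is used since the problem is
multiplicative scale, and every output row then has mean exactly 1.

Platform coverage (fraction of signature genes present) is recorded per
signature; scores are still computed below the default 0.5 threshold with a
warning (configurable to error). Scores are computed on the matrix as
provided; an optional log2(x+1) pre-transform exists but is off by default,
since both array intensities and normalized RSEM means are commonly scored
on their native scale and the choice is the caller's.

## CMS classification by nearest-template prediction

Templates are per-class marker gene sets (exactly CMS1–4, disjoint,
non-empty), supplied as a (gene, class) TSV; the synthetic generator ships
its own. Marker genes present on the platform are collapsed to gene level
(mean over probes) and gene-wise centered/scaled across the cohort. For
sample x and class k with indicator template t_k, the distance is

    dCMSk = (1 − cos(x, t_k)) / 2  ∈ [0, 1],

so an aligned profile scores 0, an anti-aligned one 1, an orthogonal one
0.5. A cosine-on-standardized-data distance was chosen because the distance
must live on [0, 1] and template-correlation distances are the convention
in this classifier family; a Pearson variant would behave near-identically
on centered data.

Confidence: the nearest class's p-value is the add-one-smoothed fraction of
n_perm within-sample gene-label permutations achieving a distance at most
the observed one (default n_perm = 1000); Benjamini–Hochberg FDR is taken
across samples, and samples with FDR > 0.05 are labelled NA (the threshold
is exposed in configuration). Propensities are CMSk\* = 1 − dCMSk exactly;
the argmax propensity always equals the argmin-distance label.

Note that the reported p is for the *minimum* of four distances, so under a
pure-noise null its CDF is bounded above by 4t rather than uniform; the
tests assert this bracketing rather than strict uniformity. The practical
consequence is conservative: noise cohorts are called NA essentially always
at n_perm = 1000.

Permutations are drawn from a per-sample substream keyed by (seed,
CRC32(sample id)), which makes classification deterministic given the seed
and invariant to the order of samples in the matrix.

This module reproduces the classification *procedure*, not any specific
tool's numeric distances; real marker templates are a drop-in input file.

## Cohort statistics

* Correlation matrices are pairwise-complete with per-pair n recorded
  (cohorts routinely have slightly different n per analysis); constant
  columns yield missing (not zero) correlations. P-values come from the
  t approximation.
* Mann–Whitney uses exact enumeration when n₁+n₂ ≤ 20 and there are no
  ties, else the tie-corrected normal approximation. Welch's t is the
  unequal-variance t test.
* The trend test is Cochran–Armitage on a 2×k ordered table with default
  scores 1..k. The statistic uses the finite-population (permutation)
  variance A(N−A)/(N−1)·σ²_s, so the asymptotic branch (1-df chi-square)
  and the exact branch — exhaustive enumeration of the conditional
  multivariate-hypergeometric null, i.e. the infinite-shuffle limit —
  share one statistic. The exact branch matches an independent
  subject-subset enumeration oracle to machine precision on every small
  table, and a literal 100k-shuffle oracle within Monte-Carlo error.
* The summary cross-tabulation (`table_one`) reports "N (pct)" cells with
  half-up rounding to one decimal and the denominators such tables use:
  grand total for class percentages, samples with known sex/site for those
  columns, and the primary-tumor count for stage percentages. On the
  built-in reconstruction of a published 2250-tumor cohort
  (`crcsig.datasets.reference_crosstab`) the cells reproduce the printed
  table; three printed cells differ from the arithmetic under the table's
  own stated denominators by one final digit, and the package reports the
  arithmetic.
* Extreme correlation p-values are reported as computed; displays may
  floor at 10⁻³²⁰ but stored values are never altered.

## Survival

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
`lifelines`; the module adds the Greenwood variance
S(t)²·Σ d_i/(n_i(n_i−d_i)) from the event table, a step-function container,
and the quartile plumbing (samples missing overall-survival data are
dropped with a reported count; quartiles use the scoring module's
convention; both the overall 4-group log-rank and the Q4-vs-Q1 pairwise
test are returned). Ties between events and censorings are resolved
events-first, the standard convention. Times are days internally; no
covariate adjustment is performed (unadjusted KM only).

## Synthetic cohorts

The generator is a linear-Gaussian latent-factor model — deliberately the
simplest construction that plants the three structures the analyses are
about:

1. **Correlated signaling axes.** Four latent axes (MEK18, MEKIBP, SRC,
   EMT) are multivariate normal. Defaults: corr(MEKIBP, SRC) = 0.90,
   corr(SRC, EMT) = 0.85, corr(MEK18, MEKIBP) = 0.05; the three unstated
   pairs are single-factor products (e.g. corr(MEKIBP, EMT) = 0.765) so the
   matrix is positive semi-definite by construction. Signature genes are
   gene = ±latent + N(0, 1), with sizes mirroring the real gene lists
   (18, 13, 61, 5, and a 20-up/5-down EMT set whose down genes anti-load,
   standing in for epithelial markers such as CDH1). Dasa-S genes load on
   the SRC axis. With unit latent and noise variance, the correlation
   between two k-gene scores on axes correlated ρ attenuates to
   ρ/√((1+1/k_a)(1+1/k_b)) — e.g. 0.9 → 0.860 for the 13- and 61-gene
   scores — and `expected_score_correlation` computes this closed form for
   the recovery tests.
2. **Class structure.** Classes CMS1–4 plus an unclassifiable noise
   fraction are drawn at proportions (0.136, 0.300, 0.154, 0.304, 0.106),
   the composition of a large mixed CRC cohort. Each class shifts its 50
   marker genes by 2 SD (the template the classifier sees) and shifts the
   latent axes (CMS4 high SRC/EMT/bypass, CMS1 highest MEK output with
   intermediate bypass/SRC, CMS2/3 epithelial-low). Mutation flags follow
   class-dependent rates (BRAF V600E enriched in CMS1, KRAS in CMS3/4, MSI
   in CMS1) with BRAF and KRAS/NRAS mutually exclusive per sample, standard
   CRC biology. Site (primary/metastatic), stage and sex are drawn per
   class at cohort-like frequencies.
3. **Prognosis.** Overall survival is exponential with hazard
   5·10⁻⁴/day · exp(class log-HR + 0.30·SRC latent), class log-HRs 0.35
   (CMS1) and 0.45 (CMS4), independent exponential censoring targeting 25%.
   `simulate_survival_only` is a fast path drawing only scores and survival
   with a per-quartile hazard gradient, used for replicated power studies.

Optionally each gene is expanded into 1–k probes with a per-probe offset
and replication noise (probe_noise_sd, default 0.3) to exercise the
probe-level scoring path.

Everything is drawn from one seeded generator: identical (config, seed)
gives bit-identical cohorts.

**What the generator does and does not emulate.** It reproduces the
*statistical* structure the pipeline assumes — correlated score axes, class
mean shifts, mutation enrichment, a survival gradient — with Gaussian
noise. It does not emulate microarray noise physics, batch effects,
normalization artifacts, gene-gene correlation beyond the latent axes, or
any biological regulation. Passing recovery tests therefore shows the
pipeline's *inference machinery* is correct at realistic effect sizes and
sample sizes, not that any biological conclusion transfers to real data.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 150–500 samples (2000 for
distributional checks), 1000 permutations for classification confidence,
200 replicates for survival power, and exhaustive enumeration for the
small-sample statistical oracles (all Mann–Whitney splits with n₁+n₂ ≤ 8;
all 2×3 trend tables with total ≤ 12) — sizes at which the planted effects
are comfortably detectable and full runs complete in well under a minute.
Standardization requires IQR > 0 (tolerance checks at 1e-9); cosine
distances are clipped to [0, 1] against floating-point drift; degenerate
(zero-variance) template genes are dropped before classification; the
permutation p uses add-one smoothing so it is never 0.

## Known limitations

* NTP distances are not numerically comparable to any specific published
  classifier's output; real templates and cohorts are required to reproduce
  published CMS calls.
* The Mann–Whitney exact small-n branch is an extension beyond what large
  cohorts need (asymptotics are certain at n > 2000).
* No batch correction, array preprocessing or cross-dataset normalization;
  matrices are scored as provided.
* The generator's clinical layer draws fields independently given class;
  joint sex×site×stage structure is not modelled.
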