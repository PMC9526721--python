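# Methods

This note documents the models, conventions and numerical choices behind
`sigscreen`, and what the synthetic-data experiments do and do not show.

## Expression preprocessing

The pipeline consumes an already-summarized genes × samples matrix (raw
array processing — CEL parsing, background correction, probe summarization —
is out of scope).  Stages run in a fixed order: sample QC → quantile
normalization → variance filter.

**Sample QC.**  Each sample's mean Pearson correlation with all other
samples is computed once on the full matrix; samples more than *k* sample
standard deviations (ddof = 1) below the average of those means are flagged
(default *k* = 3).  The rule is single-pass: flags are not re-estimated
after removal.  Degenerate inputs — a constant sample, or all samples
identically correlated so the SD is zero — raise, since the rule then has
no scale.

**Quantile normalization.**  Every column is mapped onto the per-rank mean
of the sorted columns.  Ties within a column receive the mean of the
reference values across their tied ranks, which preserves the within-column
ordering exactly; for tie-free matrices the operation is exactly
idempotent.

**Variance filter.**  The top-N genes by sample variance (ddof = 1, ties by
input order; default N = 10,000).  Probe-to-gene collapsing, when a
mapping is supplied, keeps the maximum-variance probe per gene — a
documented policy choice; summarized alternatives (mean, median) change
little for the downstream correlation structure but break the "one probe,
one measured profile" interpretation.

## Co-expression network

Signed adjacency `a_ij = ((1 + cor_ij)/2)^β` (default; unsigned `|cor|^β`
behind a flag) with β = 16.  The topological overlap matrix combines direct
adjacency with shared-neighbour weight and is clustered by average linkage
on `1 − TOM`.

Two implementation notes for large networks: the elementwise β-th power is
computed by repeated squaring with a flush-to-zero at 1e−30 (high powers of
near-zero correlations otherwise land in subnormal-float territory, which
is dramatically slower on common hardware and meaningless at adjacency
scale), and the TOM pipeline runs in float32 (the ~1e−7 rounding is far
below the dissimilarity resolution of the clustering).

**Module detection.**  A static cut of the dendrogram at
`cut_height_fraction × max merge height`, followed by a minimum-size filter
(default 100; smaller clusters are labelled `unassigned`), eigengene
computation, and iterative merging of the closest module pair while their
eigengene dissimilarity (1 − correlation) is below 0.1, recomputing
eigengenes after every merge.  The static cut keeps detection deterministic
and fully testable.  The default fraction is 0.95, calibrated on two
synthetic scenarios: planted orthogonal modules must come out as exactly
their own clusters, and a pure-noise 500-gene dataset must produce no
module at all.  Higher cuts (≥ 0.98) provably admit ≥ 100-gene noise
clusters at that scale; lower cuts start splitting genuine modules.

**Eigengenes.**  First right-singular vector of the row-standardized module
submatrix, unit norm, sign-oriented so its correlation with the module's
mean standardized profile is non-negative (ties broken by making the first
nonzero coordinate positive).  Module–trait association is the Pearson
correlation of each eigengene with the per-sample trait (vehicle = 0,
treated = 1), with *p* from the *t*-distribution on n − 2 df and Bonferroni
correction over the assigned modules.

**Enrichment.**  One-sided hypergeometric over-representation of a module
in user-supplied gene sets (GMT), Benjamini–Hochberg adjusted.

## Query signature

Per-gene two-sided pooled-variance Student *t*-test between the two groups
(Welch available).  Genes with exactly zero pooled variance get t = 0,
p = 1.  The signature takes genes with raw *P* below α (default 0.005 — no
multiplicity correction, deliberately) split by the sign of the mean
difference (treated − vehicle), each list ordered by ascending *p*.
Signatures round-trip through GRP files (one gene per line, `#` comments).

## Connectivity scoring

The tag-KS statistic, null-instance rule and p/|q| scaling are described in
the README.  Additional conventions:

- **Permutation *P*.**  Null replicates draw disjoint random up/down tag
  sets of the observed sizes, re-score *every* instance and re-scale
  compendium-wide, exactly mirroring how the observed per-compound mean is
  computed; the observed statistic is then exchangeable with its nulls,
  which is what makes the *p*-value valid.  One null score matrix serves
  all compounds.  The add-one estimator `(1 + #{|null| ≥ |obs|})/(B + 1)`
  avoids p = 0.
- **Percent non-null.**  Share of a compound's instances whose nonzero
  scaled score agrees in sign with the compound mean; 0 when the mean is 0.
- **Specificity.**  Fraction of decoy signatures whose |mean scaled score|
  for the compound matches or beats the observed one (lower = more
  specific).  Decoys are user-supplied or generated random signatures.
- **Ranking.**  Permutation *p* ascending, ties by *signed* mean score
  descending, then compound name.  The sign-aware tie-break is deliberate:
  the screen looks for compounds that mimic the query, and with a planted
  mimic and a planted reverser both at the minimal attainable *p*, an
  absolute-value tie-break would order them by coin flip.
- Rank ties in ingested profiles are forbidden; an ingest option breaks
  ties by stable input order with a logged warning.

## Synthetic data

**Expression.**  Module latents e_m are drawn per sample from a standard
normal; gene g in module m is `ρ·e_m + sqrt(1−ρ²)·ε` with ρ = 0.8 and unit
noise SD by default; background genes are pure noise; a per-gene baseline
offset (uniform 6–12) puts values on a log-intensity-like scale without
touching correlations.  Trait-linked modules (default 4 of 6) shift their
latent by ±2 SD in treated samples, alternating sign so the derived
signature has both directions; the shifted modules' genes form the planted
up/down sets.  Defaults mirror the targeted study design: 3 vehicle vs 3
treated samples, ~10,000 genes after filtering.  An optional
`orthogonal_latents` flag Gram–Schmidt-orthogonalizes the latents for
recovery experiments that require exactly uncorrelated modules; the default
leaves them independent (hence chance-correlated at n = 6).  An optional
outlier sample is produced by within-column permutation, which preserves
the marginal distribution while destroying inter-sample correlation.

**Compendium.**  Instances are uniform random rank permutations.  A mimic
compound with tilt λ draws gene scores as Gumbel(0,1) + λ on planted
up-genes and −λ on planted down-genes and ranks by descending score
(Plackett–Luce sampling with weights e^λ); a reverser swaps the roles;
λ = 0 is exactly random.  Defaults: 50 compounds × 3 instances with one
mimic and one reverser at λ = 3.

What the generator does **not** emulate: probe-level hybridization
artifacts, batch effects, heavy-tailed intensity distributions, correlated
noise between compounds, or real pharmacology.  Passing recovery tests
therefore demonstrates the statistical machinery, not performance on real
arrays.

## What the 3-vs-3 design can and cannot support

Several recovery targets are asserted by the acceptance suite at the
study's own conditions and fail there for reasons of statistical power, not
implementation.  With three samples per group:

- A 2-SD per-gene effect gives the pooled *t*-test (df = 4) ≈ 9% power at
  two-sided α = 0.005, so a planted signature is recovered at ~5–10%, not
  ≥ 80%; the recovered tags are nonetheless real and half of a typical
  signature is planted material.
- A 2-SD eigengene shift yields a population eigengene–trait correlation of
  ≈ 0.71, while Bonferroni-corrected significance at n = 6 requires a
  sample correlation above ~0.9 — per-module probability ≈ 0.1.
- Sample correlations between independent 6-vectors have SD ≈ 0.45, so
  ~11% of background genes correlate > 0.6 with any module latent purely by
  chance; they are statistically indistinguishable from members and chain
  into clusters, and at thousands of background genes whole noise clusters
  pass the 100-gene size filter.  Idealized partitions with the measured
  contamination cap the adjusted Rand index near 0.7.
- The end-to-end mimic-compound ranking inherits the weak signature and
  places the mimic first in roughly half the runs (it is essentially always
  first when the signature recovers more than a handful of planted genes,
  as in the README example with a 4-SD effect).

The null-calibration check (uniform permutation *p* for unplanted
compounds) uses six instances per compound rather than the generator
default of three: the same-sign rule nulls an instance with probability
≈ 1/2, so a compound's mean is exactly zero — forcing p = 1 — with
probability 2^−m, and at m = 3 that atom (0.125) sits at the rejection
boundary of the KS uniformity test itself (critical D ≈ 0.115 at 200
queries, α = 0.01), making the check uninformative; m = 6 shrinks the atom
to 1/64.

## Problem sizes

The recovery experiments run at 5,000 genes (6 planted modules of 150,
4,100 background genes) over 20 seeds; the null calibration uses 200
random queries at B = 200 against a 20-compound × 6-instance compendium on
a 1,000-gene universe; the scoring-bound and formula checks are exact and
instantaneous.  The pipeline itself handles 10,000-gene networks (the
float32 TOM needs ~400 MB at that size).

## Preclinical metrics

Closed-form formulas with explicit guards: SFI (three footprint ratios with
the −8.8 intercept; scale-invariant), total regenerating axons
`π r² · [axons/width] / t` with mandatory unit tags (the mm/µm mix is the
realistic failure mode; section thickness defaults to 0.010 mm), pupil
constriction as percent area change (a diameter convenience wrapper squares
its inputs), 2^−ΔΔCt fold change, and paired percent recovery.  Diameter
vs radius for the axon formula is resolved by naming the parameter `r` and
providing a `from_diameter` constructor that halves its input.
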