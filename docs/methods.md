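# Methods

This note documents the models implemented in `sarcomix`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a user relying on the outputs should know about.

## Clonality index

Two mutation catalogs A and B (identity key: chromosome, position, ref, alt;
gene and effect class are annotations) are compared through their shared
mutations. For a shared mutation with background probability *p* — the
chance that a random unrelated tumor carries it — the probability of seeing
it in both members of an unrelated pair is the binomial term
P(X) = C(n,k)·pᵏ(1−p)ⁿ⁻ᵏ with n = k = 2, hence P(X) = p². The clonality
index is

    CI = −log₁₀ ∏ₘ P(X)ₘ = −2 ∑ₘ log₁₀ pₘ

over the M shared mutations. CI = 0 when nothing is shared; each shared
mutation contributes more the rarer it is. The product is accumulated in
log space, so catalogs with up to 10⁴ shared mutations at p ≥ 10⁻⁶ cannot
underflow (CI values up to 1.2·10⁵ are exact to double precision).

**Background probability.** p = (c + 1)/(N + 1), where N is the reference
cohort size and c the number of cohort samples carrying the mutation.
c is counted at exact-variant level when the identical (chrom, pos, ref,
alt) key recurs in ≥ 2 cohort samples (a hotspot), and at gene level
otherwise. The add-one smoothing keeps p > 0 for private mutations; a gene
mutated in all N samples saturates at p = 1 and contributes nothing.
Mutations without gene annotation raise an explicit error when the
gene-level fallback would be needed. The hotspot recurrence threshold (2) is
a constructor argument of `BackgroundModel`.

**Cutoff calibration.** Per repeat: every cohort sample contributes one
positive-control pair per fraction f ∈ {0.4, 0.6, 0.8} — two *independent*
uniform subsets of size round(f·|catalog|) drawn from the same tumor, whose
intersection plays the role of shared mutations — and an equal number of
negative-control pairs are sampled without replacement from the unordered
pairs of distinct cohort samples. The cutoff is the threshold maximizing
Youden's J (sensitivity + specificity − 1) where "positive call" means
CI strictly above the threshold; candidates are the midpoints between
consecutive distinct pooled CI values, and ties in J break toward the larger
threshold (favoring specificity). One pooled cutoff is taken per repeat
(fractions are not calibrated separately); 100 repeats yield the median and
the 2.5/97.5-percentile interval. Classification compares the pair's CI
against the median with strict inequality; the position relative to the 95%
band is reported alongside. Background probabilities for the controls use
the full cohort without leave-one-out — at the default cohort sizes the
difference is within the smoothing term, and positives and negatives are
treated identically.

## Leukocyte-fraction deconvolution

At an informative CpG locus *i* the observed beta value of a tumor sample is
modeled as a two-population mixture, βᵢ = β_iL·π + β_iT·(1−π), where β_iL is
the leukocyte reference and β_iT a pure-tumor surrogate. Loci are the 2000
CpGs with the largest difference of group means between leukocyte and normal
lung panels, 1000 in each direction (fewer, with a warning, if the input has
fewer discriminating probes). The leukocyte reference is the per-locus
*mean* over the leukocyte panel (the aggregation is not dictated by the
model; the mean is stable for small donor panels). The pure-tumor surrogate
is chosen per locus as the tumor value with least evidence of leukocyte
methylation — the minimum over tumors at leukocyte-high loci, the maximum at
leukocyte-low loci — rather than one whole tumor, because no single sample
need be pure everywhere.

Per locus, π = (βᵢ − β_iT)/(β_iL − β_iT), clipped to [0, 1]; loci with
spread |β_iL − β_iT| < 0.05 are excluded (guarding the division), and fewer
than 50 usable loci is an error. The sample's LF is the mode of a Gaussian
kernel density estimate (Silverman bandwidth) of the per-locus π values,
taken as the argmax over a [0, 1] grid of step 0.001; ties and near-constant
inputs resolve to the smallest π. On the synthetic mixtures (noise sd 0.03,
2000 loci) recovery is within 0.011 of truth across the full 0–1 grid and
strictly monotone.

Known bias: the per-locus extremum estimator places β_iT slightly beyond the
true pure-tumor value (an order-statistic effect growing with noise and
cohort size), which compresses estimates toward the interior by a few
hundredths at the extremes. This is inherent to the surrogate definition,
not to the implementation.

## ssGSEA

Genes are ranked by expression (descending; average ranks on ties). Walking
down the ranking, the score is Σᵢ (P_in(i) − P_out(i)), where P_in is the
ECDF of the gene set weighted by rankᵃ (α = 0.75) and P_out the unweighted
ECDF of the complement. Positive scores mean the set concentrates at the top.
Scores are rank-based — invariant to any strictly increasing transform of
the expression values — and no cross-sample normalization is applied, since
the score is used single-sample.

## EMT score

Expression of the E/M signature genes (≥ 50% of the signature must be
present) is log2(x+1)-transformed, centered per gene (not scaled, preserving
the signature genes' relative weight), and the first principal component
across samples is the score. The sign is anchored so that the mesenchymal
gene VIM has nonnegative loading (falling back to the mean mesenchymal
loading when VIM is absent), making higher scores mean more mesenchymal.
Scores are centered to mean 0; the PC1 explained-variance fraction and the
loadings are returned for inspection. A constant matrix or < 3 samples is an
error.

## Cyber-T differential expression

Per gene, the within-group variance on log2(x+1) values is shrunk toward a
local background: the mean variance of the `window` (default 101) genes
nearest in average log expression, combined as
s̃² = (ν₀·s₀² + (n−1)·s²)/(ν₀ + n − 2) with prior weight ν₀ = 10. The t
statistic uses the regularized variances with ν₀ pseudo-observations per
group added to the degrees of freedom (df = n_a + n_b − 2 + 2ν₀). A gene is
called when the linear-scale ratio of group means is ≥ 2 or ≤ 0.5 **and**
p < 0.05 — the fold-change threshold is read as a magnitude, so strong
down-regulation also qualifies. On null data the realized type-I rate is
close to nominal (≈ 0.03–0.05 at α = 0.05; the local-background shrinkage is
mildly conservative).

## Methylation probe QC and DMPs

A probe is removed if (in this order, the first violated rule being
reported): detection p > 0.01 in at least one sample; beadcount < 3 in ≥ 5%
of samples; non-CpG probe; SNP overlap; multiple alignment; X or Y
chromosome ("chrX"/"X" dialects both accepted). The kept set is independent
of rule order; filtering is idempotent.

DMPs use a moderated t-test on beta values: per-probe pooled two-group
variances are shrunk toward a scaled inverse-chi-square prior whose
parameters (d₀, s₀²) are fitted by the standard moment method on
log-variances (digamma/trigamma matching, Newton-inverted trigamma); if the
moment fit degenerates the prior falls back to d₀ = 4 with the mean
variance. p-values use df = d₀ + (n_a + n_b − 2) and are BH-adjusted across
tested probes. The test statistic is mean-based while the reported effect
size is the difference of group *medians*; a probe is a DMP iff adjusted
p ≤ 0.05 **and** |Δ median β| ≥ 0.3 — both are carried in the output because
the calling rule couples a mean-based test with a median-based effect. The
implementation is checked against R limma on a shared fixture in the test
suite. When every probe has zero variance the test falls back to an ordinary
comparison with a warning.

Cancer-specific hypermethylation probes require normal median β < 0.2 and
tumor median β > 0.3 (strict inequalities). Co-methylation probe selection
requires BH-adjusted p ≤ 0.05 and |Δ mean β| ≥ 0.2, then keeps the 3000 most
variable probes among tumors by MAD.

## Clustering and subtype assignment

Hierarchical clustering is agglomerative Ward (classical minimum
variance-increase criterion on Euclidean distances, via scipy); the tree is
cut to k clusters and labels C1…Ck are assigned by decreasing cluster size
(ties by first occurrence). Labels carry no biological identity — that
requires external annotation. Features with missing values are dropped with
a warning.

Nearest-centroid prediction log2(x+1)-transforms the cohort, centers each
gene at its cohort median (centroid predictors assume centered data), and
assigns each sample the subtype with maximal Pearson correlation over the
genes shared with the predictor (≥ 10 required). Exact ties go to the
earliest centroid column and are flagged; zero-variance profiles get no
label. Methylation-subtype similarity is the plain Euclidean distance to
per-subtype mean beta profiles over common probes.

## Genomic summaries

TMB = (SNVs + indels)/Mb with the interrogated region size an explicit
parameter — there is no hard-coded exome size; pass the capture design's
total target length. The shared-mutation percentage uses the union of the
two catalogs as denominator (shared + specific-A + specific-B = 100%). CNV
overlap merges same-state intervals per chromosome (0-based half-open) and
reports 100·(gain∩gain + loss∩loss)/(union of all covered bases); it is
invariant to splitting segments into adjacent same-state pieces. The
two-leaf Newick tree `(E:bE,S:bS):t;` uses nonsynonymous counts: trunk t =
shared, branches = specific.

The mutual-exclusivity test counts samples mutated in ≥ 2 of the query genes
and permutes each gene's sample assignments independently, preserving
per-gene mutation counts (but not per-sample burden — the simplest null
consistent with a set-level overlap statistic). p = (1 + #{overlap ≤
observed})/(n_perm + 1); the add-one correction avoids p = 0. On null
matrices the rejection rate at α = 0.05 is ≈ 0.04.

## Synthetic data: what it emulates, and what it does not

The generators produce, with one explicit seed each and bit-reproducible
output: unrelated mutation catalogs with long-tailed gene recurrence plus
private passenger mutations; paired components with an exact planted shared
fraction; beta matrices mixed from leukocyte/pure-tumor profiles with
truncated Gaussian noise; expression cohorts as subtype centroids plus
planted EMT shifts and an infiltration gradient with Gaussian noise on the
log scale; and CNV pairs whose same-state overlap percentage is exact by
construction. Ground truth is emitted only into a sidecar YAML that no
analysis stage reads (enforced by a test instrumenting file access).

Defaults are chosen to be realistic for the motivating setting: ~190
mutations per catalog (about 6/Mb over a 30 Mb coding exome, typical of a
smoking-associated carcinoma), a long-tailed gene-frequency spectrum (a few
genes at 0.3–0.6 recurrence, a tail at 0.02), beta noise sd 0.03,
expression noise sd 0.1 log2 units. These are configuration, not claims
about any particular cohort.

Not emulated: linkage between mutations and CNVs, subclonal structure and
allele frequencies, array batch/dye effects, beta-value heteroscedasticity
(noise is homoscedastic truncated Gaussian rather than beta-distributed),
probe-probe correlation, library-size variation, or realistic genome
coordinates beyond interval arithmetic needs. Passing round-trip tests
therefore demonstrates correctness of the estimators under their own model
assumptions — not robustness to every artifact of real array/sequencing
data.

## Workflows, seeds, determinism

Each workflow derives one sub-seed per stochastic stage as SHA-256 of
`"<seed>:<stage>"` reduced mod 2³¹, records them in `manifest.json`
alongside SHA-256 checksums of every output file, and writes no timestamps,
so reruns with the same seed are byte-identical. TSV outputs are UTF-8,
tab-separated, '.' decimal, `NA` for missing. CLI exit codes: 0 success,
2 input error, 3 numerical failure.

Problem sizes used by the acceptance script (30-sample cohorts, 100
calibration repeats, 2000 LF loci, 5000-probe DMP panels, 10⁴ permutations)
match the defaults above; they complete in well under a minute and scale
linearly if enlarged.

## Known limitations

- The CI model treats shared mutations as independent given their background
  probabilities; regional hypermutation violates this and inflates CI.
- Background probabilities from small cohorts (N ≲ 20) are dominated by the
  smoothing term, compressing CI differences.
- The LF estimator reports the KDE mode, which is robust to outlier loci but
  can sit on a shoulder when the per-locus π density is genuinely bimodal
  (e.g. copy-number-distorted loci); the per-locus values are returned for
  inspection.
- Cluster labels are ordinal by size, so k chosen too large silently yields
  small trailing clusters; inspect the linkage heights.
- The Cyber-T and moderated-t priors assume exchangeable variances across
  genes/probes at similar abundance; strong mean-variance trends beyond the
  local window are not modeled.
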