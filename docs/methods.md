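# Methods

## The fiber-mixture model

A skeletal-muscle biopsy is never a pure fiber-type preparation. The
simulator and the downstream analysis both treat a sample as a convex
mixture: the expected expression of feature *g* in sample *s* is

    mu_gs  ∝  f_s · E_slow,g + (1 − f_s) · E_fast,g

where `f_s ∈ [0,1]` is the sample's slow-fiber fraction and `E_slow`,
`E_fast` are fiber-type expression profiles in arbitrary units. Per
sample the expectations are rescaled to the configured library size, so
simulated counts live on the same compositional scale as sequencing
data; counts are negative binomial with variance `mu + phi·mu²`
(`phi = 0` gives Poisson). True fold changes are recorded on the
relative (library-normalized) scale as
`log2(mean type2 / mean type1)` of the expectations, and a feature is
truly differential when |true log2FC| exceeds the design's threshold
(default 0.585, a 1.5-fold change).

The default study design mirrors the ten-athlete cohort: five samples
per group, slow fractions drawn around 0.68 (SD 0.05) for the
slow-predominant group and 0.30 (SD 0.05) for the fast-predominant one,
library size 10⁶, dispersion 0.1, lognormal(4, 1.2) baseline
expression, and a 6-fold fiber-type contrast for designated marker
features (after mixing at these fractions that contrast yields
|log2FC| ≈ 0.8, comfortably above the 1.5-fold call threshold).

### miRNA–gene coupling

Host-gene coupling of miRtronic miRNAs (and repressive miRNA–target
coupling) is modelled by a shared latent Gaussian on the log2 scale:
a per-sample factor `z_s ~ N(0, latent_sd²)` is added to the miRNA's
log2 mean and `sign · z_s` to the gene's, plus independent
`N(0, noise_sd²)` member noise. Defaults are `latent_sd = 2` and
`noise_sd = 0.1`: the observed host-gene correlations this emulates are
strong (ρ ≈ 0.85–0.9 at n = 10), which requires the shared factor to
dominate both the member noise and the counting noise. Because the
per-sample rescaling makes counts compositional, coupled features
should be a small share of the library in recovery experiments —
fixtures therefore place them on a large stable background; a coupled
pair that dominates the library perturbs every other feature's ranks.

### isomiR read simulation

Each simulated read realizes one class by construction on a randomly
chosen mature reference: `trim3` deletes 1–3 terminal 3′ bases, `ext3`
appends 1–3 random (non-templated) bases, `shift5` moves the 5′ end by
±1–2 (trimming templated bases or prepending random ones), and
`polymorphic` substitutes one internal, non-terminal base. Edit sizes
are clamped so read lengths stay in [16, 28]; references without
headroom for a drawn class are redrawn. Default class fractions are
canonical 0.43, trim3 0.20, ext3 0.20, shift5 0.05, polymorphic 0.12,
matching the observed muscle isomiR composition (canonical ≈ 43%,
3′ modifications ≈ 45% split evenly between trimming and extension,
5′ ≈ 5%, polymorphic ≈ 15%, renormalized to sum to one). Fractions are
interpreted per read; published class percentages do not state whether
the sampling unit is reads or distinct isoform sequences (and they sum
above 100%, suggesting multi-labelling), so the classifier's summary
reports multi-label per-flag fractions that may likewise sum above one.
Qualities are constant 'I' (Q40) since no downstream step uses them;
no precursor/hairpin sequence is modelled, so templated and
non-templated 3′ extensions are not distinguished.

## Read classification

Placing a read against a reference at 5′ offset `o5` fixes the 3′
offset `o3 = o5 + len(read) − len(ref)` (alignment is ungapped).
Overhanging read bases are untemplated and unscored; within the
overlap, mismatches at the two terminal positions are treated as
end-variation candidates rather than internal substitutions — this
separates SNP-like variants from untemplated terminal additions.
Candidates with internal mismatches ≤ 2 and |offsets| ≤ 3 are ranked by
(internal mismatches, |o5| + |o3|, reference name); a tie between two
references on the first two keys marks the read ambiguous, which is
recorded but the read is still counted once under the lexicographic
winner (deterministic, conserving counts). Flags follow the offsets:
`shift5` iff o5 ≠ 0, `trim3` iff o3 < 0, `ext3` iff o3 > 0,
`polymorphic` iff ≥ 1 internal mismatch, `canonical` iff no other flag.
Classification is against mature references only; no genome remapping
step is performed. Optional 3′ adapter removal is an exact search for
the adapter's leading 8-mer in the read's 3′ half.

Reference generation rejects same-length sequences within Hamming
distance 4 of each other, so simulated fixtures are unambiguous by
construction.

## Normalization

TMM follows the published trimmed-mean-of-M-values procedure: the
reference sample is the one whose 75th-percentile count fraction is
closest to the mean; per sample, log ratios `M` and average abundances
`A` over features nonzero in both sample and reference are doubly
trimmed (30% from each tail of M, 5% of A) and the factor is
`2^(weighted mean of M)` with inverse-asymptotic-variance weights,
rescaled to geometric mean one. The implementation agrees with the
canonical edgeR values to 5·10⁻⁶ on a frozen NB fixture. The precision
weights depend on absolute counts, so the weighted factors are only
approximately invariant when one sample's counts are globally rescaled
(≈ 0.3% on the fixture); the unweighted variant (`weighted=False`) is
exactly invariant and is used for the strict invariance test.

The noise filter removes features with mean count ≤ 2 **and** zero
counts in ≥ 90% of samples (the conjunction reads the filter's
description literally; a disjunctive switch is provided because the
wording is ambiguous). Group-mean CPM filters use strict `>` by
default with an inclusive option, and CPM uses TMM-adjusted (effective)
library sizes. The log transform is `log2(cpm + 1)`; the prior count is
configurable and defaults to 1.0 (simple, zero-preserving).

## Differential expression

Dispersions are method-of-moments per feature on counts scaled to a
common (geometric-mean) library size with group means removed, floored
at zero, then shrunk halfway (weight 0.5) toward a lowess trend over
log2 mean expression. The group effect is a likelihood-ratio test
between a two-group-mean and a single-mean NB model — means fit by
Fisher scoring on effective-library-size offsets, dispersion held fixed
at the shrunk estimate — referred to χ²(1). This is a deliberate,
simulation-calibrated substitute for a quasi-likelihood F-test: on null
fiber-mixture simulations (2000 features, 10 per group, phi = 0.1, 200
seeds) the fraction of p < 0.05 is ≈ 0.056, and power at a 3-fold
change with 5 per group and phi = 0.1 is ≈ 99% at FDR < 0.05. Exact
equivalence with any particular edgeR version is a non-goal.

log2FC is computed from group-mean TMM-CPM with a 0.5 pseudo-CPM in
numerator and denominator (avoids division by zero; the source of the
printed fold changes is not otherwise specified), oriented type2/type1.
BH adjustment is the standard step-up procedure (statsmodels backend,
verified against a literal step-up oracle). Fiber-percentage group
comparisons use Welch's unequal-variance t-test (the published
comparison does not name its test; Welch is the safe default), with
sample SD (n−1).

## Correlation integration

Spearman's rho is the Pearson correlation of average-tie ranks; zero
rank variance raises a dedicated error rather than returning 0. The
two-sided p uses the t approximation `t = rho·sqrt((n−2)/(1−rho²))`
with n−2 df — the choice reproduces every numeric two-sided p printed
for the study's host-gene and target tables at n = 10 to printed
precision, provided the printed (3-decimal) coefficient is first
de-rounded to the nearest attainable untied value
`rho = 1 − 6S/(n(n²−1))`, S integer (`nearest_attainable_rho`).

The permutation p permutes the gene vector only (equivalent to
permuting sample pairings under exchangeability), B = 1000 by default,
with the add-one estimator `(b+1)/(B+1)` so p = 0 is impossible; a
plain `b/B` switch and an exhaustive mode (all n! permutations, exact
fraction) are provided. Per-pair substreams are spawned from the user
seed, so tables are reproducible and pairs independent. Comparisons of
|rho| use a 10⁻¹² tolerance so ties in the discrete null are counted as
hits.

Validated-target interactions require all three strong evidence
methods — reporter assay, Western blot, qPCR — matched case- and
punctuation-insensitively ("qRT-PCR" satisfies qPCR); an alternative
mode accepts any ≥ 3 distinct methods. Strong pairs are |rho| > 0.8
strict. The shared-target network keeps targets connected to at least
two of the supplied differentially expressed miRNAs; the external
enrichment FDR of the original network tool is out of scope.

## PCA and ranking

PCA is the SVD of the sample-centered (unscaled by default) matrix;
components are sign-fixed by making each component's largest-|loading|
entry positive, so results are exactly reproducible. Gene matrices are
pre-filtered by dropping the lowest-variance 10% of features (ties
broken by name); miRNA matrices are not. Abundance ranking assigns
rank 1 to the highest mean CPM per dataset, ties broken by feature
name, and absent features rank `n_features + 1`.

## Reproduction script problem sizes

`scripts/acceptance.py` uses: 1000 random classifier fixtures (4
references each), isomiR recovery at depth 5000 over 10 references,
type-I calibration over 200 seeds × 2000 features (n = 10 per group),
power/precision over 20 seeds × 2000 features (n = 5 per group, 10%
features at 3-fold), permutation calibration over 1000 null data sets
with B = 1000, coupling recovery over 200 seeds, and 1000 random BH
vectors. All sub-seeds derive from `--seed`.

## What passing tests do and do not show

The synthetic generator reproduces the statistical structure the
pipeline targets — NB counts over a fiber mixture, constructed isomiR
edits, latent miRNA–gene coupling — but not sequencing-error profiles,
adapter chemistry, multi-mapping between homologous miRNA family
members, precursor-templated extensions, or compositional artifacts of
highly dominant miRNAs (in real muscle a single miRNA can carry ~80% of
reads). Recovery results on synthetic data therefore validate the
implementation's correctness under the stated model, not the upstream
biology; classification of real reads against full miRBase references
will additionally face ambiguity between paralogous mature sequences
that the Hamming-separated synthetic references exclude by design.

## Known limitations

- The classifier has no genome remapping step, so reads from non-miRNA
  loci that resemble a mature sequence within the mismatch budget are
  counted as miRNA.
- The NB likelihood-ratio test with 1 df is slightly anticonservative
  at small n (measured type-I ≈ 0.056 at nominal 0.05); calibration is
  quantified rather than corrected.
- Permutation p-values at n = 10 have a discrete support; with
  B = 1000 the smallest attainable p is ~0.001.
- The evidence-method matcher is string-based; exotic assay spellings
  may need the `mode="any"` fallback.
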