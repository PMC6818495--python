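# Methods

This note records the models, conventions and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Genotype containers and coordinates

Genotypes are additive alt-allele counts {0, 1, 2} stored as floats with
NaN for missing; any half-call or unknown allele maps to missing.
Multi-allelic VCF records are skipped (counted and logged) rather than
split, because all downstream statistics are defined on biallelic sites
and splitting semantics (allele pairing, genotype recoding) would add
conventions the analyses do not need. VCF and all internal coordinates are
1-based inclusive; BED is 0-based half-open on disk only and converted on
read. Indels are carried through the containers but excluded from the Fst
and signature stages, which are SNV-only.

## Weir–Cockerham Fst

`site_fst_from_counts` implements the two-population (r = 2) variance
components of Weir & Cockerham (1984) with the n_c sample-size correction,
from observed genotype counts (which may be real-valued, so
Hardy–Weinberg-expected counts are accepted; `site_fst_from_frequencies`
provides that expansion for frequency-only inputs). Conventions:

- Negative θ̂ values are retained for means and quantiles, matching common
  VCFtools-style output; clamping at zero would bias the genome-wide mean
  upward, which matters when the expected differentiation is of order 10⁻³.
- A site monomorphic across both populations has a = b = c = 0 and θ̂
  undefined (NaN); such sites are excluded from means and tail statistics.
- Scans drop sites whose pooled missing rate strictly exceeds the
  `max_missing_rate` threshold (default 0.5) and sites with fewer than two
  typed individuals in either population.
- The empirical cutoff at tail probability q is the smallest observed θ
  whose empirical P = #{θ ≥ x}/N is strictly below q; ties at the cutoff
  are all reported. With a strict "<" there can be slightly fewer tail
  sites than q·N; an inclusive comparison would change the count by the
  tie multiplicity, and the strict convention is documented rather than
  asserted as the only defensible one.

## Population-specific screen

The screen asks whether either allele of a biallelic site is elevated in
the cohort by at least δ = 0.3 over that allele's frequency in each of the
four outgroup panels. Two deliberate choices:

- The EAS panel is *not* thresholded. The target set is defined as cohort
  variants shared with East Asians, and the published member SNPs include
  rows whose EAS-outgroup gaps fall below 0.3; the 0.3 criterion therefore
  applies to the cohort frequency only, with EAS recorded for context.
- The boundary is inclusive with a 1 × 10⁻⁹ numeric tolerance: the
  tightest published member sits at a gap of exactly 0.30, and floating
  subtraction of decimals (0.64 − 0.34) demands a tolerance.

Testing both alleles makes the screen invariant to which allele a panel
designates, equivalent to a sign-consistent absolute-gap rule.

## Mutational signatures

- "Supported by more than 10 reads" is read strictly: min_support = 11.
- The 96 context labels are ordered substitution-major (C>A, C>G, C>T,
  T>A, T>C, T>G), then upstream base, then downstream base, and this order
  is written into every output header; purine-centered mutations are
  reverse-complemented into the pyrimidine convention, making
  classification strand-involutive.
- NNLS refitting against a fixed catalogue is the primary path; de novo
  NMF (best of several random restarts by Frobenius error, factors matched
  to a catalogue by cosine similarity) is provided as an alternative.
  Refitting answers "how much of each known process", which is the
  question the group comparisons and the load GWAS need; NMF's
  factorization is only identifiable up to rotation unless near-pure
  samples exist, so it is secondary.
- Exposures are fit on raw counts; group comparisons use row-normalised
  proportions. The rank-sum test is exact for combined n ≤ 20 (falling
  back to the normal approximation in the presence of ties) and
  continuity-corrected asymptotic otherwise.
- The signature-load GWAS uses simple per-SNP OLS with a MAF ≥ 0.05
  filter; the significance threshold is configurable (default 10⁻⁵, with
  10⁻⁷ as a stricter preset — both conventions are in circulation for
  this design and the package does not arbitrate).

## SV consensus merging

"Overlapped more than X %" is read as *reciprocal* overlap (the minimum
over both intervals of intersection/length) with strict ">", the
field-standard convention when the denominator is unspecified. Merging is
greedy highest-overlap-first with deterministic coordinate tie-breaks,
which makes the result invariant to input order and idempotent; merged
breakpoints are the mean of all original members' breakpoints, rounded
half-up. Within-sample merging (80 %) is applied globally across callers
rather than caller-pairwise. Insertions are point-like, so reciprocal
overlap is ill-defined; they are merged by breakpoint distance ≤ 100 bp
instead, closest pairs first. Gap filtering removes consensus SVs whose
length is covered > 80 % by the *union* of gap intervals (not any single
gap). Repeat annotation flags any ≥ 1 bp intersection per repeat class.

## Association and enrichment

- Quantitative traits are normalised by the rank-based inverse-normal
  transform with Blom offsets, z = Φ⁻¹((rank − 3/8)/(n + 1/4)); a z-score
  option exists. Rank-based normalisation makes the per-SNP OLS robust to
  trait-scale choices.
- No covariates by default; sex is handled by stratification (total /
  male / female runs), matching the stratified design the package targets.
- Per-genotype comparisons use the Welch (unequal-variance) t-test; the
  equal-variance variant is not exposed because the genotype groups
  routinely differ in size and spread.
- Logistic fits flag likely complete separation (non-convergence or
  runaway estimates) instead of reporting unstable coefficients.
- Enrichment is the one-sided hypergeometric upper tail with BH
  correction; the background defaults to the union of the catalog's gene
  sets, since an unstated background is most conservatively taken as
  "genes the catalog could have returned".

## DHS linking

Distance is measured between interval midpoints with an inclusive
±500 kb window; the correlation threshold r > 0.7 is strict. Signals are
used as provided, with an optional per-site z-scoring switch (Pearson r is
invariant to it; the switch exists to mirror normalised-signal inputs).
The number of cell types is a parameter, not a constant.

## Synthetic data

The generators define the study conditions under which the package is
validated:

- **Genotypes**: Balding–Nichols — ancestral p ~ Uniform(0.05, 0.95),
  per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes
  Binomial(2, pᵢ). F is interpretable as the target Fst, and the default
  cohort shape is 339 + 116 to mirror the north/south split the analyses
  assume. No linkage disequilibrium, no allele-frequency spectrum realism
  beyond the uniform ancestral draw.
- **Outgroup panels**: planted sites satisfy the screen by construction;
  null sites pin one outgroup within 0.25 of the cohort frequency so that
  neither allele orientation can pass.
- **Singletons**: a random uniform-composition reference sequence,
  mutation contexts drawn from the signature mixture and placed at
  matching reference trinucleotides (either strand), read support drawn at
  or above the filter threshold; configurable fractions planted into the
  known set or duplicated across samples to exercise the filters.
- **SVs**: truth intervals assigned to random carrier subsets with
  Gaussian breakpoint jitter; decoys below 50 bp and above caller caps
  injected.
- **Phenotypes**: additive genetic value plus Gaussian noise, optional
  male-only effect.
- **DHS**: planted pairs share a latent factor scaled to a target Pearson
  correlation; pairs are separated beyond the window so planted links are
  unambiguous.

Every generator is a pure function of its seed (bitwise-reproducible), and
every dataset is returned together with its generating truth. What passing
tests show is that each estimator recovers the parameters of its own
generating model at realistic sample sizes; they do not show robustness to
LD, calling artifacts, population admixture, batch effects or reference
bias, none of which the generators emulate.

## Problem sizes and numerical conventions

The validation suite runs cohorts of 100–600 samples and 10²–10⁵ sites,
chosen so each statistical check has enough resolution for its tolerance
(e.g. the low-differentiation recovery uses 10⁵ sites for a ±0.0005 band
around F = 0.0015). WC oracle agreement is checked to 1 × 10⁻¹²; NNLS
recovery to a mean absolute proportion error of 0.05 at 1000 mutations per
sample; type-I error bands are ±0.02 around α. Degenerate inputs
(monomorphic sites, all-missing groups, zero-count samples, zero-variance
signals, constant traits) are either flagged, skipped with a reason, or
raised as errors, as documented per function.

## Limitations

- Two populations only (r = 2); no multi-population or haplotype-based
  differentiation statistics, and no sliding-window smoothing.
- No covariate adjustment, kinship or mixed models in association.
- The SV stage merges and annotates existing call sets; it does not call
  variants or re-assemble breakpoints, and CNV segmentation is out of
  scope.
- The DHS stage consumes prepared signal matrices, not raw ENCODE tracks.
- The bundled frequency panel is a small published table for validation
  and examples, not a substitute for full outgroup reference panels.
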