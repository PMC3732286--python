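# Methods

This note documents the statistical models, the numerical choices and the
design decisions behind `triogwas`, and what the synthetic-data tests do
and do not establish about real data.

## Genotype representation and trio QC

Genotypes are coded as the dosage of allele A1 (0, 1, 2; −1 missing), and
imputation posteriors as probability triplets indexed the same way.  A
posterior triplet is hard-called to the genotype whose probability
*strictly exceeds* the threshold (default 0.95); otherwise the call is
missing.  The strict comparison follows the convention of calling a
genotype only when one posterior clearly dominates, and makes the rule
monotone: raising the threshold can only turn calls into missings.  The
rule is applied per genotype triplet (per sample per marker), the natural
unit at which imputation software reports posteriors.

Mendelian consistency is checked only on fully typed trios: with `h` A1
alleles forced by homozygous-A1 parents and `k` heterozygous parents, a
child dosage `c` is possible iff 0 ≤ c − h ≤ k.  An inconsistency masks
the genotypes of the *whole family* at that marker (parents and all
offspring), mirroring family-wise masking by standard pedigree tools;
partially typed trios are never flagged.  Masking is all-or-none within a
family at a marker, so downstream counts never mix a masked member with
unmasked relatives.

Marker QC removes markers whose call rate is not strictly above 0.97
(denominator: all samples in the assembled panel).  Minor allele
frequency is computed from founders only (individuals without parents in
the panel) and reported against a 0.01 threshold; the MAF filter is off
by default because panels differ in whether rare markers should be
dropped or only flagged.  QC changes set membership only, never genotype
values.  Note that the call-rate filter models *array-stage* QC: a panel
whose genotypes exist only as moderately confident imputation posteriors
will legitimately lose markers here, because a 0.95 posterior cut at ~88%
confidence yields call rates near 0.89.  The expected-count TDT is the
intended analysis path for such data; it uses the posteriors directly and
does not depend on the call-rate filter.

## TDT on hard calls and on expected counts

Classical counting: each heterozygous parent of an affected child
contributes one transmission, T for A1 and U for A2; with both parents
heterozygous and a heterozygous child, one of each.  Per-marker counts
are aggregated over trios *before* testing (a single pooled test per
marker, not per-trio tests), and χ² = (T−U)²/(T+U) is referred to χ²(1).
On integer counts this is exactly McNemar's test on discordant
transmissions, which the suite verifies against an independent
implementation.

The expected-count variant enumerates the 27 joint hard-genotype
configurations of a trio, weights each by the product of the three
members' posteriors, zeroes Mendelian-inconsistent configurations and
renormalizes over the consistent mass before accumulating expected
counts.  Renormalization keeps each trio's contribution on the same scale
as a hard-called trio (its expected T+U equals the expected number of
heterozygous parents), so noisy and certain trios mix coherently.  Trios
whose consistent mass falls below 10⁻⁹ carry no usable information and
are skipped.  With certain posteriors the procedure reduces *exactly* to
hard-call counting (property-tested over random consistent trios).  The
same χ² functional is applied to the real-valued counts; its null
calibration under ascertained-family simulation is checked empirically
(rejection at α = 0.05 within three Monte-Carlo standard errors for both
modes).

Affected siblings contribute as separate trios by default (the test then
reads as linkage in the presence of association); a `one_per_family` flag
restricts to the first affected offspring when independence of trios is
wanted.

## Stratified TDT

Offspring are assigned to the high-risk stratum iff they carry the
HLA-DQA1\*02/05 risk allele *and* are homozygous for DQB1\*02; all others
are low-risk.  Strata get independent TDTs; markers are ranked by the
pooled weighted chi-square

  W = Σ_g (T_g − U_g)² / Σ_g (T_g + U_g),

which reduces to the plain chi-square for a single stratum and rewards
signal concentrated in one stratum without letting a small stratum
dominate.  W is a ranking statistic; no p-value is attached to it.
Uninformative strata contribute (0, 0) to both sums.

## Marker selection and regions

All threshold comparisons are strict ("less than").  The replication
criterion harmonizes the external effect direction to the internal A1
allele before comparing signs; markers whose external alleles match
neither internal allele are dropped from that criterion with a warning.
Selection uses the expected-count TDT p-values by default (the hard-call
results can be substituted).  Regions are maximal runs of selected
markers on one chromosome with adjacent gaps strictly below 100 kb; a gap
of exactly 100 kb splits.  Gene annotation measures the distance from the
marker to the nearest interval endpoint (0 inside the gene), keeps up to
five genes within 250 kb ordered by distance with ties broken by gene
symbol, and falls back to the single nearest gene when none is within the
window.  BED input (0-based half-open) is converted to 1-based inclusive
internally.

## Two-locus interaction model

For a marker pair, one affected offspring per family (the first in
pedigree order) is the case; the pseudo-control genotype at each locus is
`father + mother − child` on the dosage scale, well defined for every
consistent trio including double heterozygotes, and is formed per locus
independently (the loci are assumed unlinked, consistent with pairing
only across distinct regions).  Families with any of the six genotypes
missing, or a Mendelian inconsistency at either locus, are skipped; pairs
with fewer than 20 complete families are not tested.

The likelihood treats the case cell probabilities as proportional to
g_ij·f_ij (genotype frequency times penetrance) and the pseudo-control
cells as draws from g alone, with g the product of the two HWE genotype
distributions.  The pseudo-control distribution is taken unconditional on
parental genotypes; its calibration under the null is established by
simulation rather than assumed.  Identifiable parameter counts — the case
distribution identifies f only up to a scale factor — are M₀: 2, M_M: 6,
M_R: 7, M_G: 10, giving LRT degrees of freedom 8 (P₀₂), 3 (P₁₂) and 4
(P_M2).  The statistic 2Δℓ is clipped at zero before the χ² tail is
taken.

Fitting: M₀, M_M and M_G have exact maximizers, used directly.  Under M₀
a constant f cancels, so both tables are i.i.d. draws from g and the
allele-frequency MLEs are the pooled HWE margin estimates.  Under M_G a
free f lets the case distribution saturate at n/N while the frequencies
fit the pseudo-control margins.  Under M_M the case distribution is an
arbitrary product measure, so its maximum is the independence fit of the
case margins.  (At the clipped penetrance bounds [10⁻⁶, 1−10⁻⁶] these are
suprema when a margin count is zero; the discrepancy is far below the
10⁻⁶ nesting tolerance.)  The heterogeneity model M_R has no closed form
and is maximized by bounded L-BFGS-B from one moment start
(pseudo-control margin frequencies, flat penetrances 0.1) plus ten seeded
random restarts, ties resolved in favor of the earliest start.  The
numeric route exists for all four models and the suite cross-checks it
against the analytic maxima and against an exhaustive coarse grid.
Allele frequencies are constrained to [10⁻³, 1−10⁻³].

Classification of a pair: not reported unless P₀₂ < 10⁻⁴; reported pairs
with P_M2 ≥ 0.05 are multiplicative-consistent (the expected pattern when
one member is a false positive); otherwise P₁₂ < 10⁻⁴ labels epistasis,
P₁₂ > 0.05 heterogeneity, and the band between stays reported but
unlabeled.  All four thresholds are parameters.

## Expression (ΔΔCt)

The per-sample reference value is the arithmetic mean of the
reference-gene Cts, identical to the geometric mean of the 2^−Ct
quantities; reference genes are a configuration input (default ACTB,
EPCAM, PGK1).  Samples without any reference measurement are excluded
with a warning.  Group comparison uses Welch's t-test on ΔCt by default —
ΔCt is the scale on which qPCR noise is closest to Gaussian — with a
Mann–Whitney option; the suite checks Welch against a permutation test on
a small fixture.  Fold changes are ratios of group mean RQs reported as a
magnitude ≥ 1 plus a direction, ties counting as UP.  Bonferroni
correction multiplies by the number of assays with a computable p-value
by default (assays with no detectable expression do not inflate the
multiplier); the multiplier is exposed as a parameter.

## Synthetic data generator

The generator emulates the ascertained nuclear-family design: parents
drawn from HWE independently per locus (no linkage disequilibrium, the
regime the interaction model assumes), offspring by Mendelian
transmission, affection Bernoulli with a penetrance computed from the
child's genotypes, and families retained only when at least
`min_affected` (default 2 of 2) offspring are affected.  Defaults: 97
families, allele frequency 0.3, a genotype-independent baseline
penetrance of 0.02.  Multiple disease-model components combine as
independent causes, 1 − Π(1 − f_k).  Generation is vectorized in batches
and aborts if the ascertainment yield drops below one family per million
attempts.  Stratum labels derive from a designated "HLA-like" locus: high
iff homozygous for its risk allele, a proxy for DQB1\*02 homozygosity.

Posterior noise blurs the true genotype with a symmetric Dirichlet:
posterior = (1−λ)·onehot + λ·Dir(1,1,1).  Since the off-truth components
never exceed λ, the fraction of true-genotype posteriors above 0.95 is
(0.05/λ)² for λ ≥ 0.05; the default λ = 0.053 reproduces the ~88–89%
high-confidence regime of a well-imputed genome-wide panel.  λ = 0 gives
certain posteriors (and exact reduction of the expected-count TDT to
hard calls); λ = 1 gives pure Dirichlet draws that almost never clear the
call threshold.

Calibration and power simulations set the penetrance scale well above the
defaults (for example a genotype-independent 0.5 for null runs): when
affection is independent of genotype, ascertainment is independent of the
genotypes too, so the null distribution of every statistic is unchanged
while the rejection-sampling cost drops by orders of magnitude.  The
canonical planted effects used across tests are an epistatic
double-carrier penetrance (baseline 0.02, 0.30 when both loci carry a
risk allele — a 15-fold joint risk that still leaves enough off-block
cases to expose non-multiplicativity) and a heterogeneity penetrance with
per-locus carrier risks of 0.25 on a 0.01 baseline.

What the generator does *not* emulate: linkage disequilibrium and
haplotype structure, population stratification, genotyping-error
mechanisms beyond the Dirichlet blur, parental affection, or variable
family sizes.  Passing tests therefore demonstrate correctness of the
estimators under the stated model — HWE founders, no LD, ascertainment on
offspring affection — not robustness to LD-induced confounding within
regions (which the cross-region pairing rule is there to avoid) or to
stratified populations (the TDT's own robustness argument applies, but is
not separately simulated).

## Problem sizes and numerical tolerances

The test suite and acceptance script run on one CPU in a few minutes:
null LRT calibration uses 1000 datasets of 100 families (99% binomial
band around α = 0.05), discrimination 100 replicates per scenario at 500
families, frequency recovery 100 (suite) / 60 (script) replicates at 500
families, and the end-to-end pipeline demo 80 families × 10 markers.
Chi-square tails are computed with `scipy.stats.chi2.sf`; nested
log-likelihood ordering is asserted to 10⁻⁶ (optimizer tolerance);
expected-count reduction at λ = 0 is exact, not approximate.  The
simulated-founder allele-frequency check uses a 3-standard-error band.

## Known limitations

* The weighted stratified chi-square is a ranking device without an
  attached null distribution.
* The interaction LRT's χ² reference relies on asymptotics; at 100
  families with common alleles it is empirically well calibrated, but
  rare alleles (sparse table cells) may inflate the tail.
* The expected-count TDT treats posteriors as exact probabilities;
  systematically miscalibrated imputation would propagate.
* X-chromosome inheritance, parent-of-origin effects and sib-TDT designs
  without parents are out of scope.
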