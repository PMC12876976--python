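# Methods

## Genotype calling

A site is callable when its total read coverage (COV_tot, the sum of the
four base counts) reaches `min_total_coverage` (default 10 reads). The most
abundant base is always an allele; the second base is accepted as a
heterozygous allele when its relative coverage is **at least**
`min_relative_coverage` (default 0.20) of COV_tot — the boundary is
inclusive, so 20/100 is heterozygous. Only the top two bases are ever
considered: the markers are biallelic amplicon SNPs and any third base is
treated as sequencing error. Count ties are broken alphabetically
(A < C < G < T), which makes calls deterministic; ties at the het/hom
boundary are resolved toward heterozygosity by the inclusive rule. The
caller is diploid-oriented. Triploids (LLR, RRL) are identified by the
taxon-assignment step and excluded from frequency analyses: at a 20%
relative-coverage floor a 1/3-dosage allele is usually detected, but the
caller cannot distinguish 1:2 from 1:1 allele ratios, and raising the floor
(e.g. to 30%) produces false homozygotes in triploids. The threshold is
exposed as a parameter only.

Taxon assignment pools L- and R-diagnostic read counts across all
adequately covered panel sites and classifies the pooled L fraction p̂ to
the nearest expected dosage among 0 (RR), 1/3 (RRL), 1/2 (LR), 2/3 (LLR),
1 (LL), reporting the distance as a quality measure. Pooling across sites
makes the binomial error of p̂ small (SE ≈ 0.5/√(total reads)), so with ≥ 8
panel SNPs at ≥ 50× coverage misassignment between adjacent dosages
(separation ≥ 1/6) is negligible.

## Allele frequencies and SNP classification

SNPs called in fewer than 5 individuals of any analyzed taxon are removed.
Population units are built per genotype class: populations with ≥ 4
individuals of the class stand alone; smaller ones are pooled with the
other small populations of the same POPSYS and geographic region (the
region is an explicit metadata column — pooling follows named regions, not
a distance rule); a small population with no partner is flagged and
excluded. Pooling conserves allele counts by construction (unit numerator
and denominator are sums over members).

Frequencies count 2 allele copies per homozygote and 1 per heterozygote of
the designated nucleotide, over called diploid individuals only. The
designated nucleotide is the major allele in pooled LL (falling back to the
overall major allele). A SNP is species-specific when the designated allele
is at or beyond the 0.95/0.05 fixation band in **both** parental species on
opposite states — equivalently, frequency ≥ 0.95 in exactly one species.
The expected fixed state per species (0 or 1) is recorded whenever that
species is within the band. An optional `sex_separated` mode emits
additional per-sex unit rows, the dual computation used for populations
whose system assignment is ambiguous (hybrid females may immigrate from a
neighbouring system).

## Introgression rates

For species-specific SNPs, the cell value |f − expected state| is the
frequency of foreign-species alleles in that unit. Deriving the expected
state from the pooled species mean (rather than from the table's allele
label) makes the estimator invariant to which physical allele a published
row happens to track — in the packaged survey four rows are printed on the
opposite allele convention, and the estimate is unaffected. IR_SNP and
IR_POP are row/column means skipping missing cells; IR_mean is the grand
mean, which equals the count-weighted mean of IR_POP. Both the population
(N) and sample (N−1) SD over cells are reported; comparisons against the
published summaries use the sample SD, which reproduces the printed ±0.0134
(LL) where the N form gives 0.0132. Table comparisons round half-up at the
table's precision.

## POPSYS association

The response is grouped: one frequency per population unit backed by n
allele copies. The logistic model is fitted by weighted least squares on
empirical logits with Berkson minimum-logit-χ² weights w = n·f(1−f) — the
standard WLS treatment of grouped proportions; w = n is available as an
option. Frequencies are clamped to [1e-10, 1 − 1e-10] before the logit;
results are insensitive to the floor whenever frequencies are interior.
POPSYS is dummy-coded; type III F tests drop each predictor group from the
full model with unchanged weights, which makes them invariant to the
reference level. R² = 100·(1 − SSE/SST) on the weighted scale. The
goodness-of-fit χ² bins the fitted logits into 5 equal-count classes and
compares observed and fitted success/failure counts per class, with
df = classes − parameters floored at 1; the class count is a convention
(the source procedure divides fitted logits into classes without stating a
count). Forward stepwise selection enters the candidate with the smallest
type III p ≤ 0.05, ties broken by the fixed order POPSYS, LAT, LON; 0.05 is
the conventional α. Per-SNP p-values are reported raw, with a
Benjamini–Hochberg column emitted alongside but never used for the
replication path. Because the exact weighting, class-count and α
conventions of the original proprietary fits are not published, per-SNP
F statistics are expected to agree qualitatively, not digit-for-digit;
the test suite therefore checks the estimator's *properties* (normal-
equation equivalence, reference-level invariance, permutation calibration,
planted-effect power) rather than printed regression tables.

## Multilocus genotypes

MLGs are per-individual IUPAC strings over the associated SNP panel;
identical strings within a genotype class collapse into one MLG with a
multiplicity. Each MLG enters the discriminant model once (not weighted by
multiplicity): the published analysis counts observed MLGs as cases. An
MLG's POPSYS label is the modal label of its carriers (alphabetical
tie-break); shared MLGs keep the full label set.

The p-distance treats ambiguity codes as average states: identical symbols
(including identical ambiguity codes) score 0; otherwise a site scores the
mean mismatch over all resolution pairs, 1 − |A∩B|/(|A||B|); sites with N
or a gap in either sequence are deleted pairwise. UPGMA uses average
linkage with node heights at half the cluster distance, so the tree is
ultrametric by construction (checked to 1e-9); merges are deterministic.

For discriminant analysis each base maps to its proton count (A=70, T=66,
C=58, G=78) — an arbitrary but fixed quantitative coding; an ambiguity code
maps to the mean of its constituents, which preserves the dosage ordering
(A 70 < R 74 < G 78). Missing sites are mean-imputed per variable with a
logged count. Variables enter by the partial F from the one-step change in
Wilks' Λ, F = (Λ_p/Λ_{p+1} − 1)(n − g − p)/(g − 1), while the largest F is
≥ 4.0, up to 50 steps. Note that selecting the maximum over k candidates
inflates the null entry rate relative to a single F test: with 5 null
variables and F(1,38), the probability that nothing enters is
(1 − 0.053)⁵ ≈ 0.76, and the permutation test checks exactly this analytic
value. The primary reported accuracy is resubstitution (% correctly
classified); a stratified k-fold cross-validated accuracy is emitted
alongside, since resubstitution is optimistic.

Linkage disequilibrium between unphased diploid SNPs is the composite
(Burrows-type) genotypic correlation: the Pearson correlation of
designated-allele dosages (0/1/2) over individuals called at both sites;
no phasing is attempted. Monomorphic SNPs yield a missing value.

## CDS statistics

GC is computed over non-N positions (the denominator convention is ours;
with ≤ 5% N the choice moves GC by < 0.3 points). Records above 5% N are
flagged excluded. Amino-acid distances translate in frame 1 with the
standard code (inputs are CDS). The per-gene "divergence range" is
max − min of the pairwise intraspecific distances; genes whose range
strictly exceeds the empirical 95th percentile of ranges are flagged as
introgression candidates. Fig-style regressions use one value per gene.

## Synthetic cohorts

The generator emulates the cohort structure the pipeline assumes: dosage
genotypes per taxon (LL 2 L copies, RR 2 R, LR 1+1, LLR 2+1, RRL 1+2); in
parental individuals each allele copy is independently replaced by the
other species' allele with the configured introgression rate (0.01–0.1
covers the empirically observed range); per-SNP, per-POPSYS allele
frequencies can be planted to create association signal. Coverage is
negative-binomial (mean 100×, dispersion 5 by default — amplicon coverage
is overdispersed, and no empirical per-site distribution is published, so
these are conventions, not reproductions); each read reports a uniformly
chosen allele copy and is miscalled to a uniform other base with
probability 0.001 by default. One site per marker is simulated (SNPs are
analyzed independently). Fixed seed ⇒ bit-identical output.

What the simulator does **not** emulate: PCR duplicates and primer
artifacts, allele-specific amplification bias (the dosage distortion that
motivates excluding triploids), within-amplicon haplotypes, linkage between
SNPs (except the perfect co-inheritance used in LD tests), and population
structure beyond unit-level frequencies. Passing tests therefore
demonstrate correctness of the estimators under the stated sampling models,
not robustness to those artifacts.

## Problem sizes

Stochastic checks use 500 parental individuals × 16 SNPs for rate recovery
(binomial 3-SE bands on 1,000 allele copies), 30 units × 200–500
replicates for the regression calibration and power checks, and 200
replicates for the LDA permutation check; these sizes put Monte-Carlo error
well inside the asserted bands while keeping the default suite fast.

## Known limitations

* Triploid allele-dosage genotyping is out of scope; triploids are flagged
  and excluded, as in the source analysis.
* The estimator does not distinguish introgression from incomplete lineage
  sorting, homoplasy, or gene flow from sibling species; it quantifies
  departures from fixation only.
* Exact digit-level replication of the published regression and
  discriminant tables depends on unpublished conventions (WLS weights, GOF
  class count, stepwise α, resubstitution vs CV); the replication tests for
  the published MLG accuracies accept ±3 percentage points and require the
  journal's supplementary files, which are not redistributable here.
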