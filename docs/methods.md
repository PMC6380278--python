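# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the `editqtl` pipeline, and what its synthetic-data
generator does and does not emulate.

## Edit-site discovery

Candidate sites are RNA-called variants with no identically matching
(chromosome, position, ref, alt) DNA-called variant. Matching is by
alleles, not position alone: an RNA A→G call at a position where the DNA
carries A→C is retained, since the RNA substitution is still unexplained
by the genome. Subtraction requires every RNA-cohort animal to be present
in the DNA call set; otherwise the per-animal evidence cannot be compared
and the run aborts.

Filter predicates and their defaults:

- **Quality**: QUAL ≥ 30, missing genotypes ≤ 1, alternate-allele
  observations ≥ 6. Boundaries are inclusive as written.
- **Splice adjacency**: remove sites within W bp inside an annotated
  intron boundary (donor or acceptor). W defaults to 4, the window used in
  the RNA-seq variant-calling practice this filter family comes from;
  configurable.
- **Homopolymer**: remove a site lying inside a run of ≥ 5 identical
  bases, or whose immediate left or right flank begins such a run. This is
  the conservative reading of "adjacent to a homopolymer".
- **Read-end**: remove sites whose edited-read offsets all fall in the
  first or last 6 bases of reads. Offsets enter as a per-site table
  (`read_offsets.tsv`) rather than from BAMs, so the filter is testable
  without alignment parsing; a site absent from the table is not flagged.
- **Repeat mask**: remove sites inside BED-masked simple-repeat /
  low-complexity intervals.
- **Cohort support**: with N animals, keep sites where ≥ ceil(2N/3)
  animals have an edited read and ≥ ceil(2N/3) have ≥ 5 reads. The
  second clause is stated ambiguously in the protocols this follows; we
  implement the only self-consistent direction (sufficient depth in at
  least two-thirds of animals) and flag it here.

The filters are pure predicates, so they commute and re-applying them to
survivors is the identity; the tests assert both. A manual review stage
(inspecting alignments around each candidate) is deliberately not
modeled; the per-site report supports external review instead.

Classification complements ref/alt on minus-strand genes before naming
the substitution in the RNA alphabet; A-to-G on the transcript strand is
A-to-I. Region assignment walks exon/CDS structure (codon translation
for missense/synonymous), and reassigns near-gene sites to 5'/3' UTR
strand-awareness within 5 kbp — unbounded UTR reassignment would label
arbitrarily distant intergenic sites as UTR, so the bound is a deliberate
deviation kept configurable.

## Editing proportions and phenotypes

Φ = edited/total per animal per site, missing when total = 0. The mapping
phenotype uses Haldane–Anscombe pseudocounts,
y = ln(Φ*/(1−Φ*)), Φ* = (edited + ½)/(total + 1), which keeps Φ ∈ {0, 1}
animals in the model and is strictly monotone in the edited count.

Sequence-logo columns report 2 − H − e(n) bits, H the Shannon entropy of
the column's base frequencies and e(n) = 3/(2·ln2·n) the small-sample
correction; values driven negative by the correction are clipped to 0
(the presentation convention of the logo method). Neighbor-base
enrichment uses a two-sided exact binomial test against background
frequencies estimated from the ±10 bp flanks of the same sites excluding
offsets −1, 0, +1 — self-contained, no genome-wide pass. The context–Φ
association is a one-way ANOVA on **site-level mean** Φ (one observation
per site); animal-level observations would pseudo-replicate because
animals are shared across sites.

## Double-stranded structure

Per gene, sequence spanning the outermost edit sites ± 1500 bp is
extracted, split into ≤ 15 kbp chunks when longer; chunks overlap by
1.5 kbp so a helix crossing a cut is always seen whole in one chunk. The
dot-plot places a dot at (i, j) when ≥ 11 of the 15 base pairs
(s[i+k], s[j−k]), k ∈ [−7, 7], are Watson–Crick complementary. The scan
set is strict WC (A:U, C:G); G:U wobble enters only when interpreting
edited bases, not in the dot criterion. Helices are maximal anti-diagonal
runs of ≥ 25 consecutive dots (configurable), clipped to i < j so arms
never overlap; any gap splits a helix. The 25-dot minimum is the
automated stand-in for what was a manual call on plotted diagonals — it
is deliberately conservative, trading sensitivity to short or bulged
stems for determinism. Pairing maps are involutions by construction and
are verified against a brute-force re-derivation of the dot criterion,
exactly, on every test sequence.

## Association mapping

**A** is built by the tabular method: A_ii = 1 + ½A_{sire,dam},
A_ij = ½(A_{j,sire} + A_{j,dam}), unknown parents contributing 0; exact
for any topologically ordered pedigree.

Each variant is tested by GLS, y = Xβ + ε, X = [1, dosage],
Var(ε|X) = W = σ²_P(0.3·**A** + 0.7·**I**). The 0.3/0.7 weighting is a
fixed constant of the method (a REML-free compromise carried over from
the GWAS design this follows) with a config override; σ²_P is the sample
variance of the analyzed phenotype vector, re-estimated per phenotype.
Because β̂ is invariant to the overall scale of W, this convention only
fixes the χ² scale. W is Cholesky-factorized once per phenotype; all
dosage columns are whitened in one triangular solve and the two-column
regressions reduced to closed-form cross-products, matching the direct
matrix formula to 1e-8 relative (tested). Missing dosages drop animals
pairwise per variant with a refactorization on the subset; monomorphic
dosages are flagged untestable rather than returning spurious zeros.

Diagnostics: λ = median(χ²)/0.4549 (the denominator is the χ²₁ median,
asserted against the quantile function); Bonferroni thresholds α/m; cis
classification takes the minimum-p variant (ties broken by distance to
the site, then position) and calls cis iff it lies within 500 kbp on the
same chromosome.

A calibration subtlety: the nominal levels (type-I error 0.05, λ = 1)
hold **marginally** over phenotype draws. Conditional on one realized
phenotype, the across-variant dispersion of z-statistics fluctuates by
roughly 10%, so per-phenotype λ values scatter around 1 even for a
perfectly specified model; the calibration tests therefore pool 100
independent polygenic phenotypes × 1000 LD-free variants (10⁵ tests).

Expression phenotypes count only reads that lie wholly within exons or
splice exactly at annotated junctions, then apply the closed-form NB
variance-stabilizing transform f(x) = (2/√α)·asinh(√(αx))/ln 2 with a
common method-of-moments dispersion α (override available). This is an
analytic stand-in for spline-based VST fits: monotone, log2-scaled at
large counts, and variance-stabilizing across a 10³-fold mean range
(tested to < 3-fold variance ratio), which is all the downstream
correlation and GLS analyses require. Genotype QC removes variants with
MAF < 1% or exact-test Hardy–Weinberg P < 1e-30.

## Integration

Read-pair phase: 2×2 tables (edited/unedited × ref/alt) are usable when
every observed and expected cell is ≥ 6, the pair is ≤ 150 bases apart,
and the variant has R² > 0.95 with the top associated variant. The test
is Pearson χ² without Yates correction — the cell-count gate already
guards the small-sample regime the correction exists for. Significance
uses 0.05/n_usable computed at run time rather than any fixed printed
threshold, so it generalizes to any pair count.

Complementarity: for variants inside a helix, each allele is flagged by
WC pairing against the opposite base; pairs where neither allele pairs
are unusable. Effects oriented to the non-complementary allele are tested
by a one-sample, one-sided t-test for mean β̂ < 0 (destabilizing alleles
should reduce editing).

Φ–expression: Pearson r per site–gene pair over animals with both
values, Bonferroni over pairs; optional ADAR adjustment replaces
expression by its OLS residuals on ADAR expression first.

Cosegregation: Spearman correlation (average ranks) of two χ² profiles
over shared variants within the 1 Mbp window centered on the top edQTL
marker; restricting to the window matters because genome-wide null
variants dilute the rank correlation. Pairs with r > 0.707 (r² > ½) are
cosegregating. The sign-concordance test forms the per-pair product of
effect signs — both effects oriented to the alternate allele, since sign
comparisons are meaningless without a fixed allele frame — and t-tests
mean(sign) < 0, one-sided.

## Synthetic data

The generator reproduces the statistical structure the analyses assume,
with defaults fixed to the emulated study design:

- **Cohorts**: 9 discovery animals (paired DNA/RNA call sets), 355
  quantification animals, matching the two-cohort design.
- **Pedigree**: 55 founders plus 3 generations to 355 animals; random
  sire/dam pairs from the previous generation.
- **Genotypes**: founder haplotypes from a coalescent (msprime) with
  Ne = 150 — the small effective population size of dairy cattle, which
  produces the long-range LD that makes dense cis profiles informative —
  μ = 1.2e-7 and r = 1e-8 over a 3 Mbp chromosome, filtered to 400
  variants with MAF ∈ [0.05, 0.5]. Descendants receive whole parental
  haplotypes (gene drop without recombination), so LD arises only from
  founder structure and cosegregation; a per-variant independent
  transmission mode and an LD-free founder mode exist for null tests.
- **Editing**: latent ℓ = μ + β·dosage + g + e with μ = −1.6 on the logit
  scale (baseline Φ ≈ 0.17, matching the typical observed range),
  polygenic g ~ MVN(0, 0.3·**A**), residual e ~ N(0, 0.7), β = 0.8 per
  allele. β was set so a planted cis variant yields top association
  signals of −log10 p ≈ 20 at n = 355 — the order of magnitude of the
  mapped edQTL this emulates; weaker choices produce QTL that would fail
  the significance gates and never reach the downstream analyses.
  Reads: total ~ Poisson(50) (depth is a free choice; 50 gives binomial
  noise well below the biological signal), edited ~ Binomial(total,
  expit(ℓ)).
- **Expression**: NB counts with mean exp(a − 0.6·ℓ) and dispersion 0.05,
  coupling editing negatively to expression; the coupling strength makes
  the shared-causal eQTL genome-wide significant at n = 355, i.e. a pair
  that actually enters cosegregation classification.
- **Structure**: a planted inverted repeat (stem ≥ 40 nt, loop ≥ 10 nt)
  with A edit sites inside the stem and an emitted truth pairing table.
- **Phase**: 2×2 tables built by the Plackett construction so the odds
  ratio equals the configured value (default 6) exactly in expectation.

What the generator does **not** emulate: sequencing error and mapping
artifacts (decoy sites are planted explicitly instead), hyper-editing
clusters, realistic bovine sequence composition, within-chromosome
recombination, empirical depth distributions, and batch structure in
expression. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated model, not robustness to every
real-data pathology upstream of it.

## Problem sizes in the test suite

Unit tests run at n ≤ 120 animals; calibration pools 10⁵ GLS tests;
effect-size recovery uses 200 replicate estimates at n = 355, depth 50;
the end-to-end truth-table evaluation runs eight replicate 355-animal
cohorts, classifying only pairs in which both QTL are Bonferroni-
significant (mirroring how such pairs reach this analysis at all). The full suite completes in
well under a minute on one CPU.

## Known limitations

- Helix calling has no bulge tolerance; a single mismatch splits runs,
  so long imperfect stems may be reported as several helices and
  borderline (≈ min_run) stems may be missed.
- The VST is exact only under a common NB dispersion; strongly
  gene-specific dispersions are better served by an external fit, passed
  in via the `dispersion` argument.
- The GLS treats the 0.3/0.7 covariance split as known; no variance
  components are estimated.
- UTR reassignment trusts the annotation's gene span; genes with
  unannotated distal UTRs beyond 5 kbp will yield intergenic labels.
- The dot-plot excludes G:U wobble from the match criterion; structures
  stabilized mainly by wobble pairs are invisible to the scan.
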