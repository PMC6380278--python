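# editqtl

Discovery, quantification, structural context, and genetic mapping of
RNA-editing sites from paired DNA/RNA sequencing of a pedigreed mammalian
population.

Adenosine-to-inosine (A-to-I) editing, catalyzed by ADAR enzymes acting on
double-stranded pre-mRNA, appears in RNA-seq as A→G mismatches that are
absent from the matched genomic DNA. This package implements the full
analysis chain for such data in an outbred livestock setting — the kind of
design used to map editing QTL (edQTL) in dairy cattle — for researchers
who have variant calls, base counts, genotypes, expression counts, and
pedigree records, but not necessarily the original alignments:

1. **discovery** — subtract DNA-called variants from RNA-called variants;
   apply quality (QUAL ≥ 30, ≤ 1 missing genotype, ≥ 6 alt observations),
   positional (splice-adjacent, homopolymer ≥ 5 bp, read-end-only,
   repeat-masked) and cohort filters (≥ ⅔ of animals with an edited read
   and ≥ ⅔ with ≥ 5 reads); classify each site into the 12 strand-resolved
   substitution classes and a genic region.
2. **quantify** — per-animal editing proportions Φ = edited/total reads;
   mapping phenotypes y = logit((edited + ½)/(total + 1)); neighbor-base
   context, sequence-logo information content 2 − H − 3/(2·ln2·n), and
   ANOVA of site-level Φ by flanking base.
3. **structure** — dot-plot prediction of double-stranded pre-mRNA: a dot
   wherever ≥ 11 of 15 window positions are Watson–Crick complementary;
   anti-diagonal runs become helices with an explicit base-pairing map, so
   each edit site's opposite base (U, C, …) and each variant allele's
   complementarity can be read off.
4. **assoc** — pedigree numerator relationship matrix **A** (tabular
   method) and per-variant GLS: y = Xβ + ε with Var(ε|X) = W =
   σ²_P(0.3·**A** + 0.7·**I**), χ² = (β̂/se(β̂))², inflation
   λ = median(χ²)/0.4549, Bonferroni thresholds, cis calls (top variant
   within 500 kbp), exon-consistent read counting and a closed-form
   variance-stabilizing transform for expression phenotypes.
5. **integrate** — read-pair phase tests (2×2 χ², cells ≥ 6), the
   complementarity sign test (one-sided t on effects of non-complementary
   alleles), Φ–expression Pearson correlations with optional ADAR
   adjustment, and edQTL/eQTL cosegregation by Spearman correlation of χ²
   profiles over 1 Mbp windows (cosegregating when r > 0.707).
6. **sim** — a synthetic-data generator producing all of the above inputs
   with known truth: coalescent founder haplotypes (cattle-scale LD),
   gene-drop genotypes, editing counts with an additive cis effect plus a
   pedigree-correlated polygenic term, planted inverted repeats, phased
   read pairs, and negative-binomial expression coupled to editing.

## Worked example

Simulate a 355-cow quantification cohort (six edit sites, each with a
planted cis variant of +0.8 on logit Φ per allele), map edQTL and eQTL,
and test cosegregation:

```sh
editqtl simulate --seed 7 --out demo
editqtl edqtl  --dir demo --out demo/assoc
editqtl eqtl   --dir demo --out demo/assoc
editqtl integrate --dir demo --assoc-dir demo/assoc --out demo/integrate
```

`demo/assoc/cis_calls.tsv` — every site's top variant is within 500 kbp,
and five of six pass the genome-wide Bonferroni threshold:

```
#site   call  top_chrom  top_pos  top_beta  top_p      significant
site0   cis   chrQ       1826693  0.784     6.33e-14   1
site1   cis   chrQ       1850609  0.981     8.55e-11   1
site2   cis   chrQ       1212950  0.924     1.22e-14   1
...
```

`demo/integrate/coseg.tsv` — each site's edQTL against the eQTL of its
coupled gene; five pairs exceed the r > 0.707 cosegregation threshold, and
the eQTL effects are uniformly opposite in sign to the edQTL effects
(editing up, expression down), so the sign-concordance test is decisive:

```
#site   gene        n_shared  spearman_r  cosegregating  beta_edqtl  beta_eqtl
site0   gene_site0  120       0.990       1              0.784       -0.931
site1   gene_site1  123       0.924       1              0.981       -1.129
...
#n_pairs  mean_sign  t     p
5         -1.0       -inf  0.0
```

The `demo/truth/` tables hold the planted causal positions and helix
pairings for checking any of these calls.

A discovery-cohort bundle (paired DNA/RNA VCFs, genome, annotations,
masks, planted edits and decoys) is written to `demo/discovery/`; run
`editqtl discover --dir demo/discovery --out demo/sites` to exercise the
subtraction and filter chain — the five planted edits survive, every decoy
and germline SNP is removed.

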