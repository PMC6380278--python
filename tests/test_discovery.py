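"""Edit-site discovery: subtraction, filters, classification, annotation."""

import itertools

import pandas as pd
import pytest

from editqtl import discovery
from editqtl.discovery import (
    CandidateSite,
    assign_region,
    build_edit_sites,
    classify_edit,
    curate_cohort,
    positional_filter,
    quality_filter,
    subtract_dna,
    summarize_sites,
)
from editqtl.io import GeneModel, GenomicPosition, IntervalMask, VariantRecord


def _variant(pos, ref="A", alt="G", qual=60.0, gts=(0, 1, 1), ao=10,
             samples=("s1", "s2", "s3")):
    return VariantRecord(GenomicPosition("chr1", pos), ref, alt, qual,
                         list(gts), ao, list(samples))


def _candidate(pos, ref="A", alt="G", qual=60.0, miss=0, ao=10):
    return CandidateSite(GenomicPosition("chr1", pos), ref, alt, qual, miss, ao)


class TestSubtractDna:
    def test_shared_variants_removed(self):
        rna = [_variant(p) for p in range(100, 110)]
        dna = [_variant(p) for p in range(100, 107)]
        out = subtract_dna(rna, dna)
        assert [c.position.pos for c in out] == [107, 108, 109]

    def test_different_alleles_at_same_position_retained(self):
        rna = [_variant(100, "A", "G")]
        dna = [_variant(100, "A", "C")]
        assert len(subtract_dna(rna, dna)) == 1

    def test_identical_sets_empty(self):
        rna = [_variant(p) for p in (1, 2, 3)]
        assert subtract_dna(rna, rna) == []

    def test_sample_mismatch_rejected(self):
        rna = [_variant(100, samples=("s1", "s2", "s9"))]
        dna = [_variant(200)]
        with pytest.raises(ValueError, match="s9"):
            subtract_dna(rna, dna)


class TestQualityFilter:
    @pytest.mark.parametrize(
        "qual,miss,ao,kept",
        [
            (29.9, 0, 10, False),  # quality boundary
            (30.0, 1, 6, True),  # conjunction of all three thresholds
            (60.0, 2, 10, False),  # too many missing genotypes
            (60.0, 0, 5, False),  # "five or fewer" alt observations
            (60.0, 0, 6, True),
        ],
    )
    def test_thresholds(self, qual, miss, ao, kept):
        out = quality_filter([_candidate(100, qual=qual, miss=miss, ao=ao)])
        assert (len(out) == 1) == kept


class TestPositionalFilter:
    GENOME = {"chr1": "ACGT" * 2500}
    GENES = [GeneModel("g", "chr1", "+", [(1001, 2000), (3001, 4000)])]

    def test_splice_adjacent_removed(self):
        # donor at 2000; position 2002 is 2 bp into the intron
        out = positional_filter([_candidate(2002)], self.GENES, self.GENOME)
        assert out == []

    def test_internal_site_kept(self):
        out = positional_filter([_candidate(2500)], self.GENES, self.GENOME)
        assert len(out) == 1

    def test_homopolymer_adjacent_removed(self):
        genome = {"chr1": "ACGTC" + "AAAAA" + "GCGT" * 100}
        # 1-based position 5 ('C') has the AAAAA run starting immediately after
        out = positional_filter([_candidate(5, ref="C", alt="T")], [], genome)
        assert out == []

    def test_read_end_only_removed_internal_kept(self):
        offsets = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [2500, 2600],
                "read_len": [100, 100],
                "offsets": ["2;4;97;100", "3;50;80"],
            }
        )
        out = positional_filter(
            [_candidate(2500), _candidate(2600)], self.GENES, self.GENOME,
            read_offsets=offsets,
        )
        assert [c.position.pos for c in out] == [2600]

    def test_repeat_mask_removed(self):
        from editqtl.io import Interval

        mask = IntervalMask([Interval("chr1", 2490, 2510)])
        out = positional_filter([_candidate(2500)], self.GENES, self.GENOME,
                                mask=mask)
        assert out == []

    def test_missing_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chr1"):
            positional_filter([_candidate(10)], [], {"chr2": "ACGT"})


class TestCurateCohort:
    def _counts(self, edited_animals, depths):
        rows = []
        for i in range(9):
            rows.append(("chr1", 100, f"a{i}",
                         8 if i < edited_animals else 0, depths[i]))
        return pd.DataFrame(rows, columns=["chrom", "pos", "animal",
                                           "edited", "total"])

    def test_exact_two_thirds_retained(self):
        # N=9 -> ceil(2N/3)=6: 6 edited animals and 9 with depth >= 5 passes
        counts = self._counts(6, [30] * 9)
        kept, stats = curate_cohort([_candidate(100)], counts, 9)
        assert len(kept) == 1
        assert stats.per_site.iloc[0]["n_edited_animals"] == 6

    def test_below_edited_threshold_removed(self):
        kept, _ = curate_cohort([_candidate(100)], self._counts(5, [30] * 9), 9)
        assert kept == []

    def test_low_depth_cohort_removed(self):
        kept, _ = curate_cohort([_candidate(100)], self._counts(9, [4] * 9), 9)
        assert kept == []


class TestClassifyEdit:
    @pytest.mark.parametrize(
        "ref,alt,strand,expected_class,is_a2i",
        [
            ("A", "G", "+", "A-to-G", True),
            ("T", "C", "-", "A-to-G", True),  # complemented to the transcript
            ("T", "C", "+", "U-to-C", False),
            ("C", "T", "+", "C-to-U", False),
            ("G", "A", "-", "C-to-U", False),
        ],
    )
    def test_strand_resolution(self, ref, alt, strand, expected_class, is_a2i):
        assert classify_edit(ref, alt, strand) == (expected_class, is_a2i)

    def test_twelve_classes_consistent(self):
        classes = {
            classify_edit(r, a, "+")[0]
            for r in "ACGT" for a in "ACGT" if r != a
        }
        assert len(classes) == 12


class TestAssignRegion:
    GENOME = {"chr1": "A" * 200 + "ATGGCACATTAA" + "A" * 800}
    # CDS 201..212 encodes M-A-H-*; exon spans the CDS plus UTRs
    GENE = GeneModel("g", "chr1", "+", [(150, 400), (501, 600)],
                     cds=[(201, 212)])

    def test_intron(self):
        region, gene, _ = assign_region(_candidate(450), [self.GENE], self.GENOME)
        assert region == "intron" and gene == "g"

    def test_downstream_becomes_three_prime_utr(self):
        region, _, _ = assign_region(_candidate(700), [self.GENE], self.GENOME)
        assert region == "3'UTR"

    def test_far_intergenic(self):
        gene = GeneModel("g", "chr1", "+", [(150, 400)])
        region, _, _ = assign_region(_candidate(90000), [gene],
                                     {"chr1": "A" * 100000})
        assert region == "intergenic"

    def test_synonymous_vs_missense_codon(self):
        # codon GCA (Ala) at 204-206; GCA->GCG synonymous at wobble position
        syn = _candidate(206, ref="A", alt="G")
        region, _, _ = assign_region(syn, [self.GENE], self.GENOME)
        assert region == "synonymous"
        # GCA->GAA (Ala->Glu) missense at codon position 2
        mis = _candidate(205, ref="C", alt="A")
        region, _, _ = assign_region(mis, [self.GENE], self.GENOME)
        assert region == "missense"

    def test_exonic_noncoding_gene(self):
        gene = GeneModel("g", "chr1", "+", [(150, 400)])
        region, _, _ = assign_region(_candidate(300), [gene], self.GENOME)
        assert region == "noncoding-exon"


class TestSummaries:
    def test_percentages_one_decimal(self):
        sites = build_edit_sites(
            [_candidate(p) for p in (10, 20, 30)]
            + [_candidate(40, ref="C", alt="T")],
            [],
        )
        tables = summarize_sites(sites)
        cls = tables["class"].set_index("class")
        assert cls.loc["A-to-G", "count"] == 3
        assert cls.loc["A-to-G", "percent"] == 75.0

    def test_empty_set_no_division(self):
        tables = summarize_sites([])
        assert tables["class"].empty and tables["region"].empty


class TestFilterProperties:
    def test_filters_commute(self, discovery_bundle):
        b = discovery_bundle
        cands = subtract_dna(b.rna_variants, b.dna_variants)
        mask = IntervalMask(b.mask)

        def fq(cs):
            return quality_filter(list(cs))

        def fp(cs):
            return positional_filter(list(cs), b.gene_models, b.genome, mask,
                                     b.read_offsets)

        surviving = None
        for order in itertools.permutations([fq, fp]):
            out = list(cands)
            for f in order:
                out = f(out)
            keys = {c.position.pos for c in out}
            assert surviving is None or keys == surviving
            surviving = keys

    def test_curation_idempotent(self, discovery_bundle):
        b = discovery_bundle
        mask = IntervalMask(b.mask)
        _, kept, _ = discovery.discover(
            b.rna_variants, b.dna_variants, b.gene_models, b.genome, mask,
            b.read_offsets, b.edit_counts,
        )
        # every survivor passes each predicate when re-checked individually
        for c in kept:
            assert quality_filter([c])
            assert positional_filter([c], b.gene_models, b.genome, mask,
                                     b.read_offsets)
            again, _ = curate_cohort([c], b.edit_counts, 9)
            assert again == [c]

    def test_planted_truth_recovered(self, discovery_bundle):
        """All planted edits survive; no germline SNP or decoy does."""
        b = discovery_bundle
        sites, _, _ = discovery.discover(
            b.rna_variants, b.dna_variants, b.gene_models, b.genome,
            IntervalMask(b.mask), b.read_offsets, b.edit_counts,
        )
        found = {s.position.pos for s in sites}
        planted = set(b.truth.loc[b.truth["kind"] == "edit", "pos"])
        germline = set(b.truth.loc[b.truth["kind"] == "germline", "pos"])
        assert found == planted
        assert not (found & germline)
        assert all(s.is_A_to_I for s in sites)
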