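"""Candidate edit-site discovery and curation.

RNA-seq variants absent from the matched DNA call set form the initial
candidate set; quality, positional, and cohort-level filters then remove
artifact-prone calls, and the survivors are strand-resolved, classified
into the 12 substitution types, and assigned a genic region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io import GeneModel, GenomicPosition, IntervalMask, VariantRecord, complement

RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}

REGIONS = (
    "intron",
    "3'UTR",
    "5'UTR",
    "missense",
    "synonymous",
    "noncoding-exon",
    "intergenic",
)


@dataclass
class CandidateSite:
    position: GenomicPosition
    ref: str
    alt: str
    rna_qual: float
    n_missing_genotypes: int
    alt_observations: int
    read_end_only: bool = False
    near_splice: bool = False
    in_homopolymer: bool = False
    in_repeat_mask: bool = False


@dataclass
class EditSite:
    position: GenomicPosition
    transcript_strand: str
    edit_class: str  # e.g. "A-to-G" in the RNA alphabet, transcript strand
    gene_id: str | None
    region: str
    is_A_to_I: bool


@dataclass
class CurationStats:
    n_animals: int
    per_site: pd.DataFrame  # chrom, pos, n_edited_animals, n_min_depth, kept


def subtract_dna(
    rna_variants: list[VariantRecord], dna_variants: list[VariantRecord]
) -> list[CandidateSite]:
    """RNA variants with no identically matching DNA variant.

    Matching requires identical chromosome, position, ref and alt; an RNA
    variant whose position carries a *different* DNA substitution is kept.
    """
    if rna_variants and dna_variants:
        rna_samples = set(rna_variants[0].samples)
        dna_samples = set(dna_variants[0].samples)
        if rna_samples - dna_samples:
            raise ValueError(
                "animals present in RNA but absent from DNA inputs: "
                + ",".join(sorted(rna_samples - dna_samples))
            )
    dna_keys = {v.key for v in dna_variants}
    out = []
    for v in rna_variants:
        if v.key in dna_keys:
            continue
        n_missing = sum(1 for d in v.genotypes if d < 0)
        out.append(
            CandidateSite(
                position=v.position,
                ref=v.ref,
                alt=v.alt,
                rna_qual=v.qual,
                n_missing_genotypes=n_missing,
                alt_observations=v.alt_observation_count,
            )
        )
    return out


def quality_filter(
    candidates: list[CandidateSite],
    min_qual: float = 30.0,
    max_missing: int = 1,
    min_alt_observations: int = 6,
) -> list[CandidateSite]:
    """Quality >= 30, at most one missing genotype, > 5 alt observations."""
    return [
        c
        for c in candidates
        if c.rna_qual >= min_qual
        and c.n_missing_genotypes <= max_missing
        and c.alt_observations >= min_alt_observations
    ]


def _near_splice(pos: GenomicPosition, gene_models: list[GeneModel], window: int) -> bool:
    for g in gene_models:
        if g.chrom != pos.chrom:
            continue
        for donor, acceptor in g.annotated_junctions:
            if donor < pos.pos < acceptor and (
                pos.pos - donor <= window or acceptor - pos.pos <= window
            ):
                return True
    return False


def _in_homopolymer(pos: GenomicPosition, genome: dict[str, str], min_run: int = 5) -> bool:
    """Site inside a run of >= min_run identical bases, or either flanking
    side begins such a run."""
    seq = genome.get(pos.chrom)
    if seq is None:
        raise ValueError(f"no genome sequence for chromosome {pos.chrom}")
    z = pos.to_zero_based()

    def run_length(start: int, step: int) -> int:
        if not (0 <= start < len(seq)):
            return 0
        base = seq[start]
        n, i = 0, start
        while 0 <= i < len(seq) and seq[i] == base:
            n += 1
            i += step
        return n

    # run containing the site itself
    own = 1 + (run_length(z - 1, -1) if z > 0 and seq[z - 1] == seq[z] else 0) + (
        run_length(z + 1, 1) if z + 1 < len(seq) and seq[z + 1] == seq[z] else 0
    )
    if own >= min_run:
        return True
    return run_length(z + 1, 1) >= min_run or run_length(z - 1, -1) >= min_run


def _read_end_only(
    pos: GenomicPosition, read_offsets: pd.DataFrame | None, end_bases: int = 6
) -> bool:
    if read_offsets is None:
        return False
    hit = read_offsets[
        (read_offsets["chrom"] == pos.chrom) & (read_offsets["pos"] == pos.pos)
    ]
    if hit.empty:
        return False
    row = hit.iloc[0]
    offsets = [int(x) for x in str(row["offsets"]).split(";") if x]
    read_len = int(row["read_len"])
    if not offsets:
        return False
    return all(o <= end_bases or o > read_len - end_bases for o in offsets)


def positional_filter(
    candidates: list[CandidateSite],
    gene_models: list[GeneModel],
    genome: dict[str, str],
    mask: IntervalMask | None = None,
    read_offsets: pd.DataFrame | None = None,
    splice_window: int = 4,
) -> list[CandidateSite]:
    """Drop sites adjacent to splice junctions or homopolymers (>= 5 bp),
    sites seen only in the first/last six read bases, and masked repeats."""
    kept = []
    for c in candidates:
        c.near_splice = _near_splice(c.position, gene_models, splice_window)
        c.in_homopolymer = _in_homopolymer(c.position, genome)
        c.read_end_only = _read_end_only(c.position, read_offsets)
        c.in_repeat_mask = bool(mask and mask.contains(c.position))
        if not (c.near_splice or c.in_homopolymer or c.read_end_only or c.in_repeat_mask):
            kept.append(c)
    return kept


def curate_cohort(
    candidates: list[CandidateSite],
    per_animal_counts: pd.DataFrame,
    n_animals: int,
    min_depth: int = 5,
) -> tuple[list[CandidateSite], CurationStats]:
    """Cohort support filter: at least two-thirds of animals must carry an
    edited read, and at least two-thirds must have >= 5 reads at the site.

    ``per_animal_counts`` columns: chrom, pos, animal, edited, total.
    """
    threshold = math.ceil(2 * n_animals / 3)
    grouped = per_animal_counts.groupby(["chrom", "pos"])
    stats_rows = []
    kept = []
    for c in candidates:
        key = (c.position.chrom, c.position.pos)
        try:
            tab = grouped.get_group(key)
        except KeyError:
            stats_rows.append((*key, 0, 0, False))
            continue
        n_edited = int((tab["edited"] >= 1).sum())
        n_depth = int((tab["total"] >= min_depth).sum())
        ok = n_edited >= threshold and n_depth >= threshold
        stats_rows.append((*key, n_edited, n_depth, ok))
        if ok:
            kept.append(c)
    stats = CurationStats(
        n_animals=n_animals,
        per_site=pd.DataFrame(
            stats_rows, columns=["chrom", "pos", "n_edited_animals", "n_min_depth", "kept"]
        ),
    )
    return kept, stats


def classify_edit(ref: str, alt: str, gene_strand: str) -> tuple[str, bool]:
    """Strand-resolved substitution class in the RNA alphabet.

    On minus-strand genes the alleles are complemented before
    classification; A-to-G on the transcript strand is the A-to-I class.
    """
    if gene_strand == "-":
        ref, alt = complement(ref), complement(alt)
    edit_class = f"{RNA[ref]}-to-{RNA[alt]}"
    return edit_class, edit_class == "A-to-G"


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _coding_impact(
    pos: GenomicPosition, alt: str, gene: GeneModel, genome: dict[str, str]
) -> str | None:
    """missense/synonymous for a site inside the annotated CDS, else None."""
    if not any(s <= pos.pos <= e for s, e in gene.cds):
        return None
    seq = genome[pos.chrom]
    cds_seq = "".join(seq[s - 1 : e] for s, e in gene.cds)
    # index of the site within the genomic-order CDS
    idx = 0
    for s, e in gene.cds:
        if s <= pos.pos <= e:
            idx += pos.pos - s
            break
        idx += e - s + 1
    if gene.strand == "-":
        from .io import revcomp

        cds_seq = revcomp(cds_seq)
        idx = len(cds_seq) - 1 - idx
        alt = complement(alt)
    codon_start = (idx // 3) * 3
    codon = cds_seq[codon_start : codon_start + 3]
    if len(codon) < 3:
        return None
    mutated = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
    return "synonymous" if _CODON_TABLE[codon] == _CODON_TABLE[mutated] else "missense"


def assign_region(
    site: CandidateSite,
    gene_models: list[GeneModel],
    genome: dict[str, str] | None = None,
    max_utr_distance: int = 5000,
) -> tuple[str, str | None, str]:
    """Region label, gene id, and transcript strand for a site.

    Sites upstream/downstream of a gene (within ``max_utr_distance``) are
    reassigned to the 5'/3' UTR respectively, strand-aware, because they
    were discovered in expressed sequence; farther sites are intergenic.
    """
    pos = site.position
    containing = [
        g for g in gene_models if g.chrom == pos.chrom and g.start <= pos.pos <= g.end
    ]
    if containing:
        g = containing[0]
        in_exon = any(s <= pos.pos <= e for s, e in g.exons)
        if not in_exon:
            return "intron", g.gene_id, g.strand
        if g.cds and genome is not None:
            impact = _coding_impact(pos, site.alt, g, genome)
            if impact is not None:
                return impact, g.gene_id, g.strand
        if g.cds:
            cds_lo, cds_hi = g.cds[0][0], g.cds[-1][1]
            if pos.pos < cds_lo:
                side = "5'UTR" if g.strand == "+" else "3'UTR"
            elif pos.pos > cds_hi:
                side = "3'UTR" if g.strand == "+" else "5'UTR"
            else:
                side = "noncoding-exon"
            return side, g.gene_id, g.strand
        return "noncoding-exon", g.gene_id, g.strand
    # nearest gene within range: upstream -> 5'UTR, downstream -> 3'UTR
    best = None
    for g in gene_models:
        if g.chrom != pos.chrom:
            continue
        d = g.start - pos.pos if pos.pos < g.start else pos.pos - g.end
        if d <= max_utr_distance and (best is None or d < best[0]):
            best = (d, g)
    if best is not None:
        g = best[1]
        before = pos.pos < g.start
        if (before and g.strand == "+") or (not before and g.strand == "-"):
            return "5'UTR", g.gene_id, g.strand
        return "3'UTR", g.gene_id, g.strand
    return "intergenic", None, "+"


def build_edit_sites(
    candidates: list[CandidateSite],
    gene_models: list[GeneModel],
    genome: dict[str, str] | None = None,
) -> list[EditSite]:
    sites = []
    for c in candidates:
        region, gene_id, strand = assign_region(c, gene_models, genome)
        edit_class, is_a2i = classify_edit(c.ref, c.alt, strand)
        sites.append(
            EditSite(c.position, strand, edit_class, gene_id, region, is_a2i)
        )
    return sites


def percent(count: int, total: int) -> float:
    """Reported percentage: 100 * count / total, one decimal place."""
    return round(100.0 * count / total, 1) if total else 0.0


def summarize_sites(edit_sites: list[EditSite]) -> dict[str, pd.DataFrame]:
    """Count and percentage tables by substitution class and by region.

    Percentages are 100 * count / total rounded to one decimal place.
    """
    out = {}
    for name, keyfun in (
        ("class", lambda s: s.edit_class),
        ("region", lambda s: s.region),
    ):
        counts: dict[str, int] = {}
        for s in edit_sites:
            counts[keyfun(s)] = counts.get(keyfun(s), 0) + 1
        total = sum(counts.values())
        rows = [
            (k, v, percent(v, total))
            for k, v in sorted(counts.items(), key=lambda kv: -kv[1])
        ]
        out[name] = pd.DataFrame(rows, columns=[name, "count", "percent"])
    return out


def discover(
    rna_variants: list[VariantRecord],
    dna_variants: list[VariantRecord],
    gene_models: list[GeneModel],
    genome: dict[str, str],
    mask: IntervalMask | None = None,
    read_offsets: pd.DataFrame | None = None,
    per_animal_counts: pd.DataFrame | None = None,
    n_animals: int | None = None,
) -> tuple[list[EditSite], list[CandidateSite], CurationStats | None]:
    """Run the full discovery chain; returns sites, survivors, stats."""
    cands = subtract_dna(rna_variants, dna_variants)
    cands = quality_filter(cands)
    cands = positional_filter(cands, gene_models, genome, mask, read_offsets)
    stats = None
    if per_animal_counts is not None:
        if n_animals is None:
            n_animals = per_animal_counts["animal"].nunique()
        cands, stats = curate_cohort(cands, per_animal_counts, n_animals)
    return build_edit_sites(cands, gene_models, genome), cands, stats
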