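"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; positions cross the
module boundary as 1-based only inside :class:`GenomicPosition` (the VCF/GFF
convention) and are converted exactly on read/write.  All tabular artifacts
are tab-separated with a header line beginning ``#``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger("editqtl")

MISSING = -1  # missing genotype dosage sentinel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True, order=True)
class GenomicPosition:
    """A 1-based genomic coordinate, e.g. chr27:37,355,505."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("chromosome name must be nonempty")

    def to_zero_based(self) -> int:
        return self.pos - 1


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval (the BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: GenomicPosition) -> bool:
        return (
            position.chrom == self.chrom
            and self.start <= position.to_zero_based() < self.end
        )


@dataclass
class VariantRecord:
    """A biallelic SNV with per-animal alt-dosage genotypes."""

    position: GenomicPosition
    ref: str
    alt: str
    qual: float
    genotypes: list[int] = field(default_factory=list)  # dosage 0/1/2, MISSING
    alt_observation_count: int = 0
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref, self.alt):
            if allele not in "ACGT" or len(allele) != 1:
                raise ValueError(f"not a single-nucleotide allele: {allele!r}")
        if self.alt_observation_count < 0:
            raise ValueError("alt_observation_count must be >= 0")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.position.chrom, self.position.pos, self.ref, self.alt)


@dataclass
class GeneModel:
    """Exon structure of one gene; intervals 1-based inclusive as in GFF3."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 <= e0:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def annotated_junctions(self) -> set[tuple[int, int]]:
        """(donor, acceptor) = (end of exon k, start of exon k+1), 1-based."""
        return {
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        }


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into biallelic SNV records.

    Multi-allelic records are split into one record per alternate allele
    (genotype dosage counted against that allele); indel alleles are dropped
    with a logged count.  The alt observation count comes from the FreeBayes
    ``AO`` INFO field when present, otherwise from the genotypes.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_indels = 0
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for v in vcf:
        alts = v.ALT or []
        ao = v.INFO.get("AO")
        if ao is not None and not isinstance(ao, tuple):
            ao = (ao,)
        for alt_index, alt in enumerate(alts):
            if len(v.REF) != 1 or len(alt) != 1 or alt == "*":
                n_indels += 1
                continue
            allele_code = alt_index + 1
            dosages = []
            for gt in v.genotypes:
                alleles = [a for a in gt[:-1]]
                if any(a < 0 for a in alleles):
                    dosages.append(MISSING)
                else:
                    dosages.append(sum(1 for a in alleles if a == allele_code))
            if ao is not None:
                alt_obs = int(ao[alt_index])
            else:
                alt_obs = sum(d for d in dosages if d > 0)
            records.append(
                VariantRecord(
                    position=GenomicPosition(v.CHROM, v.POS),
                    ref=v.REF,
                    alt=alt,
                    qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                    genotypes=dosages,
                    alt_observation_count=alt_obs,
                    samples=samples,
                )
            )
    if n_indels:
        log.info("%d indel allele(s) excluded from %s", n_indels, path)
    return records


class IntervalMask:
    """Merged set of masked intervals with point-membership queries."""

    def __init__(self, intervals: Iterable[Interval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged = [ivs[0]]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = merged

    @property
    def intervals(self) -> set[Interval]:
        return {
            Interval(c, s, e)
            for c, ivs in self._merged.items()
            for s, e in ivs
        }

    def contains(self, position: GenomicPosition) -> bool:
        import bisect

        ivs = self._merged.get(position.chrom)
        if not ivs:
            return False
        p = position.to_zero_based()
        i = bisect.bisect_right(ivs, (p, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= p < ivs[i][1]


def read_bed_mask(path: str | Path) -> IntervalMask:
    """Read a BED3+ file of masked regions; overlapping intervals merge."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                log.warning("%s:%d: start >= end, record rejected", path, lineno)
                continue
            intervals.append(Interval(chrom, start, end))
    return IntervalMask(intervals)


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models (exons + CDS, grouped by gene) from GFF3."""
    genes: dict[str, dict] = {}
    feature_to_gene: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    orphans = 0
    with open(path) as fh:
        rows = []
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            rows.append(parts)

    def attrs(col: str) -> dict[str, str]:
        out = {}
        for item in col.split(";"):
            if "=" in item:
                k, _, v = item.partition("=")
                out[k.strip()] = v.strip()
        return out

    # first pass: genes and transcript parentage
    for parts in rows:
        ftype, a = parts[2].lower(), attrs(parts[8])
        fid = a.get("ID")
        if ftype == "gene":
            gid = fid or a.get("gene_id") or a.get("Name")
            genes[gid] = {"chrom": parts[0], "strand": parts[6]}
            if fid:
                feature_to_gene[fid] = gid
        elif ftype in ("mrna", "transcript") and fid:
            parent = a.get("Parent")
            if parent in feature_to_gene:
                feature_to_gene[fid] = feature_to_gene[parent]
            elif parent in genes:
                feature_to_gene[fid] = parent
    # second pass: exons / CDS
    for parts in rows:
        ftype, a = parts[2].lower(), attrs(parts[8])
        if ftype not in ("exon", "cds"):
            continue
        parent = a.get("Parent", "")
        gid = None
        for p in parent.split(","):
            if p in feature_to_gene:
                gid = feature_to_gene[p]
                break
            if p in genes:
                gid = p
                break
        if gid is None:
            orphans += 1
            continue
        target = exons if ftype == "exon" else cds
        target.setdefault(gid, []).append((int(parts[3]), int(parts[4])))
    if orphans:
        log.warning("%d exon/CDS feature(s) without a parent gene skipped", orphans)
    models = []
    for gid, meta in genes.items():
        if gid not in exons:
            continue
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=meta["chrom"],
                strand=meta["strand"],
                exons=sorted(set(exons[gid])),
                cds=sorted(set(cds.get(gid, []))),
            )
        )
    return models


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    samples: Sequence[str],
    contigs: dict[str, int] | None = None,
) -> None:
    """Write biallelic SNV records as a minimal VCF 4.2 file with GT fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(r.position.chrom for r in records):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observations">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in sorted(records, key=lambda r: (r.position.chrom, r.position.pos)):
            gts = "\t".join(gt_codes[d] for d in r.genotypes)
            fh.write(
                f"{r.position.chrom}\t{r.position.pos}\t.\t{r.ref}\t{r.alt}\t"
                f"{r.qual:g}\t.\tAO={r.alt_observation_count}\tGT\t{gts}\n"
            )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a '#'-prefixed header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    return df


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (small) FASTA into a dict of upper-case sequences."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
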