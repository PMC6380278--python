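"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a two-cohort edQTL study design: a small
"discovery" set with paired DNA/RNA variant calls (for the subtraction and
curation stages) and a large "quantification" set with pedigree, genotypes,
editing proportions, expression counts, and read-pair phase tables (for the
mapping and integration stages).

Genetic structure: founder haplotypes are drawn from a coalescent
simulation with a small effective population size, giving the long-range
linkage disequilibrium characteristic of dairy cattle; descendants then
receive whole parental haplotypes by gene drop (no within-chromosome
recombination), so LD arises only from founder structure and
cosegregation and cis windows remain meaningful.  An
independent-transmission mode re-draws the transmitted allele per
variant, destroying LD for null tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io as eio
from .assoc import a_matrix
from .io import GenomicPosition, Interval, VariantRecord

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Conditions for the synthetic cohorts.

    Defaults mirror a cattle edQTL study design (9 discovery animals,
    355 quantification animals, ~50 reads per edit site, 500 kbp cis
    windows implying a multi-Mbp chromosome) with field-realistic values
    elsewhere.
    """

    n_founders: int = 55
    n_generations: int = 3
    n_animals: int = 355
    n_variants: int = 400
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_edit_sites: int = 6
    causal_effect_logit: float = 0.8
    polygenic_variance: float = 0.3
    residual_variance: float = 0.7
    depth_mean: float = 50.0
    expression_dispersion: float = 0.05
    phi_expression_slope: float = -0.6
    phase_odds_ratio: float = 6.0
    mu_logit: float = -1.6  # baseline logit editing proportion (phi ~ 0.17)
    chrom: str = "chrQ"
    chrom_span: int = 3_000_000
    founder_ne: int = 150  # dairy-cattle-scale effective population size
    mutation_rate: float = 1.2e-7
    recombination_rate: float = 1e-8
    founder_ld: bool = True  # False: exchangeable (LD-free) founder draws
    independent_transmission: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.polygenic_variance < 0 or self.residual_variance < 0:
            raise ValueError("variances must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.expression_dispersion <= 0:
            raise ValueError("expression dispersion must be > 0")


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents precede offspring."""

    ids: list[str]
    sire: np.ndarray  # parent index, -1 unknown
    dam: np.ndarray
    generation: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        idx = np.arange(n)
        if np.any(self.sire >= idx) or np.any(self.dam >= idx):
            raise ValueError("parents must precede offspring")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def to_frame(self) -> pd.DataFrame:
        def name(i: int) -> str:
            return self.ids[i] if i >= 0 else "."

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
                "generation": self.generation,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        index = {name: i for i, name in enumerate(df["id"])}

        def idx(name: str) -> int:
            return index.get(name, -1)

        return cls(
            ids=list(df["id"]),
            sire=np.array([idx(s) for s in df["sire"]]),
            dam=np.array([idx(d) for d in df["dam"]]),
            generation=np.asarray(
                df["generation"] if "generation" in df else np.zeros(len(df), int)
            ),
        )


def simulate_pedigree(config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Multi-generation pedigree: founders, then offspring of random pairs."""
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    if config.n_generations < 1:
        raise ValueError("need at least 1 generation of offspring")
    n_off = config.n_animals - config.n_founders
    if n_off < config.n_generations:
        raise ValueError("n_animals too small for the requested generations")
    per_gen = [n_off // config.n_generations] * config.n_generations
    per_gen[-1] += n_off - sum(per_gen)
    ids = [f"F{i:04d}" for i in range(config.n_founders)]
    sire = [-1] * config.n_founders
    dam = [-1] * config.n_founders
    gen = [0] * config.n_founders
    prev = list(range(config.n_founders))
    for g, size in enumerate(per_gen, start=1):
        cur = []
        for _ in range(size):
            s, d = rng.choice(prev, size=2, replace=False)
            i = len(ids)
            ids.append(f"G{g}{len(cur):04d}")
            sire.append(int(s))
            dam.append(int(d))
            gen.append(g)
            cur.append(i)
        prev = cur
    return Pedigree(ids, np.array(sire), np.array(dam), np.array(gen))


@dataclass
class GenotypeSim:
    positions: np.ndarray  # 1-based bp on config.chrom
    dosages: np.ndarray  # n_animals x n_variants, int8
    haplotypes: np.ndarray  # n_animals x 2 x n_variants, uint8
    allele_freqs: np.ndarray  # founder-pool frequencies
    chrom: str


def _founder_haplotypes(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Founder haplotypes: positions, haplotype matrix
    (2*n_founders x n_variants), and allele frequencies.

    Default: a coalescent sample (msprime) whose LD decays with distance.
    With ``founder_ld=False`` variants are drawn independently at
    Hardy-Weinberg frequencies — free-recombination founders for null
    calibration, where between-variant correlation must vanish.
    """
    if not config.founder_ld:
        m = config.n_variants
        positions = np.sort(
            rng.choice(np.arange(1, config.chrom_span + 1), size=m, replace=False)
        )
        lo, hi = config.maf_range
        freqs = rng.uniform(lo, hi, size=m)
        haps = (rng.random((2 * config.n_founders, m)) < freqs).astype(np.uint8)
        return positions, haps, freqs

    import msprime

    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=config.n_founders,
        ploidy=2,
        population_size=config.founder_ne,
        sequence_length=config.chrom_span,
        recombination_rate=config.recombination_rate,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=config.mutation_rate,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
    )
    G = mts.genotype_matrix().astype(np.uint8)  # variants x haplotypes
    positions = mts.tables.sites.position.astype(np.int64) + 1
    freqs = G.mean(axis=1)
    lo, hi = config.maf_range
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = np.flatnonzero((maf >= lo) & (maf <= hi))
    # unique positions only (finite-sites recurrent hits)
    _, first = np.unique(positions[keep], return_index=True)
    keep = keep[first]
    if len(keep) < config.n_variants:
        raise ValueError(
            f"coalescent yielded {len(keep)} usable variants < "
            f"n_variants={config.n_variants}; raise mutation_rate"
        )
    sel = np.sort(rng.choice(keep, size=config.n_variants, replace=False))
    return positions[sel], G[sel].T.copy(), freqs[sel]


def simulate_genotypes(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator
) -> GenotypeSim:
    """Coalescent founder haplotypes plus Mendelian gene drop."""
    m = config.n_variants
    positions, founder_haps, freqs = _founder_haplotypes(config, rng)
    n = len(pedigree)
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    next_founder = 0
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        for h, parent in enumerate((s, d)):
            if parent < 0:
                haps[i, h] = founder_haps[2 * next_founder + h]
            elif config.independent_transmission:
                pick = rng.integers(0, 2, size=m)
                haps[i, h] = haps[parent, pick, np.arange(m)]
            else:
                haps[i, h] = haps[parent, rng.integers(0, 2)]
        if s < 0 and d < 0:
            next_founder += 1
    dosages = haps.sum(axis=1).astype(np.int8)
    return GenotypeSim(positions, dosages, haps, freqs, config.chrom)


@dataclass
class EditingSim:
    edited: np.ndarray  # n_animals x n_sites, int
    total: np.ndarray  # n_animals x n_sites, int (0 => missing phi)
    latent: np.ndarray  # n_animals x n_sites latent logit values
    causal_index: np.ndarray  # variant column per site
    site_ids: list[str]


def simulate_editing(
    dosages: np.ndarray,
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
    causal_index: np.ndarray | None = None,
    A: np.ndarray | None = None,
) -> EditingSim:
    """Editing counts under the additive cis + polygenic + noise model.

    latent_i = mu + beta * dosage_i + g_i + e_i, g ~ MVN(0, sigma2_g A),
    e ~ N(0, sigma2_e); total reads Poisson(depth_mean), edited reads
    Binomial(total, expit(latent)).
    """
    n, m = dosages.shape
    k = config.n_edit_sites
    if causal_index is None:
        causal_index = rng.choice(m, size=k, replace=False)
    causal_index = np.asarray(causal_index)
    k = len(causal_index)
    if config.polygenic_variance > 0:
        if A is None:
            A = a_matrix(pedigree)
        try:
            L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular relationship matrix with polygenic variance > 0") from exc
        g = np.sqrt(config.polygenic_variance) * (L @ rng.standard_normal((n, k)))
    else:
        g = np.zeros((n, k))
    e = np.sqrt(config.residual_variance) * rng.standard_normal((n, k))
    latent = (
        config.mu_logit
        + config.causal_effect_logit * dosages[:, causal_index].astype(float)
        + g
        + e
    )
    total = rng.poisson(config.depth_mean, size=(n, k))
    edited = rng.binomial(total, expit(latent))
    site_ids = [f"site{j}" for j in range(k)]
    return EditingSim(edited, total, latent, causal_index, site_ids)


# ---------------------------------------------------------------------------
# pre-mRNA with a planted inverted repeat


@dataclass
class PremrnaSim:
    name: str
    sequence: str
    pairings: list[tuple[int, int]]  # 0-based (i, j), i < j, truth table
    edit_positions: list[int]  # 0-based, inside the forward stem
    stem: tuple[int, int]  # forward-arm interval, 0-based half-open


def random_rna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def simulate_premrna(
    config: SimConfig,
    rng: np.random.Generator,
    stem_len: int = 50,
    loop_len: int = 12,
    flank: int = 150,
    n_edits: int = 3,
) -> PremrnaSim:
    """Sequence with a planted inverted repeat harboring edit sites.

    Layout: flank + stem + loop + revcomp(stem) + flank.  The truth table
    pairs stem position k with the mirrored position of the reverse arm.
    """
    if stem_len < 40 or loop_len < 10:
        raise ValueError("planted stems need stem >= 40 nt and loop >= 10 nt")
    stem = list(random_rna(stem_len, rng))
    edit_offsets = np.sort(
        rng.choice(np.arange(5, stem_len - 5), size=n_edits, replace=False)
    )
    for k in edit_offsets:
        stem[k] = "A"
    stem_seq = "".join(stem)
    seq = (
        random_rna(flank, rng)
        + stem_seq
        + random_rna(loop_len, rng)
        + eio.revcomp(stem_seq)
        + random_rna(flank, rng)
    )
    a = flank  # forward arm start
    b = flank + stem_len + loop_len  # reverse arm start
    pairings = [(a + k, b + stem_len - 1 - k) for k in range(stem_len)]
    return PremrnaSim(
        name="premrna",
        sequence=seq,
        pairings=pairings,
        edit_positions=[a + int(k) for k in edit_offsets],
        stem=(a, a + stem_len),
    )


# ---------------------------------------------------------------------------
# read-pair phase tables


def simulate_read_pairs(
    phase_odds_ratio: float,
    n_reads: int,
    rng: np.random.Generator,
    p_edit: float = 0.4,
    p_alt: float = 0.5,
) -> np.ndarray:
    """2x2 read-pair counts, rows (edited, unedited) x cols (ref, alt).

    Cell probabilities follow the Plackett construction so the table's odds
    ratio, (edited&alt * unedited&ref) / (edited&ref * unedited&alt),
    equals ``phase_odds_ratio`` in expectation.
    """
    psi = float(phase_odds_ratio)
    if psi < 0:
        raise ValueError("odds ratio must be >= 0")
    if np.isinf(psi):
        x = min(p_edit, p_alt)
    elif psi == 1.0:
        x = p_edit * p_alt
    else:
        s = 1.0 + (p_edit + p_alt) * (psi - 1.0)
        x = (s - np.sqrt(s * s - 4.0 * psi * (psi - 1.0) * p_edit * p_alt)) / (
            2.0 * (psi - 1.0)
        )
    probs = np.array(
        [
            [p_edit - x, x],
            [1.0 - p_edit - p_alt + x, p_alt - x],
        ]
    )
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum()
    if n_reads == 0:
        return np.zeros((2, 2), dtype=int)
    counts = rng.multinomial(n_reads, probs.ravel()).reshape(2, 2)
    return counts


def simulate_expression(
    latent: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    target_mean: float = 500.0,
) -> np.ndarray:
    """Negative-binomial expression counts coupled to the editing latent.

    mean_i = exp(a + slope * latent_i), with a set so the population mean
    depth is near ``target_mean``; dispersion alpha from the config.
    """
    latent = np.asarray(latent, dtype=float)
    slope = config.phi_expression_slope
    a = np.log(target_mean) - slope * latent.mean(axis=0, keepdims=True)
    mu = np.exp(a + slope * latent)
    alpha = config.expression_dispersion
    if alpha < 1e-8:
        return rng.poisson(mu)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu))


# ---------------------------------------------------------------------------
# discovery bundle: genome, paired DNA/RNA call sets, annotations, truth


@dataclass
class DiscoveryBundle:
    genome: dict[str, str]
    gene_models: list
    rna_variants: list[VariantRecord]
    dna_variants: list[VariantRecord]
    mask: list[Interval]
    read_offsets: pd.DataFrame  # chrom, pos, read_len, offsets of edited reads
    edit_counts: pd.DataFrame  # chrom, pos, animal, edited, total
    truth: pd.DataFrame  # chrom, pos, kind
    samples: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_fasta(self.genome, outdir / "genome.fasta")
        contigs = {c: len(s) for c, s in self.genome.items()}
        eio.write_vcf(self.rna_variants, outdir / "rna.vcf", self.samples, contigs)
        eio.write_vcf(self.dna_variants, outdir / "dna.vcf", self.samples, contigs)
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.gene_models:
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
                    )
                for s, e in g.cds:
                    fh.write(
                        f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={g.gene_id}\n"
                    )
        with open(outdir / "mask.bed", "w") as fh:
            for iv in self.mask:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        eio.write_tsv(self.read_offsets, outdir / "read_offsets.tsv")
        eio.write_tsv(self.edit_counts, outdir / "edit_counts.tsv")
        eio.write_tsv(self.truth, outdir / "truth_discovery.tsv")


def _plant_context(genome: list[str], pos1: int, ref: str) -> None:
    """Write a run-free 11-mer around a planted site (1-based pos)."""
    motif = "CTGAC" + ref + "TCAGA"
    z = pos1 - 1 - 5
    genome[z : z + 11] = list(motif)


def simulate_discovery(
    seed: int = 0, n_animals: int = 9, chrom: str = "chr1", length: int = 24000
) -> DiscoveryBundle:
    """Paired DNA/RNA call sets with planted edits, SNPs and filter decoys.

    Planted truth: genuine edit sites appear only in the RNA call set and
    pass every filter; germline SNPs appear in both call sets; decoys fail
    exactly one filter each (quality, missing genotypes, alt observations,
    splice adjacency, homopolymer, read-end, repeat mask, cohort support).
    """
    rng = np.random.default_rng(seed)
    genome = list(random_rna(length, rng))
    samples = [f"D{i}" for i in range(n_animals)]

    from .io import GeneModel

    genes = [
        GeneModel("geneA", chrom, "+", [(1001, 3000), (4001, 6000), (7001, 9000)],
                  cds=[(4201, 5400)]),
        GeneModel("geneB", chrom, "-", [(10001, 12500), (13501, 16000)]),
        GeneModel("geneC", chrom, "+", [(18001, 20000)]),
    ]
    mask = [Interval(chrom, 21000, 22000)]

    def gts(n_het: int, n_missing: int = 0) -> list[int]:
        g = [1] * n_het + [0] * (n_animals - n_het - n_missing) + [eio.MISSING] * n_missing
        return g

    rna: list[VariantRecord] = []
    dna: list[VariantRecord] = []
    truth_rows = []
    offsets_rows = []
    counts_rows = []

    def add_edit(pos1: int, ref: str, alt: str, kind: str, *, qual: float = 60.0,
                 n_missing: int = 0, alt_obs: int = 24, offsets: str | None = None,
                 n_edited_animals: int = 9, depth: int = 30) -> None:
        _plant_context(genome, pos1, ref)
        rna.append(
            VariantRecord(GenomicPosition(chrom, pos1), ref, alt, qual,
                          gts(min(7, n_edited_animals), n_missing), alt_obs, samples)
        )
        truth_rows.append((chrom, pos1, kind))
        offsets_rows.append(
            (chrom, pos1, 100, offsets or "15;33;47;58;72;88")
        )
        for i, animal in enumerate(samples):
            edited = 8 if i < n_edited_animals else 0
            counts_rows.append((chrom, pos1, animal, edited, depth))

    # genuine edits (pass all filters)
    add_edit(3500, "A", "G", "edit")              # geneA intron
    add_edit(4630, "A", "G", "edit")              # geneA CDS
    add_edit(13000, "T", "C", "edit")             # geneB intron (- strand: A-to-I)
    add_edit(9200, "A", "G", "edit")              # just downstream of geneA (3'UTR rule)
    add_edit(18500, "A", "G", "edit")             # geneC noncoding exon

    # filter decoys, one failing predicate each
    add_edit(2200, "A", "G", "decoy_quality", qual=29.0)
    add_edit(2400, "A", "G", "decoy_missing", n_missing=2)
    add_edit(2600, "A", "G", "decoy_altobs", alt_obs=5)
    add_edit(3002, "A", "G", "decoy_splice")       # 2 bp into intron after donor 3000
    add_edit(5600, "A", "G", "decoy_homopolymer")
    genome[5600:5605] = list("AAAAA")              # run starts right of site 5600
    add_edit(7500, "A", "G", "decoy_readend", offsets="2;3;5;96;99")
    add_edit(21500, "A", "G", "decoy_mask")
    add_edit(8200, "A", "G", "decoy_cohort", n_edited_animals=5)
    add_edit(8400, "A", "G", "decoy_depth", depth=4)

    # germline SNPs: called in both RNA and DNA
    for pos1, ref, alt in [(1500, "C", "T"), (11000, "G", "A"), (19000, "T", "G")]:
        _plant_context(genome, pos1, ref)
        for dest in (rna, dna):
            dest.append(
                VariantRecord(GenomicPosition(chrom, pos1), ref, alt, 80.0,
                              gts(6), 30, samples)
            )
        truth_rows.append((chrom, pos1, "germline"))

    return DiscoveryBundle(
        genome={chrom: "".join(genome)},
        gene_models=genes,
        rna_variants=rna,
        dna_variants=dna,
        mask=mask,
        read_offsets=pd.DataFrame(
            offsets_rows, columns=["chrom", "pos", "read_len", "offsets"]
        ),
        edit_counts=pd.DataFrame(
            counts_rows, columns=["chrom", "pos", "animal", "edited", "total"]
        ),
        truth=pd.DataFrame(truth_rows, columns=["chrom", "pos", "kind"]),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# quantification bundle writer (CLI `simulate`)


def write_qtl_bundle(outdir: str | Path, config: SimConfig) -> None:
    """Simulate and write the full quantification-cohort bundle."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    ped = simulate_pedigree(config, rng)
    geno = simulate_genotypes(ped, config, rng)
    edit = simulate_editing(geno.dosages, ped, config, rng)
    expr = simulate_expression(edit.latent, config, rng)

    eio.write_tsv(ped.to_frame(), outdir / "pedigree.tsv")
    records = [
        VariantRecord(
            GenomicPosition(geno.chrom, int(p)), "A", "G", 100.0,
            list(map(int, geno.dosages[:, k])), int((geno.dosages[:, k] > 0).sum()),
            ped.ids,
        )
        for k, p in enumerate(geno.positions)
    ]
    eio.write_vcf(records, outdir / "genotypes.vcf", ped.ids,
                  {geno.chrom: config.chrom_span})

    rows = []
    site_pos = config.chrom_span // (len(edit.site_ids) + 1)
    site_positions = {}
    for j, sid in enumerate(edit.site_ids):
        # site sits 10 kbp from its causal variant: a cis-regulated site
        pos = int(geno.positions[edit.causal_index[j]]) + 10_000
        site_positions[sid] = pos
        for i, animal in enumerate(ped.ids):
            rows.append((sid, geno.chrom, pos, animal,
                         int(edit.edited[i, j]), int(edit.total[i, j])))
    eio.write_tsv(
        pd.DataFrame(rows, columns=["site", "chrom", "pos", "animal", "edited", "total"]),
        outdir / "edit_counts.tsv",
    )
    expr_df = pd.DataFrame(
        expr.T, index=[f"gene_{s}" for s in edit.site_ids], columns=ped.ids
    ).reset_index(names="gene")
    eio.write_tsv(expr_df, outdir / "expression_counts.tsv")

    pre = simulate_premrna(config, rng)
    eio.write_fasta({pre.name: pre.sequence}, outdir / "premrna.fasta")
    eio.write_tsv(
        pd.DataFrame(pre.pairings, columns=["pos_i", "pos_j"]),
        outdir / "truth" / "helix_pairs.tsv",
    )
    eio.write_tsv(
        pd.DataFrame(
            {
                "site": edit.site_ids,
                "site_pos": [site_positions[s] for s in edit.site_ids],
                "causal_pos": geno.positions[edit.causal_index],
                "beta": config.causal_effect_logit,
            }
        ),
        outdir / "truth" / "causal.tsv",
    )

    # read-pair phase tables for each site against its causal variant
    phase_rows = []
    for j, sid in enumerate(edit.site_ids):
        table = simulate_read_pairs(config.phase_odds_ratio, 400, rng)
        phase_rows.append(
            (sid, int(geno.positions[edit.causal_index[j]]),
             int(table[0, 0]), int(table[0, 1]), int(table[1, 0]), int(table[1, 1]),
             120, 1.0)
        )
    eio.write_tsv(
        pd.DataFrame(
            phase_rows,
            columns=["site", "variant_pos", "edited_ref", "edited_alt",
                     "unedited_ref", "unedited_alt", "separation", "ld_r2"],
        ),
        outdir / "phase_counts.tsv",
    )
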