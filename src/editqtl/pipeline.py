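"""File-level pipeline stages behind the CLI.

Each stage reads the TSV/VCF/FASTA artifacts of earlier stages and writes
tab-separated outputs with '#'-prefixed headers, so any stage can be
re-run or inspected independently.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, discovery, integrate, quantify, sim, structure
from . import io as eio
from .io import GenomicPosition

log = logging.getLogger("editqtl")


def _log_inputs(stage: str, paths: list[Path], seed: int | None = None) -> None:
    import importlib.metadata

    try:
        version = importlib.metadata.version("editqtl")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    np_version = np.__version__
    for p in paths:
        if p.exists():
            digest = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
            log.info("%s input %s sha256:%s", stage, p, digest)
    log.info("%s editqtl=%s numpy=%s seed=%s", stage, version, np_version, seed)


def run_simulate(outdir: str | Path, seed: int, overrides: dict | None = None) -> None:
    """Write the quantification-cohort bundle and a discovery bundle."""
    outdir = Path(outdir)
    fields = {f for f in sim.SimConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in (overrides or {}).items() if k in fields}
    config = sim.SimConfig(seed=seed, **kwargs)
    _log_inputs("simulate", [], seed)
    sim.write_qtl_bundle(outdir, config)
    bundle = sim.simulate_discovery(seed=seed)
    bundle.write(outdir / "discovery")


def run_discover(indir: str | Path, outdir: str | Path) -> pd.DataFrame:
    """Discovery chain on a directory holding rna.vcf, dna.vcf, genes.gff3,
    genome.fasta, mask.bed, read_offsets.tsv, edit_counts.tsv."""
    indir, outdir = Path(indir), Path(outdir)
    paths = {
        name: indir / name
        for name in (
            "rna.vcf", "dna.vcf", "genes.gff3", "genome.fasta",
            "mask.bed", "read_offsets.tsv", "edit_counts.tsv",
        )
    }
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError("missing required input(s): " + ", ".join(missing))
    _log_inputs("discover", list(paths.values()))
    rna = eio.read_vcf(paths["rna.vcf"])
    dna = eio.read_vcf(paths["dna.vcf"])
    genes = eio.read_gff_genes(paths["genes.gff3"])
    genome = eio.read_fasta(paths["genome.fasta"])
    mask = eio.read_bed_mask(paths["mask.bed"])
    offsets = eio.read_tsv(paths["read_offsets.tsv"])
    counts = eio.read_tsv(paths["edit_counts.tsv"])
    sites, cands, stats = discovery.discover(
        rna, dna, genes, genome, mask, offsets, counts
    )
    rows = [
        (
            s.position.chrom, s.position.pos, c.ref, c.alt, s.transcript_strand,
            s.edit_class, int(s.is_A_to_I), s.gene_id or ".", s.region,
        )
        for s, c in zip(sites, cands)
    ]
    sites_df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "strand", "edit_class",
                 "is_A_to_I", "gene", "region"],
    )
    eio.write_tsv(sites_df, outdir / "sites.tsv")
    summaries = discovery.summarize_sites(sites)
    summary = pd.concat(
        [df.rename(columns={name: "key"}).assign(table=name)
         for name, df in summaries.items()],
        ignore_index=True,
    )[["table", "key", "count", "percent"]]
    eio.write_tsv(summary, outdir / "summary.tsv")
    if stats is not None:
        eio.write_tsv(stats.per_site, outdir / "curation.tsv")
    return sites_df


def run_quantify(indir: str | Path, outdir: str | Path) -> None:
    """phi values and logit phenotypes from edit_counts.tsv."""
    indir, outdir = Path(indir), Path(outdir)
    counts_path = indir / "edit_counts.tsv"
    if not counts_path.exists():
        raise FileNotFoundError(f"missing required input: {counts_path}")
    _log_inputs("quantify", [counts_path])
    counts = eio.read_tsv(counts_path)
    phi = quantify.compute_phi(counts)
    eio.write_tsv(
        phi[["site", "animal", "edited", "total", "phi"]], outdir / "phi.tsv"
    )
    eio.write_tsv(quantify.site_phi_summary(phi), outdir / "phi_summary.tsv")
    pheno = quantify.logit_phenotype(counts)
    eio.write_tsv(pheno.reset_index(), outdir / "phenotypes.tsv")


def run_structure(indir: str | Path, outdir: str | Path, min_run: int = 25) -> None:
    """Dot-plot scan of premrna.fasta; helices and sparse dot triplets."""
    indir, outdir = Path(indir), Path(outdir)
    fasta = indir / "premrna.fasta"
    if not fasta.exists():
        raise FileNotFoundError(f"missing required input: {fasta}")
    _log_inputs("structure", [fasta])
    sequences = eio.read_fasta(fasta)
    helix_rows, dot_rows = [], []
    for name, seq in sequences.items():
        plot = structure.dotplot_scan(seq)
        for i, j in plot.pairs():
            dot_rows.append((name, i, j))
        for k, h in enumerate(structure.extract_helices(plot, min_run=min_run)):
            helix_rows.append(
                (name, k, h.forward[0], h.forward[1], h.reverse[0], h.reverse[1])
            )
    eio.write_tsv(
        pd.DataFrame(
            helix_rows,
            columns=["sequence", "helix", "fwd_start", "fwd_end", "rev_start", "rev_end"],
        ),
        outdir / "helices.tsv",
    )
    eio.write_tsv(
        pd.DataFrame(dot_rows, columns=["sequence", "i", "j"]),
        outdir / "dotplot.tsv",
    )


def _load_genotypes(indir: Path) -> tuple[np.ndarray, list[GenomicPosition], list[str]]:
    records = eio.read_vcf(indir / "genotypes.vcf")
    positions = [r.position for r in records]
    dosages = np.array([r.genotypes for r in records]).T  # animals x variants
    samples = records[0].samples if records else []
    return dosages, positions, samples


def _relationship_matrix(indir: Path, samples: list[str]) -> np.ndarray:
    ped = sim.Pedigree.from_frame(eio.read_tsv(indir / "pedigree.tsv"))
    A = assoc.a_matrix(ped)
    order = [ped.ids.index(s) for s in samples]
    return A[np.ix_(order, order)]


def _scan_phenotypes(
    phenotypes: pd.DataFrame,
    dosages: np.ndarray,
    positions: list[GenomicPosition],
    A: np.ndarray,
    outdir: Path,
    prefix: str,
    site_positions: dict[str, GenomicPosition] | None = None,
) -> None:
    """GLS scan of every phenotype column; per-phenotype association TSVs,
    inflation statistics, and cis/trans calls when site positions are
    known."""
    lambda_rows, cis_rows = [], []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        scan = assoc.GlsScan(y, A)
        results = scan.scan(dosages, positions)
        df = pd.DataFrame(
            [
                (r.position.chrom, r.position.pos, r.beta, r.se, r.chi2, r.p,
                 r.n_used, int(r.untestable))
                for r in results
            ],
            columns=["chrom", "pos", "beta", "se", "chi2", "p", "n", "untestable"],
        )
        eio.write_tsv(df, outdir / f"assoc_{prefix}_{name}.tsv")
        chi2 = df.loc[df["untestable"] == 0, "chi2"].to_numpy()
        lambda_rows.append((name, assoc.inflation(chi2)))
        if site_positions and name in site_positions:
            label, top = assoc.classify_cis(results, site_positions[name])
            threshold = assoc.bonferroni(0.05, int((df["untestable"] == 0).sum()))
            cis_rows.append(
                (name, label, top.position.chrom, top.position.pos, top.beta,
                 top.p, int(top.p < threshold))
            )
    eio.write_tsv(
        pd.DataFrame(lambda_rows, columns=["phenotype", "lambda"]),
        outdir / f"lambda_{prefix}.tsv",
    )
    if cis_rows:
        eio.write_tsv(
            pd.DataFrame(
                cis_rows,
                columns=["site", "call", "top_chrom", "top_pos", "top_beta",
                         "top_p", "significant"],
            ),
            outdir / "cis_calls.tsv",
        )


def run_edqtl(indir: str | Path, outdir: str | Path) -> None:
    """GLS association scan of logit-phi phenotypes against all variants."""
    indir, outdir = Path(indir), Path(outdir)
    required = [indir / "edit_counts.tsv", indir / "genotypes.vcf", indir / "pedigree.tsv"]
    for p in required:
        if not p.exists():
            raise FileNotFoundError(f"missing required input: {p}")
    _log_inputs("edqtl", required)
    counts = eio.read_tsv(indir / "edit_counts.tsv")
    pheno = quantify.logit_phenotype(counts)
    dosages, positions, samples = _load_genotypes(indir)
    pheno = pheno.reindex(samples)
    A = _relationship_matrix(indir, samples)
    keep = assoc.genotype_qc(dosages)
    dosages = dosages[:, keep]
    positions = [p for p, k in zip(positions, keep) if k]
    site_pos = {
        row["site"]: GenomicPosition(row["chrom"], int(row["pos"]))
        for _, row in counts[["site", "chrom", "pos"]].drop_duplicates().iterrows()
    }
    _scan_phenotypes(pheno, dosages, positions, A, outdir, "edqtl", site_pos)


def run_eqtl(indir: str | Path, outdir: str | Path) -> None:
    """GLS association scan of VST expression phenotypes."""
    indir, outdir = Path(indir), Path(outdir)
    required = [indir / "expression_counts.tsv", indir / "genotypes.vcf",
                indir / "pedigree.tsv"]
    for p in required:
        if not p.exists():
            raise FileNotFoundError(f"missing required input: {p}")
    _log_inputs("eqtl", required)
    expr = eio.read_tsv(indir / "expression_counts.tsv").set_index("gene")
    vst = assoc.vst(expr)
    dosages, positions, samples = _load_genotypes(indir)
    pheno = vst.T.reindex(samples)
    A = _relationship_matrix(indir, samples)
    keep = assoc.genotype_qc(dosages)
    dosages = dosages[:, keep]
    positions = [p for p, k in zip(positions, keep) if k]
    _scan_phenotypes(pheno, dosages, positions, A, outdir, "eqtl")


def run_integrate(indir: str | Path, assoc_dir: str | Path, outdir: str | Path) -> None:
    """Phase tests, phi-expression correlations, and edQTL/eQTL
    cosegregation with the sign-concordance test."""
    indir, assoc_dir, outdir = Path(indir), Path(assoc_dir), Path(outdir)
    phase_path = indir / "phase_counts.tsv"
    if not phase_path.exists():
        raise FileNotFoundError(f"missing required input: {phase_path}")
    _log_inputs("integrate", [phase_path])
    phase_df = eio.read_tsv(phase_path)
    pairs = [
        integrate.PhasePair(
            site=row["site"],
            variant_pos=int(row["variant_pos"]),
            observed=np.array(
                [[row["edited_ref"], row["edited_alt"]],
                 [row["unedited_ref"], row["unedited_alt"]]]
            ),
            separation=int(row["separation"]),
            ld_r2=float(row["ld_r2"]),
        )
        for _, row in phase_df.iterrows()
    ]
    eio.write_tsv(integrate.phase_enrichment(pairs), outdir / "phase_results.tsv")

    counts = eio.read_tsv(indir / "edit_counts.tsv")
    pheno = quantify.logit_phenotype(counts)
    expr = eio.read_tsv(indir / "expression_counts.tsv").set_index("gene")
    vst = assoc.vst(expr).T
    site_gene = [(s, f"gene_{s}") for s in pheno.columns if f"gene_{s}" in vst.columns]
    vst = vst.reindex(pheno.index)
    corr = integrate.phi_expression_correlation(pheno, vst, site_gene)
    eio.write_tsv(corr, outdir / "correlations.tsv")

    coseg_rows = []
    effect_pairs = []
    for site, gene in site_gene:
        ed_path = assoc_dir / f"assoc_edqtl_{site}.tsv"
        eq_path = assoc_dir / f"assoc_eqtl_{gene}.tsv"
        if not (ed_path.exists() and eq_path.exists()):
            continue
        ed = eio.read_tsv(ed_path)
        eq = eio.read_tsv(eq_path)
        top = ed.loc[ed["p"].idxmin()]
        # QTL profiles are compared over a 1 Mbp window centered on the
        # top edQTL marker
        window = abs(ed["pos"] - top["pos"]) <= 500_000
        pair = integrate.cosegregation(
            ed.loc[window, ["pos", "chi2"]], eq[["pos", "chi2"]], site, gene
        )
        eq_at_top = eq.loc[eq["pos"] == top["pos"], "beta"]
        beta_pair = (float(top["beta"]),
                     float(eq_at_top.iloc[0]) if len(eq_at_top) else np.nan)
        coseg_rows.append(
            (site, gene, pair.n_shared, pair.spearman_r, pair.p,
             int(pair.cosegregating), beta_pair[0], beta_pair[1])
        )
        if pair.cosegregating and np.isfinite(beta_pair[1]):
            effect_pairs.append(beta_pair)
    coseg_df = pd.DataFrame(
        coseg_rows,
        columns=["site", "gene", "n_shared", "spearman_r", "p",
                 "cosegregating", "beta_edqtl", "beta_eqtl"],
    )
    eio.write_tsv(coseg_df, outdir / "coseg.tsv")
    if len(effect_pairs) >= 2:
        mean_sign, t, p = integrate.sign_concordance(effect_pairs)
        eio.write_tsv(
            pd.DataFrame(
                [(len(effect_pairs), mean_sign, t, p)],
                columns=["n_pairs", "mean_sign", "t", "p"],
            ),
            outdir / "sign_concordance.tsv",
        )
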