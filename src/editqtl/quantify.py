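"""Editing proportions (phi), mapping phenotypes, and sequence context.

phi is the per-animal, per-site fraction of RNA-seq reads carrying the
edited base.  The mapping phenotype is the logit of phi with
Haldane-Anscombe pseudocounts, logit((edited + 0.5) / (total + 1)), which
keeps animals with phi of exactly 0 or 1 in the model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicPosition, revcomp

LN2 = np.log(2.0)
RNA_BASES = ("A", "C", "G", "U")


def compute_phi(edit_counts: pd.DataFrame) -> pd.DataFrame:
    """Long table of phi values from (site, animal, edited, total) counts.

    phi = edited / total; missing (NaN) where total is 0.
    """
    bad = edit_counts[edit_counts["edited"] > edit_counts["total"]]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"edited > total for site {r['site']} animal {r['animal']}"
        )
    out = edit_counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["phi"] = np.where(
            out["total"] > 0, out["edited"] / out["total"].astype(float), np.nan
        )
    return out


def site_phi_summary(phi_table: pd.DataFrame) -> pd.DataFrame:
    """Mean and median phi per site across animals (missing excluded)."""
    return (
        phi_table.groupby("site")["phi"]
        .agg(mean_phi="mean", median_phi="median", n="count")
        .reset_index()
    )


def logit_phenotype(edit_counts: pd.DataFrame) -> pd.DataFrame:
    """Wide phenotype matrix (animals x sites) of pseudocount-logit phi.

    y = ln(phi* / (1 - phi*)) with phi* = (edited + 0.5) / (total + 1);
    strictly monotone in the edited count at fixed total, finite at the
    boundaries.  Animals with zero total reads are missing (NaN).
    """
    t = edit_counts.copy()
    phi_star = (t["edited"] + 0.5) / (t["total"] + 1.0)
    t["y"] = np.where(
        t["total"] > 0, np.log(phi_star / (1.0 - phi_star)), np.nan
    )
    return t.pivot_table(index="animal", columns="site", values="y", dropna=False)


# ---------------------------------------------------------------------------
# sequence context


def site_context(
    position: GenomicPosition, strand: str, genome: dict[str, str], halfwidth: int
) -> str | None:
    """Transcript-strand sequence of width 2*halfwidth+1 centered on a site
    (DNA alphabet); None if it would run off the chromosome."""
    seq = genome[position.chrom]
    z = position.to_zero_based()
    if z - halfwidth < 0 or z + halfwidth >= len(seq):
        return None
    window = seq[z - halfwidth : z + halfwidth + 1].upper()
    return revcomp(window) if strand == "-" else window


def neighbor_frequencies(
    sites, genome: dict[str, str], background_halfwidth: int = 10
) -> pd.DataFrame:
    """Base counts at the -1/+1 neighbors of edit sites, with enrichment
    p-values.

    Background base frequencies are estimated from the +/-10 bp flanks of
    the same sites excluding offsets -1, 0, +1; each observed neighbor
    count is tested against its background frequency with a two-sided
    exact binomial test.
    """
    up: dict[str, int] = {b: 0 for b in "ACGT"}
    down: dict[str, int] = {b: 0 for b in "ACGT"}
    background: dict[str, int] = {b: 0 for b in "ACGT"}
    hw = background_halfwidth
    for s in sites:
        ctx = site_context(s.position, s.transcript_strand, genome, hw)
        if ctx is None:
            continue
        up[ctx[hw - 1]] += 1
        down[ctx[hw + 1]] += 1
        for k, base in enumerate(ctx):
            if abs(k - hw) > 1 and base in background:
                background[base] += 1
    bg_total = sum(background.values())
    rows = []
    for offset, counts in (("-1", up), ("+1", down)):
        total = sum(counts.values())
        for base in "ACGT":
            bg_freq = background[base] / bg_total if bg_total else np.nan
            p = (
                stats.binomtest(counts[base], total, bg_freq).pvalue
                if total and bg_total
                else np.nan
            )
            rows.append(
                (
                    offset,
                    "U" if base == "T" else base,
                    counts[base],
                    counts[base] / total if total else np.nan,
                    bg_freq,
                    p,
                )
            )
    return pd.DataFrame(
        rows, columns=["offset", "base", "count", "frequency", "background", "p"]
    )


def information_bits(frequencies: dict[str, float] | np.ndarray, n: int) -> float:
    """Logo column information: 2 - H - e(n) bits, clipped at 0.

    H is the Shannon entropy of the base frequencies in bits and
    e(n) = 3 / (2 ln2 n) is the small-sample correction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    f = np.asarray(
        [frequencies[b] for b in RNA_BASES]
        if isinstance(frequencies, dict)
        else frequencies,
        dtype=float,
    )
    nz = f[f > 0]
    H = float(-(nz * np.log2(nz)).sum())
    e_n = 3.0 / (2.0 * LN2 * n)
    return max(0.0, 2.0 - H - e_n)


def logo(sites, genome: dict[str, str], halfwidth: int = 10) -> pd.DataFrame:
    """Per-offset base frequencies and information content around edit
    sites (transcript strand; the edit column holds the unedited
    reference base)."""
    hw = halfwidth
    columns = {k: {b: 0 for b in "ACGT"} for k in range(-hw, hw + 1)}
    for s in sites:
        ctx = site_context(s.position, s.transcript_strand, genome, hw)
        if ctx is None:
            continue
        for k in range(-hw, hw + 1):
            base = ctx[k + hw]
            if base in "ACGT":
                columns[k][base] += 1
    rows = []
    for k in range(-hw, hw + 1):
        counts = columns[k]
        n = sum(counts.values())
        freqs = {
            ("U" if b == "T" else b): (counts[b] / n if n else 0.0) for b in "ACGT"
        }
        info = information_bits(freqs, n) if n else 0.0
        rows.append((k, *[freqs[b] for b in RNA_BASES], n, round(info, 3)))
    return pd.DataFrame(
        rows, columns=["offset", *(f"freq_{b}" for b in RNA_BASES), "n", "bits"]
    )


# ---------------------------------------------------------------------------
# context-phi association


def phi_by_context(
    phi_site_means: pd.DataFrame, contexts: pd.DataFrame
) -> pd.DataFrame:
    """One-way ANOVA of site-level mean phi by neighbor-base grouping.

    ``contexts`` columns: site, up, down (transcript-strand neighbor
    bases).  Groupings tested: upstream base, downstream base, and the
    joint 16-level up.down grouping.  Site-level means avoid
    pseudo-replication across animals.
    """
    merged = phi_site_means.merge(contexts, on="site")
    merged["joint"] = merged["up"] + "." + merged["down"]
    rows = []
    for grouping in ("up", "down", "joint"):
        groups = [
            g["mean_phi"].to_numpy()
            for _, g in merged.groupby(grouping)
            if len(g) > 0
        ]
        if len(groups) < 2:
            rows.append((grouping, np.nan, np.nan, len(merged)))
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p = 0.0, 1.0  # all values identical: no group effect
        else:
            f_stat, p = stats.f_oneway(*groups)
        rows.append((grouping, float(f_stat), float(p), len(merged)))
    means = (
        merged.groupby("up")["mean_phi"].mean().rename("group_mean").reset_index()
    )
    table = pd.DataFrame(rows, columns=["grouping", "F", "p", "n_sites"])
    table.attrs["upstream_group_means"] = means
    return table


def paired_base_phi_summary(
    phi_site_means: pd.DataFrame, opposite_bases: pd.DataFrame
) -> pd.DataFrame:
    """Median site-level phi grouped by the helix base opposite the edit.

    ``opposite_bases`` columns: site, opposite (RNA base or NaN for sites
    outside any helix; those are excluded).
    """
    merged = phi_site_means.merge(opposite_bases, on="site")
    merged = merged.dropna(subset=["opposite"])
    return (
        merged.groupby("opposite")["mean_phi"]
        .agg(median_phi="median", n="count")
        .reset_index()
    )
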