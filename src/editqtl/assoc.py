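"""Pedigree covariance and GLS association mapping.

The mapping model treats each phenotype (logit editing proportion, VST
expression, or a lactation trait) as

    y = X beta + eps,    Var(eps | X) = W = sigma2_P * (0.3 A + 0.7 I)

where ``A`` is the pedigree numerator relationship matrix and ``sigma2_P``
the phenotypic variance.  Each variant is tested individually with
X = [1, dosage]; the reported chi-square is (beta_hat / se)^2 on 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from .io import MISSING, GenomicPosition

# median of the chi-square distribution with 1 df; the denominator of the
# inflation statistic
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))

DEFAULT_WEIGHTS = (0.3, 0.7)


def a_matrix(pedigree) -> np.ndarray:
    """Additive numerator relationship matrix by the tabular method.

    Accepts a Pedigree-like object with integer ``sire``/``dam`` arrays
    (parent index, -1 for unknown) or a ``(sire, dam)`` pair.  Parents must
    precede their offspring.
    """
    if hasattr(pedigree, "sire"):
        sire, dam = pedigree.sire, pedigree.dam
    else:
        sire, dam = pedigree
    sire = np.asarray(sire, dtype=int)
    dam = np.asarray(dam, dtype=int)
    n = len(sire)
    if np.any(sire >= np.arange(n)) or np.any(dam >= np.arange(n)):
        raise ValueError("pedigree is not topologically ordered (parent after child)")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
    return A


@dataclass
class AssocResult:
    """Per-variant GLS output."""

    position: GenomicPosition | None
    beta: float
    se: float
    chi2: float
    p: float
    n_used: int
    untestable: bool = False


class GlsScan:
    """One phenotype, many variants: factorize W once, whiten per variant.

    sigma2_P is the sample variance of the analyzed phenotype vector; W is
    Cholesky-factorized once and reused across variants.  Animals with a
    missing phenotype are dropped up front; animals with a missing dosage
    are dropped pairwise per variant (with a refactorization on the subset).
    """

    def __init__(
        self,
        y: np.ndarray,
        A: np.ndarray | None = None,
        weights: tuple[float, float] = DEFAULT_WEIGHTS,
    ):
        y = np.asarray(y, dtype=float)
        self.keep = np.isfinite(y)
        self.y = y[self.keep]
        n = len(self.y)
        if n < 3:
            raise ValueError("need at least 3 non-missing phenotype values")
        if A is None:
            A = np.eye(len(y))
        self.A = np.asarray(A, dtype=float)[np.ix_(self.keep, self.keep)]
        self.weights = weights
        self.sigma2p = float(np.var(self.y, ddof=1))
        if self.sigma2p <= 0:
            raise ValueError("phenotype has zero variance")
        W = self.sigma2p * (weights[0] * self.A + weights[1] * np.eye(n))
        try:
            self._L = cholesky(W, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError("W is singular or not positive definite") from exc
        self._yw = solve_triangular(self._L, self.y, lower=True)
        self._ow = solve_triangular(self._L, np.ones(n), lower=True)

    def scan(
        self,
        dosages: np.ndarray,
        positions: list[GenomicPosition] | None = None,
    ) -> list[AssocResult]:
        """Test every column of ``dosages`` (n_animals x n_variants)."""
        D = np.asarray(dosages, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        D = D[self.keep, :]
        miss = (D == MISSING) | ~np.isfinite(D)
        results: list[AssocResult] = [None] * D.shape[1]  # type: ignore[list-item]
        pos = positions or [None] * D.shape[1]

        complete = ~miss.any(axis=0)
        if complete.any():
            Dw = solve_triangular(self._L, D[:, complete], lower=True)
            out = _fast_two_column_gls(self._ow, Dw, self._yw)
            for slot, res in zip(np.flatnonzero(complete), out):
                results[slot] = res
        for k in np.flatnonzero(~complete):
            ok = ~miss[:, k]
            if ok.sum() < 3:
                results[k] = AssocResult(pos[k], np.nan, np.nan, np.nan, np.nan, int(ok.sum()), True)
                continue
            sub = GlsScan(np.where(ok, self.y, np.nan), self.A, self.weights)
            results[k] = sub.scan(D[:, k][:, None])[0]
        for k, p_ in enumerate(pos):
            results[k].position = p_
        return results


def _fast_two_column_gls(ow: np.ndarray, Dw: np.ndarray, yw: np.ndarray) -> list[AssocResult]:
    """Closed-form [1, dosage] GLS for many whitened dosage columns at once."""
    n = len(yw)
    s11 = float(ow @ ow)
    t1 = float(ow @ yw)
    s12 = ow @ Dw
    s22 = np.einsum("ij,ij->j", Dw, Dw)
    t2 = Dw.T @ yw
    det = s11 * s22 - s12**2
    testable = det > 1e-10 * s11 * np.maximum(s22, 1e-30)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s11 * t2 - s12 * t1) / det
        var_beta = s11 / det
        se = np.sqrt(var_beta)
        chi2 = (beta / se) ** 2
        p = stats.chi2.sf(chi2, df=1)
    out = []
    for k in range(Dw.shape[1]):
        if not testable[k]:
            out.append(AssocResult(None, np.nan, np.nan, np.nan, np.nan, n, True))
        else:
            out.append(
                AssocResult(None, float(beta[k]), float(se[k]), float(chi2[k]), float(p[k]), n)
            )
    return out


def gls_fit(
    y: np.ndarray,
    dosage: np.ndarray,
    A: np.ndarray | None = None,
    weights: tuple[float, float] = DEFAULT_WEIGHTS,
    position: GenomicPosition | None = None,
) -> AssocResult:
    """GLS fit of a single variant; see :class:`GlsScan` for the model."""
    res = GlsScan(y, A, weights).scan(np.asarray(dosage)[:, None], [position])[0]
    return res


def inflation(chi2_values: np.ndarray) -> float:
    """Inflation statistic: observed median chi-square over 0.4549."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    chi2_values = chi2_values[np.isfinite(chi2_values)]
    if len(chi2_values) == 0:
        raise ValueError("no finite chi-square values")
    return float(np.median(chi2_values) / CHI2_MEDIAN_1DF)


def bonferroni(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def classify_cis(
    results: list[AssocResult],
    site_position: GenomicPosition,
    window: int = 500_000,
) -> tuple[str, AssocResult]:
    """Label a QTL cis/trans by the location of its top associated variant.

    The top variant minimizes p; ties break by distance to the edited site,
    then by genomic position.  The QTL is cis iff the top variant lies on
    the same chromosome within ``window`` bp of the site.
    """
    testable = [r for r in results if not r.untestable and r.position is not None]
    if not testable:
        raise ValueError("no testable variants")

    def dist(r: AssocResult) -> float:
        if r.position.chrom != site_position.chrom:
            return float("inf")
        return abs(r.position.pos - site_position.pos)

    top = min(testable, key=lambda r: (r.p, dist(r), r.position.chrom, r.position.pos))
    is_cis = (
        top.position.chrom == site_position.chrom
        and abs(top.position.pos - site_position.pos) <= window
    )
    return ("cis" if is_cis else "trans"), top


# ---------------------------------------------------------------------------
# expression phenotypes


def read_counts_for_gene(blocks: list[tuple[int, int]], gene) -> bool:
    """Does a read (aligned blocks, 1-based inclusive) count for a gene?

    A read counts iff every block lies inside an exon of the gene and every
    inter-block gap corresponds to an annotated exon junction; reads that
    splice at an unannotated site are excluded.
    """
    exons = gene.exons
    for s, e in blocks:
        if not any(xs <= s and e <= xe for xs, xe in exons):
            return False
    junctions = gene.annotated_junctions
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        if (e0, s1) not in junctions:
            return False
    return True


def exonic_counts(reads: pd.DataFrame, gene_models: list) -> pd.DataFrame:
    """Count exon-consistent reads per gene per animal.

    ``reads`` needs columns animal, chrom, blocks (semicolon-separated
    "start-end" pairs, 1-based inclusive).
    """
    genes_by_chrom: dict[str, list] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    animals = sorted(reads["animal"].unique())
    counts = pd.DataFrame(
        0, index=[g.gene_id for g in gene_models], columns=animals, dtype=int
    )
    for row in reads.itertuples(index=False):
        blocks = sorted(
            tuple(map(int, b.split("-"))) for b in str(row.blocks).split(";")
        )
        for g in genes_by_chrom.get(row.chrom, []):
            if read_counts_for_gene(blocks, g):
                counts.loc[g.gene_id, row.animal] += 1
    return counts


def estimate_dispersion(counts: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across genes (rows)."""
    counts = np.asarray(counts, dtype=float)
    m = counts.mean(axis=1)
    v = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (v - m) / m**2
    alpha = alpha[np.isfinite(alpha) & (alpha > 0)]
    if len(alpha) == 0:
        return 1e-8
    return float(np.median(alpha))


def vst(counts, dispersion: float | None = None):
    """Variance-stabilizing transform for NB counts with common dispersion.

    f(x) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x)) / ln(2); approximately
    log2-scaled for large x and 2*sqrt(x)/ln 2 as alpha -> 0.  Monotone in x.
    """
    x = np.asarray(counts, dtype=float)
    alpha = estimate_dispersion(np.atleast_2d(x)) if dispersion is None else dispersion
    if alpha <= 0:
        raise ValueError("dispersion must be positive")
    out = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x)) / np.log(2.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


# ---------------------------------------------------------------------------
# genotype QC


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test (two-sided, by heterozygote-count
    probability ordering)."""
    n = n_het + n_hom_ref + n_hom_alt
    n_rare = n_het + 2 * min(n_hom_ref, n_hom_alt)
    if n == 0 or n_rare == 0:
        return 1.0
    # probabilities over all heterozygote counts with the same allele counts
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    from scipy.special import gammaln

    for i, h in enumerate(hets):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        logp[i] = (
            gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(rare_hom + 1)
            - gammaln(common_hom + 1)
            + h * np.log(2)
            + gammaln(n_rare + 1)
            + gammaln(2 * n - n_rare + 1)
            - gammaln(2 * n + 1)
        )
    p_all = np.exp(logp - logp.max())
    p_all /= p_all.sum()
    p_obs = p_all[hets == n_het][0]
    return float(min(1.0, p_all[p_all <= p_obs * (1 + 1e-12)].sum()))


def genotype_qc(
    dosages: np.ndarray, maf_min: float = 0.01, hwe_p_min: float = 1e-30
) -> np.ndarray:
    """Boolean keep-mask over variant columns: MAF and HWE screens."""
    D = np.ma.masked_equal(np.asarray(dosages), MISSING)
    freq = D.mean(axis=0).filled(np.nan) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    for k in np.flatnonzero(keep):
        col = D[:, k].compressed()
        n_het = int((col == 1).sum())
        n0 = int((col == 0).sum())
        n2 = int((col == 2).sum())
        if hwe_exact_test(n_het, n0, n2) < hwe_p_min:
            keep[k] = False
    return keep
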