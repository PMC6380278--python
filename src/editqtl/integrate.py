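"""Cross-layer analyses linking edits, variants, expression and traits.

Four analyses: (1) read-pair phase enrichment between an edit site and a
nearby candidate variant (2x2 chi-square of independence); (2) the
complementarity sign test — whether alleles that break base-pairing at
the edit site depress editing; (3) phi-expression Pearson correlations
with optional ADAR-expression adjustment; (4) cosegregation of QTL pairs
by Spearman correlation of their chi-square association profiles, with
effect-sign concordance across cosegregating pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

COSEG_R_THRESHOLD = 0.707  # |r| > 0.707 ~ r^2 > 0.5


@dataclass
class PhasePair:
    """An edit site, a nearby variant, and their 2x2 read-pair table.

    Observed rows are (edited, unedited), columns (ref, alt).  The pair is
    usable when every observed and expected cell is at least 6, the sites
    are within 150 bases, and the variant is in LD (R^2 > 0.95) with the
    top associated variant.
    """

    site: str
    variant_pos: int
    observed: np.ndarray
    separation: int
    ld_r2: float
    expected: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.shape != (2, 2):
            raise ValueError("observed table must be 2x2")
        total = self.observed.sum()
        if total > 0:
            rows = self.observed.sum(axis=1, keepdims=True)
            cols = self.observed.sum(axis=0, keepdims=True)
            self.expected = rows @ cols / total
        else:
            self.expected = np.zeros((2, 2))

    @property
    def usable(self) -> bool:
        return (
            bool((self.observed >= 6).all())
            and bool((self.expected >= 6).all())
            and self.separation <= 150
            and self.ld_r2 > 0.95
        )

    @property
    def exclusion_reason(self) -> str | None:
        if (self.observed < 6).any() or (self.expected < 6).any():
            return "cell_below_6"
        if self.separation > 150:
            return "separation_above_150"
        if self.ld_r2 <= 0.95:
            return "ld_below_0.95"
        return None


def pearson_chi2(observed: np.ndarray) -> float:
    """Pearson chi-square of independence, sum (O-E)^2 / E with expected
    counts from the margins; no continuity correction."""
    observed = np.asarray(observed, dtype=float)
    total = observed.sum()
    expected = (
        observed.sum(axis=1, keepdims=True) @ observed.sum(axis=0, keepdims=True)
    ) / total
    return float(((observed - expected) ** 2 / expected).sum())


def phase_test(pair: PhasePair) -> tuple[float, float]:
    """Pearson chi-square test of independence on the 2x2 table, 1 df,
    no continuity correction.  Raises on unusable pairs."""
    if not pair.usable:
        raise ValueError(f"pair not usable: {pair.exclusion_reason}")
    chi2 = pearson_chi2(pair.observed)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def phase_enrichment(pairs: list[PhasePair], alpha: float = 0.05) -> pd.DataFrame:
    """Run phase tests over all usable pairs with a Bonferroni threshold
    computed from the number of usable pairs; unusable pairs are reported
    with their exclusion reason."""
    usable = [p for p in pairs if p.usable]
    threshold = alpha / len(usable) if usable else np.nan
    rows = []
    for p in pairs:
        if p.usable:
            chi2, pval = phase_test(p)
            rows.append(
                (p.site, p.variant_pos, chi2, pval, pval < threshold, None)
            )
        else:
            rows.append((p.site, p.variant_pos, np.nan, np.nan, False, p.exclusion_reason))
    df = pd.DataFrame(
        rows,
        columns=["site", "variant_pos", "chi2", "p", "significant", "excluded"],
    )
    df.attrs["n_usable"] = len(usable)
    df.attrs["threshold"] = threshold
    return df


def complementarity_test(noncomplementary_betas: np.ndarray) -> tuple[float, float]:
    """One-sample, one-sided t-test that the mean allele-substitution
    effect of the non-complementary allele is below zero.

    Effects must be oriented to the non-complementary allele before the
    call; pairs where neither allele pairs the opposite base are excluded
    upstream.
    """
    betas = np.asarray(noncomplementary_betas, dtype=float)
    betas = betas[np.isfinite(betas)]
    if len(betas) < 2:
        raise ValueError("need at least 2 effects")
    if np.ptp(betas) == 0:
        # zero-spread limit: the t statistic diverges
        mean = float(betas.mean())
        if mean == 0:
            return 0.0, 0.5
        return float(np.sign(mean) * np.inf), 0.0 if mean < 0 else 1.0
    res = stats.ttest_1samp(betas, 0.0, alternative="less")
    return float(res.statistic), float(res.pvalue)


def phi_expression_correlation(
    logit_phi: pd.DataFrame,
    vst_expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    adar_expr: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between logit-phi and VST expression per
    site-gene pair, over animals with both values.

    When ``adar_expr`` is given, each expression column is first replaced
    by its residuals from an ordinary least squares fit on ADAR
    expression, removing variation attributable to enzyme abundance.
    Significance is Bonferroni-corrected across the tested pairs.
    """
    expr = vst_expr.copy()
    if adar_expr is not None:
        a = adar_expr.reindex(expr.index).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(a)), a])
        for col in expr.columns:
            yv = expr[col].to_numpy(dtype=float)
            ok = np.isfinite(yv) & np.isfinite(a)
            coef, *_ = np.linalg.lstsq(X[ok], yv[ok], rcond=None)
            resid = np.full_like(yv, np.nan)
            resid[ok] = yv[ok] - X[ok] @ coef
            expr[col] = resid
    rows = []
    m = len(pairs)
    for site, gene in pairs:
        x = logit_phi[site].astype(float)
        y = expr[gene].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            rows.append((site, gene, np.nan, np.nan, n, False))
            continue
        r, p = stats.pearsonr(x[ok], y[ok])
        rows.append((site, gene, float(r), float(p), n, p < alpha / m))
    return pd.DataFrame(
        rows, columns=["site", "gene", "r", "p", "n", "significant"]
    )


@dataclass
class CosegPair:
    """Two QTL profiles compared over their shared variants."""

    name_a: str
    name_b: str
    n_shared: int
    spearman_r: float
    p: float
    cosegregating: bool


def cosegregation(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    name_a: str = "a",
    name_b: str = "b",
    r_threshold: float = COSEG_R_THRESHOLD,
) -> CosegPair:
    """Spearman correlation of two chi-square association profiles.

    Profiles are DataFrames with columns (pos, chi2); only variants
    present in both are compared (average ranks on ties).  The pair is
    classified cosegregating when r exceeds 0.707 (r^2 > 0.5).
    """
    merged = profile_a.merge(profile_b, on="pos", suffixes=("_a", "_b")).dropna()
    n = len(merged)
    if n < 3:
        return CosegPair(name_a, name_b, n, np.nan, np.nan, False)
    r, p = stats.spearmanr(merged["chi2_a"], merged["chi2_b"])
    return CosegPair(name_a, name_b, n, float(r), float(p), bool(r > r_threshold))


def sign_concordance(
    effect_pairs: list[tuple[float, float]]
) -> tuple[float, float, float]:
    """One-sided t-test that cosegregating QTL pairs have opposite signs.

    Each item is (beta_top_edqtl, beta_other_qtl) with both effects
    oriented to the same (alternate) allele; the per-pair sign product
    s in {-1, +1} is tested for mean(s) < 0.  Returns (mean sign, t, p).
    """
    signs = np.array(
        [np.sign(a) * np.sign(b) for a, b in effect_pairs], dtype=float
    )
    signs = signs[signs != 0]
    if len(signs) < 2:
        raise ValueError("need at least 2 sign products")
    if np.ptp(signs) == 0:
        # degenerate all-equal case: t is +/- infinity
        mean = float(signs.mean())
        return mean, float(np.sign(mean) * np.inf), 0.0 if mean < 0 else 1.0
    res = stats.ttest_1samp(signs, 0.0, alternative="less")
    return float(signs.mean()), float(res.statistic), float(res.pvalue)
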