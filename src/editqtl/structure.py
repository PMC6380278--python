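"""Double-stranded pre-mRNA prediction by dot-plot scanning.

A dot is placed at a position pair (i, j) when at least 11 of the 15
nucleotide pairs centered on (i, j) — sequence[i+k] against sequence[j-k]
— are Watson-Crick complementary (A:U/T, C:G only; G:U wobble is excluded
from the scan and enters only when interpreting edited bases).  Runs of
consecutive dots along an anti-diagonal are potential double-stranded
helices, with position i paired to j = (i+j) - i along the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel, GenomicPosition

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# Watson-Crick pairing on codes (A:U/T, C:G); N pairs nothing
_PAIR = np.zeros((5, 5), dtype=bool)
for a, b in ((0, 3), (3, 0), (1, 2), (2, 1)):
    _PAIR[a, b] = True


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in sequence.upper()), dtype=np.int8)


@dataclass
class RegionSpec:
    """A per-gene extraction window around its outermost edit sites."""

    gene_id: str
    chrom: str
    start: int  # 0-based half-open, clipped to the chromosome
    end: int
    chunks: list[tuple[int, int]]  # sub-intervals scanned separately


@dataclass
class HelixRegion:
    """One predicted double-stranded segment (region-local coordinates).

    ``pairing`` maps positions of both arms onto each other (an
    involution); arms have equal length and do not overlap.
    """

    forward: tuple[int, int]  # 0-based half-open
    reverse: tuple[int, int]
    pairing: dict[int, int] = field(repr=False)

    def __post_init__(self) -> None:
        if self.forward[1] > self.reverse[0]:
            raise ValueError("helix arms overlap")
        if self.forward[1] - self.forward[0] != self.reverse[1] - self.reverse[0]:
            raise ValueError("helix arms differ in length")

    def __len__(self) -> int:
        return self.forward[1] - self.forward[0]

    def contains(self, pos: int) -> bool:
        return (
            self.forward[0] <= pos < self.forward[1]
            or self.reverse[0] <= pos < self.reverse[1]
        )


@dataclass
class DotPlot:
    """Sparse dot matrix, stored per anti-diagonal (d = i + j)."""

    n: int
    window: int
    min_match: int
    diagonals: dict[int, np.ndarray]  # d -> sorted i positions with a dot

    def has_dot(self, i: int, j: int) -> bool:
        arr = self.diagonals.get(i + j)
        return arr is not None and i in arr

    def pairs(self):
        for d, arr in sorted(self.diagonals.items()):
            for i in arr:
                yield int(i), int(d - i)

    def to_dense(self) -> np.ndarray:
        m = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.pairs():
            m[i, j] = True
        return m


def extract_regions(
    site_positions: dict[str, list[GenomicPosition]],
    gene_models: list[GeneModel],
    genome: dict[str, str],
    pad: int = 1500,
    max_len: int = 15_000,
    overlap: int = 1500,
) -> list[RegionSpec]:
    """Per gene, the window spanning its outermost edit sites +/- 1.5 kbp,
    split into <= 15 kbp chunks with 1.5 kbp overlap when longer."""
    genes = {g.gene_id: g for g in gene_models}
    out = []
    for gene_id, positions in site_positions.items():
        if not positions or gene_id not in genes:
            continue
        g = genes[gene_id]
        chrom_len = len(genome[g.chrom])
        lo = min(p.pos for p in positions)
        hi = max(p.pos for p in positions)
        start = max(0, lo - 1 - pad)
        end = min(chrom_len, hi + pad)
        chunks = []
        if end - start <= max_len:
            chunks.append((start, end))
        else:
            step = max_len - overlap
            s = start
            while True:
                e = min(end, s + max_len)
                chunks.append((s, e))
                if e >= end:
                    break
                s += step
        out.append(RegionSpec(gene_id, g.chrom, start, end, chunks))
    return out


def dotplot_scan(sequence: str, window: int = 15, min_match: int = 11) -> DotPlot:
    """Scan a sequence against its own complement.

    Positions within window//2 of either end are not evaluated; sequences
    shorter than the window give an empty plot.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if min_match > window:
        raise ValueError("min_match cannot exceed window")
    codes = _encode(sequence)
    n = len(codes)
    half = window // 2
    diagonals: dict[int, np.ndarray] = {}
    if n < window:
        return DotPlot(n, window, min_match, diagonals)
    kernel = np.ones(window)
    for d in range(2 * n - 1):
        i_lo = max(0, d - (n - 1))
        i_hi = min(n - 1, d)
        if i_hi - i_lo + 1 < window:
            continue
        i_range = np.arange(i_lo, i_hi + 1)
        v = _PAIR[codes[i_range], codes[d - i_range]].astype(float)
        sums = np.convolve(v, kernel, mode="valid")
        centers = i_range[half : len(i_range) - half]
        hits = centers[sums >= min_match]
        # a dot also requires the window to fit around j = d - i
        hits = hits[(d - hits - half >= 0) & (d - hits + half < n)]
        if len(hits):
            diagonals[d] = hits
    return DotPlot(n, window, min_match, diagonals)


def extract_helices(dotplot: DotPlot, min_run: int = 25) -> list[HelixRegion]:
    """Anti-diagonal runs of >= min_run consecutive dots become helices.

    Runs are clipped to the i < j half-plane so the two arms never
    overlap; bulges (any gap) split helices.
    """
    helices = []
    for d, arr in sorted(dotplot.diagonals.items()):
        if len(arr) == 0:
            continue
        breaks = np.flatnonzero(np.diff(arr) != 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(arr) - 1]))
        for s_idx, e_idx in zip(starts, ends):
            i0, i1 = int(arr[s_idx]), int(arr[e_idx])
            i1 = min(i1, (d - 1) // 2)  # keep strictly i < j
            length = i1 - i0 + 1
            if length < min_run:
                continue
            pairing = {}
            for i in range(i0, i1 + 1):
                pairing[i] = d - i
                pairing[d - i] = i
            helices.append(
                HelixRegion(
                    forward=(i0, i1 + 1),
                    reverse=(d - i1, d - i0 + 1),
                    pairing=pairing,
                )
            )
    return helices


_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U", "U": "U"}
_RNA_PAIR = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}


def opposite_base(
    pos: int, helices: list[HelixRegion], sequence: str
) -> str | None:
    """RNA base predicted to pair with a position, or None outside helices."""
    for h in helices:
        if pos in h.pairing:
            return _TO_RNA[sequence[h.pairing[pos]].upper()]
    return None


def allele_complementarity(
    ref: str, alt: str, pos: int, helices: list[HelixRegion], sequence: str
) -> dict[str, bool] | None:
    """Watson-Crick complementarity of each variant allele with the helix
    base opposite the variant; None when the variant is outside every
    helix.  A pair where neither allele is complementary is unusable for
    the complementarity sign test."""
    opp = opposite_base(pos, helices, sequence)
    if opp is None:
        return None
    return {
        allele: (_TO_RNA[allele.upper()], opp) in _RNA_PAIR
        for allele in (ref, alt)
    }
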