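"""Pile-up meta-gene analysis (PMGA).

For each gene of length l (in bins) a (3l)x(3l) obs/exp neighborhood -- the
gene body plus equal upstream/downstream flanks -- is rescaled to a fixed
60x60 pseudo-size by area-weighted averaging, rotated into the transcription
forward direction, and averaged over all genes of a cluster.  The same
machinery produces 60-bin meta-gene coverage profiles, 30x30 inter-gene
pileups for gene pairs, and off-diagonal pileups around pairs of track peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import ObsExpMatrix
from .scoring import gene_bins
from .tracks import CoverageTrack, GeneRecord

__all__ = [
    "PileupResult",
    "INTRA_PSEUDO_SIZE",
    "INTER_PSEUDO_SIZE",
    "extract_block",
    "rescale_to",
    "orient",
    "pmga_intra",
    "pmga_inter",
    "chip_metagene",
    "peak_pileup",
]

logger = logging.getLogger(__name__)

INTRA_PSEUDO_SIZE = 60
INTER_PSEUDO_SIZE = 30


@dataclass
class PileupResult:
    """Mean pileup matrix (or profile) with the number of items aggregated."""

    values: np.ndarray
    n: int
    cluster: str = ""


def extract_block(oe: ObsExpMatrix, gene: GeneRecord) -> np.ndarray | None:
    """The (3l)x(3l) obs/exp block: gene body flanked by one gene length each side.

    Returns ``None`` (logged) when a flank would run off the chromosome.
    """
    bins = gene_bins(gene, oe.resolution)
    l = len(bins)
    lo, hi = bins[0] - l, bins[-1] + 1 + l
    if lo < 0 or hi > oe.n_bins:
        logger.info("gene %s skipped: 3l window leaves the matrix", gene.id)
        return None
    return oe.values[lo:hi, lo:hi]


def _area_weights(source: int, target: int) -> np.ndarray:
    """(target, source) fractional-overlap weight matrix, rows sum to src/tgt."""
    edges = np.linspace(0.0, source, target + 1)
    W = np.zeros((target, source))
    for t in range(target):
        lo = np.maximum(edges[t], np.arange(source))
        hi = np.minimum(edges[t + 1], np.arange(source) + 1)
        W[t] = np.clip(hi - lo, 0.0, None)
    return W


def rescale_to(block: np.ndarray, target: int) -> np.ndarray:
    """Area-weighted downscale of a square block to target x target.

    Each destination pixel is the weighted mean of the source pixels it
    covers, with fractional overlaps for non-integer ratios (exactly
    mean-preserving on unmasked input).  NaN source pixels are excluded; a
    destination pixel is NaN only when all its contributors are.  Upsampling
    is refused.
    """
    block = np.asarray(block, dtype=float)
    src = block.shape[0]
    if block.shape[0] != block.shape[1]:
        raise ValueError("block must be square")
    if src < target:
        raise ValueError(f"cannot upsample a {src}-bin block to {target}")
    W = _area_weights(src, target)
    valid = (~np.isnan(block)).astype(float)
    filled = np.nan_to_num(block)
    num = W @ (filled * valid) @ W.T
    den = W @ valid @ W.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def orient(block: np.ndarray, strand: str) -> np.ndarray:
    """Align a square gene block to the transcription forward direction.

    Reverse-strand blocks are rotated 180 degrees (both axes flipped) so the
    TSS corner always sits at (0, 0); applying it twice is the identity.
    """
    if strand == "+":
        return block
    return block[::-1, ::-1]


def pmga_intra(oe: ObsExpMatrix, genes: list[GeneRecord],
               cluster: str = "", target: int = INTRA_PSEUDO_SIZE) -> PileupResult:
    """Element-wise mean of oriented, rescaled gene blocks (valid-count norm)."""
    acc = np.zeros((target, target))
    cnt = np.zeros((target, target))
    n = 0
    for gene in genes:
        block = extract_block(oe, gene)
        if block is None:
            continue
        scaled = orient(rescale_to(block, target), gene.strand)
        ok = ~np.isnan(scaled)
        acc[ok] += scaled[ok]
        cnt[ok] += 1
        n += 1
    if n == 0:
        raise ValueError("no eligible gene in cluster")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    return PileupResult(values=mean, n=n, cluster=cluster)


def _rect_rescale(block: np.ndarray, target: int) -> np.ndarray:
    """Per-axis area-weighted downscale of a rectangular block."""
    r, c = block.shape
    if r < target or c < target:
        raise ValueError("cannot upsample inter-gene block")
    Wr = _area_weights(r, target)
    Wc = _area_weights(c, target)
    valid = (~np.isnan(block)).astype(float)
    filled = np.nan_to_num(block)
    num = Wr @ (filled * valid) @ Wc.T
    den = Wr @ valid @ Wc.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def eligible_pairs(genes: list[GeneRecord], min_sep: int, max_sep: int) -> list[tuple]:
    """Gene pairs whose midpoint separation lies in [min_sep, max_sep]."""
    pairs = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gi, gj = genes[i], genes[j]
            mi, mj = (gi.start + gi.end) / 2, (gj.start + gj.end) / 2
            if min_sep <= abs(mj - mi) <= max_sep:
                pairs.append((gi, gj) if mi <= mj else (gj, gi))
    return pairs


def pmga_inter(oe: ObsExpMatrix, genes: list[GeneRecord],
               min_sep: int = 128_000, max_sep: int = 2_000_000,
               cluster: str = "", target: int = INTER_PSEUDO_SIZE) -> PileupResult:
    """Off-diagonal pileup of gene pairs at 30x30 pseudo-size.

    For each eligible pair, the (3 l1)x(3 l2) obs/exp region centered on the
    two gene midpoints is rescaled per-axis to target x target, each axis
    flipped independently for reverse-strand genes ("parallel forward"
    alignment), then averaged.  Pairs with overlapping 3l windows or windows
    leaving the matrix are skipped (logged).
    """
    acc = np.zeros((target, target))
    cnt = np.zeros((target, target))
    n = 0
    for g1, g2 in eligible_pairs(genes, min_sep, max_sep):
        b1 = gene_bins(g1, oe.resolution)
        b2 = gene_bins(g2, oe.resolution)
        l1, l2 = len(b1), len(b2)
        r_lo, r_hi = b1[0] - l1, b1[-1] + 1 + l1
        c_lo, c_hi = b2[0] - l2, b2[-1] + 1 + l2
        if r_lo < 0 or c_lo < 0 or r_hi > oe.n_bins or c_hi > oe.n_bins:
            logger.info("pair (%s,%s) skipped: window leaves the matrix",
                        g1.id, g2.id)
            continue
        if r_hi > c_lo:
            logger.info("pair (%s,%s) skipped: 3l windows overlap", g1.id, g2.id)
            continue
        block = oe.values[r_lo:r_hi, c_lo:c_hi]
        scaled = _rect_rescale(block, target)
        if g1.strand == "-":
            scaled = scaled[::-1, :]
        if g2.strand == "-":
            scaled = scaled[:, ::-1]
        ok = ~np.isnan(scaled)
        acc[ok] += scaled[ok]
        cnt[ok] += 1
        n += 1
    if n == 0:
        raise ValueError("no eligible gene pair")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    return PileupResult(values=mean, n=n, cluster=cluster)


def chip_metagene(track: CoverageTrack, genes: list[GeneRecord],
                  cluster: str = "", n_bins: int = INTRA_PSEUDO_SIZE,
                  chrom_length: int | None = None) -> PileupResult:
    """Mean 60-bin coverage profile over the 3l domain of each gene.

    The 3l domain (flank + body + flank, in bp) is split into ``n_bins``
    equal pseudo-bins with base-pair-weighted coverage, flipped for
    reverse-strand genes, and averaged over the cluster.
    """
    acc = np.zeros(n_bins)
    n = 0
    for gene in genes:
        l = gene.length
        lo, hi = gene.start - l, gene.end + l
        if lo < 0 or (chrom_length is not None and hi > chrom_length):
            logger.info("gene %s skipped: 3l domain leaves the chromosome", gene.id)
            continue
        profile = track.binned(lo, hi, n_bins)
        if gene.strand == "-":
            profile = profile[::-1]
        acc += profile
        n += 1
    if n == 0:
        raise ValueError("no eligible gene in cluster")
    return PileupResult(values=acc / n, n=n, cluster=cluster)


def peak_pileup(oe: ObsExpMatrix, peaks: list[tuple[int, int]],
                window: int = 10, min_sep: int = 160_000,
                max_sep: int = 320_000) -> PileupResult:
    """Mean off-diagonal pileup of windows centered at peak-pair pixels.

    ``peaks`` are (start, end) bp intervals, sorted by position.  Every pair
    with center separation within [min_sep, max_sep] contributes one
    (2*window+1)^2 obs/exp window centered at the (peak_i, peak_j) pixel;
    pairs whose window leaves the matrix are skipped.  An empty result (no
    pair in range) is returned with ``n=0`` and NaN values.
    """
    size = 2 * window + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n = 0
    r = oe.resolution
    centers = [(s + e) // 2 for s, e in peaks]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            sep = abs(centers[j] - centers[i])
            if not (min_sep <= sep <= max_sep):
                continue
            bi, bj = centers[i] // r, centers[j] // r
            if (bi - window < 0 or bj - window < 0
                    or bi + window + 1 > oe.n_bins or bj + window + 1 > oe.n_bins):
                logger.info("peak pair (%d,%d) skipped: too close to the edge", i, j)
                continue
            win = oe.values[bi - window: bi + window + 1,
                            bj - window: bj + window + 1]
            ok = ~np.isnan(win)
            acc[ok] += win[ok]
            cnt[ok] += 1
            n += 1
    if n == 0:
        logger.warning("peak_pileup: no peak pair within the separation range")
        return PileupResult(values=np.full((size, size), np.nan), n=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = acc / cnt
    mean[cnt == 0] = np.nan
    return PileupResult(values=mean, n=n)
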