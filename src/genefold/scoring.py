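"""Per-gene contact (IC) and Pol II (IR) scores, clustering and comparisons.

The IC score of a gene is the mean observed/expected contact value over all
pairs of bins inside the gene body,

    IC = sum_{i<j} c_ij / (N (N-1) / 2),

a dimensionless measure of intra-gene condensation.  The IR score is the
mean coverage-track signal over the gene's bins,

    IR = sum_i p_i / N,

a proxy for transcriptional activity.  Genes are clustered by dyadic length
interval and by the integer-rounded log2 of IR, mirroring how gene classes
are formed before pileup analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ObsExpMatrix
from .tracks import CoverageTrack, GeneRecord

__all__ = [
    "GeneScores",
    "gene_bins",
    "choose_resolution",
    "ic_score",
    "ir_score",
    "score_genes",
    "cluster_genes",
    "compare_conditions",
    "filter_by_track",
    "MIN_GENE_LENGTH",
    "MIN_CLUSTER_SIZE",
]

logger = logging.getLogger(__name__)

#: genes shorter than this are excluded by default (resolution limitations)
MIN_GENE_LENGTH = 1_000
#: clusters smaller than this are flagged as under-powered for map pileups
MIN_CLUSTER_SIZE = 25


@dataclass
class GeneScores:
    """Scores for one gene at the resolution used to compute them."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    resolution: int
    n_bins: int
    ic: float
    ir: float


def gene_bins(gene: GeneRecord, resolution: int) -> np.ndarray:
    """Indices of the matrix bins fully contained in the gene body."""
    b0 = -(-gene.start // resolution)
    b1 = gene.end // resolution
    return np.arange(b0, b1)


def choose_resolution(gene: GeneRecord, available: list[int]) -> int:
    """Pick the coarsest available resolution r with gene length > 20*r.

    Coarser bins maximize counts per pixel; the 20-bin floor keeps enough
    pixels per gene for a meaningful average.  Raises ``ValueError`` when no
    available resolution qualifies (gene excluded upstream).
    """
    eligible = [r for r in available if gene.length > 20 * r]
    if not eligible:
        raise ValueError(
            f"gene {gene.id} ({gene.length} bp) shorter than 20x the finest "
            f"available resolution"
        )
    return max(eligible)


def ic_score(oe: ObsExpMatrix, gene: GeneRecord, resolution: int | None = None) -> float:
    """Mean obs/exp over unmasked bin pairs i<j inside the gene body.

    The diagonal is excluded; pairs touching masked bins are excluded from
    numerator and denominator alike.  Returns NaN when every pair is masked.
    """
    r = resolution or oe.resolution
    if r != oe.resolution:
        raise ValueError("resolution does not match the obs/exp matrix")
    bins = gene_bins(gene, r)
    if len(bins) < 2:
        raise ValueError(f"gene {gene.id}: needs >= 2 bins at {r} bp")
    block = oe.values[np.ix_(bins, bins)]
    iu = np.triu_indices(len(bins), k=1)
    pairs = block[iu]
    pairs = pairs[~np.isnan(pairs)]
    if pairs.size == 0:
        logger.warning("gene %s: all intra-gene pairs masked", gene.id)
        return float("nan")
    return float(pairs.mean())


def ir_score(track: CoverageTrack, gene: GeneRecord, resolution: int) -> float:
    """Mean per-bin coverage p_i over the gene's bins (base-pair weighted)."""
    bins = gene_bins(gene, resolution)
    if len(bins) == 0:
        raise ValueError(f"gene {gene.id}: no full bin at {resolution} bp")
    per_bin = [track.mean(int(b) * resolution, (int(b) + 1) * resolution)
               for b in bins]
    return float(np.mean(per_bin))


def score_genes(
    oe_by_resolution: dict[int, ObsExpMatrix],
    track: CoverageTrack,
    genes: list[GeneRecord],
    min_length: int = MIN_GENE_LENGTH,
) -> pd.DataFrame:
    """Score every eligible gene at its per-gene chosen resolution.

    Genes shorter than ``min_length`` or than 20x the finest available
    resolution are excluded (logged).  Returns one row per scored gene.
    """
    available = sorted(oe_by_resolution)
    rows = []
    for gene in genes:
        if gene.length < min_length:
            logger.info("gene %s excluded: shorter than %d bp", gene.id, min_length)
            continue
        try:
            r = choose_resolution(gene, available)
        except ValueError:
            logger.info("gene %s excluded: below resolution floor", gene.id)
            continue
        oe = oe_by_resolution[r]
        bins = gene_bins(gene, r)
        rows.append({
            "gene": gene.id, "chrom": gene.chrom, "start": gene.start,
            "end": gene.end, "strand": gene.strand, "resolution": r,
            "n_bins": len(bins),
            "ic": ic_score(oe, gene, r),
            "ir": ir_score(track, gene, r),
        })
    return pd.DataFrame(rows)


def _length_bin_label(length: int) -> str:
    k = int(math.floor(math.log2(max(length, 1) / 1000.0)))
    lo, hi = 2**k, 2 ** (k + 1)
    return f"{lo}-{hi} kb"


def cluster_genes(scores: pd.DataFrame,
                  min_cluster_size: int = MIN_CLUSTER_SIZE) -> pd.DataFrame:
    """Assign each gene an integer log2(IR) bin and a dyadic length bin.

    Genes with IR <= 0 cannot be log-binned and are assigned the lowest
    occupied bin (logged).  Clusters (ir_bin x length_bin) with fewer than
    ``min_cluster_size`` members are flagged ``under_powered``: pileup maps
    built from them lack statistics and are excluded from map aggregation.
    """
    out = scores.copy()
    ir = out["ir"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        bins = np.where(ir > 0, np.round(np.log2(np.where(ir > 0, ir, 1.0))),
                        np.nan)
    if np.isnan(bins).any():
        fallback = np.nanmin(bins) if np.isfinite(bins).any() else 0.0
        n_bad = int(np.isnan(bins).sum())
        logger.warning("%d genes with IR <= 0 assigned to lowest bin", n_bad)
        bins = np.where(np.isnan(bins), fallback, bins)
    out["ir_bin"] = bins.astype(int)
    out["length_bin"] = [(_length_bin_label(e - s))
                         for s, e in zip(out["start"], out["end"])]
    sizes = out.groupby(["ir_bin", "length_bin"])["gene"].transform("size")
    out["cluster_size"] = sizes
    out["under_powered"] = sizes < min_cluster_size
    return out


def compare_conditions(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Per-gene log2 fold-changes of IC and IR between two conditions.

    Genes present in only one condition are dropped (count logged).  Returns
    the merged per-gene table plus the Spearman rank correlation (average
    ranks for ties) between the two fold-changes; the correlation is NaN and
    flagged ``degenerate`` when either fold-change is constant.
    """
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
    dropped = len(a) + len(b) - 2 * len(merged)
    if dropped:
        logger.info("compare_conditions: %d unmatched gene records dropped", dropped)
    merged["dlog2_ic"] = np.log2(merged["ic_b"] / merged["ic_a"])
    merged["dlog2_ir"] = np.log2(merged["ir_b"] / merged["ir_a"])
    x, y = merged["dlog2_ic"].to_numpy(), merged["dlog2_ir"].to_numpy()
    degenerate = (len(merged) < 2 or np.allclose(x, x[0]) or np.allclose(y, y[0]))
    if degenerate:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = stats.spearmanr(x, y)
    return {"table": merged, "spearman_rho": float(rho), "p_value": float(p),
            "n_dropped": dropped, "degenerate": degenerate}


def filter_by_track(genes: list[GeneRecord], track: CoverageTrack,
                    quantile: float) -> list[GeneRecord]:
    """Drop genes whose mean track occupancy exceeds the given quantile.

    Used e.g. to restrict analysis to cohesin-poor genes by removing the
    high-occupancy tail of an SMC1a track.  ``quantile=1.0`` keeps all genes.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    occ = np.array([track.mean(g.start, g.end) for g in genes])
    if len(genes) == 0:
        return []
    threshold = np.quantile(occ, quantile)
    kept = [g for g, o in zip(genes, occ) if o <= threshold]
    logger.info("filter_by_track: removed %d/%d genes above quantile %.2f",
                len(genes) - len(kept), len(genes), quantile)
    return kept
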