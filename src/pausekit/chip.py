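"""Paired-end Pol II ChIP fragment-center profiling.

Paired-end sequencing gives each immunoprecipitated fragment's center
directly, avoiding the read-shifting uncertainty of single-end ChIP.  The
operations here score promoter enrichment from fragment centers, keep the
top fraction of genes by that score, build strand-mirrored binned metagene
profiles (25-bp bins by default downstream), and detect promoter-proximal
peaks — on real-like data the twin peaks at the TSS and ~+110 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .models import ChIPFragment, GeneModel


@dataclass
class MetageneProfile:
    """Mean per-bin item counts per gene around aligned anchors."""

    bin_edges: np.ndarray  # length n_bins + 1, TSS-relative nt
    values: np.ndarray  # mean counts per gene per bin
    n_genes: int
    bin_size: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.bin_edges) != len(self.values) + 1:
            raise ValueError("bin_edges must have one more entry than values")
        if np.any(self.values < 0):
            raise ValueError("values must be nonnegative")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def total_items(self) -> float:
        """Number of in-window items across all genes (conservation check)."""
        return float(self.values.sum() * self.n_genes)


def promoter_enrichment(
    fragments: Sequence[ChIPFragment],
    gene: GeneModel,
    genome_length: int,
    promoter_window: int = 500,
) -> float:
    """Fragment-center density in the promoter over the genome-wide density.

    The promoter is the +-``promoter_window`` nt interval around the
    annotated TSS (strand-agnostic); both densities are centers per kb, so
    uniform coverage scores ~1.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if not fragments:
        raise ValueError("zero background fragments")
    centers = np.array([f.center for f in fragments if f.chrom == gene.chrom])
    n_total = len(fragments)
    lo = gene.annotated_tss - promoter_window
    hi = gene.annotated_tss + promoter_window
    n_prom = int(np.sum((centers >= lo) & (centers <= hi))) if centers.size else 0
    prom_len = hi - lo + 1
    return (n_prom / prom_len) / (n_total / genome_length)


def select_top_fraction(
    gene_scores: pd.DataFrame,
    fraction: float = 0.30,
    score_col: str = "promoter_enrichment_score",
) -> pd.DataFrame:
    """Retain the ceil(fraction * n) genes with the highest scores.

    Ties at the cut break lexicographically by gene_id so the selection is
    deterministic and invariant to input row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if gene_scores.empty:
        raise ValueError("gene table must be non-empty")
    scores = gene_scores[score_col]
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    k = math.ceil(fraction * len(gene_scores))
    ordered = gene_scores.sort_values(
        [score_col, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered.head(k).reset_index(drop=True)


def metagene(
    positions_by_gene: Mapping[str, Sequence[int]],
    anchors: Mapping[str, tuple[int, str]],
    window: int = 500,
    bin_size: int = 25,
) -> MetageneProfile:
    """Bin per-gene item positions around anchors and average across genes.

    ``positions_by_gene`` maps gene_id to genomic positions (ChIP fragment
    centers or scRNA ends); ``anchors`` maps gene_id to (coordinate,
    strand).  Minus-strand genes are mirrored before aggregation so
    positive offsets always point downstream.  Bins cover [-window,
    window) and total signal is conserved: values.sum() * n_genes equals
    the number of in-window items.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if window % bin_size != 0:
        raise ValueError("window must be a multiple of bin_size")
    missing = set(positions_by_gene) - set(anchors)
    if missing:
        raise ValueError(f"genes without anchors: {sorted(missing)}")
    edges = np.arange(-window, window + bin_size, bin_size)
    total = np.zeros(len(edges) - 1)
    n_genes = 0
    for gid, positions in positions_by_gene.items():
        coord, strand = anchors[gid]
        sign = 1 if strand == "+" else -1
        offs = (np.asarray(positions, dtype=int) - coord) * sign
        offs = offs[(offs >= -window) & (offs < window)]
        total += np.bincount(
            (offs + window) // bin_size, minlength=len(edges) - 1
        )[: len(edges) - 1]
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no genes provided")
    return MetageneProfile(
        bin_edges=edges, values=total / n_genes, n_genes=n_genes, bin_size=bin_size
    )


def detect_promoter_peaks(
    profile: MetageneProfile, smoothing_bins: int = 3
) -> list[tuple[float, float]]:
    """Local maxima of the smoothed metagene, as (bin-center offset, height).

    The profile is smoothed with a centered moving average over
    ``smoothing_bins`` bins; interior local maxima exceeding the median of
    the smoothed profile are reported, tallest first.  A plateau maximum
    reports its center bin.  An all-zero profile yields no peaks.
    """
    values = profile.values
    if values.size == 0:
        raise ValueError("profile is empty")
    if np.all(values == 0):
        return []
    smooth = uniform_filter1d(values, size=smoothing_bins, mode="nearest")
    med = float(np.median(smooth))
    centers = profile.bin_centers
    peaks: list[tuple[float, float]] = []
    n = len(smooth)
    i = 1
    while i < n - 1:
        if smooth[i] <= smooth[i - 1]:
            i += 1
            continue
        # start of a rise; find plateau extent
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        if j < n - 1 and smooth[j + 1] < smooth[i] and smooth[i] > med:
            mid = (i + j) // 2
            peaks.append((float(centers[mid]), float(smooth[i])))
        i = j + 1
    peaks.sort(key=lambda p: -p[1])
    return peaks
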