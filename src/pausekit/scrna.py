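"""TSS and pause-site calling from paired-end short capped RNAs.

The 5' end of a short capped RNA marks where Pol II initiated; the 3' end
marks where it paused.  This module refines annotated TSSs to the position
with the most scRNA 5'-end support, histograms pause (3'-end) offsets,
builds annotated- vs. scRNA-centered metagene profiles with a sharpness
metric, summarizes divergent (antisense) transcription upstream of the TSS,
and computes base-frequency / information-content matrices for sequence
windows around start sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .models import GeneModel, ScRNARead

#: 5'-end admission gate around the called TSS for pause profiling, nt.
DEFAULT_TSS_GATE = 2


@dataclass(frozen=True)
class TSSCall:
    """A refined (scRNA-derived) transcription start site for one gene."""

    gene_id: str
    scrna_tss: int
    support: int
    offset_from_annotated: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("support must be >= 1")


@dataclass
class PauseProfile:
    """Histogram of sense 3'-end offsets downstream of a (called) TSS."""

    gene_id: str
    offsets: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def modal_offset(self) -> int:
        """Offset with the highest count; ties break to the smallest offset."""
        return int(self.offsets[int(np.argmax(self.counts))])

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


def _sense_reads(reads: Sequence[ScRNARead], gene: GeneModel):
    return [r for r in reads if r.strand == gene.strand and r.chrom == gene.chrom]


def call_tss(
    reads: Sequence[ScRNARead], gene: GeneModel, window: int = 500
) -> TSSCall | None:
    """Refine the annotated TSS to the modal scRNA 5'-end position.

    Scans the +-``window`` nt interval around the annotated TSS for the
    position with the highest number of sense 5'-end hits.  Ties break
    first by smallest |offset from annotation|, then by the upstream-most
    position.  Returns None (no-call) when no sense 5' end falls in the
    window.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    hits = Counter()
    for r in _sense_reads(reads, gene):
        off = gene.to_offset(r.five_prime)
        if -window <= off <= window:
            hits[off] += 1
    if not hits:
        return None
    best = min(hits, key=lambda o: (-hits[o], abs(o), o))
    return TSSCall(
        gene_id=gene.gene_id,
        scrna_tss=gene.from_offset(best),
        support=hits[best],
        offset_from_annotated=best,
    )


def pause_profile(
    reads: Sequence[ScRNARead],
    tss: int,
    gene: GeneModel,
    max_offset: int = 200,
    tss_gate: int = DEFAULT_TSS_GATE,
) -> PauseProfile | None:
    """Histogram sense 3'-end offsets in [1, max_offset] downstream of tss.

    Only reads whose 5' end lies within +-``tss_gate`` nt of ``tss``
    contribute, so pause offsets are measured from the called start site.
    Returns None when no read qualifies.
    """
    if max_offset <= 0:
        raise ValueError("max_offset must be > 0")
    counts = np.zeros(max_offset, dtype=int)
    for r in _sense_reads(reads, gene):
        if abs(gene.to_offset(r.five_prime, anchor=tss)) > tss_gate:
            continue
        off = gene.to_offset(r.three_prime, anchor=tss)
        if 1 <= off <= max_offset:
            counts[off - 1] += 1
    if counts.sum() == 0:
        return None
    return PauseProfile(
        gene_id=gene.gene_id, offsets=np.arange(1, max_offset + 1), counts=counts
    )


def length_distribution(reads: Sequence[ScRNARead]) -> dict[int, int]:
    """Histogram of scRNA lengths (5'-to-3' end distances, nt)."""
    if not reads:
        raise ValueError("reads must be non-empty")
    return dict(sorted(Counter(r.length for r in reads).items()))


@dataclass
class RecenterResult:
    """Annotated- vs. scRNA-centered 5'-end metagene profiles (1-bp bins)."""

    offsets: np.ndarray
    annotated_profile: np.ndarray
    recentered_profile: np.ndarray
    annotated_sharpness: float
    recentered_sharpness: float
    n_genes: int


def recenter_profiles(
    reads_by_gene: Mapping[str, Sequence[ScRNARead]],
    genes: Mapping[str, GeneModel],
    calls: Sequence[TSSCall],
    window: int = 500,
    sharp_halfwidth: int = 2,
) -> RecenterResult:
    """Compare metagene 5'-end profiles before and after TSS re-centering.

    For each gene, sense 5'-end offsets are histogrammed (1-bp bins) around
    the annotated TSS and around the scRNA-called TSS; per-gene profiles
    are averaged across genes.  Sharpness is the fraction of in-window
    5'-end signal within +-``sharp_halfwidth`` nt of the center; restoring
    the true start sites sharpens the profile whenever annotations are off.
    """
    call_by_gene = {c.gene_id: c for c in calls}
    missing = set(reads_by_gene) - set(call_by_gene)
    if missing:
        raise ValueError(f"genes without a TSS call: {sorted(missing)}")
    missing = set(reads_by_gene) - set(genes)
    if missing:
        raise ValueError(f"unknown gene ids: {sorted(missing)}")
    size = 2 * window + 1
    ann = np.zeros(size)
    rec = np.zeros(size)
    n_genes = 0
    for gid, reads in reads_by_gene.items():
        gene = genes[gid]
        call = call_by_gene[gid]
        ga = np.zeros(size)
        gr = np.zeros(size)
        for r in _sense_reads(reads, gene):
            off_a = gene.to_offset(r.five_prime)
            off_r = gene.to_offset(r.five_prime, anchor=call.scrna_tss)
            if -window <= off_a <= window:
                ga[off_a + window] += 1
            if -window <= off_r <= window:
                gr[off_r + window] += 1
        if ga.sum() == 0 and gr.sum() == 0:
            continue
        ann += ga
        rec += gr
        n_genes += 1
    if n_genes == 0:
        raise ValueError("no gene contributed any in-window 5' end")
    offsets = np.arange(-window, window + 1)
    core = slice(window - sharp_halfwidth, window + sharp_halfwidth + 1)

    def _sharp(p: np.ndarray) -> float:
        tot = p.sum()
        return float(p[core].sum() / tot) if tot > 0 else 0.0

    return RecenterResult(
        offsets=offsets,
        annotated_profile=ann / n_genes,
        recentered_profile=rec / n_genes,
        annotated_sharpness=_sharp(ann),
        recentered_sharpness=_sharp(rec),
        n_genes=n_genes,
    )


def sequence_window_frequencies(
    sequences: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position base frequencies and information content for aligned windows.

    Returns a 4 x L frequency matrix (rows A, C, G, T; columns normalized
    over non-N counts) and the per-column information content in bits,
    IC = 2 + sum_b f_b log2 f_b, which is 0 for a uniform column and 2 for
    a fixed base.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("all sequences must have equal length")
    arr = np.array([list(s.upper()) for s in sequences])
    bad = ~np.isin(arr, list("ACGTN"))
    if bad.any():
        raise ValueError("sequences must be over the ACGTN alphabet")
    freqs = np.zeros((4, L))
    for i, base in enumerate("ACGT"):
        freqs[i] = (arr == base).sum(axis=0)
    totals = freqs.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a column contains only N")
    freqs /= totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return freqs, np.clip(ic, 0.0, 2.0)


@dataclass
class AntisenseProfile:
    """Upstream antisense 3'-end histogram and its signal-weighted center."""

    upstream_offsets: np.ndarray  # positive nt upstream of the TSS
    counts: np.ndarray
    center: float  # signal-weighted mean, positive nt upstream

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


def antisense_profile(
    reads: Sequence[ScRNARead],
    tss: int,
    gene: GeneModel,
    window: int = 500,
) -> AntisenseProfile | None:
    """Profile divergent-transcription 3' ends upstream of the TSS.

    Considers reads antisense to the gene whose 3' ends fall within
    ``window`` nt upstream of ``tss``; the center is the signal-weighted
    mean upstream distance.  Returns None when no antisense read qualifies.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    counts = np.zeros(window, dtype=int)
    for r in reads:
        if r.chrom != gene.chrom or r.strand == gene.strand:
            continue
        upstream = -gene.to_offset(r.three_prime, anchor=tss)
        if 1 <= upstream <= window:
            counts[upstream - 1] += 1
    if counts.sum() == 0:
        return None
    offsets = np.arange(1, window + 1)
    center = float(np.average(offsets, weights=counts))
    return AntisenseProfile(upstream_offsets=offsets, counts=counts, center=center)
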