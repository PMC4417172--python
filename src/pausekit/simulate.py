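"""Synthetic inputs for every stage of the pausing pipeline.

Each generator emulates one data type the analyses consume, with the
statistical structure reported for promoter-proximal Pol II pausing in
MCF-7 cells:

* short capped RNAs whose 5' ends cluster at the TSS with initiator-like
  jitter and whose 3' ends sit 33-35 nt downstream (the pause), plus broad
  antisense transcription centered ~150 nt upstream;
* paired-end ChIP fragments whose centers form twin promoter peaks, via a
  sonication shear-bias model around the paused-polymerase footprint;
* permanganate lane profiles responding linearly to the unpaired-DNA
  (transcription-bubble) fraction;
* exponential loss of pausing signal after triptolide blocks initiation;
* a two-state (vacant/paused) gene-copy simulator for occupancy checks.

All generators are bit-reproducible under a fixed integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    SCRNA_MAX_LEN,
    SCRNA_MIN_LEN,
    ChIPFragment,
    DecaySeries,
    GeneModel,
    LaneProfile,
    ScRNARead,
)

MAX_REDRAWS = 1000

# discrete distribution: either an explicit pmf {value: prob} or a
# ("normal", {"mean": m, "sd": s, "min": lo}) spec rounded to integers
DistSpec = Mapping[int, float] | tuple


def _check_pmf(dist: Mapping[int, float], name: str) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {total})")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative mass")


def sample_discrete(rng: np.random.Generator, dist: DistSpec, size: int) -> np.ndarray:
    """Draw integers from a pmf dict or a truncated rounded-normal spec."""
    if isinstance(dist, Mapping):
        vals = np.array(sorted(dist), dtype=int)
        probs = np.array([dist[v] for v in vals], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(vals, size=size, p=probs)
    kind, par = dist
    if kind != "normal":
        raise ValueError(f"unknown distribution kind {kind!r}")
    draws = np.rint(rng.normal(par["mean"], par["sd"], size=size)).astype(int)
    lo = int(par.get("min", 1))
    return np.maximum(draws, lo)


def _dist_max(dist: DistSpec) -> int:
    if isinstance(dist, Mapping):
        return max(dist)
    _, par = dist
    # practical upper bound for the truncated normal: mean + 6 sd
    return int(par["mean"] + 6 * par["sd"])


@dataclass
class KineticParams:
    """Kinetic and positional parameters of the scRNA generator.

    k_init is initiation events per gene copy per minute; t_half the pause
    half-life in minutes (pause-exit rate k_off = ln2 / t_half).  The
    positional distributions are over TSS-relative nt offsets.
    """

    k_init: float = 0.05
    t_half: float = 10.0
    pause_offset_dist: Mapping[int, float] = field(
        default_factory=lambda: {33: 1 / 3, 34: 1 / 3, 35: 1 / 3}
    )
    tss_jitter_dist: Mapping[int, float] = field(
        default_factory=lambda: {-2: 0.05, -1: 0.15, 0: 0.60, 1: 0.15, 2: 0.05}
    )
    antisense_center: float = 150.0
    antisense_spread: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_init <= 0:
            raise ValueError("k_init must be > 0")
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")
        if self.antisense_center <= 0:
            raise ValueError("antisense_center must be > 0")
        _check_pmf(self.pause_offset_dist, "pause_offset_dist")
        _check_pmf(self.tss_jitter_dist, "tss_jitter_dist")

    @property
    def k_off(self) -> float:
        return math.log(2) / self.t_half


@dataclass
class ShearBiasParams:
    """Sonication model around the paused-polymerase footprint.

    ``mechanistic`` mode encodes the hypothesis that sonication breakage is
    disfavored within the footprint protected by the paused complex:
    shear ends pile up at the footprint edges ``footprint_center +-
    footprint_halfwidth``, and the immunoprecipitation recovers the DNA
    pieces crosslinked to the complex — the fragment abutting the upstream
    edge, the fragment abutting the downstream edge (together weight
    ``1 - span_weight``, split evenly), or, with weight ``span_weight``,
    a piece spanning the whole protected footprint.  No fragment endpoint
    ever falls strictly inside the footprint, and the fragment-center
    profile is bimodal, straddling the footprint.  ``empirical`` mode
    instead draws fragment centers directly from a two-component Gaussian
    location mixture (the observed twin-peak geometry around the TSS and
    +110 nt).
    """

    footprint_center: int = 34
    footprint_halfwidth: int = 14
    fragment_length_dist: DistSpec = ("normal", {"mean": 200, "sd": 50, "min": 50})
    mode: str = "empirical"
    mixture_centers: Sequence[float] = (0.0, 110.0)
    mixture_sds: Sequence[float] = (20.0, 20.0)
    mixture_weights: Sequence[float] = (0.5, 0.5)
    span_weight: float = 0.2
    region_halfwidth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.footprint_halfwidth < 0:
            raise ValueError("footprint_halfwidth must be >= 0")
        if self.mode not in ("mechanistic", "empirical"):
            raise ValueError("mode must be 'mechanistic' or 'empirical'")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 <= self.span_weight < 1.0:
            raise ValueError("span_weight must be in [0, 1)")
        if len(self.mixture_centers) != len(self.mixture_sds) or len(
            self.mixture_centers
        ) != len(self.mixture_weights):
            raise ValueError("mixture component lists must align")


def generate_scrna_reads(
    genes: Sequence[GeneModel],
    params: KineticParams,
    n_reads_per_gene: int,
    antisense_fraction: float = 0.0,
    max_redraws: int = MAX_REDRAWS,
) -> list[ScRNARead]:
    """Simulate paired-end short capped RNAs for each gene.

    Sense reads initiate at ``true_tss`` plus jitter and terminate at the
    pause offset; a binomial ``antisense_fraction`` of reads instead come
    from divergent transcription, with 3' ends Gaussian around
    ``antisense_center`` nt upstream of the TSS.  Draws whose length falls
    outside the gel window [18, 120] nt (or < 1) are redrawn, at most
    ``max_redraws`` times per read before erroring.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_reads_per_gene <= 0:
        raise ValueError("n_reads_per_gene must be > 0")
    if not 0.0 <= antisense_fraction <= 1.0:
        raise ValueError("antisense_fraction must be in [0, 1]")
    rng = np.random.default_rng(params.seed)
    reads: list[ScRNARead] = []
    for gene in genes:
        n_anti = int(rng.binomial(n_reads_per_gene, antisense_fraction))
        n_sense = n_reads_per_gene - n_anti
        reads.extend(_sense_reads(rng, gene, params, n_sense, max_redraws))
        reads.extend(_antisense_reads(rng, gene, params, n_anti, max_redraws))
    return reads


def _rejection_fill(rng, n, draw, accept, max_redraws, what):
    """Vectorized rejection sampling: redraw failed slots up to the cap."""
    out = draw(n)
    bad = ~accept(out)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > max_redraws:
            raise RuntimeError(
                f"exceeded {max_redraws} redraws generating {what}; "
                "check the offset distributions"
            )
        redraw = draw(int(bad.sum()))
        out = _scatter(out, bad, redraw)
        bad = ~accept(out)
    return out


def _scatter(base: np.ndarray, mask: np.ndarray, new: np.ndarray) -> np.ndarray:
    out = base.copy()
    out[mask] = new
    return out


def _sense_reads(rng, gene, params, n, max_redraws) -> list[ScRNARead]:
    if n == 0:
        return []
    pairs = _rejection_fill(
        rng,
        n,
        lambda k: np.column_stack(
            [
                sample_discrete(rng, params.tss_jitter_dist, k),
                sample_discrete(rng, params.pause_offset_dist, k),
            ]
        ),
        lambda p: (p[:, 1] - p[:, 0] >= max(1, SCRNA_MIN_LEN))
        & (p[:, 1] - p[:, 0] <= SCRNA_MAX_LEN),
        max_redraws,
        "sense scRNA reads",
    )
    anchor = gene.true_tss
    return [
        ScRNARead(
            gene.chrom,
            gene.strand,
            gene.from_offset(int(j), anchor=anchor),
            gene.from_offset(int(p), anchor=anchor),
        )
        for j, p in pairs
    ]


def _antisense_reads(rng, gene, params, n, max_redraws) -> list[ScRNARead]:
    """Divergent reads: opposite strand, 3' ends upstream of the gene TSS."""
    if n == 0:
        return []
    centers = _rejection_fill(
        rng,
        n,
        lambda k: np.rint(
            rng.normal(params.antisense_center, params.antisense_spread, size=k)
        ).astype(int),
        lambda c: c >= 1,
        max_redraws,
        "antisense 3'-end offsets",
    )
    lengths = _rejection_fill(
        rng,
        n,
        lambda k: sample_discrete(rng, params.pause_offset_dist, k),
        lambda L: (L >= SCRNA_MIN_LEN) & (L <= SCRNA_MAX_LEN),
        max_redraws,
        "antisense read lengths",
    )
    anti_strand = "-" if gene.strand == "+" else "+"
    anchor = gene.true_tss
    reads = []
    for c, L in zip(centers, lengths):
        three = gene.from_offset(-int(c), anchor=anchor)  # upstream of TSS
        # the antisense 5' end lies further toward the gene (its own TSS)
        five = three + (int(L) if gene.strand == "+" else -int(L))
        reads.append(ScRNARead(gene.chrom, anti_strand, five, three))
    return reads


def generate_chip_fragments(
    genes: Sequence[GeneModel],
    shear: ShearBiasParams,
    n_frags_per_gene: int,
) -> list[ChIPFragment]:
    """Simulate paired-end Pol II ChIP fragments around each promoter.

    Empirical mode draws fragment centers from the configured location
    mixture (TSS-relative, strand-aware).  Mechanistic mode draws shear
    breakpoints uniformly over ``+- region_halfwidth`` with breakpoints
    relocating to the nearest footprint edge, so no fragment endpoint falls
    strictly inside the protected footprint.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    if n_frags_per_gene <= 0:
        raise ValueError("n_frags_per_gene must be > 0")
    rng = np.random.default_rng(shear.seed)
    frags: list[ChIPFragment] = []
    for gene in genes:
        if shear.mode == "empirical":
            offs, lens = _empirical_fragments(rng, shear, n_frags_per_gene)
        else:
            offs, lens = _mechanistic_fragments(rng, shear, n_frags_per_gene)
        for c, L in zip(offs, lens):
            center = gene.from_offset(int(c), anchor=gene.true_tss)
            start = center - int(L) // 2
            frags.append(ChIPFragment(gene.chrom, start, start + int(L)))
    return frags


def _empirical_fragments(rng, shear, n):
    comp = rng.choice(
        len(shear.mixture_weights), size=n, p=np.asarray(shear.mixture_weights)
    )
    centers = np.rint(
        rng.normal(
            np.asarray(shear.mixture_centers)[comp],
            np.asarray(shear.mixture_sds)[comp],
        )
    ).astype(int)
    lengths = sample_discrete(rng, shear.fragment_length_dist, n)
    return centers, lengths


def _mechanistic_fragments(rng, shear, n):
    lo = shear.footprint_center - shear.footprint_halfwidth
    hi = shear.footprint_center + shear.footprint_halfwidth
    width = hi - lo
    if width > _dist_max(shear.fragment_length_dist):
        raise ValueError(
            "protected footprint wider than any fragment: no fragment can "
            "span it, so no valid fragments exist in mechanistic mode"
        )
    lengths = sample_discrete(rng, shear.fragment_length_dist, n)
    # which crosslinked piece each draw recovers: upstream-abutting,
    # downstream-abutting, or footprint-spanning
    u = rng.random(n)
    side_w = (1.0 - shear.span_weight) / 2.0
    starts = np.empty(n, dtype=int)
    ends = np.empty(n, dtype=int)
    up = u < side_w
    down = (u >= side_w) & (u < 2 * side_w)
    span = ~(up | down)
    # shear ends pile at the footprint edges; flanking pieces abut them
    ends[up] = lo
    starts[up] = lo - lengths[up]
    starts[down] = hi
    ends[down] = hi + lengths[down]
    if np.any(span):
        span_len = _rejection_fill(
            rng,
            int(span.sum()),
            lambda k: sample_discrete(rng, shear.fragment_length_dist, k),
            lambda L: L >= max(width, 1),
            MAX_REDRAWS,
            "footprint-spanning fragments",
        )
        overhang = rng.integers(0, span_len - width + 1)
        starts[span] = lo - overhang
        ends[span] = starts[span] + span_len
        lengths[span] = span_len
    centers = (starts + ends) // 2
    return centers, ends - starts


def generate_lane_profile(
    region_start: int,
    region_end: int,
    sequence: str,
    bubble_interval: tuple[int, int],
    bubble_fraction: float,
    background: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    gain: float = 10.0,
    noise_model: str = "additive",
) -> LaneProfile:
    """Simulate a permanganate footprinting lane.

    Thymine positions inside ``bubble_interval`` (closed, TSS-relative)
    respond linearly to the unpaired-DNA fraction: expected intensity
    ``background + gain * bubble_fraction``; every other position stays at
    ``background``.  Gaussian noise (additive or multiplicative) is
    truncated at zero.
    """
    if not 0.0 <= bubble_fraction <= 1.0:
        raise ValueError("bubble_fraction must be in [0, 1]")
    offsets = np.arange(region_start, region_end)
    if len(sequence) != len(offsets):
        raise ValueError("sequence length must match the region")
    a, b = bubble_interval
    if a < region_start or b >= region_end or a > b:
        raise ValueError("region must cover bubble_interval")
    seq = np.frombuffer(sequence.upper().encode(), dtype="S1")
    is_t = seq == b"T"
    in_bubble = (offsets >= a) & (offsets <= b)
    expected = np.full(offsets.shape, float(background))
    expected[is_t & in_bubble] += gain * bubble_fraction
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise_model == "additive":
            intensities = expected + rng.normal(0.0, noise_sd, size=expected.shape)
        elif noise_model == "multiplicative":
            intensities = expected * (
                1.0 + rng.normal(0.0, noise_sd, size=expected.shape)
            )
        else:
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")
        intensities = np.maximum(intensities, 0.0)
    else:
        intensities = expected
    return LaneProfile(offsets, intensities, is_t)


def generate_decay_series(
    t_half: float,
    times: Sequence[float],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_model: str = "multiplicative",
) -> DecaySeries:
    """Simulate loss of pausing signal after an initiation block.

    Expected reactivity at time t is 2**(-t / t_half) relative to t = 0.
    Noise is Gaussian, multiplicative (relative sd) or additive, truncated
    at zero.
    """
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if 0.0 not in times:
        raise ValueError("times must include 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    expected = 2.0 ** (-times / t_half)
    rng = np.random.default_rng(seed)
    values = np.tile(expected, (n_replicates, 1))
    if noise_sd > 0:
        if noise_model == "multiplicative":
            values = values * (1.0 + rng.normal(0.0, noise_sd, size=values.shape))
        elif noise_model == "additive":
            values = values + rng.normal(0.0, noise_sd, size=values.shape)
        else:
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")
        values = np.maximum(values, 0.0)
    return DecaySeries(times=times, replicate_values=values, normalized=False)


def generate_gene_table(
    n_genes: int,
    enrichment_dist: tuple = ("lognormal", {"mean": 1.0, "sigma": 1.0}),
    seed: int = 0,
) -> pd.DataFrame:
    """Table of (gene_id, promoter_enrichment_score) with unique ids.

    ``enrichment_dist`` is ("lognormal", {mean, sigma}) on the log scale or
    ("point", {"value": v}); scores are strictly positive.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    rng = np.random.default_rng(seed)
    kind, par = enrichment_dist
    if kind == "lognormal":
        scores = rng.lognormal(par["mean"], par["sigma"], size=n_genes)
    elif kind == "point":
        scores = np.full(n_genes, float(par["value"]))
        if scores[0] <= 0:
            raise ValueError("point-mass score must be > 0")
    else:
        raise ValueError(f"unknown enrichment distribution {kind!r}")
    width = len(str(n_genes))
    ids = [f"gene{str(i).zfill(width)}" for i in range(n_genes)]
    return pd.DataFrame(
        {"gene_id": ids, "promoter_enrichment_score": scores}
    )


def simulate_two_state_occupancy(
    k_init: float,
    t_half: float,
    n_copies: int = 10_000,
    seed: int = 0,
    relaxation_multiples: float = 10.0,
) -> float:
    """Monte-Carlo paused fraction of a vacant<->paused gene-copy ensemble.

    Each gene copy gains a paused polymerase at rate ``k_init`` and loses it
    at ``k_off = ln2 / t_half`` (Gillespie per copy).  Copies start vacant
    and are sampled after ``relaxation_multiples`` relaxation times
    1 / (k_init + k_off), close to stationarity; the closed-form stationary
    fraction is k_init / (k_init + k_off).
    """
    if k_init <= 0 or t_half <= 0:
        raise ValueError("k_init and t_half must be > 0")
    k_off = math.log(2) / t_half
    t_end = relaxation_multiples / (k_init + k_off)
    rng = np.random.default_rng(seed)
    t = np.zeros(n_copies)
    paused = np.zeros(n_copies, dtype=bool)
    active = np.ones(n_copies, dtype=bool)
    while np.any(active):
        rates = np.where(paused, k_off, k_init)
        waits = rng.exponential(1.0 / rates[active])
        t_new = t[active] + waits
        flip = t_new <= t_end
        idx = np.flatnonzero(active)
        t[idx] = np.minimum(t_new, t_end)
        paused[idx[flip]] = ~paused[idx[flip]]
        active[idx[~flip]] = False
    return float(paused.mean())


def make_gene_panel(
    n_genes: int,
    chrom: str = "chrSim",
    spacing: int = 100_000,
    tss_shift_dist: Mapping[int, float] | None = None,
    seed: int = 0,
    start: int = 50_000,
) -> list[GeneModel]:
    """Evenly spaced synthetic genes, alternating strands.

    ``tss_shift_dist`` (pmf over nt) offsets each gene's true TSS from its
    annotation, to exercise scRNA-based re-centering.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        tss = start + i * spacing
        shift = 0
        if tss_shift_dist is not None:
            shift = int(sample_discrete(rng, tss_shift_dist, 1)[0])
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                strand=strand,
                annotated_tss=tss,
                true_tss=tss + shift * (1 if strand == "+" else -1),
            )
        )
    return genes
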