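"""Readers and writers for the plain-text interchange formats.

scRNA reads and ChIP fragments travel as 10-column BEDPE-like TSV
(chrom, start1, end1, chrom, start2, end2, name, score, strand1, strand2)
or as 6-column BED of the whole molecule; gene models as BED6; lane
profiles, decay series, calibration series and gene score tables as
headered TSV.  All coordinates are 0-based half-open on disk.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import ChIPFragment, DecaySeries, GeneModel, LaneProfile, ScRNARead

BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def write_scrna_bedpe(reads: Sequence[ScRNARead], path: str | Path) -> None:
    """BEDPE with mate 1 = the 5' (capped) end, mate 2 = the 3' end."""
    rows = []
    for i, r in enumerate(reads):
        rows.append(
            (
                r.chrom, r.five_prime, r.five_prime + 1,
                r.chrom, r.three_prime, r.three_prime + 1,
                f"scrna{i}", r.length, r.strand, r.strand,
            )
        )
    pd.DataFrame(rows, columns=BEDPE_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_scrna_bedpe(path: str | Path) -> list[ScRNARead]:
    df = pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLS)
    return [
        ScRNARead(
            chrom=row.chrom1,
            strand=row.strand1,
            five_prime=int(row.start1),
            three_prime=int(row.start2),
        )
        for row in df.itertuples()
    ]


def write_scrna_bed(reads: Sequence[ScRNARead], path: str | Path) -> None:
    """BED6 of whole scRNA molecules (5'..3' span, strand-aware)."""
    rows = []
    for i, r in enumerate(reads):
        lo = min(r.five_prime, r.three_prime)
        hi = max(r.five_prime, r.three_prime) + 1
        rows.append((r.chrom, lo, hi, f"scrna{i}", r.length, r.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_fragments_bed(frags: Sequence[ChIPFragment], path: str | Path) -> None:
    rows = [
        (f.chrom, f.start, f.end, f"frag{i}", 0, ".") for i, f in enumerate(frags)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path: str | Path) -> list[ChIPFragment]:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2])
    return [
        ChIPFragment(chrom=row[1], start=int(row[2]), end=int(row[3]))
        for row in df.itertuples()
    ]


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """BED6; thickStart-free convention: the TSS is the strand-aware 5' end."""
    rows = []
    for g in genes:
        rows.append((g.chrom, g.annotated_tss, g.annotated_tss + 1, g.gene_id, 0, g.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None)
    return [
        GeneModel(
            gene_id=str(row[4]),
            chrom=row[1],
            strand=row[6],
            annotated_tss=int(row[2]),
        )
        for row in df.itertuples()
    ]


def write_lane_tsv(lane: LaneProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "offset": lane.offsets,
            "intensity": lane.intensities,
            "is_thymine": lane.is_thymine.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_lane_tsv(path: str | Path) -> LaneProfile:
    df = pd.read_csv(path, sep="\t")
    return LaneProfile(
        offsets=df["offset"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        is_thymine=df["is_thymine"].to_numpy().astype(bool),
    )


def write_decay_tsv(series: DecaySeries, path: str | Path) -> None:
    rows = []
    for rep in range(series.n_replicates):
        for j, t in enumerate(series.times):
            rows.append((t, rep, series.replicate_values[rep, j]))
    pd.DataFrame(rows, columns=["time_min", "replicate", "reactivity"]).to_csv(
        path, sep="\t", index=False
    )


def read_decay_tsv(path: str | Path, normalized: bool = False) -> DecaySeries:
    df = pd.read_csv(path, sep="\t")
    times = np.sort(df["time_min"].unique())
    reps = np.sort(df["replicate"].unique())
    values = np.empty((len(reps), len(times)))
    for i, rep in enumerate(reps):
        sub = df[df["replicate"] == rep].set_index("time_min")
        values[i] = sub.loc[times, "reactivity"].to_numpy()
    return DecaySeries(times=times, replicate_values=values, normalized=normalized)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequence windows (e.g. TSS-centered) keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_pwm(freqs: np.ndarray, path: str | Path) -> None:
    """Position-weight-matrix text: one row per base, tab-separated."""
    with open(path, "w") as fh:
        for base, row in zip("ACGT", freqs):
            fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
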