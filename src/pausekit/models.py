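"""Core domain records shared across the pausing pipeline.

Coordinate conventions
----------------------
Genomic intervals are 0-based half-open.  TSS-relative offsets put the TSS
base at offset 0, with positive offsets downstream *in the direction of
transcription*; minus-strand genes are mirrored before any TSS-relative
arithmetic.  A short capped RNA's length is the distance between its 3'- and
5'-end coordinates, so a read initiating at the TSS with its 3' end at
offset +34 has length 34 nt (the field convention that equates scRNA length
with the pause position downstream of the start site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gel size-selection window for short capped RNAs, nt.
SCRNA_MIN_LEN = 18
SCRNA_MAX_LEN = 120


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, and its annotated vs. true start site.

    ``true_tss`` may differ from ``annotated_tss`` to exercise TSS
    re-centering; for real annotations the two coincide.
    """

    gene_id: str
    chrom: str
    strand: str
    annotated_tss: int
    true_tss: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.annotated_tss < 0:
            raise ValueError("annotated_tss must be >= 0")
        if self.true_tss is None:
            object.__setattr__(self, "true_tss", self.annotated_tss)
        elif self.true_tss < 0:
            raise ValueError("true_tss must be >= 0")

    @property
    def direction(self) -> int:
        """+1 on the plus strand, -1 on the minus strand."""
        return 1 if self.strand == "+" else -1

    def to_offset(self, position: int, anchor: int | None = None) -> int:
        """Genomic position -> TSS-relative offset (transcription direction)."""
        a = self.annotated_tss if anchor is None else anchor
        return (position - a) * self.direction

    def from_offset(self, offset: int, anchor: int | None = None) -> int:
        """TSS-relative offset -> genomic position."""
        a = self.annotated_tss if anchor is None else anchor
        return a + offset * self.direction


@dataclass(frozen=True)
class ScRNARead:
    """A short capped RNA as the (5', 3') genomic end pair of one molecule.

    On the plus strand ``five_prime <= three_prime``; on the minus strand the
    inequality flips.  Length is the absolute end-to-end distance in nt.
    """

    chrom: str
    strand: str
    five_prime: int
    three_prime: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.five_prime > self.three_prime:
            raise ValueError("plus-strand read must have five_prime <= three_prime")
        if self.strand == "-" and self.five_prime < self.three_prime:
            raise ValueError("minus-strand read must have five_prime >= three_prime")

    @property
    def length(self) -> int:
        return abs(self.three_prime - self.five_prime)


@dataclass(frozen=True)
class ChIPFragment:
    """One sequenced immunoprecipitated DNA fragment (paired-end)."""

    chrom: str
    start: int
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class LaneProfile:
    """Per-position permanganate band intensities along one gel lane.

    Offsets are TSS-relative; ``is_thymine`` masks the positions where
    permanganate can react (unpaired T bases give signal).
    """

    offsets: np.ndarray
    intensities: np.ndarray
    is_thymine: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.is_thymine = np.asarray(self.is_thymine, dtype=bool)
        if not (len(self.offsets) == len(self.intensities) == len(self.is_thymine)):
            raise ValueError("offsets, intensities and is_thymine must align")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    def intensity_at(self, offset: int) -> float:
        idx = np.flatnonzero(self.offsets == offset)
        if idx.size == 0:
            raise KeyError(f"offset {offset} not in lane")
        return float(self.intensities[idx[0]])


@dataclass
class DecaySeries:
    """Pausing signal vs. time after blocking initiation with triptolide.

    ``replicate_values`` has shape (n_replicates, n_times).  When
    ``normalized`` the replicate mean at t = 0 equals 1.
    """

    times: np.ndarray
    replicate_values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.replicate_values = np.atleast_2d(
            np.asarray(self.replicate_values, dtype=float)
        )
        if self.replicate_values.shape[1] != len(self.times):
            raise ValueError("replicate_values second axis must match times")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if 0.0 not in self.times:
            raise ValueError("times must include 0")
        if np.any(self.replicate_values < 0):
            raise ValueError("values must be nonnegative")
        if self.normalized:
            t0 = float(np.mean(self.replicate_values[:, self.times == 0.0]))
            if abs(t0 - 1.0) > 1e-9:
                raise ValueError("normalized series must have unit mean at t=0")

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[0]
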