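"""Core domain types for transcript-space MeRIP-seq analysis.

All coordinates are 0-based half-open intervals in transcript space
(5'->3'); genome alignment and splicing are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

CONDITIONS = ("parental", "resistant", "resensitized")
SEGMENTS = ("UTR5", "CDS", "UTR3", "noncoding")

RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with an optional 5'UTR/CDS/3'UTR partition.

    ``cds_start``/``cds_end`` are ``None`` for noncoding transcripts, in
    which case every position maps to segment ``"noncoding"``.
    """

    gene_id: str
    transcript_id: str
    length: int
    cds_start: int | None = None
    cds_end: int | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(
                f"{self.transcript_id}: length must be positive, got {self.length}"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(
                f"{self.transcript_id}: cds_start and cds_end must both be set or both be None"
            )
        if self.coding:
            if not 0 <= self.cds_start <= self.cds_end <= self.length:
                raise FormatError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                    f"does not fit in [0, {self.length})"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != {self.length}"
            )

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def utr5(self) -> tuple[int, int] | None:
        return (0, self.cds_start) if self.coding else None

    @property
    def cds(self) -> tuple[int, int] | None:
        return (self.cds_start, self.cds_end) if self.coding else None

    @property
    def utr3(self) -> tuple[int, int] | None:
        return (self.cds_end, self.length) if self.coding else None

    def segment_at(self, position: int) -> str:
        """Segment label of a single transcript position."""
        if not 0 <= position < self.length:
            raise ValueError(
                f"{self.transcript_id}: position {position} outside [0, {self.length})"
            )
        if not self.coding:
            return "noncoding"
        if position < self.cds_start:
            return "UTR5"
        if position < self.cds_end:
            return "CDS"
        return "UTR3"

    def segment_overlaps(self, start: int, end: int) -> dict[str, int]:
        """Nucleotide overlap of interval [start, end) with each segment."""
        if not (0 <= start < end <= self.length):
            raise ValueError(
                f"{self.transcript_id}: interval [{start}, {end}) outside [0, {self.length})"
            )
        if not self.coding:
            return {"noncoding": end - start}
        out = {}
        for name, (s, e) in (
            ("UTR5", self.utr5),
            ("CDS", self.cds),
            ("UTR3", self.utr3),
        ):
            out[name] = max(0, min(end, e) - max(start, s))
        return out


@dataclass
class ReadLibrary:
    """A sequencing library as raw read intervals in transcript space.

    ``reads`` maps transcript_id -> (n, 2) int array of [start, end)
    intervals.  ``total_mapped`` is the library's total mRNA-mapped read
    count used for normalization; it may exceed the number of stored
    reads (stored reads can be a subset).
    """

    sample_id: str
    condition: str
    replicate: int
    assay: str  # "IP" or "input"
    reads: dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("IP", "input"):
            raise ValueError(f"assay must be 'IP' or 'input', got {self.assay!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        n = self.n_reads
        if self.total_mapped == 0 and n > 0:
            self.total_mapped = n
        if self.total_mapped < n:
            raise ValueError(
                f"{self.sample_id}: total_mapped ({self.total_mapped}) < stored reads ({n})"
            )

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads.values())

    def validate_against(self, models: Mapping[str, TranscriptModel]) -> None:
        """Check every read interval fits its transcript."""
        unknown = sorted(set(self.reads) - set(models))
        if unknown:
            raise ValueError(
                f"{self.sample_id}: reads on unknown transcripts: {', '.join(unknown)}"
            )
        for tid, ivals in self.reads.items():
            if len(ivals) == 0:
                continue
            L = models[tid].length
            if (ivals[:, 0] < 0).any() or (ivals[:, 1] > L).any() or (
                ivals[:, 0] >= ivals[:, 1]
            ).any():
                raise ValueError(
                    f"{self.sample_id}: read interval outside [0, {L}) on {tid}"
                )


@dataclass(frozen=True)
class Peak:
    """An IP-enriched interval on one transcript, called in one group."""

    transcript_id: str
    start: int
    end: int
    group: str
    score: float = 0.0
    q_value: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak [{self.start}, {self.end}) on {self.transcript_id}: start >= end"
            )
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class UnionPeak:
    """A maximal disjoint interval of the cross-group peak union."""

    transcript_id: str
    start: int
    end: int
    source_groups: frozenset[str]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("start >= end")
        if not self.source_groups:
            raise ValueError("source_groups must be nonempty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return f"{self.transcript_id}:{self.start}-{self.end}"


@dataclass
class DecayCourse:
    """Actinomycin-D chase CT values for one gene and a reference gene.

    ``ct_target``/``ct_reference`` are (n_timepoints,) or
    (n_timepoints, n_replicates) arrays of qPCR threshold cycles.
    """

    gene_id: str
    timepoints: np.ndarray  # hours, strictly increasing, includes 0
    ct_target: np.ndarray
    ct_reference: np.ndarray
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ct_target = np.asarray(self.ct_target, dtype=float)
        self.ct_reference = np.asarray(self.ct_reference, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must include t=0 as the first point")
        for name, arr in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if arr.shape[0] != len(self.timepoints):
                raise ValueError(f"{name} first axis must match timepoints")

    def mean_ct(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged (target, reference) CT per timepoint."""
        t = self.ct_target if self.ct_target.ndim == 1 else self.ct_target.mean(axis=1)
        r = (
            self.ct_reference
            if self.ct_reference.ndim == 1
            else self.ct_reference.mean(axis=1)
        )
        return t, r


def reads_as_array(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Pack (start, end) pairs into the (n, 2) int64 array ReadLibrary uses."""
    arr = np.asarray(list(intervals), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr
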