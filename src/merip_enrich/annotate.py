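"""Peak annotation: transcript segments, metagene profile, DRACH motifs.

Segment assignment gives each peak the single label (5'UTR / CDS /
3'UTR, or noncoding) with the largest nucleotide overlap, breaking ties
CDS > UTR3 > UTR5 — the convention behind pie-chart segment fractions.
The metagene profile rescales each coding transcript so the 5'UTR, CDS
and 3'UTR each span one unit interval ([0,1), [1,2), [2,3)) and bins
peak midpoints into a density.  The motif scan counts occurrences of
the canonical m6A 5-mers (GGACU, GAACU, AAACU, AGACU by default) or the
degenerate DRACH pattern [GAU][GA]AC[UAC] in peak sequences, counting
overlapping occurrences at every start position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Peak, TranscriptModel, UnionPeak

DEFAULT_MOTIFS = ("GGACU", "GAACU", "AAACU", "AGACU")
DRACH_PATTERN = "[GAU][GA]AC[UAC]"

_TIE_ORDER = {"CDS": 0, "UTR3": 1, "UTR5": 2}


@dataclass(frozen=True)
class SegmentAssignment:
    transcript_id: str
    start: int
    end: int
    segment: str
    overlap_nt: dict


def assign_peak_segment(
    peak: Peak | UnionPeak, model: TranscriptModel
) -> SegmentAssignment:
    """Label a peak with its majority-overlap transcript segment."""
    if peak.transcript_id != model.transcript_id:
        raise ValueError(
            f"peak transcript {peak.transcript_id} != model {model.transcript_id}"
        )
    overlaps = model.segment_overlaps(peak.start, peak.end)
    if not model.coding:
        segment = "noncoding"
    else:
        segment = min(
            overlaps, key=lambda s: (-overlaps[s], _TIE_ORDER[s])
        )
    return SegmentAssignment(peak.transcript_id, peak.start, peak.end, segment, overlaps)


def segment_fractions(
    assignments: Sequence[SegmentAssignment],
) -> pd.DataFrame:
    """Counts and fractions of peaks per segment (fractions sum to 1)."""
    if not assignments:
        raise ValueError("segment_fractions needs at least one assignment")
    counts = pd.Series([a.segment for a in assignments]).value_counts()
    df = pd.DataFrame(
        {
            "segment": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / counts.sum(),
        }
    )
    return df.sort_values("segment").reset_index(drop=True)


def metagene_profile(
    peaks: Sequence[Peak | UnionPeak],
    models: Mapping[str, TranscriptModel],
    bins_per_region: int = 30,
) -> pd.DataFrame:
    """Peak-midpoint density over the tripartite metagene axis [0, 3).

    Only peaks on coding transcripts contribute; a midpoint at fraction
    f of its segment maps to f, 1+f or 2+f for 5'UTR, CDS, 3'UTR.
    Density integrates to 1 over [0, 3).
    """
    coords = []
    for p in peaks:
        m = models[p.transcript_id]
        if not m.coding:
            continue
        mid = (p.start + p.end) / 2.0
        for offset, (s, e) in enumerate((m.utr5, m.cds, m.utr3)):
            if e > s and s <= mid < e:
                coords.append(offset + (mid - s) / (e - s))
                break
        else:
            # midpoint in a zero-length segment boundary; clamp into CDS
            coords.append(1.0 if mid < m.cds_start else 2.0 - 1e-9)
    if not coords:
        raise ValueError("metagene_profile needs at least one peak on a coding transcript")
    edges = np.linspace(0.0, 3.0, 3 * bins_per_region + 1)
    density, _ = np.histogram(coords, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )


def _scan_overlapping(sequence: str, motif: str) -> int:
    """Occurrences of a literal or character-class motif, overlap-permitting."""
    classes = _parse_pattern(motif)
    k = len(classes)
    n = 0
    for i in range(len(sequence) - k + 1):
        if all(sequence[i + j] in cls for j, cls in enumerate(classes)):
            n += 1
    return n


def _parse_pattern(pattern: str) -> list[frozenset]:
    classes = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            classes.append(frozenset(pattern[i + 1 : j]))
            i = j + 1
        else:
            classes.append(frozenset(pattern[i]))
            i += 1
    return classes


def scan_motifs(
    peaks: Sequence[Peak | UnionPeak],
    sequences: Mapping[str, str],
    motifs: Iterable[str] = DEFAULT_MOTIFS,
) -> tuple[pd.DataFrame, float]:
    """Per-peak motif occurrence counts and the fraction of peaks with >= 1.

    ``sequences`` maps transcript_id to RNA sequence (T accepted, mapped
    to U).  Motifs may be literal 5-mers or bracketed character classes
    such as the degenerate DRACH pattern.
    """
    motifs = list(motifs)
    missing = sorted({p.transcript_id for p in peaks} - set(sequences))
    if missing:
        raise ValueError("no sequence for transcripts: " + ", ".join(missing))
    rows = []
    for p in peaks:
        seq = sequences[p.transcript_id].upper().replace("T", "U")
        sub = seq[p.start : p.end]
        counts = {m: _scan_overlapping(sub, m) for m in motifs}
        rows.append(
            {
                "transcript_id": p.transcript_id,
                "start": p.start,
                "end": p.end,
                **counts,
                "total": sum(counts.values()),
            }
        )
    df = pd.DataFrame(rows)
    fraction = float((df["total"] > 0).mean()) if len(df) else 0.0
    return df, fraction
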