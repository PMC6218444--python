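"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
GTF-lite
    Tab-separated GTF dialect in transcript space: the seqname column
    holds the transcript_id, features are ``transcript`` and optional
    ``CDS``, coordinates are GTF-style 1-based inclusive on disk and
    converted to the internal 0-based half-open frame, and attributes
    are limited to ``gene_id``/``transcript_id``.
BED6
    Read intervals and peaks; the chrom column holds the transcript_id.
    The strand column is written ``+`` and ignored on read (transcript
    space is always 5'->3').
FASTA
    Transcript sequences; T and U are accepted interchangeably on read,
    sequences are written on the RNA alphabet (U).
bedGraph
    Per-base fragment coverage, for inspection in a genome browser.
TSV
    All tables, via pandas (UTF-8, '.' decimal, header row).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FormatError, Peak, ReadLibrary, TranscriptModel

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

PEAK_SCORE_CAP = 50.0  # window-ratio value mapped to BED score 1000


# ---------------------------------------------------------------------------
# GTF-lite transcript models
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_transcript_models(path: str | Path) -> dict[str, TranscriptModel]:
    """Load transcript models from a GTF-lite file.

    Returns a dict keyed by transcript_id.  Overlapping or contradictory
    CDS rows raise :class:`FormatError` naming the transcript.
    """
    transcripts: dict[str, dict] = {}
    cds_rows: dict[str, list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            seqname, _src, feature, start, end, _score, _strand, _frame, attrs = fields
            attributes = _parse_attributes(attrs)
            tid = attributes.get("transcript_id", seqname)
            start0, end0 = int(start) - 1, int(end)  # GTF 1-based inclusive
            if feature == "transcript":
                if tid in transcripts:
                    raise FormatError(f"{path}:{lineno}: duplicate transcript {tid}")
                transcripts[tid] = {
                    "gene_id": attributes.get("gene_id", tid),
                    "length": end0 - start0,
                }
            elif feature == "CDS":
                cds_rows.setdefault(tid, []).append((start0, end0))
            # other features ignored
    models: dict[str, TranscriptModel] = {}
    for tid, info in transcripts.items():
        cds_start = cds_end = None
        rows = sorted(cds_rows.get(tid, []))
        if rows:
            # multiple CDS rows must be contiguous pieces of one interval
            for (s1, e1), (s2, e2) in zip(rows, rows[1:]):
                if s2 != e1:
                    raise FormatError(
                        f"transcript {tid}: overlapping or discontiguous CDS rows"
                    )
            cds_start, cds_end = rows[0][0], rows[-1][1]
        try:
            models[tid] = TranscriptModel(
                gene_id=info["gene_id"],
                transcript_id=tid,
                length=info["length"],
                cds_start=cds_start,
                cds_end=cds_end,
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"transcript {tid}: {exc}") from exc
    for tid in cds_rows:
        if tid not in transcripts:
            raise FormatError(f"CDS row for undeclared transcript {tid}")
    return models


def write_transcript_models(
    models: Mapping[str, TranscriptModel], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(models):
            m = models[tid]
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"{tid}\tmerip_enrich\ttranscript\t1\t{m.length}\t.\t+\t.\t{attrs}\n"
            )
            if m.coding:
                fh.write(
                    f"{tid}\tmerip_enrich\tCDS\t{m.cds_start + 1}\t{m.cds_end}"
                    f"\t.\t+\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED6 read libraries and peaks
# ---------------------------------------------------------------------------

def read_read_library(
    path: str | Path,
    *,
    sample_id: str | None = None,
    condition: str = "custom",
    replicate: int = 1,
    assay: str = "input",
    total_mapped: int | None = None,
) -> ReadLibrary:
    """Load a BED6 (or BED3+) file of read intervals into a ReadLibrary.

    ``total_mapped`` defaults to the number of rows when unspecified.
    """
    reads: dict[str, list[tuple[int, int]]] = {}
    n = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            tid, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            reads.setdefault(tid, []).append((start, end))
            n += 1
    arrays = {
        tid: np.asarray(ivals, dtype=np.int64) for tid, ivals in reads.items()
    }
    return ReadLibrary(
        sample_id=sample_id or Path(path).stem,
        condition=condition,
        replicate=replicate,
        assay=assay,
        reads=arrays,
        total_mapped=n if total_mapped is None else total_mapped,
    )


def write_read_library(library: ReadLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample={library.sample_id} condition={library.condition} "
                 f"replicate={library.replicate} assay={library.assay} "
                 f"total_mapped={library.total_mapped}\n")
        for tid in sorted(library.reads):
            for i, (s, e) in enumerate(library.reads[tid]):
                fh.write(f"{tid}\t{s}\t{e}\t{library.sample_id}.{i}\t0\t+\n")


def write_peaks(
    peaks: Sequence[Peak], path: str | Path, score_cap: float = PEAK_SCORE_CAP
) -> None:
    """Write peaks as BED6; score = round(1000 * min(1, score/score_cap))."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# BED6 peaks: transcript_id, start, end, group, scaled_score, strand\n")
        for p in sorted(peaks, key=lambda p: (p.transcript_id, p.start, p.end)):
            bed_score = round(1000 * min(1.0, p.score / score_cap))
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.group}\t{bed_score}\t+\n"
            )


def read_peaks(path: str | Path) -> list[Peak]:
    """Read a peaks BED6 file back; q_value is not carried by the format."""
    peaks = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 BED columns")
            peaks.append(
                Peak(
                    transcript_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    group=fields[3],
                    score=float(fields[4]) if len(fields) > 4 else 0.0,
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# FASTA sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load sequences keyed by record id; DNA T is mapped to RNA U."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(sequences[name].replace("T", "U")), id=name, description="")
        for name in sorted(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_sequences(
    models: Mapping[str, TranscriptModel], sequences: Mapping[str, str]
) -> dict[str, TranscriptModel]:
    """Return models with sequences attached (missing entries left bare)."""
    out = {}
    for tid, m in models.items():
        seq = sequences.get(tid)
        out[tid] = (
            TranscriptModel(
                m.gene_id, m.transcript_id, m.length, m.cds_start, m.cds_end, seq
            )
            if seq is not None
            else m
        )
    return out


# ---------------------------------------------------------------------------
# bedGraph coverage and TSV tables
# ---------------------------------------------------------------------------

def write_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base coverage tracks as run-length bedGraph intervals."""
    with open(path, "w", encoding="utf-8") as fh:
        for tid in sorted(coverage):
            cov = np.asarray(coverage[tid])
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [cov.size]])
            for s, e in zip(starts, ends):
                v = cov[s]
                if v != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{v:g}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, encoding="utf-8")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8", **kwargs)
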