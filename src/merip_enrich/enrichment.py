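"""Union-peak fold-enrichment quantification across conditions.

The core read-count analysis: peaks called in any condition are merged
into a union set so every condition is quantified over identical
regions; raw reads (not fragment-extended) overlapping each union peak
are counted in every IP and input library and normalized to counts per
million mRNA-mapped reads; fold enrichment is computed with two
formulas,

    fe_simple   = a / b
    fe_windowed = (a / c) / (b / d)

where a and b are the normalized IP and input peak counts and c and d
are the per-library medians of 100-bp sliding-window read counts over
the peak-containing gene (a gene-level background correction).
Replicate fold enrichments are averaged per group; cross-group change
per peak is log2(fe_g2) - log2(fe_g1); per-sample summaries are the
mean and median fold enrichment across peaks.

Zeros are handled by a pairwise pseudocount of 0.5 raw-count units
(normalized alongside): when either member of the (a, b) — or (c, d) —
pair is zero, 0.5 is added to both, which keeps the algebraic identity
fe_windowed = fe_simple * (d / c) exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import Peak, ReadLibrary, TranscriptModel, UnionPeak
from .peaks import pair_pseudocount, tile_windows

DEFAULT_WINDOW = 100
DEFAULT_STEP = 50
DEFAULT_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Union peaks
# ---------------------------------------------------------------------------

def union_peaks(peaks_by_group: Mapping[str, Sequence[Peak]]) -> list[UnionPeak]:
    """Merge all groups' peaks into maximal disjoint union intervals.

    A peak called in any group is included; each union interval records
    the set of groups whose peaks overlap it by >= 1 nt.
    """
    by_tid: dict[str, list[tuple[int, int, str]]] = {}
    for group, peaks in peaks_by_group.items():
        for p in peaks:
            by_tid.setdefault(p.transcript_id, []).append((p.start, p.end, group))
    out: list[UnionPeak] = []
    for tid in sorted(by_tid):
        ivals = sorted(by_tid[tid])
        merged: list[list] = []  # [start, end, set(groups)]
        for s, e, g in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].add(g)
            else:
                merged.append([s, e, {g}])
        for s, e, groups in merged:
            out.append(UnionPeak(tid, s, e, frozenset(groups)))
    return out


# ---------------------------------------------------------------------------
# Read counting and normalization
# ---------------------------------------------------------------------------

def count_reads_in_interval(
    library: ReadLibrary, transcript_id: str, start: int, end: int
) -> int:
    """Raw reads overlapping [start, end) by >= 1 nt (no fragment extension)."""
    ivals = library.reads.get(transcript_id)
    if ivals is None or len(ivals) == 0:
        return 0
    return int(np.count_nonzero((ivals[:, 0] < end) & (ivals[:, 1] > start)))


def count_reads_in_peak(library: ReadLibrary, peak: Peak | UnionPeak) -> int:
    return count_reads_in_interval(library, peak.transcript_id, peak.start, peak.end)


def normalize_count(raw: float, total_mapped: int) -> float:
    """Counts-per-million of mRNA-mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive for normalization")
    return raw * 1e6 / total_mapped


def gene_window_stats(
    library: ReadLibrary,
    model: TranscriptModel,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    exclude: tuple[int, int] | None = None,
) -> float:
    """Median raw read count over sliding windows tiled along the gene.

    Windows are [k*step, k*step+window) clipped to the transcript;
    transcripts shorter than ``window`` use one whole-transcript window.
    ``exclude`` optionally drops windows overlapping a region (peak
    exclusion for sensitivity analysis); the median is the mean of the
    two central order statistics for even window counts.
    """
    win = tile_windows(model.length, window, step)
    if exclude is not None:
        keep = (win[:, 1] <= exclude[0]) | (win[:, 0] >= exclude[1])
        if keep.any():  # never drop every window
            win = win[keep]
    ivals = library.reads.get(model.transcript_id)
    if ivals is None or len(ivals) == 0:
        return 0.0
    starts = np.sort(ivals[:, 0])
    ends = np.sort(ivals[:, 1])
    n = len(ivals)
    # reads overlapping [s, e) = n - (#reads ending <= s) - (#reads starting >= e)
    counts = (
        n
        - np.searchsorted(ends, win[:, 0], side="right")
        - (n - np.searchsorted(starts, win[:, 1], side="left"))
    )
    return float(np.median(counts))


# ---------------------------------------------------------------------------
# Fold-enrichment formulas
# ---------------------------------------------------------------------------

def fold_enrichment_simple(
    a: float, b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """fe = a/b with the pairwise zero pseudocount."""
    a, b = pair_pseudocount(a, b, pseudocount)
    return a / b


def fold_enrichment_windowed(
    a: float, b: float, c: float, d: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """fe = (a/c)/(b/d) with the pairwise zero pseudocount on both pairs."""
    a, b = pair_pseudocount(a, b, pseudocount)
    c, d = pair_pseudocount(c, d, pseudocount)
    return (a / c) / (b / d)


def replicate_mean(values: Iterable[float]) -> float:
    """Arithmetic mean over replicates; rejects an empty collection."""
    vals = list(values)
    if not vals:
        raise ValueError("replicate_mean needs at least one value")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Per-peak, per-sample quantification
# ---------------------------------------------------------------------------

@dataclass
class QuantificationParams:
    window: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    exclude_peak_background: bool = False


def quantify_enrichment(
    peaks: Sequence[UnionPeak],
    libraries: Sequence[ReadLibrary],
    models: Mapping[str, TranscriptModel],
    params: QuantificationParams | None = None,
) -> pd.DataFrame:
    """Per-(union peak, IP/input sample pair) enrichment records.

    Libraries are paired by (condition, replicate); each pair yields one
    record per peak with normalized a, b, c, d (post-pseudocount CPM)
    and both fold-enrichment values.
    """
    params = params or QuantificationParams()
    pairs: dict[tuple[str, int], dict[str, ReadLibrary]] = {}
    for lib in libraries:
        pairs.setdefault((lib.condition, lib.replicate), {})[lib.assay] = lib
    incomplete = [k for k, v in pairs.items() if set(v) != {"IP", "input"}]
    if incomplete:
        raise ValueError(f"unpaired libraries for: {incomplete}")

    # per-library gene-background medians are shared across peaks on a gene
    rows = []
    for (cond, rep), pair in sorted(pairs.items()):
        ip, inp = pair["IP"], pair["input"]
        if ip.total_mapped <= 0 or inp.total_mapped <= 0:
            raise ValueError(f"{cond} rep{rep}: zero total_mapped")
        bg_cache: dict[tuple[str, str, tuple | None], float] = {}
        for peak in peaks:
            model = models[peak.transcript_id]
            excl = (peak.start, peak.end) if params.exclude_peak_background else None
            a_raw = float(count_reads_in_peak(ip, peak))
            b_raw = float(count_reads_in_peak(inp, peak))
            key_c = (ip.sample_id, peak.transcript_id, excl)
            key_d = (inp.sample_id, peak.transcript_id, excl)
            if key_c not in bg_cache:
                bg_cache[key_c] = gene_window_stats(
                    ip, model, params.window, params.step, exclude=excl
                )
            if key_d not in bg_cache:
                bg_cache[key_d] = gene_window_stats(
                    inp, model, params.window, params.step, exclude=excl
                )
            c_raw, d_raw = bg_cache[key_c], bg_cache[key_d]
            a_p, b_p = pair_pseudocount(a_raw, b_raw, params.pseudocount)
            c_p, d_p = pair_pseudocount(c_raw, d_raw, params.pseudocount)
            a = normalize_count(a_p, ip.total_mapped)
            b = normalize_count(b_p, inp.total_mapped)
            c = normalize_count(c_p, ip.total_mapped)
            d = normalize_count(d_p, inp.total_mapped)
            rows.append(
                {
                    "peak": peak.key,
                    "transcript_id": peak.transcript_id,
                    "start": peak.start,
                    "end": peak.end,
                    "condition": cond,
                    "replicate": rep,
                    "sample": f"{cond}_rep{rep}",
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "fe_simple": a / b,
                    "fe_windowed": (a / c) / (b / d),
                }
            )
    return pd.DataFrame(rows)


def group_mean_enrichment(
    records: pd.DataFrame, formula: str = "simple"
) -> pd.DataFrame:
    """Replicate-mean fold enrichment per (peak, condition)."""
    col = {"simple": "fe_simple", "windowed": "fe_windowed"}[formula]
    out = (
        records.groupby(["peak", "transcript_id", "start", "end", "condition"])[col]
        .mean()
        .rename("mean_fe")
        .reset_index()
    )
    out["formula"] = formula
    return out


def cross_group_log2fc(
    group_fe: pd.DataFrame, group1: str, group2: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-peak log2(fe_g2) - log2(fe_g1).

    Returns (delta table, peaks quantified in only one of the groups);
    one-sided peaks are reported, never silently dropped into the delta.
    """
    g1 = group_fe[group_fe["condition"] == group1].set_index("peak")["mean_fe"]
    g2 = group_fe[group_fe["condition"] == group2].set_index("peak")["mean_fe"]
    if (g1 <= 0).any() or (g2 <= 0).any():
        raise ValueError("nonpositive mean fold enrichment")
    common = g1.index.intersection(g2.index)
    delta = pd.DataFrame(
        {
            "peak": common,
            "fe_group1": g1.loc[common].to_numpy(),
            "fe_group2": g2.loc[common].to_numpy(),
            "log2fc": np.log2(g2.loc[common].to_numpy())
            - np.log2(g1.loc[common].to_numpy()),
        }
    )
    only = sorted(g1.index.symmetric_difference(g2.index))
    missing = pd.DataFrame(
        {
            "peak": only,
            "present_in": [group1 if p in g1.index else group2 for p in only],
        }
    )
    return delta, missing


def summarize_enrichment(fe_values: Iterable[float]) -> tuple[float, float]:
    """(mean, median) fold enrichment across peaks for one sample."""
    vals = np.asarray(list(fe_values), dtype=float)
    if vals.size == 0:
        raise ValueError("summarize_enrichment needs at least one value")
    return float(vals.mean()), float(np.median(vals))


def summarize_by_sample(
    records: pd.DataFrame, formula: str = "simple"
) -> pd.DataFrame:
    """Per-sample mean and median fold enrichment across peaks."""
    col = {"simple": "fe_simple", "windowed": "fe_windowed"}[formula]
    rows = []
    for sample, grp in records.groupby("sample"):
        mean, median = summarize_enrichment(grp[col])
        rows.append(
            {
                "sample": sample,
                "condition": grp["condition"].iloc[0],
                "formula": formula,
                "mean_fe": mean,
                "median_fe": median,
                "n_peaks": len(grp),
            }
        )
    return pd.DataFrame(rows)


def log2fc_histogram(
    deltas: Iterable[float], bins: int | Sequence[float] = 40
) -> pd.DataFrame:
    """Histogram of per-peak log2 fold changes as a (bin edges, count) table."""
    vals = np.asarray(list(deltas), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("log2fc_histogram needs at least one finite value")
    counts, edges = np.histogram(vals, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def plot_log2fc_histogram(hist: pd.DataFrame, path) -> None:
    """Render a binned log2 fold-change table as a bar plot (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    widths = hist["bin_right"] - hist["bin_left"]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist["bin_left"], hist["count"], width=widths, align="edge",
           color="#4878a8", edgecolor="white")
    ax.axvline(0.0, color="black", lw=0.8, ls="--")
    ax.set_xlabel("log2 fold change of peak enrichment")
    ax.set_ylabel("peaks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
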