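"""Window-based IP-vs-input peak calling in transcript space.

This is a deliberately simple, documented caller: reads are extended 3'
to the library fragment length, per-position coverage is summed over
replicates, overlapping windows are tiled along each transcript, and
each window's IP count is tested against IP+input with a one-sided
binomial test at the library-size-implied null proportion, with
Benjamini-Hochberg correction across all windows of the run.
Significant windows passing fold and count filters are merged into
peaks.  Downstream quantification re-counts raw reads inside union
peaks, so results there are insensitive to the caller's internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import Peak, ReadLibrary, TranscriptModel


@dataclass
class PeakCallingParams:
    """Tuning knobs of the window test.

    ``fragment_length`` is the 3' extension applied to reads when
    building coverage (default 200, the conventional MeRIP fragment
    size); ``min_fold`` filters on the library-size-normalized IP/input
    ratio; ``max_merge_gap`` is the largest nt gap bridged when merging
    significant windows.
    """

    window: int = 100
    step: int = 50
    fragment_length: int = 200
    min_ip_count: float = 10.0
    fdr: float = 0.05
    min_fold: float = 2.0
    max_merge_gap: int = 0
    pseudocount: float = 0.5

    def validate(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("require 0 < step <= window")
        for name in ("fragment_length", "min_ip_count", "fdr", "min_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fdr > 1:
            raise ValueError("fdr must be <= 1")
        if self.max_merge_gap < 0:
            raise ValueError("max_merge_gap must be >= 0")


def pair_pseudocount(a: float, b: float, pseudocount: float = 0.5) -> tuple[float, float]:
    """Add the pseudocount to BOTH members of a ratio pair when either is 0.

    Keeps ratios finite while leaving fully observed pairs untouched.
    """
    if a == 0 or b == 0:
        return a + pseudocount, b + pseudocount
    return a, b


def tile_windows(length: int, window: int, step: int) -> np.ndarray:
    """(n, 2) window intervals [k*step, k*step+window) clipped to length.

    Transcripts shorter than ``window`` get one whole-transcript window.
    """
    if length <= window:
        return np.array([[0, length]], dtype=np.int64)
    starts = np.arange(0, length, step, dtype=np.int64)
    starts = starts[starts < length]
    ends = np.minimum(starts + window, length)
    return np.column_stack([starts, ends])


def build_coverage(
    library: ReadLibrary,
    models: Mapping[str, TranscriptModel],
    fragment_length: int,
) -> dict[str, np.ndarray]:
    """Per-position fragment coverage: reads extended 3' to fragment_length.

    Extension is clipped at the transcript end.  Transcripts without
    reads get all-zero tracks.
    """
    unknown = sorted(set(library.reads) - set(models))
    if unknown:
        raise ValueError(
            f"{library.sample_id}: reads on transcripts absent from models: "
            + ", ".join(unknown)
        )
    coverage: dict[str, np.ndarray] = {}
    for tid in sorted(models):
        L = models[tid].length
        diff = np.zeros(L + 1, dtype=np.int64)
        ivals = library.reads.get(tid)
        if ivals is not None and len(ivals):
            starts = ivals[:, 0]
            ends = np.minimum(
                np.maximum(ivals[:, 1], starts + fragment_length), L
            )
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        coverage[tid] = np.cumsum(diff[:-1])
    return coverage


def _sum_tracks(tracks: Sequence[Mapping[str, np.ndarray]]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for tr in tracks:
        for tid, cov in tr.items():
            out[tid] = out.get(tid, 0) + cov
    return out


def test_windows(
    ip_coverage: Mapping[str, np.ndarray],
    input_coverage: Mapping[str, np.ndarray],
    lib_sizes: tuple[float, float],
    params: PeakCallingParams,
) -> pd.DataFrame:
    """Per-window counts, normalized ratio and binomial p over all transcripts.

    Window counts a_w (IP) and b_w (input) are the mean per-position
    coverage in the window.  p is the one-sided upper tail of
    Binomial(n = a_w + b_w, p0 = libIP / (libIP + libIN)) at a_w, after
    rounding to integers; the ratio uses the pairwise pseudocount and
    the library-size normalization, never the test.  The q column is
    BH-adjusted across every window of the call.
    """
    params.validate()
    lib_ip, lib_in = lib_sizes
    if lib_ip <= 0 or lib_in <= 0:
        raise ValueError("library sizes must be positive")
    if set(ip_coverage) != set(input_coverage):
        raise ValueError("IP and input coverage must cover the same transcripts")
    p0 = lib_ip / (lib_ip + lib_in)

    rows = []
    for tid in sorted(ip_coverage):
        cov_ip = ip_coverage[tid]
        cov_in = input_coverage[tid]
        win = tile_windows(len(cov_ip), params.window, params.step)
        cum_ip = np.concatenate([[0], np.cumsum(cov_ip)])
        cum_in = np.concatenate([[0], np.cumsum(cov_in)])
        widths = (win[:, 1] - win[:, 0]).astype(float)
        a = (cum_ip[win[:, 1]] - cum_ip[win[:, 0]]) / widths
        b = (cum_in[win[:, 1]] - cum_in[win[:, 0]]) / widths
        for (s, e), aw, bw in zip(win, a, b):
            rows.append((tid, int(s), int(e), aw, bw))
    df = pd.DataFrame(rows, columns=["transcript_id", "start", "end", "a", "b"])
    if df.empty:
        df["ratio"] = df["p"] = df["q"] = []
        return df

    ap, bp = np.asarray(df["a"]), np.asarray(df["b"])
    zero = (ap == 0) | (bp == 0)
    ap = np.where(zero, ap + params.pseudocount, ap)
    bp = np.where(zero, bp + params.pseudocount, bp)
    df["ratio"] = (ap / lib_ip) / (bp / lib_in)

    k = np.rint(df["a"]).astype(np.int64)
    n = k + np.rint(df["b"]).astype(np.int64)
    # upper tail P[X >= k]; k=0 gives p=1 by construction
    df["p"] = stats.binom.sf(k - 1, np.maximum(n, 1), p0)
    df.loc[n == 0, "p"] = 1.0
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def merge_windows(windows: pd.DataFrame, params: PeakCallingParams, group: str = "") -> list[Peak]:
    """Merge significant windows (q, fold and IP-count filters) into peaks.

    Peak score is the max window ratio, peak q the min window q; windows
    are merged when separated by at most ``max_merge_gap`` nt.
    """
    params.validate()
    if windows.empty:
        return []
    sig = windows[
        (windows["q"] <= params.fdr)
        & (windows["ratio"] >= params.min_fold)
        & (windows["a"] >= params.min_ip_count)
    ].sort_values(["transcript_id", "start", "end"])
    peaks: list[Peak] = []
    cur = None  # [tid, start, end, score, q]
    for row in sig.itertuples(index=False):
        if (
            cur is not None
            and row.transcript_id == cur[0]
            and row.start <= cur[2] + params.max_merge_gap
        ):
            cur[2] = max(cur[2], row.end)
            cur[3] = max(cur[3], row.ratio)
            cur[4] = min(cur[4], row.q)
        else:
            if cur is not None:
                peaks.append(Peak(cur[0], cur[1], cur[2], group, cur[3], cur[4]))
            cur = [row.transcript_id, row.start, row.end, row.ratio, row.q]
    if cur is not None:
        peaks.append(Peak(cur[0], cur[1], cur[2], group, cur[3], cur[4]))
    return peaks


def call_peaks(
    ip_libraries: Sequence[ReadLibrary],
    input_libraries: Sequence[ReadLibrary],
    models: Mapping[str, TranscriptModel],
    params: PeakCallingParams | None = None,
    group: str | None = None,
) -> list[Peak]:
    """Call peaks for one condition, summing replicate coverage.

    Library sizes are the summed ``total_mapped`` of the replicates.
    """
    params = params or PeakCallingParams()
    if not ip_libraries or not input_libraries:
        raise ValueError("need at least one IP and one input library")
    group = group if group is not None else ip_libraries[0].condition
    ip_cov = _sum_tracks(
        [build_coverage(l, models, params.fragment_length) for l in ip_libraries]
    )
    in_cov = _sum_tracks(
        [build_coverage(l, models, params.fragment_length) for l in input_libraries]
    )
    lib_ip = float(sum(l.total_mapped for l in ip_libraries))
    lib_in = float(sum(l.total_mapped for l in input_libraries))
    windows = test_windows(ip_cov, in_cov, (lib_ip, lib_in), params)
    return merge_windows(windows, params, group=group)


def call_peaks_by_condition(
    libraries: Sequence[ReadLibrary],
    models: Mapping[str, TranscriptModel],
    params: PeakCallingParams | None = None,
) -> dict[str, list[Peak]]:
    """Group libraries by condition and call peaks in each."""
    conditions = sorted({l.condition for l in libraries})
    out = {}
    for cond in conditions:
        ip = [l for l in libraries if l.condition == cond and l.assay == "IP"]
        inp = [l for l in libraries if l.condition == cond and l.assay == "input"]
        if not ip or not inp:
            raise ValueError(f"condition {cond}: missing IP or input libraries")
        out[cond] = call_peaks(ip, inp, models, params, group=cond)
    return out
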