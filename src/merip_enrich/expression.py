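"""Differential expression and its overlap with m6A-bearing genes.

DE follows the microarray-style criteria: a Welch two-sample t-test per
gene on log2 intensities, with a gene called up (down) when the
linear-scale fold difference between group means is >= 1.5 (<= 1/1.5)
and the t-test p-value is < 0.05.  No multiple-testing correction is
applied by default; BH adjustment is available as an option.  The
overlap step intersects up- and down-regulated gene lists with the set
of genes bearing m6A peaks and reports counts and percentages per
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class OverlapResult:
    """Venn counts of DE genes against an m6A gene set, per direction."""

    n_up: int
    n_down: int
    n_up_m6a: int
    n_down_m6a: int

    @property
    def pct_up(self) -> float:
        return 100.0 * self.n_up_m6a / self.n_up if self.n_up else 0.0

    @property
    def pct_down(self) -> float:
        return 100.0 * self.n_down_m6a / self.n_down if self.n_down else 0.0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "direction": ["up", "down"],
                "n_de": [self.n_up, self.n_down],
                "n_m6a_overlap": [self.n_up_m6a, self.n_down_m6a],
                "pct_overlap": [self.pct_up, self.pct_down],
            }
        )


def differential_expression(
    matrix: pd.DataFrame,
    groups: Mapping[str, str],
    group1: str,
    group2: str,
    alpha: float = 0.05,
    fold: float = 1.5,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t-test and fold-change calls (group2 vs group1).

    ``matrix`` is genes x samples on the log2 scale.  The fold criterion
    is evaluated on the linear scale: ratio of group means of unlogged
    intensities.  Returns gene_id, log2fc, p, call in {up, down, ns}.
    """
    cols1 = [s for s in matrix.columns if groups.get(s) == group1]
    cols2 = [s for s in matrix.columns if groups.get(s) == group2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError("need >= 2 samples per group for the t-test")
    x1 = matrix[cols1].to_numpy(dtype=float)
    x2 = matrix[cols2].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(x2, x1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    if bh_correct:
        p = multipletests(p, method="fdr_bh")[1]
    lin1 = np.exp2(x1).mean(axis=1)
    lin2 = np.exp2(x2).mean(axis=1)
    fc = lin2 / lin1
    call = np.where(
        (fc >= fold) & (p < alpha),
        "up",
        np.where((fc <= 1.0 / fold) & (p < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "log2fc": np.log2(fc),
            "p": p,
            "call": call,
        }
    ).reset_index(drop=True)


def overlap_with_m6a(
    de: pd.DataFrame, m6a_genes: Iterable[str]
) -> OverlapResult:
    """Intersect up/down DE gene lists with the m6A-bearing gene set."""
    m6a = set(m6a_genes)
    up = set(de.loc[de["call"] == "up", "gene_id"])
    down = set(de.loc[de["call"] == "down", "gene_id"])
    return OverlapResult(
        n_up=len(up),
        n_down=len(down),
        n_up_m6a=len(up & m6a),
        n_down_m6a=len(down & m6a),
    )


def overlap_from_counts(
    n_up: int, n_up_m6a: int, n_down: int, n_down_m6a: int
) -> OverlapResult:
    """Overlap summary from pre-tabulated list sizes and intersection counts."""
    if not (0 <= n_up_m6a <= n_up and 0 <= n_down_m6a <= n_down):
        raise ValueError("overlap counts must be within list sizes")
    return OverlapResult(n_up, n_down, n_up_m6a, n_down_m6a)
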