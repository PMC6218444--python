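"""qPCR ΔCT quantification and actinomycin-D mRNA decay kinetics.

Relative expression is 2^-(CT_target - CT_reference) (the ΔCT method
against a stable reference such as GAPDH).  For a transcription-shutoff
(actinomycin-D) time course, the percent of mRNA remaining at time t is
the reference-normalized abundance relative to t = 0.  A first-order
decay model N(t) = N(0) * exp(-k t) is fitted by least squares on
ln(percent) vs t, giving t1/2 = ln 2 / k; a flat course (slope above a
small tolerance of zero) is flagged stable with infinite half-life —
the fit is an extension for summarizing decay-rate comparisons, since
percent-remaining curves themselves are the primary readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import DecayCourse

STABLE_SLOPE_TOL = 1e-3  # per hour; |slope| below this is "no measurable decay"


@dataclass(frozen=True)
class HalfLifeEstimate:
    gene_id: str
    t_half: float          # hours; inf when stable
    decay_rate: float      # per hour
    fit_r2: float


def delta_ct_expression(ct_target: float, ct_reference: float) -> float:
    """Relative expression 2^-(CT_target - CT_reference)."""
    return float(2.0 ** -(np.asarray(ct_target) - np.asarray(ct_reference)))


def percent_remaining(course: DecayCourse) -> np.ndarray:
    """Percent mRNA remaining vs t=0 after reference normalization.

    Replicate CTs at a timepoint are averaged (in CT space) before the
    transformation; the value at t=0 is exactly 100.
    """
    ct_t, ct_r = course.mean_ct()
    dct = ct_t - ct_r
    return 100.0 * 2.0 ** -(dct - dct[0])


def fit_half_life(
    timepoints: np.ndarray,
    percents: np.ndarray,
    gene_id: str = "",
    stable_tol: float = STABLE_SLOPE_TOL,
) -> HalfLifeEstimate:
    """Log-linear least-squares fit of percent-remaining vs time.

    Requires >= 3 timepoints and positive percents.  When the fitted
    slope is >= -stable_tol the transcript is flagged stable
    (infinite t_half, decay_rate 0).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(percents, dtype=float)
    if t.size < 3:
        raise ValueError("need >= 3 timepoints to fit a half-life")
    if np.any(y <= 0):
        raise ValueError("percents must be positive for the log-linear fit")
    res = stats.linregress(t, np.log(y))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    if res.slope >= -stable_tol:
        return HalfLifeEstimate(gene_id, np.inf, 0.0, r2)
    k = -res.slope
    return HalfLifeEstimate(gene_id, float(np.log(2) / k), float(k), r2)


def fit_course(course: DecayCourse, stable_tol: float = STABLE_SLOPE_TOL) -> HalfLifeEstimate:
    """Percent-remaining transform followed by the half-life fit."""
    return fit_half_life(
        course.timepoints, percent_remaining(course), course.gene_id, stable_tol
    )


def loading_normalized_signal(
    signal: float, loading: float, control_signal: float, control_loading: float
) -> float:
    """Fold vs control after loading normalization: (s/l)/(s0/l0).

    The densitometry convention for blots normalized to a loading
    control such as beta-actin.
    """
    if loading <= 0 or control_loading <= 0:
        raise ValueError("loading values must be positive")
    return (signal / loading) / (control_signal / control_loading)
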