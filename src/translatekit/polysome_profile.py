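"""Quantification of digitized polysome absorbance traces.

A polysome profile is an A254 absorbance curve over sucrose-gradient depth.
Two regions are quantified: the sub-polysomal region (40S/60S/80S peaks) and
the polysomal region (first through twelfth polysomal peak).  Areas are
trapezoidal integrals of absorbance above the baseline, where the baseline
is the lowest point of the whole trace.  The polysomal/sub-polysomal area
ratio indexes global translation; replicate ratios are expressed as fold
change over the mean of a reference group and compared between groups with
an exact two-sided Mann-Whitney U test (the conventional nonparametric
two-sample location test).

Region boundaries are user-supplied: peak calling on scanned charts is
deliberately not automated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PolysomeTrace",
    "ProfileQuant",
    "read_trace_csv",
    "trace_auc",
    "profile_ratio",
    "compare_profiles",
]


@dataclass
class PolysomeTrace:
    """Absorbance trace plus the three region boundaries
    (subpoly_start, poly_start, poly_end) in position units."""

    positions: np.ndarray
    absorbance: np.ndarray
    boundaries: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.positions.shape != self.absorbance.shape:
            raise ValueError("positions and absorbance lengths differ")
        if len(self.positions) < 2:
            raise ValueError("need at least 2 trace points")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        a, b, c = self.boundaries
        if not a < b < c:
            raise ValueError("boundaries must satisfy subpoly_start < poly_start < poly_end")
        lo, hi = self.positions[0], self.positions[-1]
        if a < lo or c > hi:
            raise ValueError("boundaries outside the trace span")

    @property
    def baseline(self) -> float:
        """Lowest absorbance over the whole trace (Y-axis lower limit)."""
        return float(self.absorbance.min())


@dataclass
class ProfileQuant:
    auc_subpoly: float
    auc_poly: float
    ratio: float
    fold_change_vs_reference: float | None = None


def read_trace_csv(
    path: str | Path, boundaries: tuple[float, float, float]
) -> PolysomeTrace:
    """Read a position,absorbance CSV into a trace with the given boundaries."""
    df = pd.read_csv(path)
    for col in ("position", "absorbance"):
        if col not in df.columns:
            raise ValueError(f"trace CSV missing column {col!r}")
    return PolysomeTrace(
        positions=df["position"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        boundaries=boundaries,
    )


def trace_auc(trace: PolysomeTrace, region: tuple[float, float]) -> float:
    """Area of (absorbance - global minimum) over a region, trapezoidal.

    Region endpoints falling between samples are linearly interpolated so
    adjacent regions tile exactly.
    """
    lo, hi = region
    if hi <= lo:
        raise ValueError("region must have positive width")
    if lo < trace.positions[0] or hi > trace.positions[-1]:
        raise ValueError("region outside the trace span")
    inside = (trace.positions > lo) & (trace.positions < hi)
    xs = np.concatenate(([lo], trace.positions[inside], [hi]))
    ys = np.interp(xs, trace.positions, trace.absorbance) - trace.baseline
    if len(xs) < 2:
        raise ValueError("fewer than 2 points in region")
    return float(np.trapezoid(ys, xs))


def profile_ratio(trace: PolysomeTrace) -> ProfileQuant:
    """Polysomal area normalized to the sub-polysomal area."""
    subpoly_start, poly_start, poly_end = trace.boundaries
    auc_sub = trace_auc(trace, (subpoly_start, poly_start))
    auc_poly = trace_auc(trace, (poly_start, poly_end))
    if auc_sub <= 0:
        raise ValueError("sub-polysomal area is zero; ratio undefined")
    return ProfileQuant(auc_subpoly=auc_sub, auc_poly=auc_poly, ratio=auc_poly / auc_sub)


def compare_profiles(
    ratios_reference: Sequence[float], ratios_test: Sequence[float]
) -> tuple[np.ndarray, float]:
    """Fold changes of test ratios over the reference mean, plus an exact
    two-sided Mann-Whitney U p-value for the group difference.

    Needs >= 3 replicate ratios per group.  With fully separated groups of
    four replicates each the exact two-sided p is 2/70 ~ 0.0286.
    """
    ref = np.asarray(ratios_reference, dtype=float)
    test = np.asarray(ratios_test, dtype=float)
    if len(ref) < 3 or len(test) < 3:
        raise ValueError("need >= 3 replicate ratios per group")
    ref_mean = ref.mean()
    if ref_mean <= 0:
        raise ValueError("reference mean ratio must be positive")
    fold_changes = test / ref_mean
    res = stats.mannwhitneyu(test, ref, alternative="two-sided", method="exact")
    return fold_changes, float(res.pvalue)
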