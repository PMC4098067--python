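"""Chromatin-compaction phenotype measurements and comparisons.

Implements the measurement conventions used for interphase-distance
FISH and nuclear-size phenotypes: intensity-weighted centroids of probe
signals, Euclidean inter-probe distance converted to nm, percent change
of a mutant's median (or mean) relative to wild type, two-sample tests
(Welch's t for yeast-style data, Mann-Whitney U for human-style data),
and elliptical nuclear cross-sectional area (D1/2)*(D2/2)*pi from the
long and short orthogonal axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from histevo.residue_stats import mann_whitney_u


@dataclass
class LabeledPointCloud:
    """Pixel coordinates of one probe signal with intensity weights."""

    points: np.ndarray  # shape (n, 2)
    weights: np.ndarray  # shape (n,)
    channel: str = "green"
    nm_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights must have equal length")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.weights.sum() <= 0:
            raise ValueError("total weight must be positive")
        if self.nm_per_pixel <= 0:
            raise ValueError("nm_per_pixel must be positive")


@dataclass
class NuclearAxes:
    """Long (d1) and short (d2) orthogonal nuclear axis lengths, um."""

    d1: float
    d2: float

    def __post_init__(self) -> None:
        if not (self.d1 >= self.d2 > 0):
            raise ValueError(f"require d1 >= d2 > 0, got ({self.d1}, {self.d2})")


@dataclass
class PhenotypeComparison:
    wt_n: int
    mut_n: int
    wt_median: float
    mut_median: float
    wt_mean: float
    mut_mean: float
    percent_change: float
    p_value: float
    test: str  # "t_test" or "mann_whitney"
    center: str  # "median" or "mean"


def weighted_centroid(cloud: LabeledPointCloud) -> tuple[float, float]:
    """Intensity-weighted mean position of a probe signal, in pixels."""
    total = cloud.weights.sum()
    x, y = (cloud.points * cloud.weights[:, None]).sum(axis=0) / total
    return float(x), float(y)


def interprobe_distance(green: LabeledPointCloud, red: LabeledPointCloud) -> float:
    """Euclidean distance between probe centroids, converted to nm."""
    if not math.isclose(green.nm_per_pixel, red.nm_per_pixel):
        raise ValueError(
            f"nm_per_pixel mismatch: {green.nm_per_pixel} vs {red.nm_per_pixel}"
        )
    gx, gy = weighted_centroid(green)
    rx, ry = weighted_centroid(red)
    return math.hypot(gx - rx, gy - ry) * green.nm_per_pixel


def percent_change(wt_values: Sequence[float], mut_values: Sequence[float],
                   center: str = "median") -> float:
    """Signed % difference of mutant vs WT center: 100*(mut - wt)/wt."""
    if center not in ("median", "mean"):
        raise ValueError(f"unknown center {center!r}")
    fn = np.median if center == "median" else np.mean
    wt_c = float(fn(np.asarray(wt_values, dtype=float)))
    mut_c = float(fn(np.asarray(mut_values, dtype=float)))
    if wt_c == 0:
        raise ValueError("WT center is zero; percent change undefined")
    return 100.0 * (mut_c - wt_c) / wt_c


def phenotype_test(wt_values: Sequence[float], mut_values: Sequence[float],
                   test: str = "t_test", center: str = "median",
                   ) -> PhenotypeComparison:
    """Compare WT and mutant measurement distributions.

    ``test="t_test"`` runs Welch's two-sided t test; ``"mann_whitney"``
    delegates to :func:`histevo.residue_stats.mann_whitney_u`. Both
    centers are reported; percent change follows ``center``.
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    if wt.size < 2 or mut.size < 2:
        raise ValueError("each sample needs n >= 2")
    if test == "t_test":
        _, p = stats.ttest_ind(wt, mut, equal_var=False)
        p = 1.0 if math.isnan(p) else float(p)
    elif test == "mann_whitney":
        p = mann_whitney_u(wt, mut).p_two_sided
    else:
        raise ValueError(f"unknown test {test!r}")
    return PhenotypeComparison(
        wt_n=wt.size, mut_n=mut.size,
        wt_median=float(np.median(wt)), mut_median=float(np.median(mut)),
        wt_mean=float(wt.mean()), mut_mean=float(mut.mean()),
        percent_change=percent_change(wt, mut, center=center),
        p_value=p, test=test, center=center,
    )


def ellipse_area(axes: NuclearAxes) -> float:
    """Elliptical nuclear cross-sectional area: (d1/2)*(d2/2)*pi, um^2."""
    return (axes.d1 / 2.0) * (axes.d2 / 2.0) * math.pi
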