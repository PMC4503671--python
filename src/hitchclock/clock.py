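"""Molecular-clock regression of cumulative fixed mutations over generations.

Each sweeping genome lineage contributes one data point per acquired
cluster, placed at the generation where that lineage's frequency first
exceeds 10%: the cumulative number of synonymous, non-synonymous and
non-coding mutations it has fixed so far.  An ordinary least-squares line
through those points (including the zero-count baseline) is the clock; its
slope divided by the per-category site count gives the per-site fixation
rate, to be compared with the spontaneous mutation accumulation rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trajectories import ClusterSet, GenomeLineage, classify_fate

__all__ = [
    "FixationPoint",
    "ClockFit",
    "first_exceed_generation",
    "fixation_points",
    "fit_clock",
    "compare_to_spontaneous",
    "BASELINE_GENERATION",
    "SYNONYMOUS_SITES",
    "NONSYNONYMOUS_SITES",
]

#: Generation taken as the zero-count origin of the clock.
BASELINE_GENERATION = 5212
#: Default per-category site counts (bp); no count is used for non-coding.
SYNONYMOUS_SITES = 0.96e6
NONSYNONYMOUS_SITES = 3.2e6


@dataclass
class FixationPoint:
    """Cumulative fixed-mutation counts of one lineage at one generation."""

    generation: int
    counts: dict[str, int]
    lineage_id: Optional[str] = None

    def count(self, category: str) -> int:
        return self.counts.get(category, 0)


@dataclass
class ClockFit:
    """Least-squares clock line for one mutation category."""

    category: str
    slope: float
    intercept: float
    p_value: float
    per_site_rate: Optional[float]
    n_points: int
    stderr: float
    through_origin: bool = False

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a clock fit needs at least 3 points")


def first_exceed_generation(
    series: pd.Series, threshold: float = 0.1
) -> Optional[int]:
    """Earliest sampled generation with frequency strictly above threshold.

    No interpolation: only the sampled time points are candidates.  Returns
    None if the series never exceeds the threshold.
    """
    if len(series) == 0:
        raise ValueError("series must be non-empty")
    above = series[series > threshold]
    return int(above.index[0]) if len(above) else None


def fixation_points(
    lineages: Sequence[GenomeLineage],
    clusters: ClusterSet,
    baseline_generation: int = BASELINE_GENERATION,
    threshold: float = 0.1,
    fixed_threshold: float = 0.95,
) -> list[FixationPoint]:
    """Clock data points from clusters that fixed along their lineage.

    Walks each lineage's cluster chain in onset order; every cluster that
    ends at or above ``fixed_threshold`` (it fixed in the line) contributes
    one point at its first-exceed generation, carrying the category counts
    accumulated along the chain so far.  The walk stops at the first
    cluster that did not fix — clusters that lost to interference or died
    out, and anything nested under them, contribute nothing: the clock
    tracks only the lineage that dominates at the end.  Points shared
    between lineages through a common ancestry prefix are emitted once.
    A zero-count point at the baseline generation anchors the regression.
    """
    points: dict[tuple[str, ...], FixationPoint] = {}
    for lin in lineages:
        cum: dict[str, int] = {}
        for depth, cid in enumerate(lin.clusters):
            cluster = clusters[cid]
            if classify_fate(cluster.mean, fixed_threshold=fixed_threshold) != "fixed-in-line":
                break
            for cat, n in cluster.categories.items():
                cum[cat] = cum.get(cat, 0) + n
            gen = first_exceed_generation(cluster.mean, threshold)
            if gen is None:
                continue
            key = tuple(lin.clusters[: depth + 1])
            if key not in points:
                points[key] = FixationPoint(
                    generation=gen, counts=dict(cum), lineage_id=lin.lineage_id
                )
    out = [FixationPoint(generation=baseline_generation, counts={})]
    out.extend(sorted(points.values(), key=lambda p: (p.generation, p.lineage_id)))
    return out


def fit_clock(
    points: Sequence[FixationPoint],
    category: str,
    site_count: Optional[float] = None,
    through_origin: bool = False,
    baseline_generation: Optional[int] = None,
) -> ClockFit:
    """Ordinary least squares of cumulative count against generation.

    The default fit carries an intercept and includes the baseline zero
    point like any other.  ``through_origin`` instead regresses counts on
    ``generation - baseline`` with no intercept (sensitivity variant).
    The two-sided p-value tests slope != 0.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a clock fit")
    x = np.array([p.generation for p in points], dtype=float)
    y = np.array([p.count(category) for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("degenerate fit: all points at the same generation")

    if through_origin:
        if baseline_generation is None:
            baseline_generation = int(x.min())
        xo = x - baseline_generation
        sxx = float(np.dot(xo, xo))
        if sxx == 0:
            raise ValueError("degenerate fit: no spread around the baseline")
        slope = float(np.dot(xo, y) / sxx)
        resid = y - slope * xo
        dof = len(x) - 1
        s2 = float(np.dot(resid, resid)) / dof if dof > 0 else float("nan")
        stderr = math.sqrt(s2 / sxx)
        if stderr == 0:
            pval = 0.0 if slope != 0 else 1.0
        else:
            tstat = slope / stderr
            pval = 2 * stats.t.sf(abs(tstat), dof)
        intercept = 0.0
    else:
        res = stats.linregress(x, y)
        slope = float(res.slope)
        intercept = float(res.intercept)
        pval = float(res.pvalue)
        stderr = float(res.stderr)

    return ClockFit(
        category=category,
        slope=slope,
        intercept=intercept,
        p_value=float(pval),
        per_site_rate=slope / site_count if site_count else None,
        n_points=len(points),
        stderr=stderr,
        through_origin=through_origin,
    )


def compare_to_spontaneous(fit: ClockFit, mu: float) -> dict:
    """Ratio of the fitted per-site fixation rate to the spontaneous rate.

    The hitchhiking clock predicts the two coincide; ``same_order`` flags a
    ratio within one order of magnitude either way.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if fit.per_site_rate is None:
        raise ValueError("fit has no per-site rate (no site count supplied)")
    ratio = fit.per_site_rate / mu
    return {
        "per_site_rate": fit.per_site_rate,
        "mu": mu,
        "ratio": ratio,
        "same_order": 0.1 <= ratio <= 10.0,
    }
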