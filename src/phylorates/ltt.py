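"""Lineages-through-time step functions, summation, binning, and the overall
semi-log diversification rate.

An :class:`LTTSeries` is a right-continuous-toward-the-present step function:
``counts[i]`` is the number of lineages in force from ``times[i]`` (inclusive)
until the next, more recent, event.  Before the first event (older than the
root) the count is 0; the final segment extends to the present, t = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tree_io import DatedTree, node_ages

__all__ = ["LTTSeries", "LTTRegression", "compute_ltt", "sum_ltt", "millennial_series", "global_rate"]


@dataclass(frozen=True)
class LTTSeries:
    """Number of lineages as a step function of time BP."""

    times: np.ndarray  # strictly decreasing event times, years BP
    counts: np.ndarray  # lineage count in force at and after each event
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)
        if times.ndim != 1 or times.shape != counts.shape or times.size == 0:
            raise ValueError("times and counts must be equal-length 1-d arrays")
        if np.any(np.diff(times) >= 0):
            raise ValueError("event times must be strictly decreasing (years BP)")
        if np.any(counts < 1):
            raise ValueError("lineage counts must be positive")

    @property
    def origin(self) -> float:
        """Oldest event time (the root for a single-tree series), years BP."""
        return float(self.times[0])

    def value_at(self, t):
        """N(t) for scalar or array ``t`` (years BP); 0 before the first event.

        An event exactly at ``t`` is included: the returned value is the count
        in force at that instant, moving toward the present.
        """
        t = np.asarray(t, dtype=float)
        # times are descending; find the most recent event with time >= t
        idx = np.searchsorted(-self.times, -t, side="right") - 1
        out = np.where(idx >= 0, self.counts[np.clip(idx, 0, None)], 0)
        return out if out.ndim else out.item()

    def integrate(self, t_old: float, t_young: float) -> float:
        """Exact integral of the step function over [t_young, t_old] (years BP)."""
        if t_old < t_young:
            raise ValueError("t_old must be >= t_young")
        edges = np.concatenate(([t_old], self.times[(self.times < t_old) & (self.times > t_young)], [t_young]))
        widths = -np.diff(edges)
        values = self.value_at(edges[:-1])
        return float(np.sum(widths * np.asarray(values, dtype=float)))


def compute_ltt(tree: DatedTree) -> LTTSeries:
    """Build the lineages-through-time series of a tree pruned to extant tips.

    The series starts at the crown root with a count equal to the root's
    outdegree and ends with the extant tip count at the present.  Simultaneous
    splits (including polytomies) merge into a single step.
    """
    label = tree.family_name or ""
    if tree.n_tips == 1:
        warnings.warn("single-tip tree: constant LTT with one lineage", stacklevel=2)
        return LTTSeries(np.array([tree.root_age]), np.array([1]), label=label)
    ages = node_ages(tree)
    increments: dict[float, int] = {}
    for node in tree.root.preorder():
        if not node.is_leaf:
            age = ages[node]
            increments[age] = increments.get(age, 0) + len(node.children) - 1
    times = np.array(sorted(increments, reverse=True))
    counts = 1 + np.cumsum([increments[t] for t in times])
    return LTTSeries(times, counts, label=label)


def sum_ltt(series: list[LTTSeries], label: str = "sum") -> LTTSeries:
    """Sum step functions on the absolute BP axis.

    Each series contributes 0 before its own first event, so a family adds
    lineages only from its root onward.
    """
    if not series:
        raise ValueError("need at least one series to sum")
    times = np.unique(np.concatenate([s.times for s in series]))[::-1]
    total = np.zeros(times.size, dtype=int)
    for s in series:
        total += np.asarray(s.value_at(times), dtype=int)
    return LTTSeries(times, total, label=label)


def millennial_series(series: LTTSeries, bin_width: float = 1000.0) -> list[tuple[float, float]]:
    """Time-weighted mean lineage count per ``bin_width``-year bin.

    Bins are anchored at the present: [k*w, (k-1)*w) years BP.  Bins that are
    entirely older than the first event are omitted.  Returns (bin midpoint
    BP, mean N) pairs ordered from oldest to youngest.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(series.origin / bin_width))
    out = []
    for k in range(n_bins, 0, -1):
        t_old, t_young = k * bin_width, (k - 1) * bin_width
        mean = series.integrate(t_old, t_young) / bin_width
        if not out and mean == 0.0:
            continue  # empty leading bin
        out.append(((t_old + t_young) / 2.0, mean))
    return out


@dataclass(frozen=True)
class LTTRegression:
    """OLS fit of ln N against elapsed time."""

    slope: float  # yr^-1
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n_points: int
    degenerate: bool = False  # all counts equal: slope 0, r^2 undefined


def global_rate(series: LTTSeries, points: str = "events") -> LTTRegression:
    """Overall diversification rate: the semi-log slope of the LTT curve.

    Regresses ln N on time elapsed since the first event, evaluated either at
    the event times (``points="events"``) or on an annual grid
    (``points="annual"``).
    """
    if points == "events":
        t = series.times
        n = series.counts.astype(float)
    elif points == "annual":
        t = np.arange(np.floor(series.origin), -1.0, -1.0)
        t = t[t >= 0]
        n = np.asarray(series.value_at(t), dtype=float)
        keep = n > 0
        t, n = t[keep], n[keep]
    else:
        raise ValueError("points must be 'events' or 'annual'")
    if t.size < 3:
        raise ValueError("need at least 3 points for the semi-log regression")
    elapsed = series.origin - t
    y = np.log(n)
    if np.all(n == n[0]):
        return LTTRegression(0.0, float(y[0]), np.nan, np.nan, np.nan, t.size, degenerate=True)
    fit = stats.linregress(elapsed, y)
    r2 = fit.rvalue**2
    dof = t.size - 2
    f_stat = r2 / (1.0 - r2) * dof if r2 < 1.0 else np.inf
    return LTTRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        f_statistic=float(f_stat),
        p_value=float(fit.pvalue),
        n_points=int(t.size),
    )
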