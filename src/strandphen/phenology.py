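"""Seasonal (day-of-year) density estimation for event streams.

Event phenologies — shark detections at monitored sites, seal census
counts, human-shark incidents, stranding dates — are summarised as
normalised densities over the 366-day calendar circle.  Because several
of these seasons straddle the new year, smoothing is *circular*: a
wrapped Gaussian kernel is used, implemented by replicating each event
at +/-366 days and renormalising on [1, 366].  Cumulative distribution
functions from a stated origin day, density peaks, and circular lags
between two phenologies are derived from the densities.

The kernel family and bandwidth are configurable; the default bandwidth
is Silverman's rule on the unwrapped sample, floored at 3 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DetectionSeries, doy

YEAR_DAYS = 366
GRID = np.arange(1, YEAR_DAYS + 1)

_BANDWIDTH_FLOOR = 3.0  # days


@dataclass(frozen=True)
class PhenologyDensity:
    """Normalised seasonal density on the 366-day circle (unit-day grid)."""

    grid: np.ndarray        # day-of-year points 1..366
    values: np.ndarray      # density per day; sums to 1
    bandwidth: float        # days
    n_events: int

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")
        if abs(float(self.values.sum()) - 1.0) > 1e-9:
            raise ValueError("density must integrate to 1 over the year")


@dataclass(frozen=True)
class PhenologyCDF:
    """Cumulative seasonal mass starting from ``origin`` (wraps once)."""

    grid: np.ndarray        # unwrapped day axis, origin..origin+365
    values: np.ndarray      # nondecreasing, ends at 1
    origin: int


def silverman_bandwidth(days: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule-of-thumb on the (unwrapped) weighted sample, floored."""
    n_eff = float(weights.sum()) ** 2 / float((weights**2).sum())
    mean = float(np.average(days, weights=weights))
    var = float(np.average((days - mean) ** 2, weights=weights))
    sd = np.sqrt(var)
    if sd == 0.0:
        raise ValueError("bandwidth 'auto' undefined for a single distinct day; "
                         "pass an explicit bandwidth")
    return max(_BANDWIDTH_FLOOR, 1.06 * sd * n_eff ** (-0.2))


def estimate_density(events, bandwidth: float | str = "auto",
                     weights=None) -> PhenologyDensity:
    """Wrapped-Gaussian kernel density of day-of-year events.

    Parameters
    ----------
    events
        Day-of-year values in [1, 366].
    bandwidth
        Kernel standard deviation in days, or ``"auto"`` for Silverman's
        rule (floored at 3 days).
    weights
        Optional nonnegative integer weights (e.g. daily detection counts).
    """
    days = np.asarray(events, dtype=float)
    if weights is None:
        w = np.ones_like(days)
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    keep = w > 0
    days, w = days[keep], w[keep]
    if w.sum() == 0 or days.size == 0:
        raise ValueError("no positively weighted events")
    if np.unique(days).size < 2 and bandwidth == "auto":
        raise ValueError("bandwidth 'auto' requires >= 2 distinct days; "
                         "pass an explicit bandwidth")
    h = silverman_bandwidth(days, w) if bandwidth == "auto" else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    # wrapped kernel: replicate events enough years to each side that the
    # kernel tails (4 sigma) are fully represented on the grid
    k = max(1, int(np.ceil(4 * h / YEAR_DAYS)))
    shifts = np.arange(-k, k + 1) * YEAR_DAYS
    centers = (days[None, :] + shifts[:, None]).ravel()
    cw = np.tile(w, 2 * k + 1)
    z = (GRID[:, None] - centers[None, :]) / h
    dens = (np.exp(-0.5 * z**2) * cw[None, :]).sum(axis=1)
    dens /= dens.sum()  # renormalise on the 1..366 grid (1-day steps)
    return PhenologyDensity(GRID.copy(), dens, h, int(round(float(w.sum()))))


def relative_density(series: DetectionSeries,
                     bandwidth: float | str = "auto") -> PhenologyDensity:
    """Detection counts as kernel weights on their day-of-year.

    The output is normalised, so it is invariant to the overall count
    scale; weekly census series are handled identically, with counts
    assigned to the census dates.
    """
    days = np.array([doy(d) for d, _ in series.entries], dtype=float)
    counts = np.array([c for _, c in series.entries], dtype=float)
    if counts.sum() <= 0:
        raise ValueError(f"{series.species} series has no positive counts")
    return estimate_density(days, bandwidth=bandwidth, weights=counts)


def to_cdf(density: PhenologyDensity, origin: int = 1) -> PhenologyCDF:
    """Cumulative mass from ``origin``, wrapping once around the circle."""
    if not 1 <= origin <= YEAR_DAYS:
        raise ValueError("origin must be a day-of-year in [1, 366]")
    order = (np.arange(YEAR_DAYS) + (origin - 1)) % YEAR_DAYS
    values = np.cumsum(density.values[order])
    grid = origin + np.arange(YEAR_DAYS)
    return PhenologyCDF(grid, values, origin)


def peak_doy(density: PhenologyDensity) -> int:
    """Grid argmax; ties broken by the earliest day after day 1."""
    return int(density.grid[int(np.argmax(density.values))])


def median_doy(density: PhenologyDensity, origin: int = 1) -> int:
    """First grid day (unwrapped from ``origin``) where the CDF reaches 0.5."""
    cdf = to_cdf(density, origin)
    idx = int(np.searchsorted(cdf.values, 0.5))
    return int((cdf.grid[idx] - 1) % YEAR_DAYS + 1)


def circular_lag(a_day: float, b_day: float) -> float:
    """Signed circular difference b - a, mapped to (-183, +183]."""
    diff = (b_day - a_day) % YEAR_DAYS
    if diff > YEAR_DAYS / 2:
        diff -= YEAR_DAYS
    return diff


def phenology_lag(a: PhenologyDensity, b: PhenologyDensity,
                  statistic: str = "peak") -> float:
    """Days by which phenology ``b`` trails ``a`` (positive = b later).

    ``statistic`` is ``"peak"`` (density argmax) or ``"median"`` (CDF
    midpoint from day 1).
    """
    if statistic == "peak":
        return circular_lag(peak_doy(a), peak_doy(b))
    if statistic == "median":
        return circular_lag(median_doy(a), median_doy(b))
    raise ValueError("statistic must be 'peak' or 'median'")


def export_density(density: PhenologyDensity, path) -> None:
    """Write a two-column (day, value) comma-separated file."""
    np.savetxt(path, np.column_stack([density.grid, density.values]),
               fmt=("%d", "%.10g"), delimiter=",", header="day,value", comments="")
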