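"""Demographic risk-factor statistics for stranding records.

Shark-bite risk is not demographically even: dispersal-prone strata
(males, immatures) strand with shark trauma at different rates than the
rest of the population.  This module provides the test battery used to
quantify that:

* 2x2 (and r x c) contingency tables over post-exclusion records;
* chi-squared tests of independence, with the Yates continuity
  correction ON by default for 2x2 tables;
* Wilcoxon rank-sum and paired signed-rank comparisons, exact by full
  enumeration at small n and normal-approximated (with tie correction)
  otherwise;
* a within-stratum bootstrap of the male proportion ("male bias"),
  resampling individual records with replacement either pooled or
  within triennial bins, summarised by the replicate median and a
  percentile confidence interval.

No multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import StrandingRecord


@dataclass(frozen=True)
class ContingencyTable:
    row_factor: str
    col_factor: str
    row_levels: tuple[str, ...]
    col_levels: tuple[str, ...]
    cells: np.ndarray           # shape (r, c), nonnegative ints

    @property
    def row_margins(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.cells.sum())


@dataclass(frozen=True)
class TestResult:
    statistic_name: str         # chi_squared | W_rank_sum | V_signed_rank
    value: float
    df: int | None
    sample_sizes: tuple[int, ...]
    p_value: float
    correction: bool = False
    method: str = ""            # e.g. "yates", "exact", "normal_approx"


@dataclass(frozen=True)
class BiasSummary:
    group: str
    n_records: int
    male_count: int
    median: float               # bootstrap median of the male proportion
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_replicates: int
    grouping: str               # pooled | per_bin


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# contingency tables and chi-squared
# ---------------------------------------------------------------------------

def build_contingency(records: Sequence[StrandingRecord],
                      row_factor: str, col_factor: str,
                      strata_filter: Callable[[StrandingRecord], bool] | None = None,
                      row_levels: Sequence[str] | None = None,
                      col_levels: Sequence[str] | None = None,
                      ) -> ContingencyTable:
    """Exact cell counts of ``row_factor`` x ``col_factor`` over records.

    Factor names are record attributes (``sex``, ``age_class``, ``cause``).
    Level order may be pinned via ``row_levels`` / ``col_levels``; a named
    level with zero count raises, as does an empty record set.
    """
    recs = [r for r in records if strata_filter is None or strata_filter(r)]
    if not recs:
        raise ValueError("no records after filtering; table undefined")
    rvals = [getattr(r, row_factor) for r in recs]
    cvals = [getattr(r, col_factor) for r in recs]
    rlev = tuple(row_levels) if row_levels else tuple(sorted(set(rvals)))
    clev = tuple(col_levels) if col_levels else tuple(sorted(set(cvals)))
    cells = np.zeros((len(rlev), len(clev)), dtype=int)
    for rv, cv in zip(rvals, cvals):
        if rv in rlev and cv in clev:
            cells[rlev.index(rv), clev.index(cv)] += 1
    for name, levels, margins in ((row_factor, rlev, cells.sum(axis=1)),
                                  (col_factor, clev, cells.sum(axis=0))):
        for lev, m in zip(levels, margins):
            if m == 0:
                raise ValueError(f"factor {name!r} level {lev!r} is empty")
    return ContingencyTable(row_factor, col_factor, rlev, clev, cells)


def chi_squared(table: ContingencyTable | np.ndarray,
                yates: bool = True) -> TestResult:
    """Chi-squared test of independence.

    For a 2x2 table the statistic is ``sum((|O - E| - c)^2 / E)`` with the
    Yates continuity constant ``c = 0.5`` when ``yates`` (the default) and
    ``c = 0`` otherwise; larger tables use the plain Pearson statistic.
    The p-value comes from the chi-squared distribution on (r-1)(c-1)
    degrees of freedom.  A zero margin makes the test undefined.
    """
    cells = table.cells if isinstance(table, ContingencyTable) else np.asarray(table)
    cells = cells.astype(float)
    if cells.ndim != 2 or min(cells.shape) < 2:
        raise ValueError("table must be at least 2x2")
    rows, cols = cells.sum(axis=1), cells.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: chi-squared test undefined")
    n = cells.sum()
    expected = np.outer(rows, cols) / n
    c = 0.5 if (yates and cells.shape == (2, 2)) else 0.0
    dev = np.maximum(np.abs(cells - expected) - c, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (cells.shape[0] - 1) * (cells.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return TestResult("chi_squared", statistic, df, (int(n),), p,
                      correction=c > 0, method="yates" if c > 0 else "pearson")


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 12


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _two_sided_from_null(null: np.ndarray, observed: float) -> float:
    """Two-sided p as the null mass at least as far from the mean as observed."""
    center = float(null.mean())
    p = float(np.mean(np.abs(null - center) >= abs(observed - center) - 1e-12))
    return min(1.0, p)


def wilcoxon(x: Sequence[float], y: Sequence[float],
             mode: str = "rank_sum") -> TestResult:
    """Wilcoxon comparison of two samples.

    ``rank_sum``
        Two independent samples; the statistic is the first-sample
        Mann-Whitney count ``W = R_x - n_x(n_x+1)/2`` (the convention of
        R's ``wilcox.test``).  Exact p by enumeration of all rank
        assignments when the combined n is <= 12, else a tie-corrected
        normal approximation.
    ``signed_rank_paired``
        Paired samples of equal length; zero differences are discarded,
        the statistic is the positive-rank sum ``V``.  Exact p by
        enumeration of sign assignments when the number of nonzero pairs
        is <= 12.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if mode == "rank_sum":
        if xa.size == 0 or ya.size == 0:
            raise ValueError("rank_sum requires two nonempty samples")
        return _rank_sum(xa, ya)
    if mode == "signed_rank_paired":
        if xa.size != ya.size:
            raise ValueError("paired mode requires equal-length samples")
        return _signed_rank(xa, ya)
    raise ValueError("mode must be 'rank_sum' or 'signed_rank_paired'")


def _rank_sum(x: np.ndarray, y: np.ndarray) -> TestResult:
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)  # Mann-Whitney U of x
    if n1 + n2 <= _EXACT_LIMIT:
        null = np.array([sum(combo) - n1 * (n1 + 1) / 2
                         for combo in itertools.combinations(ranks, n1)])
        p = _two_sided_from_null(null, w)
        method = "exact"
    else:
        mean = n1 * n2 / 2
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie = float(((counts**3 - counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12 * ((n + 1) - tie)
        z = (w - mean - 0.5 * np.sign(w - mean)) / math.sqrt(var) if var > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    return TestResult("W_rank_sum", w, None, (n1, n2), min(1.0, p), method=method)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> TestResult:
    diffs = x - y
    diffs = diffs[diffs != 0]           # zero-discard rule
    m = diffs.size
    if m == 0:
        return TestResult("V_signed_rank", 0.0, None, (x.size, y.size), 1.0,
                          method="degenerate")
    ranks = _midranks(np.abs(diffs))
    v = float(ranks[diffs > 0].sum())
    if m <= _EXACT_LIMIT:
        null = np.array([sum(itertools.compress(ranks, signs))
                         for signs in itertools.product((0, 1), repeat=m)],
                        dtype=float)
        p = _two_sided_from_null(null, v)
        method = "exact"
    else:
        mean = m * (m + 1) / 4
        _, counts = np.unique(np.abs(diffs), return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24 - float((counts**3 - counts).sum()) / 48
        z = (v - mean - 0.5 * np.sign(v - mean)) / math.sqrt(var) if var > 0 else 0.0
        p = float(2 * stats.norm.sf(abs(z)))
        method = "normal_approx"
    return TestResult("V_signed_rank", v, None, (x.size, y.size), min(1.0, p),
                      method=method)


# ---------------------------------------------------------------------------
# male-bias bootstrap
# ---------------------------------------------------------------------------

def bootstrap_bias(records: Sequence[StrandingRecord], cfg: BootstrapConfig,
                   grouping: str = "per_bin", group_label: str = "",
                   start_year: int = 1997, width_years: int = 3) -> BiasSummary:
    """Bootstrap the male proportion of a stratum of stranding records.

    Each replicate resamples the individual records with replacement —
    within the whole stratum (``pooled``) or within each triennial bin
    with bin-size weighting (``per_bin``, the default) — and records the
    replicate male proportion.  The summary is the median of the
    replicate distribution and the central ``ci_level`` percentile
    interval.  Deterministic given ``cfg.seed``.
    """
    if not records:
        raise ValueError("stratum has no records")
    sexes = np.array([r.sex for r in records])
    if not set(sexes) <= {"M", "F"}:
        raise ValueError("bootstrap_bias requires sex in {M, F} for every record")
    male = (sexes == "M").astype(float)
    rng = np.random.default_rng(cfg.seed)
    reps = cfg.n_replicates
    if grouping == "pooled":
        idx = rng.integers(0, male.size, size=(reps, male.size))
        props = male[idx].mean(axis=1)
    elif grouping == "per_bin":
        bins = np.array([(r.date.year - start_year) // width_years for r in records])
        male_totals = np.zeros(reps)
        for b in np.unique(bins):
            sub = male[bins == b]
            idx = rng.integers(0, sub.size, size=(reps, sub.size))
            male_totals += sub[idx].sum(axis=1)
        props = male_totals / male.size      # bin-size-weighted pool
    else:
        raise ValueError("grouping must be 'pooled' or 'per_bin'")
    alpha = (1 - cfg.ci_level) / 2
    lo, med, hi = np.quantile(props, [alpha, 0.5, 1 - alpha])
    return BiasSummary(group_label, male.size, int(male.sum()), float(med),
                       float(lo), float(hi), cfg.ci_level, reps, grouping)


def observed_bias_by_bin(records: Sequence[StrandingRecord],
                         start_year: int = 1997, width_years: int = 3,
                         ) -> dict[int, float]:
    """Observed per-bin male proportion (point estimates, no resampling)."""
    bins: dict[int, list[float]] = {}
    for r in records:
        if r.sex not in ("M", "F"):
            raise ValueError("sex must be M or F")
        b = (r.date.year - start_year) // width_years
        bins.setdefault(b, []).append(1.0 if r.sex == "M" else 0.0)
    return {b: float(np.mean(v)) for b, v in sorted(bins.items())}
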