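"""Synthetic stranding / detection / incident data with known ground truth.

The generator emulates the three surveillance streams the pipeline
consumes, so that every downstream stage can be exercised and its
estimates checked against a known truth without any external download:

* **strandings** — exact per-(bin, sex, maturity, cause) cell counts;
  shark-attributed dates drawn from a wrapped normal on the 366-day
  circle with a per-bin season centre and a per-bin central-80% window
  width (sigma = width80 / (2 * 1.2816), so ~80% of draws span the
  window); other-cause dates uniform over the bin's calendar span
  (the neutral no-seasonality null); years uniform within the bin.
* **detections** — a daily shark series with arrival / peak / departure
  phases (raised-cosine ramps on the circular axis, Poisson counts) and
  a weekly seal census series with a Gaussian-shaped seasonal peak.
* **incidents** — ``n_valid`` rows satisfying every inclusion criterion
  of the incident filter plus ``n_distractors`` rows, each violating at
  least one criterion (wrong species, provoked, non-injurious, wrong
  region, out-of-range year), with per-row violation flags.

Ground truth (per-bin window endpoints, per-stratum male bias, implied
centre trend slope) is emitted as a JSON sidecar for recovery tests.
Every product is reproducible from ``SyntheticConfig.seed``; the three
generators draw from independent substreams of that seed.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_io import (
    OTTER_TALLY_CELLS_1997_2017,
    OTTER_TALLY_TOTALS_1997_2017,
    DetectionSeries,
    IncidentRecord,
    StrandingRecord,
    date_from_doy,
    days_in_year,
    write_detections,
    write_incidents,
    write_strandings,
)

Z80 = 1.2816                 # upper 90% normal quantile: central 80% = +/- Z80 sigma
YEAR_DAYS = 366
_MIN_WIDTH80 = 1e-2          # degenerate window widths collapse to the centre

# substream ids for per-product seed derivation
_STREAM_STRANDINGS, _STREAM_DETECTIONS, _STREAM_INCIDENTS = 11, 22, 33


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth description of one synthetic dataset."""

    seed: int
    n_bins: int = 7
    bin_width_years: int = 3
    start_year: int = 1997
    #: (bin, sex, maturity, cause) -> count; sex in {M, F},
    #: maturity in {immature, mature}, cause in {shark, other}
    cell_counts: Mapping[tuple[int, str, str, str], int] = field(default_factory=dict)
    season_center: Mapping[int, float] = field(default_factory=dict)   # bin -> DOY
    season_width80: Mapping[int, float] = field(default_factory=dict)  # bin -> days
    #: shark detection phases: (arrival_doy, peak_doy, departure_doy, n_individuals)
    shark_phase: tuple[int, int, int, int] = (213, 288, 60, 30)
    #: seal census: (peak_doy, spread_days, peak_count)
    seal_census: tuple[int, float, int] = (305, 30.0, 300)
    #: incident log: (n_valid, n_distractors)
    incident_log: tuple[int, int] = (75, 40)
    detection_years: tuple[int, int] = (2007, 2013)
    census_years: tuple[int, int] = (1987, 2013)
    incident_year_range: tuple[int, int] = (1997, 2018)

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.bin_width_years < 1:
            raise ConfigurationError("n_bins and bin_width_years must be >= 1")
        for (b, sex, mat, cause), n in self.cell_counts.items():
            if not 0 <= b < self.n_bins:
                raise ConfigurationError(f"cell bin {b} outside [0, {self.n_bins})")
            if sex not in ("M", "F") or mat not in ("immature", "mature") \
                    or cause not in ("shark", "other") or n < 0:
                raise ConfigurationError(f"bad cell {(b, sex, mat, cause)} -> {n}")
        for b, c in self.season_center.items():
            if not 1 <= c <= YEAR_DAYS:
                raise ConfigurationError(f"season_center[{b}]={c} outside [1, 366]")
        for b, w in self.season_width80.items():
            if w < 0:
                raise ConfigurationError(f"season_width80[{b}]={w} negative")
        for d in self.shark_phase[:3]:
            if not 1 <= d <= YEAR_DAYS:
                raise ConfigurationError(f"shark phase day {d} outside [1, 366]")
        if any(n < 0 for n in (self.shark_phase[3], *self.incident_log,
                               self.seal_census[2])):
            raise ConfigurationError("counts must be nonnegative")

    def bin_years(self, b: int) -> tuple[int, int]:
        lo = self.start_year + b * self.bin_width_years
        return lo, lo + self.bin_width_years - 1

    def center(self, b: int) -> float:
        return float(self.season_center.get(b, 250.0))

    def width80(self, b: int) -> float:
        return float(self.season_width80.get(b, 90.0))


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# strandings
# ---------------------------------------------------------------------------

def wrapped_normal_doy(center: float, width80: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Integer day-of-year draws from a wrapped normal on the 366-day circle.

    ``sigma = width80 / (2 * Z80)`` so the central 80% of the unwrapped
    draws spans approximately ``width80`` days.
    """
    sigma = max(width80, _MIN_WIDTH80) / (2 * Z80)
    draws = rng.normal(center, sigma, size=size)
    return (np.round(draws) - 1) % YEAR_DAYS + 1


def gen_strandings(cfg: SyntheticConfig) -> list[StrandingRecord]:
    """Stranding records with exactly the configured per-cell counts."""
    rng = _rng(cfg, _STREAM_STRANDINGS)
    records: list[StrandingRecord] = []
    for (b, sex, maturity, cause), n in sorted(cfg.cell_counts.items()):
        if n == 0:
            continue
        y_lo, y_hi = cfg.bin_years(b)
        years = rng.integers(y_lo, y_hi + 1, size=n)
        if cause == "shark":
            doys = wrapped_normal_doy(cfg.center(b), cfg.width80(b), n, rng)
        else:
            # uniform over the bin's calendar span: no seasonality
            doys = np.array([rng.integers(1, days_in_year(y) + 1) for y in years])
        for y, d in zip(years, doys):
            records.append(StrandingRecord(date_from_doy(int(y), int(d)),
                                           sex, maturity, cause))
    return records


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def _shark_expected(doy: np.ndarray, arrival: int, peak: int, departure: int,
                    n_individuals: int) -> np.ndarray:
    """Expected daily detection count: raised-cosine ramp up then down (circular)."""
    t_up = (peak - arrival) % YEAR_DAYS or 1
    t_down = (departure - peak) % YEAR_DAYS or 1
    u = (doy - arrival) % YEAR_DAYS
    v = (doy - peak) % YEAR_DAYS
    out = np.zeros_like(doy, dtype=float)
    rising = u <= t_up
    out[rising] = 0.5 * (1 - np.cos(np.pi * u[rising] / t_up))
    falling = (~rising) & (v <= t_down)
    out[falling] = 0.5 * (1 + np.cos(np.pi * v[falling] / t_down))
    return n_individuals * out


def shark_expected_curve(cfg: SyntheticConfig) -> np.ndarray:
    """Expected shark detections for days 1..366 (the generator's mean curve)."""
    arrival, peak, departure, n_ind = cfg.shark_phase
    return _shark_expected(np.arange(1, YEAR_DAYS + 1), arrival, peak,
                           departure, n_ind)


def seal_expected_curve(cfg: SyntheticConfig) -> np.ndarray:
    """Expected seal census count for days 1..366 (circular Gaussian bump)."""
    peak_doy, spread, peak_count = cfg.seal_census
    d = np.arange(1, YEAR_DAYS + 1, dtype=float)
    dist = np.abs(d - peak_doy)
    dist = np.minimum(dist, YEAR_DAYS - dist)
    return peak_count * np.exp(-0.5 * (dist / spread) ** 2)


def gen_detections(cfg: SyntheticConfig) -> tuple[DetectionSeries, DetectionSeries]:
    """(daily shark series, weekly seal series) with Poisson count noise."""
    rng = _rng(cfg, _STREAM_DETECTIONS)
    arrival, peak, departure, n_ind = cfg.shark_phase

    y0, y1 = cfg.detection_years
    start = _dt.date(y0, 1, 1)
    n_days = (_dt.date(y1, 12, 31) - start).days + 1
    dates = [start + _dt.timedelta(days=i) for i in range(n_days)]
    doys = np.array([d.timetuple().tm_yday for d in dates])
    mean = _shark_expected(doys, arrival, peak, departure, n_ind)
    counts = rng.poisson(mean)
    shark = DetectionSeries("shark", "daily",
                            tuple(zip(dates, (int(c) for c in counts))))

    peak_doy, spread, peak_count = cfg.seal_census
    c0, c1 = cfg.census_years
    wstart = _dt.date(c0, 1, 1)
    n_weeks = ((_dt.date(c1, 12, 31) - wstart).days) // 7 + 1
    wdates = [wstart + _dt.timedelta(weeks=i) for i in range(n_weeks)]
    wdoys = np.array([d.timetuple().tm_yday for d in wdates], dtype=float)
    dist = np.abs(wdoys - peak_doy)
    dist = np.minimum(dist, YEAR_DAYS - dist)
    wmean = peak_count * np.exp(-0.5 * (dist / spread) ** 2)
    wcounts = rng.poisson(wmean)
    seal = DetectionSeries("seal", "weekly",
                           tuple(zip(wdates, (int(c) for c in wcounts))))
    return shark, seal


# ---------------------------------------------------------------------------
# incidents
# ---------------------------------------------------------------------------

_VIOLATIONS = ("species", "provoked", "injurious", "region", "year")


def gen_incidents(cfg: SyntheticConfig
                  ) -> tuple[list[IncidentRecord], list[tuple[str, ...]]]:
    """Incident rows plus per-row violation flags (empty tuple = valid).

    Valid rows satisfy every default inclusion criterion (white shark,
    California, unprovoked, injurious, year in range); each distractor
    violates at least one, chosen at random.
    """
    rng = _rng(cfg, _STREAM_INCIDENTS)
    n_valid, n_distractors = cfg.incident_log
    y_lo, y_hi = cfg.incident_year_range
    records: list[IncidentRecord] = []
    flags: list[tuple[str, ...]] = []

    def _random_date(year: int) -> _dt.date:
        return date_from_doy(year, int(rng.integers(1, days_in_year(year) + 1)))

    for _ in range(n_valid):
        records.append(IncidentRecord(
            date=_random_date(int(rng.integers(y_lo, y_hi + 1))),
            species_label="white shark", provoked=False, injurious=True,
            region="California", fatal=bool(rng.random() < 0.1)))
        flags.append(())

    for _ in range(n_distractors):
        k = int(rng.integers(1, len(_VIOLATIONS) + 1))
        chosen = tuple(sorted(rng.choice(_VIOLATIONS, size=k, replace=False)))
        year = 1980 if "year" in chosen else int(rng.integers(y_lo, y_hi + 1))
        records.append(IncidentRecord(
            date=_random_date(year),
            species_label="tiger shark" if "species" in chosen else "white shark",
            provoked="provoked" in chosen,
            injurious="injurious" not in chosen,
            region="Florida" if "region" in chosen else "California",
            fatal=False))
        flags.append(chosen)
    return records, flags


# ---------------------------------------------------------------------------
# ground truth and file output
# ---------------------------------------------------------------------------

def ground_truth(cfg: SyntheticConfig) -> dict:
    """True seasonal windows, male biases, and centre-trend slope."""
    bins = sorted({b for b in range(cfg.n_bins)})
    windows = {b: {"center": cfg.center(b),
                   "start": cfg.center(b) - cfg.width80(b) / 2,
                   "end": cfg.center(b) + cfg.width80(b) / 2,
                   "width80": cfg.width80(b)} for b in bins}
    bias = {}
    for maturity in ("immature", "mature"):
        for cause in ("shark", "other"):
            m = sum(n for (b, s, mt, c), n in cfg.cell_counts.items()
                    if s == "M" and mt == maturity and c == cause)
            f = sum(n for (b, s, mt, c), n in cfg.cell_counts.items()
                    if s == "F" and mt == maturity and c == cause)
            bias[f"{maturity}_{cause}"] = m / (m + f) if m + f else None
    slope = None
    if len(bins) >= 2:
        fit = stats.linregress(bins, [cfg.center(b) for b in bins])
        slope = float(fit.slope)
    return {"seed": cfg.seed, "windows": windows, "male_bias": bias,
            "center_trend_slope": slope}


def write_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate all three streams plus the ground-truth sidecar to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "strandings": out / "strandings.csv",
        "detections": out / "detections.csv",
        "incidents": out / "incidents.csv",
        "truth": out / "ground_truth.json",
    }
    write_strandings(gen_strandings(cfg), paths["strandings"])
    write_detections(gen_detections(cfg), paths["detections"])
    incidents, _ = gen_incidents(cfg)
    write_incidents(incidents, paths["incidents"])
    paths["truth"].write_text(json.dumps(ground_truth(cfg), indent=2, sort_keys=True))
    return paths


def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Nonnegative integer split of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        w = np.ones_like(w)
    raw = w / w.sum() * total
    out = np.floor(raw).astype(int)
    order = np.argsort(-(raw - out), kind="stable")
    for i in order[: total - out.sum()]:
        out[i] += 1
    return out.tolist()


def published_scale_config(seed: int,
                           center0: float = 250.0, slope: float = -13.73,
                           width_lo: float = 60.0, width_hi: float = 240.0,
                           ) -> SyntheticConfig:
    """A configuration at the scale of the published 1997-2017 otter record.

    Per-bin cell counts follow the published tally; in the four bins where
    the published shark cells do not sum to the published shark total, the
    total is taken as authoritative and redistributed over the cells by
    largest remainder (the non-shark cells are consistent and used as
    printed).  Season centres advance linearly (default -13.73 days per
    bin from day 250) and central-80% widths grow linearly (default 60 to
    240 days, i.e. ~2 to ~8 months) — the study conditions for seasonal
    expansion and advance.
    """
    cells = dict(OTTER_TALLY_CELLS_1997_2017)
    keys = [("M", "mature"), ("F", "mature"), ("M", "immature"), ("F", "immature")]
    for b, (shark_total, _ns) in OTTER_TALLY_TOTALS_1997_2017.items():
        printed = [cells[(b, s, m, "shark")] for s, m in keys]
        if sum(printed) != shark_total:
            for (s, m), n in zip(keys, _largest_remainder(printed, shark_total)):
                cells[(b, s, m, "shark")] = n
    n_bins = len(OTTER_TALLY_TOTALS_1997_2017)
    centers = {b: center0 + slope * b for b in range(n_bins)}
    widths = {b: width_lo + (width_hi - width_lo) * b / (n_bins - 1)
              for b in range(n_bins)}
    return SyntheticConfig(seed=seed, n_bins=n_bins, cell_counts=cells,
                           season_center=centers, season_width80=widths)
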