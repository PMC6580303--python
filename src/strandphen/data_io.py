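"""Reading, validation, and aggregation of stranding-surveillance record streams.

Three delimited-text streams feed the analysis pipeline:

* **strandings** — one row per live-stranded animal (date, sex, age class,
  cause-of-stranding label, alive-at-recovery flag);
* **incidents** — a shark-incident log in the style of public shark-attack
  files (species, provocation, injury, region, date);
* **detections** — daily or weekly counts of individuals detected at
  monitored sites, per species.

This module also carries the published triennial tallies of California sea
otter live strandings (1997-2017), used as a reference input by the
demographic analyses, together with the inclusion/exclusion rules applied
before any demographic or seasonal inference: pups are always excluded, and
geriatric animals are excluded unless the stranding is shark-attributed.
"""

from __future__ import annotations

import datetime as _dt
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SEXES = ("M", "F", "unknown")
AGE_CLASSES = ("pup", "immature", "mature", "geriatric")
CAUSES = ("shark", "other")
DETECTION_SPECIES = ("shark", "seal", "human_incident")
CADENCES = ("daily", "weekly")

#: Published triennial tallies of California sea otter live strandings,
#: 1997-2017, by sex, maturity and shark attribution.  Keys are
#: (bin_index, sex, maturity, cause); bin 0 covers 1997-1999.
OTTER_TALLY_CELLS_1997_2017: Mapping[tuple[int, str, str, str], int] = {
    # bin 0: 1997-1999
    (0, "M", "mature", "shark"): 0, (0, "M", "mature", "other"): 3,
    (0, "M", "immature", "shark"): 0, (0, "M", "immature", "other"): 3,
    (0, "F", "mature", "shark"): 2, (0, "F", "mature", "other"): 3,
    (0, "F", "immature", "shark"): 2, (0, "F", "immature", "other"): 3,
    # bin 1: 2000-2002
    (1, "M", "mature", "shark"): 2, (1, "M", "mature", "other"): 5,
    (1, "M", "immature", "shark"): 1, (1, "M", "immature", "other"): 7,
    (1, "F", "mature", "shark"): 1, (1, "F", "mature", "other"): 10,
    (1, "F", "immature", "shark"): 1, (1, "F", "immature", "other"): 8,
    # bin 2: 2003-2005
    (2, "M", "mature", "shark"): 4, (2, "M", "mature", "other"): 12,
    (2, "M", "immature", "shark"): 1, (2, "M", "immature", "other"): 8,
    (2, "F", "mature", "shark"): 1, (2, "F", "mature", "other"): 21,
    (2, "F", "immature", "shark"): 1, (2, "F", "immature", "other"): 7,
    # bin 3: 2006-2008
    (3, "M", "mature", "shark"): 4, (3, "M", "mature", "other"): 9,
    (3, "M", "immature", "shark"): 2, (3, "M", "immature", "other"): 17,
    (3, "F", "mature", "shark"): 7, (3, "F", "mature", "other"): 13,
    (3, "F", "immature", "shark"): 0, (3, "F", "immature", "other"): 19,
    # bin 4: 2009-2011
    (4, "M", "mature", "shark"): 9, (4, "M", "mature", "other"): 10,
    (4, "M", "immature", "shark"): 3, (4, "M", "immature", "other"): 9,
    (4, "F", "mature", "shark"): 3, (4, "F", "mature", "other"): 14,
    (4, "F", "immature", "shark"): 4, (4, "F", "immature", "other"): 6,
    # bin 5: 2012-2014
    (5, "M", "mature", "shark"): 19, (5, "M", "mature", "other"): 13,
    (5, "M", "immature", "shark"): 4, (5, "M", "immature", "other"): 10,
    (5, "F", "mature", "shark"): 1, (5, "F", "mature", "other"): 17,
    (5, "F", "immature", "shark"): 7, (5, "F", "immature", "other"): 9,
    # bin 6: 2015-2017
    (6, "M", "mature", "shark"): 20, (6, "M", "mature", "other"): 15,
    (6, "M", "immature", "shark"): 17, (6, "M", "immature", "other"): 17,
    (6, "F", "mature", "shark"): 1, (6, "F", "mature", "other"): 15,
    (6, "F", "immature", "shark"): 9, (6, "F", "immature", "other"): 23,
}

#: Published per-bin totals of shark- and non-shark-attributed live
#: strandings (same bins as above).  Note: in four bins the published
#: sex-by-maturity shark cells do not sum to the published shark total;
#: ``tally_consistency_report`` surfaces those discrepancies.
OTTER_TALLY_TOTALS_1997_2017: Mapping[int, tuple[int, int]] = {
    0: (4, 12), 1: (4, 30), 2: (7, 48), 3: (7, 58),
    4: (23, 39), 5: (33, 49), 6: (47, 70),
}

#: Calendar labels of the triennial bins used for the published tallies.
TALLY_BIN_LABELS = ("1997-1999", "2000-2002", "2003-2005", "2006-2008",
                    "2009-2011", "2012-2014", "2015-2017")


class SchemaError(ValueError):
    """A required column is missing or a file-level contract is broken."""


@dataclass(frozen=True)
class RowIssue:
    """One row-level validation failure (machine-readable report entry)."""

    row: int            # 0-based data-row index (header excluded)
    field: str
    reason: str


@dataclass(frozen=True)
class StrandingRecord:
    """One live-stranding event."""

    date: _dt.date
    sex: str                      # M | F | unknown
    age_class: str                # pup | immature | mature | geriatric
    cause: str                    # shark | other
    alive_at_recovery: bool = True

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex {self.sex!r} not in {SEXES}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class {self.age_class!r} not in {AGE_CLASSES}")
        if self.cause not in CAUSES:
            raise ValueError(f"cause {self.cause!r} not in {CAUSES}")


@dataclass(frozen=True)
class IncidentRecord:
    """One entry from a shark-incident log."""

    date: _dt.date
    species_label: str
    provoked: bool
    injurious: bool
    region: str
    fatal: bool | None = None


@dataclass(frozen=True)
class DetectionSeries:
    """Ordered (date, count) pairs of detections for one species."""

    species: str                  # shark | seal | human_incident
    cadence: str                  # daily | weekly
    entries: tuple[tuple[_dt.date, int], ...]

    def __post_init__(self) -> None:
        if self.species not in DETECTION_SPECIES:
            raise ValueError(f"species {self.species!r} not in {DETECTION_SPECIES}")
        if self.cadence not in CADENCES:
            raise ValueError(f"cadence {self.cadence!r} not in {CADENCES}")
        dates = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("detection dates must be strictly increasing")
        if any(c < 0 for _, c in self.entries):
            raise ValueError("detection counts must be nonnegative")


@dataclass
class AggregatedCounts:
    """Per-bin cell counts and shark / non-shark totals (tally layout).

    ``quotient`` is the ratio shark_total / nonshark_total per bin — the
    convention of the published tally's "proportion shark bitten" column
    (e.g. 4/12 = 0.33).  ``fraction`` is the alternative definition
    shark_total / (shark_total + nonshark_total); both are exposed,
    clearly labelled.  Quotients are ``None`` where the denominator is 0.
    """

    cells: dict[tuple[int, str, str, str], int]
    bin_totals: dict[int, tuple[int, int]]        # bin -> (shark, nonshark)
    quotient: dict[int, float | None]
    fraction: dict[int, float | None]

    @property
    def grand_total(self) -> int:
        return sum(s + ns for s, ns in self.bin_totals.values())


# ---------------------------------------------------------------------------
# calendar helpers
# ---------------------------------------------------------------------------

def doy(date: _dt.date) -> int:
    """Day-of-year in [1, 366] (leap-aware; Jan 1 -> 1)."""
    return date.timetuple().tm_yday


def date_from_doy(year: int, day_of_year: int) -> _dt.date:
    """Inverse of :func:`doy` for a given year.

    Day 366 in a non-leap year maps to Dec 31 (day 365) so the result
    stays inside ``year``.
    """
    last = doy(_dt.date(year, 12, 31))
    return _dt.date(year, 1, 1) + _dt.timedelta(days=min(day_of_year, last) - 1)


def days_in_year(year: int) -> int:
    return doy(_dt.date(year, 12, 31))


# ---------------------------------------------------------------------------
# readers / writers (headered comma-separated text, ISO-8601 dates)
# ---------------------------------------------------------------------------

_STRANDING_COLUMNS = ("date", "sex", "age_class", "cause", "alive_at_recovery")
_INCIDENT_COLUMNS = ("date", "species_label", "provoked", "injurious", "region")
_DETECTION_COLUMNS = ("species", "cadence", "date", "count")

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(text: str) -> bool:
    t = str(text).strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _load_frame(path: str | Path, required: Sequence[str],
                column_map: Mapping[str, str] | None) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return frame


def read_strandings(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    ) -> tuple[list[StrandingRecord], list[RowIssue]]:
    """Read stranding records; invalid rows go to the issue report.

    ``column_map`` maps canonical field names to the file's column names.
    Unknown sex is retained but flagged in the report.
    """
    frame = _load_frame(path, _STRANDING_COLUMNS[:4], column_map)
    records: list[StrandingRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            date = _dt.date.fromisoformat(str(row.date).strip())
        except ValueError:
            issues.append(RowIssue(i, "date", f"unparseable date {row.date!r} (line {i + 2})"))
            continue
        sex = str(row.sex).strip()
        if sex not in SEXES:
            issues.append(RowIssue(i, "sex", f"sex {sex!r} not in {SEXES}"))
            continue
        if sex == "unknown":
            issues.append(RowIssue(i, "sex", "unknown sex retained but excluded "
                                             "from sex-stratified analyses"))
        age = str(row.age_class).strip()
        if age not in AGE_CLASSES:
            issues.append(RowIssue(i, "age_class", f"age_class {age!r} not in {AGE_CLASSES}"))
            continue
        cause = str(row.cause).strip()
        if cause not in CAUSES:
            issues.append(RowIssue(i, "cause", f"cause {cause!r} not in {CAUSES}"))
            continue
        alive = True
        if "alive_at_recovery" in frame.columns:
            try:
                alive = _parse_bool(getattr(row, "alive_at_recovery"))
            except ValueError as exc:
                issues.append(RowIssue(i, "alive_at_recovery", str(exc)))
                continue
        records.append(StrandingRecord(date, sex, age, cause, alive))
    return records, issues


def write_strandings(records: Iterable[StrandingRecord], path: str | Path) -> None:
    rows = [{"date": r.date.isoformat(), "sex": r.sex, "age_class": r.age_class,
             "cause": r.cause, "alive_at_recovery": r.alive_at_recovery}
            for r in records]
    pd.DataFrame(rows, columns=list(_STRANDING_COLUMNS)).to_csv(path, index=False)


def read_incidents(path: str | Path,
                   column_map: Mapping[str, str] | None = None,
                   ) -> tuple[list[IncidentRecord], list[RowIssue]]:
    """Read a shark-incident log (one row per human-shark interaction)."""
    frame = _load_frame(path, _INCIDENT_COLUMNS, column_map)
    records: list[IncidentRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            date = _dt.date.fromisoformat(str(row.date).strip())
            provoked = _parse_bool(row.provoked)
            injurious = _parse_bool(row.injurious)
            fatal = None
            if "fatal" in frame.columns and str(getattr(row, "fatal")).strip():
                fatal = _parse_bool(getattr(row, "fatal"))
        except ValueError as exc:
            issues.append(RowIssue(i, "-", f"{exc} (line {i + 2})"))
            continue
        records.append(IncidentRecord(date, str(row.species_label).strip(),
                                      provoked, injurious,
                                      str(row.region).strip(), fatal))
    return records, issues


def write_incidents(records: Iterable[IncidentRecord], path: str | Path) -> None:
    rows = [{"date": r.date.isoformat(), "species_label": r.species_label,
             "provoked": r.provoked, "injurious": r.injurious,
             "region": r.region, "fatal": "" if r.fatal is None else r.fatal}
            for r in records]
    pd.DataFrame(rows, columns=list(_INCIDENT_COLUMNS) + ["fatal"]).to_csv(path, index=False)


def read_detections(path: str | Path,
                    column_map: Mapping[str, str] | None = None,
                    ) -> list[DetectionSeries]:
    """Read detection series; one series per (species, cadence) pair."""
    frame = _load_frame(path, _DETECTION_COLUMNS, column_map)
    out: list[DetectionSeries] = []
    for (species, cadence), sub in frame.groupby(["species", "cadence"], sort=False):
        entries = tuple(
            (_dt.date.fromisoformat(str(d).strip()), int(c))
            for d, c in zip(sub["date"], sub["count"])
        )
        out.append(DetectionSeries(str(species), str(cadence), entries))
    return out


def write_detections(series: Iterable[DetectionSeries], path: str | Path) -> None:
    rows = [{"species": s.species, "cadence": s.cadence,
             "date": d.isoformat(), "count": c}
            for s in series for d, c in s.entries]
    pd.DataFrame(rows, columns=list(_DETECTION_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filtering, exclusions, binning, aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IncidentCriteria:
    """Inclusion criteria for the incident log.

    A record is retained only if the species label matches, the region
    matches, the interaction was unprovoked and injurious, and the year
    falls inside ``year_range`` (inclusive).
    """

    species_label: str = "white shark"
    region: str = "California"
    provoked: bool = False
    injurious: bool = True
    year_range: tuple[int, int] = (1997, 2018)

    def __post_init__(self) -> None:
        if not self.species_label or not self.region:
            raise ValueError("species_label and region must be non-empty")

    def matches(self, rec: IncidentRecord) -> bool:
        return (rec.species_label == self.species_label
                and rec.region == self.region
                and rec.provoked == self.provoked
                and rec.injurious == self.injurious
                and self.year_range[0] <= rec.date.year <= self.year_range[1])


def filter_incidents(records: Sequence[IncidentRecord],
                     criteria: IncidentCriteria) -> list[IncidentRecord]:
    """Retain exactly the incidents matching every criterion (order kept)."""
    return [r for r in records if criteria.matches(r)]


def apply_stranding_exclusions(records: Sequence[StrandingRecord]
                               ) -> list[StrandingRecord]:
    """Drop pups unconditionally and geriatrics unless shark-attributed.

    Pup and non-shark-bitten geriatric strandings arise from circumstances
    unique to those demographics and are excluded from all demographic and
    seasonal inference; a shark-bitten geriatric is retained.
    """
    out = []
    for r in records:
        if r.age_class == "pup":
            continue
        if r.age_class == "geriatric" and r.cause != "shark":
            continue
        out.append(r)
    return out


def assign_bins(records: Sequence[StrandingRecord], start_year: int = 1997,
                width_years: int = 3,
                ) -> tuple[OrderedDict[int, list[StrandingRecord]], list[RowIssue]]:
    """Group records into consecutive ``width_years``-year bins.

    A record from year *y* goes to bin ``(y - start_year) // width_years``.
    Records dated before ``start_year`` are excluded with a report entry,
    never silently.
    """
    if width_years < 1:
        raise ValueError("width_years must be >= 1")
    bins: OrderedDict[int, list[StrandingRecord]] = OrderedDict()
    issues: list[RowIssue] = []
    for i, r in enumerate(records):
        if r.date.year < start_year:
            issues.append(RowIssue(i, "date",
                                   f"year {r.date.year} precedes start_year {start_year}; "
                                   "record excluded"))
            continue
        b = (r.date.year - start_year) // width_years
        bins.setdefault(b, []).append(r)
    return OrderedDict(sorted(bins.items())), issues


def bin_label(bin_index: int, start_year: int = 1997, width_years: int = 3) -> str:
    lo = start_year + bin_index * width_years
    return f"{lo}-{lo + width_years - 1}"


def aggregate_counts(binned: Mapping[int, Sequence[StrandingRecord]]
                     ) -> AggregatedCounts:
    """Tally post-exclusion records into the published-table layout.

    Cells are (bin, sex, maturity, cause) counts over records with known
    sex and maturity in {immature, mature}; bin totals count *all* records
    in the bin, so unknown-sex records appear in totals but in no cell.
    """
    cells: dict[tuple[int, str, str, str], int] = {}
    bin_totals: dict[int, tuple[int, int]] = {}
    for b, recs in binned.items():
        shark = sum(1 for r in recs if r.cause == "shark")
        bin_totals[b] = (shark, len(recs) - shark)
        for r in recs:
            if r.sex in ("M", "F") and r.age_class in ("immature", "mature"):
                key = (b, r.sex, r.age_class, r.cause)
                cells[key] = cells.get(key, 0) + 1
    quotient = {b: (s / ns if ns else None) for b, (s, ns) in bin_totals.items()}
    fraction = {b: (s / (s + ns) if s + ns else None)
                for b, (s, ns) in bin_totals.items()}
    return AggregatedCounts(cells, bin_totals, quotient, fraction)


def tally_consistency_report(cells: Mapping[tuple[int, str, str, str], int],
                             totals: Mapping[int, tuple[int, int]]) -> list[str]:
    """Compare per-bin cell sums against separately stated totals.

    Returns one message per discrepancy.  The published 1997-2017 otter
    tally has four bins whose shark cells do not sum to the stated shark
    total; such inconsistencies are reported, never silently reconciled.
    """
    report = []
    for b, (shark_tot, nonshark_tot) in sorted(totals.items()):
        for cause, stated in (("shark", shark_tot), ("other", nonshark_tot)):
            got = sum(n for (bb, _s, _m, c), n in cells.items()
                      if bb == b and c == cause)
            if got != stated:
                report.append(f"bin {b}: {cause} cells sum to {got}, "
                              f"stated total is {stated}")
    return report


def records_from_counts(counts: Mapping[tuple[str, str], int],
                        year: int = 2000, cause: str = "shark",
                        ) -> list[StrandingRecord]:
    """Materialise individual records from (sex, maturity) -> count.

    Convenience for running record-level procedures (e.g. the sex-bias
    bootstrap) on published aggregate tallies; dates are placeholders.
    """
    out = []
    for (sex, maturity), n in counts.items():
        out.extend(StrandingRecord(_dt.date(year, 7, 1), sex, maturity, cause)
                   for _ in range(n))
    return out
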