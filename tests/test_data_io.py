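import datetime as dt

import pytest

from strandphen import data_io as dio
from strandphen import (
    IncidentCriteria,
    IncidentRecord,
    StrandingRecord,
    aggregate_counts,
    apply_stranding_exclusions,
    assign_bins,
    doy,
    filter_incidents,
    tally_consistency_report,
)


@pytest.mark.parametrize("date,expected", [
    (dt.date(1997, 1, 1), 1),
    (dt.date(2000, 12, 31), 366),   # leap year
    (dt.date(2017, 12, 31), 365),
    (dt.date(2017, 8, 15), 227),
])
def test_day_of_year(date, expected):
    assert doy(date) == expected
    assert dio.date_from_doy(date.year, expected) == date


def test_stranding_roundtrip(tmp_path, rec):
    records = [rec(), rec(sex="F", age_class="pup", cause="other"),
               rec(year=2016, age_class="geriatric")]
    path = tmp_path / "s.csv"
    dio.write_strandings(records, path)
    back, issues = dio.read_strandings(path)
    assert back == records and not issues


def test_incident_roundtrip(tmp_path):
    records = [IncidentRecord(dt.date(2001, 6, 1), "white shark", False, True,
                              "California", True),
               IncidentRecord(dt.date(2005, 9, 9), "tiger shark", True, False,
                              "Florida", None)]
    path = tmp_path / "i.csv"
    dio.write_incidents(records, path)
    back, issues = dio.read_incidents(path)
    assert back == records and not issues


def test_detection_roundtrip(tmp_path):
    series = dio.DetectionSeries(
        "seal", "weekly",
        ((dt.date(2010, 1, 4), 5), (dt.date(2010, 1, 11), 0)))
    path = tmp_path / "d.csv"
    dio.write_detections([series], path)
    assert dio.read_detections(path) == [series]


def test_row_validation_and_schema(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("date,sex,age_class,cause\n"
                    "2001-06-01,X,mature,shark\n"
                    "not-a-date,M,mature,shark\n"
                    "2001-06-01,M,mature,shark\n")
    records, issues = dio.read_strandings(path)
    assert len(records) == 1
    fields = {(i.row, i.field) for i in issues}
    assert (0, "sex") in fields and (1, "date") in fields
    assert any("line 3" in i.reason for i in issues)  # date error carries line no.

    bad = tmp_path / "bad.csv"
    bad.write_text("date,sex\n2001-06-01,M\n")
    with pytest.raises(dio.SchemaError):
        dio.read_strandings(bad)


def test_unknown_sex_retained_but_flagged(tmp_path):
    path = tmp_path / "s.csv"
    path.write_text("date,sex,age_class,cause\n2001-06-01,unknown,mature,shark\n")
    records, issues = dio.read_strandings(path)
    assert len(records) == 1 and records[0].sex == "unknown"
    assert issues and issues[0].field == "sex"


def test_exclusion_rules(rec):
    records = [rec(age_class="pup", cause="shark"),
               rec(age_class="pup", cause="other"),
               rec(age_class="geriatric", cause="shark"),
               rec(age_class="geriatric", cause="other"),
               rec(age_class="mature", cause="other"),
               rec(age_class="immature", cause="shark")]
    kept = apply_stranding_exclusions(records)
    # pups always go; geriatrics only survive if shark-bitten
    assert kept == [records[2], records[4], records[5]]


def test_bin_assignment_and_boundaries(rec):
    records = [rec(year=1997), rec(year=1999), rec(year=2000), rec(year=2017),
               rec(year=1995)]
    bins, issues = assign_bins(records, start_year=1997, width_years=3)
    assert [r.date.year for r in bins[0]] == [1997, 1999]
    assert bins[1][0].date.year == 2000
    assert bins[6][0].date.year == 2017
    assert len(issues) == 1 and "1995" in issues[0].reason  # not silent


def test_aggregation_conservation_and_quotients(rec):
    binned = {0: [rec(cause="shark")] * 4 + [rec(cause="other")] * 12,
              6: [rec(year=2016, cause="shark")] * 47
                 + [rec(year=2016, cause="other")] * 70,
              3: []}
    agg = aggregate_counts(binned)
    assert agg.bin_totals[0] == (4, 12) and round(agg.quotient[0], 2) == 0.33
    assert agg.bin_totals[6] == (47, 70) and round(agg.quotient[6], 2) == 0.67
    assert agg.quotient[3] is None and agg.fraction[3] is None
    assert agg.grand_total == 4 + 12 + 47 + 70
    assert round(agg.fraction[0], 2) == 0.25  # alternative definition, labelled


def test_incident_filter_and_idempotence():
    crit = IncidentCriteria(year_range=(1997, 2018))
    ok = IncidentRecord(dt.date(2001, 6, 1), "white shark", False, True, "California")
    records = [
        ok,
        IncidentRecord(dt.date(2001, 6, 1), "white shark", True, True, "California"),
        IncidentRecord(dt.date(2001, 6, 1), "white shark", False, False, "California"),
        IncidentRecord(dt.date(2001, 6, 1), "tiger shark", False, True, "California"),
        IncidentRecord(dt.date(2005, 3, 2), "white shark", False, True, "California"),
    ]
    kept = filter_incidents(records, crit)
    assert kept == [records[0], records[4]]
    assert filter_incidents(kept, crit) == kept  # idempotent
    assert filter_incidents([records[1]] * 3, crit) == []


def test_published_tally_inconsistencies_surface():
    report = tally_consistency_report(dio.OTTER_TALLY_CELLS_1997_2017,
                                      dio.OTTER_TALLY_TOTALS_1997_2017)
    flagged = {int(line.split()[1][:-1]) for line in report}
    assert flagged == {1, 3, 4, 5}          # the four shark-cell mismatches
    assert all("shark" in line for line in report)
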