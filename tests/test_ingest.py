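"""FAERS-dialect parsing, deduplication and event filtering."""

import math
import warnings

import pandas as pd
import pytest

from pvsignal import SchemaError, deduplicate, filter_event, read_quarter
from pvsignal.ingest import (
    age_to_years,
    filter_window,
    parse_faers_dates,
    quarter_bounds,
    write_quarter,
)

MODERN_DEMO = """primaryid$caseid$caseversion$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$occp_cod$reporter_country
1001$501$1$20230115$20221201$55$YR$F$70$KG$MD$United States
1002$502$1$20230220$$24$MON$M$154$LBS$CN$Japan
"""
MODERN_DRUG = """primaryid$drug_seq$role_cod$drugname
1001$1$PS$ATORVASTATIN CALCIUM 20MG
1001$2$SS$NITROFURANTOIN
1002$1$PS$MINOCYCLINE
1002$2$C$IBUPROFEN
"""
MODERN_REAC = """primaryid$pt
1001$Autoimmune hepatitis
1001$Nausea
1002$Rash
"""
MODERN_OUTC = """primaryid$outc_cod
1001$HO
1001$OT
1002$DE
"""
MODERN_THER = """primaryid$dsg_drug_seq$start_dt
1001$1$20221001
"""


def _write(tmp_path, contents):
    paths = {}
    for name, text in contents.items():
        p = tmp_path / f"{name.upper()}.txt"
        p.write_text(text)
        paths[name] = p
    return paths


@pytest.fixture()
def modern_paths(tmp_path):
    return _write(tmp_path, {
        "demo": MODERN_DEMO, "drug": MODERN_DRUG, "reac": MODERN_REAC,
        "outc": MODERN_OUTC, "ther": MODERN_THER,
    })


class TestReadQuarter:
    def test_row_counts_equal_record_counts(self, modern_paths):
        data = read_quarter(modern_paths)
        assert len(data.reports) == 2
        assert len(data.mentions) == 4
        assert len(data.reactions) == 3

    def test_field_parsing(self, modern_paths):
        r = read_quarter(modern_paths).reports.set_index("primaryid")
        assert r.loc["1001", "sex"] == "female"
        assert r.loc["1001", "age_years"] == 55.0
        assert r.loc["1002", "age_years"] == pytest.approx(2.0)
        assert r.loc["1002", "weight_kg"] == pytest.approx(154 * 0.453592)
        assert r.loc["1001", "reporter_occupation"] == "Physician"
        assert r.loc["1001", "outcomes"] == {"hospitalization", "other serious"}
        assert r.loc["1002", "outcomes"] == {"death"}
        assert pd.isna(r.loc["1002", "event_date"])

    def test_role_code_passthrough_and_therapy_join(self, modern_paths):
        m = read_quarter(modern_paths).mentions
        assert list(m["role"]) == ["PS", "SS", "PS", "C"]
        joined = m.set_index(["primaryid", "drug_seq"])
        assert joined.loc[("1001", 1.0), "start_date"] == pd.Timestamp("2022-10-01")
        assert pd.isna(joined.loc[("1002", 1.0), "start_date"])

    def test_missing_mandatory_column_names_it(self, tmp_path):
        paths = _write(tmp_path, {
            "demo": "primaryid$caseid$caseversion\n1$1$1\n",
            "drug": MODERN_DRUG, "reac": MODERN_REAC,
        })
        with pytest.raises(SchemaError, match="fda_dt"):
            read_quarter(paths)

    def test_empty_file_warns_and_yields_empty(self, tmp_path):
        paths = _write(tmp_path, {
            "demo": "", "drug": MODERN_DRUG, "reac": MODERN_REAC,
        })
        with pytest.warns(UserWarning, match="empty file"):
            data = read_quarter(paths)
        assert data.reports.empty

    def test_legacy_layout(self, tmp_path):
        paths = _write(tmp_path, {
            "demo": ("isr$case$fda_dt$event_dt$age$age_cod$gndr_cod$wt$wt_cod"
                     "$occp_cod$reporter_country\n"
                     "7001$401$20080115$2007$60$YR$M$80$KG$PH$France\n"),
            "drug": "isr$drug_seq$role_cod$drugname\n7001$1$PS$HYDRALAZINE\n",
            "reac": "isr$pt\n7001$Autoimmune hepatitis\n",
        })
        data = read_quarter(paths, layout="legacy")
        r = data.reports.iloc[0]
        assert r["primaryid"] == "7001"
        assert r["case_version"] == 0
        assert r["sex"] == "male"
        assert r["event_date"] == pd.Timestamp("2007-01-01")
        assert r["reporter_occupation"] == "Pharmacist"


class TestDates:
    @pytest.mark.parametrize("raw,expected", [
        ("20230115", "2023-01-15"),
        ("202303", "2023-03-01"),
        ("2021", "2021-01-01"),
    ])
    def test_partial_dates_resolve_to_period_start(self, raw, expected):
        out = parse_faers_dates(pd.Series([raw]))
        assert out.iloc[0] == pd.Timestamp(expected)

    @pytest.mark.parametrize("raw", ["99999999", "20231345", "abc", "", "20"])
    def test_unparseable_dates_become_missing(self, raw):
        assert parse_faers_dates(pd.Series([raw])).isna().all()


class TestAgeConversion:
    @pytest.mark.parametrize("value,unit,expected", [
        (55, "YR", 55.0),
        (24, "MON", 2.0),
        (5.5, "DEC", 55.0),
        (104, "WK", 2.0),
        (730.5, "DY", 2.0),
        (8766, "HR", 1.0),
    ])
    def test_unit_conversion(self, value, unit, expected):
        assert age_to_years(value, unit) == pytest.approx(expected)

    @pytest.mark.parametrize("value,unit", [
        (300, "YR"), (-1, "YR"), (15, "DEC"), (55, "XX"), (float("nan"), "YR"),
    ])
    def test_implausible_or_unknown_becomes_missing(self, value, unit):
        assert math.isnan(age_to_years(value, unit))


def _reports(rows):
    df = pd.DataFrame(rows, columns=["primaryid", "caseid", "case_version",
                                     "fda_receipt_date"])
    df["fda_receipt_date"] = pd.to_datetime(df["fda_receipt_date"])
    return df


class TestDeduplicate:
    def test_latest_version_wins(self):
        df = _reports([("1111", "111", 1, "2020-01-01"),
                       ("1112", "111", 2, "2020-02-01")])
        out = deduplicate(df)
        assert list(out["primaryid"]) == ["1112"]

    def test_distinct_cases_both_kept(self):
        df = _reports([("1", "a", 1, "2020-01-01"), ("2", "b", 1, "2020-01-01")])
        assert len(deduplicate(df)) == 2

    def test_identical_duplicates_collapse_to_one(self):
        df = _reports([("1", "a", 1, "2020-01-01"), ("1", "a", 1, "2020-01-01")])
        assert len(deduplicate(df)) == 1

    def test_version_tie_breaks_by_date_then_numeric_primaryid(self):
        df = _reports([("9", "a", 1, "2020-01-01"),
                       ("10", "a", 1, "2020-03-01"),
                       ("2", "a", 1, "2020-03-01")])
        assert list(deduplicate(df)["primaryid"]) == ["10"]

    def test_idempotent(self):
        df = _reports([("1111", "111", 1, "2020-01-01"),
                       ("1112", "111", 2, "2020-02-01"),
                       ("3", "b", 1, "2019-01-01")])
        once = deduplicate(df)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)


class TestFilterEvent:
    def test_returns_ids_of_matching_reports(self):
        reac = pd.DataFrame({
            "primaryid": ["1", "2", "3", "4", "5"],
            "pt": ["Autoimmune hepatitis", "Nausea", "autoimmune  HEPATITIS",
                   "Rash", "Hepatitis"],
        })
        assert filter_event(reac, "autoimmune hepatitis") == {"1", "3"}

    def test_empty_reaction_table(self):
        reac = pd.DataFrame(columns=["primaryid", "pt"])
        assert filter_event(reac, "autoimmune hepatitis") == set()

    def test_blank_target_rejected(self):
        with pytest.raises(ValueError):
            filter_event(pd.DataFrame(columns=["primaryid", "pt"]), "  ")


class TestWindow:
    def test_quarter_bounds(self):
        lo, hi = quarter_bounds("2004Q1")
        assert lo == pd.Timestamp("2004-01-01")
        assert hi == pd.Timestamp("2004-03-31")

    def test_membership_changes_but_fields_do_not(self):
        df = _reports([("1", "a", 1, "2003-12-31"), ("2", "b", 1, "2004-02-01")])
        out = filter_window(df, "2004Q1", "2024Q1")
        assert list(out["primaryid"]) == ["2"]
        pd.testing.assert_series_equal(
            out.iloc[0], df.iloc[1], check_names=False
        )


class TestRoundTrip:
    def test_write_then_read_preserves_fields(self, planted_data, tmp_path):
        sample = planted_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            paths = write_quarter(sample.as_quarter(), tmp_path)
        back = read_quarter(
            {k: v for k, v in paths.items()
             if k in ("demo", "drug", "reac", "outc", "ther")}
        )
        orig = sample.reports.reset_index(drop=True)
        got = back.reports.reset_index(drop=True)
        for col in ["primaryid", "caseid", "case_version", "fda_receipt_date",
                    "event_date", "sex", "age_years", "reporter_occupation",
                    "reporter_country", "outcomes"]:
            pd.testing.assert_series_equal(
                got[col], orig[col], check_names=False, check_dtype=False,
                obj=col,
            )
        assert got["weight_kg"].round(4).equals(orig["weight_kg"].round(4))
        m_orig = sample.mentions.sort_values(
            ["primaryid", "drug_seq"], ignore_index=True)
        m_got = back.mentions.sort_values(
            ["primaryid", "drug_seq"], ignore_index=True)
        for col in ["primaryid", "raw_name", "role", "start_date"]:
            pd.testing.assert_series_equal(
                m_got[col], m_orig[col], check_names=False, check_dtype=False,
                obj=col,
            )
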