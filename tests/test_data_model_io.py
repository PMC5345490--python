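"""Domain types, CSV round-trips, and validation totality."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from urchin_repro import (
    FertilityAssay,
    PipelineConfig,
    QuadratCount,
    RecordValidationError,
    SchemaError,
    SizeBin,
    SizeClassScheme,
    UrchinRecord,
)
from urchin_repro.data_model_io import (
    month_index,
    month_range,
    read_quadrat_counts,
    read_urchin_records,
    round_half_up,
    write_quadrat_counts,
    write_urchin_records,
)


# ---------------------------------------------------------------------------
# months
# ---------------------------------------------------------------------------

def test_month_arithmetic():
    assert month_index("2014-01") - month_index("2013-12") == 1
    assert month_range("2013-11", "2014-02") == ["2013-11", "2013-12", "2014-01", "2014-02"]
    with pytest.raises(ValueError):
        UrchinRecord(record_id="x", zone="HP", month="2013-13",
                     test_diameter=50, total_wet_weight=50, gonad_wet_weight=1)


# ---------------------------------------------------------------------------
# size bins / scheme
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "label,lower,upper",
    [("40-50", 40, 50), ("60+", 60, None), (" 40 – 50 ", 40, 50), ("0-10", 0, 10)],
)
def test_bin_label_dialect(label, lower, upper):
    b = SizeBin.parse(label)
    assert (b.lower, b.upper) == (lower, upper)


def test_bins_are_half_open():
    b = SizeBin(lower=40, upper=50)
    assert b.contains(40) and b.contains(49.999) and not b.contains(50)
    top = SizeBin(lower=60, upper=None)
    assert top.contains(1000)


def test_scheme_rejects_non_contiguous_bins():
    with pytest.raises(ValueError, match="contiguous"):
        SizeClassScheme(census_bins=[SizeBin(lower=0, upper=10), SizeBin(lower=20, upper=None)])


# ---------------------------------------------------------------------------
# record invariants
# ---------------------------------------------------------------------------

def test_gonad_cannot_exceed_total_weight():
    with pytest.raises(ValueError, match="exceeds total"):
        UrchinRecord(record_id="r1", zone="HP", month="2013-06",
                     test_diameter=50, total_wet_weight=4.0, gonad_wet_weight=5.0)


def test_fertility_assay_invariants():
    with pytest.raises(ValueError):
        FertilityAssay(zone="HP", month="2014-01", eggs_total=100, eggs_fertilized=101)
    # pluteus counts must come in pairs
    with pytest.raises(ValueError, match="together"):
        FertilityAssay(zone="HP", month="2014-01", eggs_total=100, eggs_fertilized=90,
                       plutei_scored=10)
    ok = FertilityAssay(zone="HP", month="2014-01", eggs_total=100, eggs_fertilized=90)
    assert ok.plutei_scored is None


def test_negative_quadrat_count_is_located():
    with pytest.raises(ValueError, match="q7"):
        QuadratCount(zone="HP", quadrat_id="q7", counts={"40-50": -1})


# ---------------------------------------------------------------------------
# CSV readers: totality and located errors
# ---------------------------------------------------------------------------

def test_read_urchins_well_formed(tmp_path, config):
    p = tmp_path / "u.csv"
    p.write_text(
        "record_id,zone,area,month,td_mm,tw_g,gw_g,sex\n"
        "r1,HP,A,2013-06,52.0,60.0,3.0,F\n"
        "r2,HP,A,2013-06,45.0,40.0,2.0,M\n"
        "r3,HP,B,2013-07,35.0,20.0,0.5,\n"
    )
    recs = read_urchin_records(p, config)
    assert len(recs) == 3
    assert recs[2].sex == "unknown"


def test_read_urchins_invalid_row_names_record(tmp_path, config):
    p = tmp_path / "u.csv"
    p.write_text(
        "record_id,zone,area,month,td_mm,tw_g,gw_g,sex\n"
        "bad1,HP,A,2013-06,52.0,4.0,5.0,F\n"
    )
    with pytest.raises(RecordValidationError, match="bad1"):
        read_urchin_records(p, config)


def test_read_urchins_missing_column(tmp_path, config):
    p = tmp_path / "u.csv"
    p.write_text("record_id,zone,month,td_mm,tw_g,gw_g,sex\n")
    with pytest.raises(SchemaError, match="area"):
        read_urchin_records(p, config)


def test_read_urchins_header_only(tmp_path, config, caplog):
    p = tmp_path / "u.csv"
    p.write_text("record_id,zone,area,month,td_mm,tw_g,gw_g,sex\n")
    import logging

    with caplog.at_level(logging.WARNING):
        assert read_urchin_records(p, config) == []
    assert any("header only" in r.message for r in caplog.records)


def test_read_quadrats_dialect_and_errors(tmp_path, config):
    p = tmp_path / "q.csv"
    p.write_text(
        "zone,area,quadrat_id,area_m2,0-10,10-20,20-30,30-40,40-50,50-60,60+\n"
        "HP,A,q1,0.25,0,0,0,0,2,1,0\n"
    )
    (q,) = read_quadrat_counts(p, config)
    assert q.counts["40-50"] == 2 and q.counts["50-60"] == 1
    assert q.quadrat_area == 0.25

    bad = tmp_path / "bad.csv"
    bad.write_text("zone,area,quadrat_id,40-50\nHP,A,q9,-1\n")
    with pytest.raises(RecordValidationError, match="q9"):
        read_quadrat_counts(bad, config)

    unknown = tmp_path / "unk.csv"
    unknown.write_text("zone,area,quadrat_id,45-55\nHP,A,q1,0\n")
    with pytest.raises(SchemaError, match="45-55"):
        read_quadrat_counts(unknown, config)


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

record_strategy = st.builds(
    UrchinRecord,
    record_id=st.text(alphabet="abcdefgh0123456789", min_size=1, max_size=8),
    zone=st.sampled_from(["HP", "LP"]),
    area=st.sampled_from(["A", "B"]),
    month=st.sampled_from([f"2013-{m:02d}" for m in range(6, 13)]),
    test_diameter=st.floats(min_value=10, max_value=90, allow_nan=False),
    total_wet_weight=st.floats(min_value=1, max_value=200, allow_nan=False),
    gonad_wet_weight=st.just(0.0),
    sex=st.sampled_from(["F", "M", "unknown"]),
)


@given(st.lists(record_strategy, min_size=1, max_size=12))
def test_urchin_round_trip_identity(tmp_path_factory, records):
    """Write-then-read is the identity on every field."""
    # gonad weight must respect the invariant; derive it from total weight
    records = [
        r.model_copy(update={"gonad_wet_weight": r.total_wet_weight * 0.05})
        for r in records
    ]
    path = tmp_path_factory.mktemp("rt") / "u.csv"
    write_urchin_records(records, path)
    back = read_urchin_records(path)
    assert back == records


def test_quadrat_round_trip(tmp_path, config):
    qs = [
        QuadratCount(zone="HP", area="A", quadrat_id=f"q{i}", replicate="r1",
                     quadrat_area=0.25,
                     counts={label: (i + j) % 3 for j, label in enumerate(config.scheme.bin_labels)})
        for i in range(4)
    ]
    path = tmp_path / "q.csv"
    write_quadrat_counts(qs, path, config)
    assert read_quadrat_counts(path, config) == qs


# ---------------------------------------------------------------------------
# rounding convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "value,dec,expected",
    [(0.1134, 2, 0.11), (0.1917, 2, 0.19), (0.2197, 2, 0.22), (0.10985, 2, 0.11),
     (0.095, 2, 0.10), (70.4545, 1, 70.5), (0.025, 2, 0.03), (73.15, 1, 73.2)],
)
def test_round_half_up(value, dec, expected):
    assert round_half_up(value, dec) == pytest.approx(expected)
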