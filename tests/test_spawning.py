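"""Spawning-event detection and per-event statistics.

The detector's output is checked against declarative event axioms rather
than a re-implementation: within each event the pre value is the slice
maximum and the post value the slice minimum (earliest ties); every event
drops by at least the threshold; events are disjoint and time-ordered;
and completeness — outside the detected spans there is no
(slice-max, slice-min) pair that drops by the threshold.
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from urchin_repro import DomainError, detect_events, individual_gamete_output, spawning_magnitude
from urchin_repro.data_model_io import EventDetectionParams, month_from_index
from urchin_repro.spawning import SpawningEvent, events_frame

from conftest import make_series


# ---------------------------------------------------------------------------
# per-event statistics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pre,post,igo",
    [(4.4, 1.3, 0.031), (6.6, 1.6, 0.050), (5.2, 1.0, 0.042), (5.4, 2.5, 0.029)],
)
def test_individual_gamete_output(pre, post, igo):
    assert individual_gamete_output(pre, post) == pytest.approx(igo)


@pytest.mark.parametrize(
    "pre,post,mag",
    [(4.4, 1.3, 70.45454545), (4.0, 1.2, 70.0), (6.6, 1.6, 75.75757575),
     (5.2, 1.0, 80.76923077), (6.7, 2.5, 62.68656716), (5.4, 2.5, 53.70370370),
     (5.0, 0.0, 100.0)],
)
def test_spawning_magnitude(pre, post, mag):
    assert spawning_magnitude(pre, post) == pytest.approx(mag)


def test_no_decline_is_a_domain_error():
    with pytest.raises(DomainError):
        individual_gamete_output(5.0, 5.0)
    with pytest.raises(DomainError):
        spawning_magnitude(0.0, 0.0)
    with pytest.raises(DomainError):
        spawning_magnitude(3.0, 4.0)


@given(
    pre=st.floats(min_value=0.5, max_value=12, allow_nan=False),
    frac=st.floats(min_value=0.01, max_value=0.99, allow_nan=False),
)
def test_magnitude_igo_consistency(pre, frac):
    """magnitude == 100 * (100 * igo) / pre for every decline."""
    post = pre * (1 - frac)
    igo = individual_gamete_output(pre, post)
    mag = spawning_magnitude(pre, post)
    assert abs(mag - 100.0 * (100.0 * igo) / pre) < 1e-9


# ---------------------------------------------------------------------------
# detection on reference shapes
# ---------------------------------------------------------------------------

def test_hp_shape_yields_one_event(hp_cs_series):
    (e,) = detect_events(hp_cs_series)
    assert (e.start_month, e.end_month) == ("2014-03", "2014-05")
    assert (e.pre_gsi, e.post_gsi) == (6.6, 1.6)


def test_lp_shape_yields_two_events(lp_cs_series):
    e1, e2 = detect_events(lp_cs_series)
    assert (e1.start_month, e1.end_month, e1.pre_gsi, e1.post_gsi) == ("2013-06", "2013-12", 6.7, 2.5)
    assert (e2.start_month, e2.end_month, e2.pre_gsi, e2.post_gsi) == ("2014-02", "2014-04", 5.4, 2.5)


def test_flat_and_monotone_series_have_no_events():
    months = [f"2013-{m:02d}" for m in range(6, 12)]
    assert detect_events(make_series(months, [4.0] * 6)) == []
    assert detect_events(make_series(months, [1, 2, 3, 4, 5, 6])) == []


def test_short_series_rejected():
    with pytest.raises(DomainError):
        detect_events(make_series(["2013-06", "2013-07"], [5.0, 1.0]))


def test_subthreshold_wiggle_ignored():
    """A 20% dip during build-up neither starts nor splits an event."""
    months = [f"2013-{m:02d}" for m in range(1, 9)]
    means = [4.0, 5.0, 4.1, 5.5, 6.0, 6.6, 3.5, 1.6]
    (e,) = detect_events(make_series(months, means))
    assert e.pre_gsi == 6.6 and e.post_gsi == 1.6


def test_ties_resolve_to_earliest_month():
    months = [f"2013-{m:02d}" for m in range(1, 8)]
    means = [2.0, 6.0, 6.0, 4.0, 1.5, 1.5, 1.6]
    (e,) = detect_events(make_series(months, means))
    assert e.start_month == "2013-02"
    assert e.end_month == "2013-05"


def test_gap_robustness(lp_cs_series):
    """Deleting a non-extremal month leaves pre/post months unchanged."""
    ref = [(e.start_month, e.end_month) for e in detect_events(lp_cs_series)]
    pts = dict(lp_cs_series.points)
    del pts["2013-10"]
    thinned = make_series(list(pts), [p.mean for p in pts.values()], zone="LP")
    assert [(e.start_month, e.end_month) for e in detect_events(thinned)] == ref


def test_detection_invariant_to_outside_months(hp_cs_series):
    """Months added outside the peak..trough span that create no new
    extremum do not change the detected events."""
    ref = [(e.start_month, e.end_month, e.pre_gsi, e.post_gsi)
           for e in detect_events(hp_cs_series)]
    pts = dict(hp_cs_series.points)
    extended = make_series(
        ["2013-04", "2013-05"] + list(pts) + ["2014-06"],
        [5.3, 5.4] + [p.mean for p in pts.values()] + [1.7],
    )
    assert [(e.start_month, e.end_month, e.pre_gsi, e.post_gsi)
            for e in detect_events(extended)] == ref


def test_min_duration_filter(hp_cs_series):
    params = EventDetectionParams(min_duration_months=3)
    assert detect_events(hp_cs_series, params) == []  # Mar-May spans 2 steps


def test_interpolated_gap_context():
    """With interpolation on, a single-month gap is filled for context but
    events still carry real months."""
    months = ["2013-01", "2013-02", "2013-04", "2013-05"]
    means = [2.0, 6.0, 3.0, 1.0]
    params = EventDetectionParams(interpolate_gaps=True)
    (e,) = detect_events(make_series(months, means), params)
    assert (e.start_month, e.end_month) == ("2013-02", "2013-05")


# ---------------------------------------------------------------------------
# event axioms (oracle)
# ---------------------------------------------------------------------------

def _axiom_check(months, means, events, thr_pct):
    idx = {m: i for i, m in enumerate(months)}
    thr = thr_pct / 100.0
    spans = []
    for e in events:
        i, j = idx[e.start_month], idx[e.end_month]
        assert i < j
        seg = means[i : j + 1]
        # pre is the slice max, post the slice min, earliest attainment
        assert e.pre_gsi == max(seg) and means.index(max(seg), i) == i
        assert e.post_gsi == min(seg) and seg.index(min(seg)) + i == j
        assert (e.pre_gsi - e.post_gsi) >= thr * e.pre_gsi - 1e-12
        spans.append((i, j))
    # disjoint and ordered
    for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
        assert b < c
    # completeness: no threshold-passing (slice-max, slice-min) pair
    # fully outside the detected spans
    bounds = [(-1, spans[0][0] if spans else len(means))]
    for (a, b), nxt in zip(spans, spans[1:] + [(len(means), len(means))]):
        bounds.append((b, nxt[0]))
    for lo, hi in bounds:
        region = range(max(lo, 0), min(hi + 1, len(means)))
        for i in region:
            for j in region:
                if i >= j:
                    continue
                seg = means[i : j + 1]
                if means[i] == max(seg) and means[j] == min(seg) and means[i] > 0:
                    assert (means[i] - means[j]) < thr * means[i], (
                        f"missed decline {months[i]}..{months[j]}"
                    )


@given(
    means=st.lists(
        st.floats(min_value=0.0, max_value=12.0, allow_nan=False).map(lambda x: round(x, 3)),
        min_size=3,
        max_size=14,
    )
)
def test_detected_events_satisfy_axioms(means):
    months = [month_from_index(2013 * 12 + k) for k in range(len(means))]
    series = make_series(months, means)
    events = detect_events(series)
    _axiom_check(months, means, events, 30.0)


def test_events_frame_columns(hp_cs_series):
    df = events_frame(detect_events(hp_cs_series))
    assert list(df.columns) == ["zone", "size_class", "start_month", "end_month",
                                "pre_gsi", "post_gsi", "igo", "magnitude_pct"]
    assert df.loc[0, "magnitude_pct"] == pytest.approx(75.7575757575)
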