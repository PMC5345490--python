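"""Spawning-event detection and per-event statistics.

A spawning event is a sustained decline of a stratum's monthly mean GSI
from a local peak (the pre-spawning month) to the subsequent trough (the
post-spawning month).  Per event:

* IGO, the mean individual gamete output, is the pre/post difference of
  mean GSI expressed as gonad mass per unit body mass:
  ``(pre - post) / 100`` in g g^-1 per spawning event;
* spawning magnitude is the fraction of pre-spawning gonad mass
  released: ``100 * (pre - post) / pre``, in percent.

Detection uses a reversal-confirmation (zigzag) scan on the mean values
only: starting from a running maximum, a decline is recognised once the
series has dropped by at least ``min_drop_pct`` percent of that maximum;
the decline then extends through any smaller rebounds, and ends at the
earliest minimum once the series rebounds by the same relative threshold
(or at the end of the series).  Month-to-month wiggles smaller than the
threshold therefore never start, split, or end an event.  Ties between
equal extremes resolve to the earliest month.  Missing months are simply
skipped (the series is treated as irregularly spaced); optional linear
interpolation of single-month gaps exists but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .data_model_io import (
    DomainError,
    EventDetectionParams,
    PipelineConfig,
    month_from_index,
    month_index,
)
from .gsi import GsiSeries


@dataclass(frozen=True)
class SpawningEvent:
    """A pre-peak to post-trough GSI decline with its derived statistics."""

    zone: str
    size_class: str
    start_month: str
    end_month: str
    pre_gsi: float
    post_gsi: float

    def __post_init__(self) -> None:
        if not self.pre_gsi > self.post_gsi >= 0:
            raise ValueError(
                f"event requires pre > post >= 0, got ({self.pre_gsi}, {self.post_gsi})"
            )
        if month_index(self.start_month) >= month_index(self.end_month):
            raise ValueError(
                f"event start {self.start_month} must precede end {self.end_month}"
            )

    @property
    def igo(self) -> float:
        """Individual gamete output, g g^-1 per spawning event."""
        return individual_gamete_output(self.pre_gsi, self.post_gsi)

    @property
    def magnitude(self) -> float:
        """Spawning magnitude, percent of pre-spawning gonad mass released."""
        return spawning_magnitude(self.pre_gsi, self.post_gsi)


def individual_gamete_output(pre_gsi: float, post_gsi: float) -> float:
    """(pre - post)/100 in g g^-1; requires an actual decline."""
    if post_gsi < 0:
        raise DomainError(f"post-spawning GSI must be nonnegative, got {post_gsi}")
    if pre_gsi <= post_gsi:
        raise DomainError(
            f"no spawning decline: pre {pre_gsi} must exceed post {post_gsi}"
        )
    return (pre_gsi - post_gsi) / 100.0


def spawning_magnitude(pre_gsi: float, post_gsi: float) -> float:
    """100 x (pre - post)/pre in percent; requires pre > post >= 0."""
    if pre_gsi <= 0:
        raise DomainError(f"pre-spawning GSI must be positive, got {pre_gsi}")
    if post_gsi < 0:
        raise DomainError(f"post-spawning GSI must be nonnegative, got {post_gsi}")
    if pre_gsi <= post_gsi:
        raise DomainError(
            f"no spawning decline: pre {pre_gsi} must exceed post {post_gsi}"
        )
    return 100.0 * (pre_gsi - post_gsi) / pre_gsi


def _interpolate_single_gaps(months: list[str], values: list[float]) -> tuple[list[str], list[float]]:
    """Fill single-month gaps linearly (context for detection only)."""
    out_m, out_v = [months[0]], [values[0]]
    for m, v in zip(months[1:], values[1:]):
        prev_idx = month_index(out_m[-1])
        if month_index(m) - prev_idx == 2:
            out_m.append(month_from_index(prev_idx + 1))
            out_v.append((out_v[-1] + v) / 2.0)
        out_m.append(m)
        out_v.append(v)
    return out_m, out_v


def detect_events(
    series: GsiSeries,
    config: Optional[Union[PipelineConfig, EventDetectionParams]] = None,
) -> list[SpawningEvent]:
    """Detect spawning events in a monthly GSI series.

    Returns disjoint, time-ordered events; a monotone non-decreasing or
    flat series yields an empty list.  Requires at least 3 months.
    """
    if config is None:
        params = EventDetectionParams()
    elif isinstance(config, PipelineConfig):
        params = config.detection
    else:
        params = config
    if len(series) < 3:
        raise DomainError(
            f"series ({series.zone!r}, {series.size_class!r}) has {len(series)} months; "
            "need at least 3"
        )
    months = series.months
    values = series.means
    if params.interpolate_gaps:
        months, values = _interpolate_single_gaps(months, values)

    thr = params.min_drop_pct / 100.0
    pivots: list[tuple[int, int]] = []  # (index, +1 peak / -1 trough)
    trend = 0  # 0 unknown, +1 seeking peak, -1 seeking trough
    ext = 0  # index of current running extreme
    for k in range(1, len(values)):
        v = values[k]
        if trend >= 0:
            if v > values[ext]:
                ext = k
            elif values[ext] > 0 and (values[ext] - v) >= thr * values[ext]:
                pivots.append((ext, +1))
                trend, ext = -1, k
        else:
            if v < values[ext]:
                ext = k
            elif v > 0 and (v - values[ext]) >= thr * v:
                pivots.append((ext, -1))
                trend, ext = +1, k
    if trend < 0:
        pivots.append((ext, -1))

    events: list[SpawningEvent] = []
    for (pi, pk), (ti, tk) in zip(pivots[:-1], pivots[1:]):
        if pk == +1 and tk == -1:
            if month_index(months[ti]) - month_index(months[pi]) < params.min_duration_months:
                continue
            events.append(
                SpawningEvent(
                    zone=series.zone,
                    size_class=series.size_class,
                    start_month=months[pi],
                    end_month=months[ti],
                    pre_gsi=values[pi],
                    post_gsi=values[ti],
                )
            )
    return events


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def events_frame(events: Sequence[SpawningEvent]) -> pd.DataFrame:
    rows = [
        {
            "zone": e.zone, "size_class": e.size_class,
            "start_month": e.start_month, "end_month": e.end_month,
            "pre_gsi": e.pre_gsi, "post_gsi": e.post_gsi,
            "igo": e.igo, "magnitude_pct": e.magnitude,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["zone", "size_class", "start_month", "end_month",
                 "pre_gsi", "post_gsi", "igo", "magnitude_pct"],
    )


def write_events(events: Sequence[SpawningEvent], path) -> None:
    events_frame(events).to_csv(path, index=False)


def read_events(path) -> list[SpawningEvent]:
    df = pd.read_csv(path, dtype={"zone": str, "size_class": str,
                                  "start_month": str, "end_month": str})
    return [
        SpawningEvent(
            zone=str(r["zone"]), size_class=str(r["size_class"]),
            start_month=str(r["start_month"]), end_month=str(r["end_month"]),
            pre_gsi=float(r["pre_gsi"]), post_gsi=float(r["post_gsi"]),
        )
        for _, r in df.iterrows()
    ]
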