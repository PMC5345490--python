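"""Gonadosomatic index: per-individual values and monthly stratum series.

GSI = 100 x gonad wet weight / total wet weight, a percentage used as a
proxy for reproductive investment.  Individuals are stratified by zone and
named size class; within a stratum, sexes are pooled by default and each
calendar month contributes one mean +- standard error point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .data_model_io import (
    EmptySeriesError,
    DomainError,
    PipelineConfig,
    SizeClassScheme,
    UrchinRecord,
    month_index,
    month_range,
)


class GsiPoint(NamedTuple):
    mean: float
    se: float
    n: int


@dataclass
class GsiSeries:
    """Monthly mean +- SE GSI for one (zone, size class) stratum.

    ``points`` maps month -> (mean, se, n) and is kept sorted by month;
    ``gap_months`` lists calendar months inside the sampled span with no
    records (the series is otherwise treated as irregularly spaced).
    """

    zone: str
    size_class: str
    points: dict[str, GsiPoint]
    gap_months: frozenset[str] = field(default_factory=frozenset)
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = dict(sorted(self.points.items(), key=lambda kv: month_index(kv[0])))
        for month, p in self.points.items():
            if p.mean < 0 or p.se < 0 or p.n < 1:
                raise ValueError(f"invalid GSI point at {month}: {p}")

    @property
    def months(self) -> list[str]:
        return list(self.points)

    @property
    def means(self) -> list[float]:
        return [p.mean for p in self.points.values()]

    def __len__(self) -> int:
        return len(self.points)


def gsi_value(gonad_wet_weight: float, total_wet_weight: float) -> float:
    """GSI percentage from the two wet weights (g)."""
    if total_wet_weight <= 0:
        raise DomainError(f"total wet weight must be positive, got {total_wet_weight}")
    if gonad_wet_weight < 0:
        raise DomainError(f"gonad wet weight must be nonnegative, got {gonad_wet_weight}")
    return 100.0 * gonad_wet_weight / total_wet_weight


def compute_gsi(record: UrchinRecord) -> float:
    return gsi_value(record.gonad_wet_weight, record.total_wet_weight)


def assign_size_class(td: float, scheme: SizeClassScheme) -> Optional[str]:
    """Named fertility class for a test diameter, or None outside all.

    Boundaries are half-open (lower inclusive, upper exclusive); the CS
    class is unbounded above.
    """
    if td <= 0:
        raise DomainError(f"test diameter must be positive, got {td}")
    for name, interval in scheme.fertility_classes.items():
        if interval.contains(td):
            return name
    return None


def monthly_series(
    records: Iterable[UrchinRecord],
    zone: str,
    size_class: str,
    config: Optional[PipelineConfig] = None,
    sex: Optional[str] = None,
) -> GsiSeries:
    """Aggregate individual GSI into a monthly series for one stratum.

    SE is the sample standard deviation over individuals divided by
    sqrt(n); a singleton month has SE 0 by convention (n is carried so
    users can filter).  Months with no records inside the sampled span
    are reported as gaps, not interpolated.
    """
    config = config or PipelineConfig()
    scheme = config.scheme
    rows = [
        (r.month, compute_gsi(r))
        for r in records
        if r.zone == zone
        and assign_size_class(r.test_diameter, scheme) == size_class
        and (sex is None or r.sex == sex)
    ]
    if not rows:
        raise EmptySeriesError(f"no records for stratum ({zone!r}, {size_class!r})")
    df = pd.DataFrame(rows, columns=["month", "gsi"])
    grouped = df.groupby("month")["gsi"]
    points: dict[str, GsiPoint] = {}
    for month, vals in grouped:
        n = len(vals)
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        points[str(month)] = GsiPoint(mean=float(vals.mean()), se=se, n=n)
    months = sorted(points, key=month_index)
    gaps = frozenset(set(month_range(months[0], months[-1])) - set(months))
    return GsiSeries(zone=zone, size_class=size_class, points=points, gap_months=gaps, sex=sex)


def all_series(
    records: Sequence[UrchinRecord], config: Optional[PipelineConfig] = None
) -> list[GsiSeries]:
    """One series per (zone, size class[, sex]) stratum present in the data."""
    config = config or PipelineConfig()
    scheme = config.scheme
    strata: list[tuple[str, str, Optional[str]]] = []
    seen = set()
    for r in records:
        cls = assign_size_class(r.test_diameter, scheme)
        if cls is None:
            continue
        for sx in ([None] if config.pool_sexes else [r.sex]):
            key = (r.zone, cls, sx)
            if key not in seen:
                seen.add(key)
                strata.append(key)
    return [
        monthly_series(records, zone, cls, config, sex=sx)
        for zone, cls, sx in sorted(strata, key=lambda k: (k[0], k[1], str(k[2])))
    ]


# ---------------------------------------------------------------------------
# CSV round-trip for the series table
# ---------------------------------------------------------------------------

def series_frame(series_list: Sequence[GsiSeries]) -> pd.DataFrame:
    rows = [
        {
            "zone": s.zone, "size_class": s.size_class, "month": month,
            "mean_gsi": p.mean, "se_gsi": p.se, "n": p.n,
        }
        for s in series_list
        for month, p in s.points.items()
    ]
    return pd.DataFrame(rows, columns=["zone", "size_class", "month", "mean_gsi", "se_gsi", "n"])


def write_gsi_series(series_list: Sequence[GsiSeries], path) -> None:
    series_frame(series_list).to_csv(path, index=False)


def read_gsi_series(path) -> list[GsiSeries]:
    df = pd.read_csv(path, dtype={"zone": str, "size_class": str, "month": str})
    out: list[GsiSeries] = []
    for (zone, cls), grp in df.groupby(["zone", "size_class"], sort=True):
        points = {
            str(row["month"]): GsiPoint(float(row["mean_gsi"]), float(row["se_gsi"]), int(row["n"]))
            for _, row in grp.iterrows()
        }
        months = sorted(points, key=month_index)
        gaps = frozenset(set(month_range(months[0], months[-1])) - set(months))
        out.append(GsiSeries(zone=str(zone), size_class=str(cls), points=points, gap_months=gaps))
    return out
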