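"""Domain types, CSV schemas, configuration and validation.

Every pipeline stage shares the vocabulary defined here: an
:class:`UrchinRecord` is one measured individual (the unit of observation
for the gonadosomatic index), a :class:`QuadratCount` is one 50x50 cm
census frame, a :class:`FertilityAssay` is one egg-fertilisation trial,
and a :class:`SizeClassScheme` fixes both the 10-mm census bins and the
named fertility classes (Small-US, US, CS).

CSV dialect is fixed: comma separator, dot decimal, UTF-8, one header
line.  Size bins are serialised as ``"lo-hi"`` with half-open semantics
``[lo, hi)``; the last, unbounded bin is written ``"lo+"`` (e.g. ``60+``).
Months are calendar year-months written ``YYYY-MM``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError as PydanticValidationError,
    field_validator,
    model_validator,
)

log = logging.getLogger(__name__)

Sex = Literal["F", "M", "unknown"]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PipelineError):
    """An input file does not match its declared schema."""


class RecordValidationError(PipelineError):
    """One or more input rows violate a domain invariant."""


class DomainError(PipelineError):
    """An operation was called outside its mathematical domain."""


class EmptySeriesError(DomainError):
    """No records exist for the requested stratum."""


class ConfigurationError(PipelineError):
    """Inputs are individually valid but mutually inconsistent."""


# ---------------------------------------------------------------------------
# Calendar months ("YYYY-MM")
# ---------------------------------------------------------------------------

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


def check_month(value: str) -> str:
    if not isinstance(value, str) or not _MONTH_RE.match(value):
        raise ValueError(f"month must be 'YYYY-MM', got {value!r}")
    return value


def month_index(month: str) -> int:
    """Months since year 0, so differences count inter-month steps."""
    year, mo = month.split("-")
    return int(year) * 12 + int(mo) - 1


def month_from_index(idx: int) -> str:
    return f"{idx // 12:04d}-{idx % 12 + 1:02d}"


def month_range(first: str, last: str) -> list[str]:
    """All calendar months from *first* to *last* inclusive."""
    a, b = month_index(first), month_index(last)
    if a > b:
        raise ValueError(f"month range reversed: {first} > {last}")
    return [month_from_index(i) for i in range(a, b + 1)]


# ---------------------------------------------------------------------------
# Size bins and the class scheme
# ---------------------------------------------------------------------------

def _fmt_mm(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


class SizeBin(BaseModel):
    """Half-open test-diameter interval ``[lower, upper)`` in mm.

    ``upper is None`` means unbounded above (the terminal bin).
    """

    model_config = ConfigDict(frozen=True)

    lower: float = Field(ge=0)
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "SizeBin":
        if self.upper is not None and self.upper <= self.lower:
            raise ValueError(f"bin upper {self.upper} must exceed lower {self.lower}")
        return self

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{_fmt_mm(self.lower)}+"
        return f"{_fmt_mm(self.lower)}-{_fmt_mm(self.upper)}"

    def contains(self, td: float) -> bool:
        return td >= self.lower and (self.upper is None or td < self.upper)

    @classmethod
    def parse(cls, label: str) -> "SizeBin":
        """Parse ``"40-50"`` / ``"60+"`` (en-dash and spaces tolerated)."""
        text = str(label).strip().replace("–", "-")
        if text.endswith("+"):
            return cls(lower=float(text[:-1]), upper=None)
        parts = text.split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse size-bin label {label!r}")
        return cls(lower=float(parts[0]), upper=float(parts[1]))


def _default_census_bins() -> list[SizeBin]:
    edges = [0, 10, 20, 30, 40, 50, 60]
    bins = [SizeBin(lower=lo, upper=hi) for lo, hi in zip(edges[:-1], edges[1:])]
    bins.append(SizeBin(lower=edges[-1], upper=None))
    return bins


def _default_fertility_classes() -> dict[str, SizeBin]:
    return {
        "Small-US": SizeBin(lower=30, upper=40),
        "US": SizeBin(lower=40, upper=50),
        "CS": SizeBin(lower=50, upper=None),
    }


class SizeClassScheme(BaseModel):
    """Census bins plus named fertility classes.

    Defaults follow the survey design: 10-mm census bins from 0 with a
    terminal ``60+`` bin, and fertility classes Small-US [30, 40) mm
    (gonads present but effectively infertile), US [40, 50) mm (fertile,
    below the legal landing size) and CS >= 50 mm (commercial size; the
    lower bound is the legal minimum landing size).
    """

    census_bins: list[SizeBin] = Field(default_factory=_default_census_bins)
    fertility_classes: dict[str, SizeBin] = Field(default_factory=_default_fertility_classes)
    fertile_flags: dict[str, bool] = Field(
        default_factory=lambda: {"Small-US": False, "US": True, "CS": True}
    )

    @model_validator(mode="after")
    def _contiguous(self) -> "SizeClassScheme":
        bins = self.census_bins
        if not bins:
            raise ValueError("census_bins must be non-empty")
        for a, b in zip(bins[:-1], bins[1:]):
            if a.upper is None:
                raise ValueError("only the last census bin may be unbounded")
            if a.upper != b.lower:
                raise ValueError(f"census bins not contiguous at {a.label} / {b.label}")
        if bins[-1].upper is not None:
            raise ValueError("last census bin must be unbounded above")
        if set(self.fertile_flags) != set(self.fertility_classes):
            raise ValueError("fertile_flags keys must match fertility_classes keys")
        return self

    @property
    def bin_labels(self) -> list[str]:
        return [b.label for b in self.census_bins]

    def find_bin(self, td: float) -> Optional[SizeBin]:
        for b in self.census_bins:
            if b.contains(td):
                return b
        return None

    def fertile_classes(self) -> list[str]:
        return [name for name, ok in self.fertile_flags.items() if ok]


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

class UrchinRecord(BaseModel):
    """One measured individual: morphometrics plus sampling metadata."""

    record_id: str
    zone: str
    area: str = ""
    month: str
    test_diameter: float = Field(gt=0, description="test diameter without spines, mm")
    total_wet_weight: float = Field(gt=0, description="total wet weight, g")
    gonad_wet_weight: float = Field(ge=0, description="gonad wet weight, g")
    sex: Sex = "unknown"

    @field_validator("month")
    @classmethod
    def _month(cls, v: str) -> str:
        return check_month(v)

    @model_validator(mode="after")
    def _weights(self) -> "UrchinRecord":
        if self.gonad_wet_weight > self.total_wet_weight:
            raise ValueError(
                f"record {self.record_id!r}: gonad weight {self.gonad_wet_weight} g "
                f"exceeds total weight {self.total_wet_weight} g"
            )
        return self


class QuadratCount(BaseModel):
    """Counts per census bin for one 0.25-m2 sampling frame."""

    zone: str
    area: str = ""
    quadrat_id: str
    replicate: Optional[str] = None
    quadrat_area: float = Field(default=0.25, gt=0, description="m2")
    counts: dict[str, int]

    @model_validator(mode="after")
    def _nonnegative(self) -> "QuadratCount":
        for label, c in self.counts.items():
            if c < 0:
                raise ValueError(
                    f"quadrat {self.quadrat_id!r}: negative count {c} in bin {label!r}"
                )
        return self

    def total_count(self) -> int:
        return sum(self.counts.values())


class FertilityAssay(BaseModel):
    """One fertilisation trial: eggs exposed to sperm, plutei scored later.

    Pluteus counts may be absent (no larval count was done); both pluteus
    fields must then be absent together.
    """

    zone: str
    month: str
    size_class: str = "US"
    eggs_total: int = Field(gt=0)
    eggs_fertilized: int = Field(ge=0)
    plutei_scored: Optional[int] = Field(default=None, ge=0)
    plutei_total: Optional[int] = Field(default=None, gt=0)

    @field_validator("month")
    @classmethod
    def _month(cls, v: str) -> str:
        return check_month(v)

    @model_validator(mode="after")
    def _consistent(self) -> "FertilityAssay":
        if self.eggs_fertilized > self.eggs_total:
            raise ValueError(
                f"assay {self.zone}/{self.month}: fertilized {self.eggs_fertilized} "
                f"> total {self.eggs_total}"
            )
        if (self.plutei_scored is None) != (self.plutei_total is None):
            raise ValueError("plutei_scored and plutei_total must be present together")
        if self.plutei_scored is not None and self.plutei_scored > self.plutei_total:
            raise ValueError(
                f"assay {self.zone}/{self.month}: plutei {self.plutei_scored} "
                f"> scored total {self.plutei_total}"
            )
        return self


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class EventDetectionParams(BaseModel):
    """Tunables for spawning-event detection.

    ``min_drop_pct`` is the minimum relative GSI decline (percent of the
    pre-spawning mean) for a peak-to-trough decline to count as a spawning
    event; the same relative threshold confirms that a decline has ended
    (the series must rebound by at least this fraction of the rebound
    level before a new build-up is recognised).
    """

    min_drop_pct: float = Field(default=30.0, gt=0, le=100)
    min_duration_months: int = Field(default=1, ge=1)
    interpolate_gaps: bool = False


class RoundingConvention(BaseModel):
    """Presentation rounding: half-up, 1 dp for percentages, 2 dp for g/g."""

    percent_decimals: int = Field(default=1, ge=0)
    mass_decimals: int = Field(default=2, ge=0)


class PipelineConfig(BaseModel):
    scheme: SizeClassScheme = Field(default_factory=SizeClassScheme)
    rounding: RoundingConvention = Field(default_factory=RoundingConvention)
    detection: EventDetectionParams = Field(default_factory=EventDetectionParams)
    fertility_threshold_pct: float = Field(default=80.0, gt=0, le=100)
    pool_sexes: bool = True
    se_unit: Literal["replicate", "quadrat"] = "replicate"
    td_sanity_mm: tuple[float, float] = (5.0, 120.0)
    default_quadrat_area_m2: float = Field(default=0.25, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _bounds(self) -> "PipelineConfig":
        lo, hi = self.td_sanity_mm
        if not 0 < lo < hi:
            raise ValueError(f"td_sanity_mm must be increasing positive, got {self.td_sanity_mm}")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero at the given decimal place.

    Goes through the shortest decimal representation of *value* so that
    e.g. 0.1134 -> 0.11 and 0.10985 -> 0.11 regardless of binary float
    artefacts.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

URCHIN_COLUMNS = ["record_id", "zone", "area", "month", "td_mm", "tw_g", "gw_g", "sex"]
FERTILITY_COLUMNS = [
    "zone", "month", "size_class",
    "eggs_total", "eggs_fertilized", "plutei_scored", "plutei_total",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_urchin_records(
    path: str | Path, config: Optional[PipelineConfig] = None
) -> list[UrchinRecord]:
    """Read individual morphometric records, validating every row.

    Every row is either accepted or contributes a located message to a
    single :class:`RecordValidationError`; no row is silently dropped.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"record_id": str, "zone": str, "area": str,
                            "month": str, "sex": str})
    _require_columns(df, URCHIN_COLUMNS, path)
    if df.empty:
        log.warning("%s: no data rows (header only)", path)
        return []
    lo, hi = config.td_sanity_mm
    records: list[UrchinRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rid = str(row["record_id"])
        sex = row["sex"] if isinstance(row["sex"], str) and row["sex"] in ("F", "M") else "unknown"
        try:
            rec = UrchinRecord(
                record_id=rid,
                zone=str(row["zone"]),
                area="" if pd.isna(row["area"]) else str(row["area"]),
                month=str(row["month"]),
                test_diameter=float(row["td_mm"]),
                total_wet_weight=float(row["tw_g"]),
                gonad_wet_weight=float(row["gw_g"]),
                sex=sex,
            )
        except (PydanticValidationError, ValueError) as exc:
            problems.append(f"row {i} (record {rid}): {_first_error(exc)}")
            continue
        if not lo < rec.test_diameter < hi:
            problems.append(
                f"row {i} (record {rid}): test diameter {rec.test_diameter} mm "
                f"outside sanity bounds ({lo}, {hi})"
            )
            continue
        records.append(rec)
    if problems:
        raise RecordValidationError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return records


def _first_error(exc: Exception) -> str:
    if isinstance(exc, PydanticValidationError):
        err = exc.errors()[0]
        return str(err.get("msg", err))
    return str(exc)


def write_urchin_records(records: Iterable[UrchinRecord], path: str | Path) -> None:
    rows = [
        {
            "record_id": r.record_id, "zone": r.zone, "area": r.area, "month": r.month,
            "td_mm": repr(r.test_diameter), "tw_g": repr(r.total_wet_weight),
            "gw_g": repr(r.gonad_wet_weight), "sex": r.sex,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=URCHIN_COLUMNS).to_csv(path, index=False)


_QUADRAT_META = ["zone", "area", "quadrat_id", "replicate", "area_m2"]


def read_quadrat_counts(
    path: str | Path, config: Optional[PipelineConfig] = None
) -> list[QuadratCount]:
    """Read quadrat censuses; non-meta columns must be size-bin labels.

    Bin labels are matched to the configured census scheme by their parsed
    interval, so dialect variants like ``"40-50"`` vs ``"40–50"`` are
    accepted; a column that parses to no configured bin is a schema error.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, float_precision="round_trip",
                     dtype={"zone": str, "area": str, "quadrat_id": str,
                            "replicate": str})
    _require_columns(df, ["zone", "quadrat_id"], path)
    scheme_bins = {(b.lower, b.upper): b.label for b in config.scheme.census_bins}
    bin_cols: dict[str, str] = {}
    for col in df.columns:
        if col in _QUADRAT_META:
            continue
        try:
            parsed = SizeBin.parse(col)
        except ValueError as exc:
            raise SchemaError(f"{path}: column {col!r} is not a size-bin label ({exc})")
        key = (parsed.lower, parsed.upper)
        if key not in scheme_bins:
            raise SchemaError(
                f"{path}: bin column {col!r} matches no configured census bin "
                f"(expected one of {', '.join(config.scheme.bin_labels)})"
            )
        bin_cols[col] = scheme_bins[key]
    if df.empty:
        log.warning("%s: no data rows (header only)", path)
        return []
    quadrats: list[QuadratCount] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        qid = str(row["quadrat_id"])
        counts: dict[str, int] = {}
        for col, label in bin_cols.items():
            raw = row[col]
            counts[label] = 0 if pd.isna(raw) else int(raw)
        area_m2 = config.default_quadrat_area_m2
        if "area_m2" in df.columns and not pd.isna(row["area_m2"]):
            area_m2 = float(row["area_m2"])
        try:
            quadrats.append(
                QuadratCount(
                    zone=str(row["zone"]),
                    area="" if "area" not in df.columns or pd.isna(row["area"]) else str(row["area"]),
                    quadrat_id=qid,
                    replicate=None if "replicate" not in df.columns or pd.isna(row["replicate"])
                    else str(row["replicate"]),
                    quadrat_area=area_m2,
                    counts=counts,
                )
            )
        except (PydanticValidationError, ValueError) as exc:
            problems.append(f"row {i} (quadrat {qid}): {_first_error(exc)}")
    if problems:
        raise RecordValidationError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return quadrats


def write_quadrat_counts(
    quadrats: Sequence[QuadratCount], path: str | Path,
    config: Optional[PipelineConfig] = None,
) -> None:
    config = config or PipelineConfig()
    labels = config.scheme.bin_labels
    rows = []
    for q in quadrats:
        row: dict[str, object] = {
            "zone": q.zone, "area": q.area, "quadrat_id": q.quadrat_id,
            "replicate": "" if q.replicate is None else q.replicate,
            "area_m2": repr(q.quadrat_area),
        }
        for label in labels:
            row[label] = q.counts.get(label, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=_QUADRAT_META + labels).to_csv(path, index=False)


def read_fertility_assays(path: str | Path) -> list[FertilityAssay]:
    df = pd.read_csv(path, dtype={"zone": str, "month": str, "size_class": str})
    _require_columns(df, ["zone", "month", "eggs_total", "eggs_fertilized"], path)
    if df.empty:
        log.warning("%s: no data rows (header only)", path)
        return []
    assays: list[FertilityAssay] = []
    problems: list[str] = []
    for i, row in df.iterrows():

        def _opt(col: str) -> Optional[int]:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return int(row[col])

        try:
            assays.append(
                FertilityAssay(
                    zone=str(row["zone"]),
                    month=str(row["month"]),
                    size_class="US" if "size_class" not in df.columns or pd.isna(row["size_class"])
                    else str(row["size_class"]),
                    eggs_total=int(row["eggs_total"]),
                    eggs_fertilized=int(row["eggs_fertilized"]),
                    plutei_scored=_opt("plutei_scored"),
                    plutei_total=_opt("plutei_total"),
                )
            )
        except (PydanticValidationError, ValueError) as exc:
            problems.append(f"row {i}: {_first_error(exc)}")
    if problems:
        raise RecordValidationError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return assays


def write_fertility_assays(assays: Sequence[FertilityAssay], path: str | Path) -> None:
    rows = [
        {
            "zone": a.zone, "month": a.month, "size_class": a.size_class,
            "eggs_total": a.eggs_total, "eggs_fertilized": a.eggs_fertilized,
            "plutei_scored": "" if a.plutei_scored is None else a.plutei_scored,
            "plutei_total": "" if a.plutei_total is None else a.plutei_total,
        }
        for a in assays
    ]
    pd.DataFrame(rows, columns=FERTILITY_COLUMNS).to_csv(path, index=False)
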