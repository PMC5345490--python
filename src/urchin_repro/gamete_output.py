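"""Gamete-output cascade: GO, TGO, MGO and whole-population totals.

For each fertile size class and spawning event, the gamete output per m2
(GO, g g^-1 m^-2 per spawning event) is the event's IGO multiplied by the
class's natural density.  Per class and year, TGO is the sum of GO over
events and MGO the mean; the whole-population popTGO and popMGO are the
sums of the class TGOs and MGOs over the fertile classes.

All arithmetic is carried at full precision; half-up rounding (1 dp for
percentages, 2 dp for g g^-1 quantities) is applied only when rendering.
A class configured fertile is included in the population totals unless
its fertility assays fail the success threshold (classes with no assay
data are assumed fertile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .data_model_io import (
    ConfigurationError,
    DomainError,
    FertilityAssay,
    PipelineConfig,
    round_half_up,
)
from .spawning import SpawningEvent


def gamete_output_per_m2(igo: float, density: float) -> float:
    """GO = IGO x natural density, g g^-1 m^-2 per spawning event."""
    if igo < 0:
        raise DomainError(f"IGO must be nonnegative, got {igo}")
    if density < 0:
        raise DomainError(f"density must be nonnegative, got {density}")
    return igo * density


def class_totals(gos: Sequence[float]) -> tuple[float, float]:
    """(TGO, MGO): sum and mean of a class's per-event GO values."""
    if not gos:
        raise DomainError("class produced no spawning events")
    tgo = sum(gos)
    return tgo, tgo / len(gos)


def population_totals(
    per_class: Mapping[str, tuple[float, float]]
) -> tuple[float, float]:
    """(popTGO, popMGO): sums of class TGOs and of class MGOs."""
    if not per_class:
        raise DomainError("no fertile classes present")
    pop_tgo = sum(t for t, _ in per_class.values())
    pop_mgo = sum(m for _, m in per_class.values())
    return pop_tgo, pop_mgo


# ---------------------------------------------------------------------------
# Fertility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayResult:
    zone: str
    month: str
    size_class: str
    fertilization_pct: float
    success: bool
    pluteus_pct: Optional[float]


@dataclass
class FertilitySummary:
    """Per-assay fertilization percentages and success flags."""

    results: list[AssayResult]
    threshold_pct: float

    def for_class(self, zone: str, size_class: str) -> list[AssayResult]:
        return [
            r for r in self.results if r.zone == zone and r.size_class == size_class
        ]

    def class_passes(self, zone: str, size_class: str) -> bool:
        """True when no assays exist, or their mean fertilization passes."""
        rs = self.for_class(zone, size_class)
        if not rs:
            return True
        mean_pct = sum(r.fertilization_pct for r in rs) / len(rs)
        return mean_pct >= self.threshold_pct


def fertility_summary(
    assays: Sequence[FertilityAssay], threshold_pct: float = 80.0
) -> FertilitySummary:
    """Fertilization %, success flag (>= threshold, inclusive) and pluteus %."""
    results = []
    for a in assays:
        pct = 100.0 * a.eggs_fertilized / a.eggs_total
        pluteus = (
            100.0 * a.plutei_scored / a.plutei_total
            if a.plutei_scored is not None
            else None
        )
        results.append(
            AssayResult(
                zone=a.zone,
                month=a.month,
                size_class=a.size_class,
                fertilization_pct=pct,
                success=pct >= threshold_pct,
                pluteus_pct=pluteus,
            )
        )
    return FertilitySummary(results=results, threshold_pct=threshold_pct)


# ---------------------------------------------------------------------------
# The report
# ---------------------------------------------------------------------------

@dataclass
class ClassOutput:
    """Per-event GO and annual totals for one fertile size class."""

    size_class: str
    density: float
    events: list[SpawningEvent]
    go: list[float]

    @property
    def tgo(self) -> float:
        return class_totals(self.go)[0]

    @property
    def mgo(self) -> float:
        return class_totals(self.go)[1]


@dataclass
class GameteOutputTable:
    """One zone's reproductive-contribution summary."""

    zone: str
    classes: dict[str, ClassOutput]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def pop_tgo(self) -> float:
        return population_totals({k: (c.tgo, c.mgo) for k, c in self.classes.items()})[0]

    @property
    def pop_mgo(self) -> float:
        return population_totals({k: (c.tgo, c.mgo) for k, c in self.classes.items()})[1]


def build_report(
    events: Sequence[SpawningEvent],
    class_density: Mapping[str, float],
    config: Optional[PipelineConfig] = None,
    fertility: Optional[FertilitySummary] = None,
) -> GameteOutputTable:
    """Assemble the per-zone gamete-output table from detected events.

    *events* must all belong to one zone; *class_density* maps named
    fertility classes to natural densities (ind m^-2).  Classes whose
    fertile flag is off, or whose fertility assays fail the threshold,
    are excluded from the population totals.
    """
    config = config or PipelineConfig()
    if not events:
        raise DomainError("no spawning events to report")
    zones = {e.zone for e in events}
    if len(zones) != 1:
        raise ConfigurationError(f"events span multiple zones: {sorted(zones)}")
    zone = zones.pop()

    by_class: dict[str, list[SpawningEvent]] = {}
    for e in sorted(events, key=lambda e: (e.size_class, e.start_month)):
        by_class.setdefault(e.size_class, []).append(e)

    classes: dict[str, ClassOutput] = {}
    excluded: dict[str, str] = {}
    for name, evs in by_class.items():
        if not config.scheme.fertile_flags.get(name, False):
            excluded[name] = "not a fertile class"
            continue
        if fertility is not None and not fertility.class_passes(zone, name):
            excluded[name] = "fertility assays below success threshold"
            continue
        if name not in class_density:
            raise ConfigurationError(
                f"zone {zone!r}: events for class {name!r} but no density"
            )
        density = class_density[name]
        go = [gamete_output_per_m2(e.igo, density) for e in evs]
        classes[name] = ClassOutput(size_class=name, density=density, events=evs, go=go)
    if not classes:
        raise DomainError(f"zone {zone!r}: no fertile class produced events")
    return GameteOutputTable(zone=zone, classes=classes, excluded=excluded)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def report_frame(
    tables: Sequence[GameteOutputTable], config: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Long-format report: full-precision and rounded value per metric."""
    config = config or PipelineConfig()
    pdec = config.rounding.percent_decimals
    mdec = config.rounding.mass_decimals
    rows = []

    def add(zone, cls, idx, metric, value, dec):
        rows.append(
            {
                "zone": zone, "size_class": cls, "event_index": idx, "metric": metric,
                "value_full": value,
                "value_rounded": round_half_up(value, dec) if value == value else value,
            }
        )

    for t in tables:
        for name, c in t.classes.items():
            for i, (e, go) in enumerate(zip(c.events, c.go), start=1):
                add(t.zone, name, i, "pre_gsi", e.pre_gsi, pdec)
                add(t.zone, name, i, "post_gsi", e.post_gsi, pdec)
                add(t.zone, name, i, "igo", e.igo, mdec)
                add(t.zone, name, i, "magnitude_pct", e.magnitude, pdec)
                add(t.zone, name, i, "go", go, mdec)
            add(t.zone, name, 0, "density", c.density, pdec)
            add(t.zone, name, 0, "tgo", c.tgo, mdec)
            add(t.zone, name, 0, "mgo", c.mgo, mdec)
        add(t.zone, "", 0, "pop_tgo", t.pop_tgo, mdec)
        add(t.zone, "", 0, "pop_mgo", t.pop_mgo, mdec)
    return pd.DataFrame(
        rows,
        columns=["zone", "size_class", "event_index", "metric", "value_full", "value_rounded"],
    )


def render_text_table(
    tables: Sequence[GameteOutputTable], config: Optional[PipelineConfig] = None
) -> str:
    """Aligned text summary mirroring the published table layout."""
    config = config or PipelineConfig()
    pdec = config.rounding.percent_decimals
    mdec = config.rounding.mass_decimals
    lines: list[str] = []
    for t in tables:
        lines.append(f"Zone {t.zone}")
        header = ["metric"]
        cols: list[tuple[str, int]] = []
        for name, c in t.classes.items():
            for i in range(len(c.events)):
                header.append(f"{name} ev{i + 1}" if len(c.events) > 1 else name)
                cols.append((name, i))
        width = max(18, *(len(h) + 2 for h in header))

        def row(label: str, values: list[str]) -> str:
            return label.ljust(24) + "".join(v.rjust(width) for v in values)

        lines.append(row("", header[1:]))

        def fmt(v: float, dec: int) -> str:
            return f"{round_half_up(v, dec):.{dec}f}"

        lines.append(row("spawning period", [
            f"{t.classes[n].events[i].start_month}..{t.classes[n].events[i].end_month}"
            for n, i in cols
        ]))
        lines.append(row("pre-spawning GSI (%)", [fmt(t.classes[n].events[i].pre_gsi, pdec) for n, i in cols]))
        lines.append(row("post-spawning GSI (%)", [fmt(t.classes[n].events[i].post_gsi, pdec) for n, i in cols]))
        lines.append(row("IGO (g/g/se)", [fmt(t.classes[n].events[i].igo, mdec) for n, i in cols]))
        lines.append(row("magnitude (%)", [fmt(t.classes[n].events[i].magnitude, pdec) for n, i in cols]))
        lines.append(row("density (ind/m2)", [fmt(t.classes[n].density, pdec) for n, i in cols]))
        lines.append(row("GO (g/g/m2/se)", [fmt(t.classes[n].go[i], mdec) for n, i in cols]))
        lines.append(row("TGO (g/g/m2/yr)", [fmt(t.classes[n].tgo, mdec) for n, i in cols]))
        lines.append(row("MGO (g/g/m2/yr)", [fmt(t.classes[n].mgo, mdec) for n, i in cols]))
        lines.append(f"popTGO (g/g/m2/yr): {fmt(t.pop_tgo, mdec)}")
        lines.append(f"popMGO (g/g/m2/yr): {fmt(t.pop_mgo, mdec)}")
        if t.excluded:
            for name, reason in t.excluded.items():
                lines.append(f"excluded: {name} ({reason})")
        lines.append("")
    return "\n".join(lines)
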