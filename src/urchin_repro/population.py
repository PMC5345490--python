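"""Quadrat censuses to densities, size-frequency, and fertile-class density.

Density per census bin is the ratio of totals — total count across
quadrats divided by total surveyed area — which is unbiased under unequal
quadrat areas.  Standard errors are computed across replicate blocks
(quadrats grouped by their (area, replicate) labels, matching a design of
two 25-m2 replicates per area); a config flag switches to per-quadrat SE.
Bin densities are translated into frequency percentages to describe the
population structure, and summed over the named class intervals to give
the natural density of each fertility class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model_io import (
    ConfigurationError,
    DomainError,
    PipelineConfig,
    QuadratCount,
    SizeBin,
    SizeClassScheme,
)

log = logging.getLogger(__name__)


@dataclass
class DensityTable:
    """Per-bin densities (ind m^-2), SEs and frequency (%) for one zone."""

    zone: str
    bins: list[str]
    mean_density: dict[str, float]
    se_density: dict[str, float]
    frequency_pct: dict[str, float]
    total_density: float
    total_se: float
    surveyed_area_m2: float
    n_blocks: int


def _block_key(q: QuadratCount, se_unit: str) -> tuple:
    if se_unit == "quadrat":
        return (q.area, q.quadrat_id)
    return (q.area, q.replicate if q.replicate is not None else "")


def densities(
    quadrats: Sequence[QuadratCount],
    zone: str,
    config: Optional[PipelineConfig] = None,
) -> DensityTable:
    """Estimate per-bin and total densities for one zone."""
    config = config or PipelineConfig()
    labels = config.scheme.bin_labels
    zq = [q for q in quadrats if q.zone == zone]
    if not zq:
        raise DomainError(f"no quadrats for zone {zone!r}")
    total_area = sum(q.quadrat_area for q in zq)
    if total_area <= 0:
        raise DomainError(f"zone {zone!r}: surveyed area is zero")

    mean_density = {
        label: sum(q.counts.get(label, 0) for q in zq) / total_area for label in labels
    }
    total_density = sum(mean_density.values())

    # SE across replicate blocks (or individual quadrats).
    blocks: dict[tuple, list[QuadratCount]] = {}
    for q in zq:
        blocks.setdefault(_block_key(q, config.se_unit), []).append(q)
    n_blocks = len(blocks)
    block_dens = {label: [] for label in labels}
    block_totals = []
    for members in blocks.values():
        area = sum(q.quadrat_area for q in members)
        tot = 0.0
        for label in labels:
            d = sum(q.counts.get(label, 0) for q in members) / area
            block_dens[label].append(d)
            tot += d
        block_totals.append(tot)

    def _se(values: list[float]) -> float:
        if len(values) < 2:
            return 0.0
        return float(np.std(values, ddof=1) / math.sqrt(len(values)))

    se_density = {label: _se(block_dens[label]) for label in labels}
    total_se = _se(block_totals)

    if total_density > 0:
        frequency = {label: 100.0 * mean_density[label] / total_density for label in labels}
    else:
        log.warning("zone %r: no urchins counted; frequencies reported as 0", zone)
        frequency = {label: 0.0 for label in labels}

    return DensityTable(
        zone=zone,
        bins=list(labels),
        mean_density=mean_density,
        se_density=se_density,
        frequency_pct=frequency,
        total_density=total_density,
        total_se=total_se,
        surveyed_area_m2=total_area,
        n_blocks=n_blocks,
    )


def table_from_bin_densities(
    zone: str,
    bin_densities: Mapping[str, float],
    surveyed_area_m2: float = float("nan"),
) -> DensityTable:
    """Build a DensityTable directly from known per-bin densities.

    Convenience for working from a published summary (no raw quadrats);
    SEs are reported as 0.
    """
    labels = list(bin_densities)
    total = float(sum(bin_densities.values()))
    freq = (
        {k: 100.0 * v / total for k, v in bin_densities.items()}
        if total > 0
        else {k: 0.0 for k in bin_densities}
    )
    return DensityTable(
        zone=zone,
        bins=labels,
        mean_density={k: float(v) for k, v in bin_densities.items()},
        se_density={k: 0.0 for k in bin_densities},
        frequency_pct=freq,
        total_density=total,
        total_se=0.0,
        surveyed_area_m2=surveyed_area_m2,
        n_blocks=0,
    )


def fertile_class_density(
    table: DensityTable, scheme: Optional[SizeClassScheme] = None
) -> dict[str, float]:
    """Sum census-bin densities into each named fertility class.

    Census bins must align with class boundaries: every bin lies entirely
    inside or entirely outside each class interval.
    """
    scheme = scheme or SizeClassScheme()
    parsed = {label: SizeBin.parse(label) for label in table.bins}
    out: dict[str, float] = {}
    for name, cls in scheme.fertility_classes.items():
        total = 0.0
        for label, b in parsed.items():
            inside = b.lower >= cls.lower and (
                cls.upper is None or (b.upper is not None and b.upper <= cls.upper)
            )
            outside = (b.upper is not None and b.upper <= cls.lower) or (
                cls.upper is not None and b.lower >= cls.upper
            )
            if inside:
                total += table.mean_density[label]
            elif not outside:
                raise ConfigurationError(
                    f"census bin {label} misaligned with class {name} "
                    f"[{cls.lower}, {cls.upper})"
                )
        out[name] = total
    return out


def size_frequency(table: DensityTable) -> dict[str, float]:
    """Frequency percentage of each census bin; requires urchins present."""
    if table.total_density <= 0:
        raise DomainError(f"zone {table.zone!r}: total density is zero")
    return {
        label: 100.0 * table.mean_density[label] / table.total_density
        for label in table.bins
    }


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def density_frame(tables: Sequence[DensityTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for label in t.bins:
            rows.append(
                {
                    "zone": t.zone, "bin": label,
                    "mean_density": t.mean_density[label],
                    "se_density": t.se_density[label],
                    "frequency_pct": t.frequency_pct[label],
                }
            )
        rows.append(
            {
                "zone": t.zone, "bin": "total",
                "mean_density": t.total_density,
                "se_density": t.total_se,
                "frequency_pct": 100.0 if t.total_density > 0 else 0.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["zone", "bin", "mean_density", "se_density", "frequency_pct"]
    )


def write_density(tables: Sequence[DensityTable], path) -> None:
    density_frame(tables).to_csv(path, index=False)


def read_density(path) -> list[DensityTable]:
    df = pd.read_csv(path, dtype={"zone": str, "bin": str})
    tables = []
    for zone, grp in df.groupby("zone", sort=True):
        data = grp[grp["bin"] != "total"]
        bin_densities = {
            str(r["bin"]): float(r["mean_density"]) for _, r in data.iterrows()
        }
        t = table_from_bin_densities(str(zone), bin_densities)
        t.se_density = {str(r["bin"]): float(r["se_density"]) for _, r in data.iterrows()}
        tot = grp[grp["bin"] == "total"]
        if not tot.empty:
            t.total_se = float(tot.iloc[0]["se_density"])
        tables.append(t)
    return tables
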