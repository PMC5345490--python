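"""Synthetic individuals, quadrat censuses and fertility assays.

The generator emulates the statistical structure the analysis assumes:

* per (zone, size class) stratum, the latent monthly mean GSI follows a
  piecewise-linear build-up to each spawning window's peak followed by a
  decline to its trough (matching the build-up/abrupt-decline shape of
  observed annual GSI cycles); individual GSI values are drawn around the
  latent mean with a common standard deviation and truncated at 0;
* body size is drawn uniformly within the class interval and total wet
  weight follows an allometric law TW = a * TD^b; gonad weight is derived
  from the sampled GSI (so the generator's ground truth is expressed in
  the same statistic the pipeline estimates);
* quadrat counts are Poisson with mean density x quadrat area, organised
  as two replicate blocks per area; a deterministic mode replaces the
  Poisson draw with expected totals for exact end-to-end checks;
* fertility assays are binomial draws for fertilised eggs and plutei.

Identical seed and specs give byte-identical output files.  The bundled
``hp_like()`` and ``lp_like()`` scenarios carry the published summary
values (peak/trough mean GSI per class, per-bin densities) as their
latent truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model_io import (
    FertilityAssay,
    PipelineConfig,
    QuadratCount,
    SizeClassScheme,
    UrchinRecord,
    check_month,
    month_index,
    write_fertility_assays,
    write_quadrat_counts,
    write_urchin_records,
)
from .gamete_output import class_totals, gamete_output_per_m2, population_totals
from .population import fertile_class_density, table_from_bin_densities
from .spawning import individual_gamete_output, spawning_magnitude


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

class SpawningWindow(BaseModel):
    """One latent spawning cycle: build-up, peak month, decline to trough."""

    build_start: str
    peak_month: str
    trough_month: str
    peak_mean: float = Field(gt=0)
    trough_mean: float = Field(ge=0)

    @model_validator(mode="after")
    def _ordered(self) -> "SpawningWindow":
        for m in (self.build_start, self.peak_month, self.trough_month):
            check_month(m)
        if not (
            month_index(self.build_start)
            <= month_index(self.peak_month)
            < month_index(self.trough_month)
        ):
            raise ValueError("window months must satisfy build_start <= peak < trough")
        if self.peak_mean <= self.trough_mean:
            raise ValueError("peak_mean must exceed trough_mean")
        return self


class GsiCycleSpec(BaseModel):
    """Latent GSI trajectory for one (zone, size class) stratum."""

    zone: str
    size_class: str
    windows: list[SpawningWindow] = Field(default_factory=list)
    baseline_mean: float = Field(default=2.5, ge=0, description="latent GSI %, outside windows")
    individual_sd: float = Field(default=0.8, ge=0, description="between-individual GSI sd, %")

    @model_validator(mode="after")
    def _disjoint(self) -> "GsiCycleSpec":
        for a, b in zip(self.windows[:-1], self.windows[1:]):
            if month_index(b.build_start) < month_index(a.trough_month):
                raise ValueError("spawning windows must be time-ordered and non-overlapping")
        return self


class AllometryParams(BaseModel):
    """Total wet weight (g) = a * TD(mm)^b; generator-only plumbing."""

    a: float = Field(default=5e-4, gt=0)
    b: float = Field(default=3.0, gt=2, lt=3.5)

    def weight(self, td: float) -> float:
        return self.a * td ** self.b


class PopulationSpec(BaseModel):
    """True per-bin densities and the census design for one zone."""

    zone: str
    bin_densities: dict[str, float]
    areas: list[str] = Field(default_factory=lambda: ["A", "B"])
    replicates_per_area: int = Field(default=2, ge=1)
    quadrats_per_block: int = Field(default=50, ge=1)
    quadrat_area: float = Field(default=0.25, gt=0, description="m2")

    @model_validator(mode="after")
    def _nonnegative(self) -> "PopulationSpec":
        if any(d < 0 for d in self.bin_densities.values()):
            raise ValueError("densities must be nonnegative")
        return self

    @property
    def total_quadrats(self) -> int:
        return len(self.areas) * self.replicates_per_area * self.quadrats_per_block


class FertilitySpec(BaseModel):
    zone: str
    months: list[str] = Field(default_factory=list)
    p_fertilization: float = Field(default=0.92, ge=0, le=1)
    p_pluteus: float = Field(default=0.97, ge=0, le=1)
    n_eggs: int = Field(default=300, ge=1)
    n_plutei: int = Field(default=150, ge=1)
    size_class: str = "US"


class ScenarioSpec(BaseModel):
    """Everything needed to generate one zone's input files."""

    name: str
    zone: str
    months: list[str]
    gsi: list[GsiCycleSpec]
    population: PopulationSpec
    fertility: FertilitySpec
    n_per_month: int = Field(default=8, ge=1)
    allometry: AllometryParams = Field(default_factory=AllometryParams)


# ---------------------------------------------------------------------------
# Latent trajectory
# ---------------------------------------------------------------------------

def latent_monthly_means(spec: GsiCycleSpec, months: Sequence[str]) -> dict[str, float]:
    """Piecewise-linear latent mean GSI per calendar month."""
    idx = [month_index(m) for m in months]
    if not spec.windows:
        return {m: spec.baseline_mean for m in months}
    anchors: list[tuple[int, float]] = []
    prev: Optional[SpawningWindow] = None
    for w in spec.windows:
        if month_index(w.build_start) < month_index(w.peak_month):
            start_val = (
                prev.trough_mean
                if prev is not None and w.build_start == prev.trough_month
                else spec.baseline_mean
            )
            if not anchors or anchors[-1][0] != month_index(w.build_start):
                anchors.append((month_index(w.build_start), start_val))
        anchors.append((month_index(w.peak_month), w.peak_mean))
        anchors.append((month_index(w.trough_month), w.trough_mean))
        prev = w
    xp = [a for a, _ in anchors]
    fp = [v for _, v in anchors]
    vals = np.interp(idx, xp, fp)
    return {m: float(v) for m, v in zip(months, vals)}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _class_interval(size_class: str, scheme: SizeClassScheme) -> tuple[float, float]:
    interval = scheme.fertility_classes[size_class]
    upper = interval.upper if interval.upper is not None else 70.0
    return interval.lower, upper


def simulate_gsi_records(
    spec: GsiCycleSpec,
    n_per_month: int,
    seed: int,
    months: Optional[Sequence[str]] = None,
    scheme: Optional[SizeClassScheme] = None,
    allometry: Optional[AllometryParams] = None,
) -> list[UrchinRecord]:
    """Draw individual morphometric records for one stratum."""
    if n_per_month < 1:
        raise ValueError("n_per_month must be >= 1")
    scheme = scheme or SizeClassScheme()
    allometry = allometry or AllometryParams()
    if months is None:
        if not spec.windows:
            raise ValueError("months must be given when the spec has no windows")
        first = spec.windows[0].build_start
        last = spec.windows[-1].trough_month
        months = [
            m for m in
            (f"{i // 12:04d}-{i % 12 + 1:02d}" for i in range(month_index(first), month_index(last) + 1))
        ]
    latent = latent_monthly_means(spec, months)
    lo, hi = _class_interval(spec.size_class, scheme)
    rng = np.random.default_rng(seed)
    records: list[UrchinRecord] = []
    for month in months:
        mu = latent[month]
        for i in range(n_per_month):
            gsi = mu if spec.individual_sd == 0 else float(rng.normal(mu, spec.individual_sd))
            gsi = max(0.0, gsi)
            td = float(rng.uniform(lo, hi))
            tw = allometry.weight(td)
            gw = gsi / 100.0 * tw
            records.append(
                UrchinRecord(
                    record_id=f"{spec.zone}-{spec.size_class}-{month}-{i:02d}",
                    zone=spec.zone,
                    area="A" if i % 2 == 0 else "B",
                    month=month,
                    test_diameter=td,
                    total_wet_weight=tw,
                    gonad_wet_weight=gw,
                    sex="F" if i % 2 == 0 else "M",
                )
            )
    return records


def simulate_quadrats(
    spec: PopulationSpec, seed: int, deterministic: bool = False
) -> list[QuadratCount]:
    """Draw quadrat censuses; counts are Poisson(density x area) per bin.

    With ``deterministic=True`` the Poisson draw is replaced by expected
    zone totals (rounded) spread evenly across quadrats, for exact
    end-to-end identities.
    """
    rng = np.random.default_rng(seed)
    labels = list(spec.bin_densities)
    quadrats: list[QuadratCount] = []
    n_total = spec.total_quadrats
    if deterministic:
        total_area = n_total * spec.quadrat_area
        per_quadrat: dict[str, list[int]] = {}
        for label in labels:
            total = int(round(spec.bin_densities[label] * total_area))
            base, extra = divmod(total, n_total)
            per_quadrat[label] = [base + (1 if i < extra else 0) for i in range(n_total)]
    qi = 0
    for area in spec.areas:
        for rep in range(1, spec.replicates_per_area + 1):
            for q in range(1, spec.quadrats_per_block + 1):
                if deterministic:
                    counts = {label: per_quadrat[label][qi] for label in labels}
                else:
                    counts = {
                        label: int(rng.poisson(spec.bin_densities[label] * spec.quadrat_area))
                        for label in labels
                    }
                quadrats.append(
                    QuadratCount(
                        zone=spec.zone,
                        area=area,
                        quadrat_id=f"{spec.zone}-{area}-r{rep}-q{q:03d}",
                        replicate=f"r{rep}",
                        quadrat_area=spec.quadrat_area,
                        counts=counts,
                    )
                )
                qi += 1
    return quadrats


def simulate_fertility(
    p_fert: float,
    n_eggs: int,
    seed: int,
    zone: str = "HP",
    month: str = "2014-01",
    size_class: str = "US",
    p_pluteus: Optional[float] = None,
    n_plutei: Optional[int] = None,
) -> FertilityAssay:
    """One binomial fertility assay; pluteus counts drawn when requested."""
    if not 0 <= p_fert <= 1:
        raise ValueError(f"p_fert must be in [0, 1], got {p_fert}")
    if n_eggs < 1:
        raise ValueError("n_eggs must be >= 1")
    rng = np.random.default_rng(seed)
    fertilized = int(rng.binomial(n_eggs, p_fert))
    scored = total = None
    if p_pluteus is not None:
        total = n_plutei or 100
        scored = int(rng.binomial(total, p_pluteus))
    return FertilityAssay(
        zone=zone, month=month, size_class=size_class,
        eggs_total=n_eggs, eggs_fertilized=fertilized,
        plutei_scored=scored, plutei_total=total,
    )


# ---------------------------------------------------------------------------
# Bundled scenarios
# ---------------------------------------------------------------------------

_YEAR = [f"2013-{m:02d}" for m in range(6, 13)] + [f"2014-{m:02d}" for m in range(1, 6)]


def hp_like() -> ScenarioSpec:
    """High-pressure-zone scenario: one late-winter/spring spawning event.

    Latent peaks/troughs and fertile-class densities carry the published
    summary values (CS 6.6 -> 1.6, US 4.4 -> 1.3; densities US 2.7,
    CS 0.6 ind m^-2); June baselines are set slightly below the
    low-pressure zone's June values.
    """
    return ScenarioSpec(
        name="hp-like",
        zone="HP",
        months=list(_YEAR),
        gsi=[
            GsiCycleSpec(
                zone="HP", size_class="CS", baseline_mean=5.5,
                windows=[SpawningWindow(
                    build_start="2013-06", peak_month="2014-03",
                    trough_month="2014-05", peak_mean=6.6, trough_mean=1.6,
                )],
            ),
            GsiCycleSpec(
                zone="HP", size_class="US", baseline_mean=4.0,
                windows=[SpawningWindow(
                    build_start="2013-06", peak_month="2014-03",
                    trough_month="2014-05", peak_mean=4.4, trough_mean=1.3,
                )],
            ),
            GsiCycleSpec(zone="HP", size_class="Small-US", baseline_mean=0.6, windows=[]),
        ],
        population=PopulationSpec(
            zone="HP",
            bin_densities={
                "0-10": 0.8, "10-20": 0.9, "20-30": 2.0, "30-40": 3.0,
                "40-50": 2.7, "50-60": 0.6, "60+": 0.0,
            },
        ),
        fertility=FertilitySpec(
            zone="HP", months=["2013-12", "2014-01", "2014-02", "2014-03", "2014-04"],
        ),
    )


def lp_like() -> ScenarioSpec:
    """Low-pressure-zone scenario: early- and late-spring spawning events.

    CS: 6.7 -> 2.5 (Jun-Dec) then 5.4 -> 2.5 (Feb-Apr); US: 5.2 -> 1.0
    then 4.0 -> 1.2 (Feb-May).  Fertile-class densities US 0.4 and
    CS 2.7 ind m^-2 follow the published summary cascade.
    """
    return ScenarioSpec(
        name="lp-like",
        zone="LP",
        months=list(_YEAR),
        gsi=[
            GsiCycleSpec(
                zone="LP", size_class="CS", baseline_mean=3.0,
                windows=[
                    SpawningWindow(build_start="2013-06", peak_month="2013-06",
                                   trough_month="2013-12", peak_mean=6.7, trough_mean=2.5),
                    SpawningWindow(build_start="2013-12", peak_month="2014-02",
                                   trough_month="2014-04", peak_mean=5.4, trough_mean=2.5),
                ],
            ),
            GsiCycleSpec(
                zone="LP", size_class="US", baseline_mean=3.0,
                windows=[
                    SpawningWindow(build_start="2013-06", peak_month="2013-06",
                                   trough_month="2013-12", peak_mean=5.2, trough_mean=1.0),
                    SpawningWindow(build_start="2013-12", peak_month="2014-02",
                                   trough_month="2014-05", peak_mean=4.0, trough_mean=1.2),
                ],
            ),
            GsiCycleSpec(zone="LP", size_class="Small-US", baseline_mean=0.6, windows=[]),
        ],
        population=PopulationSpec(
            zone="LP",
            bin_densities={
                "0-10": 0.5, "10-20": 0.6, "20-30": 0.5, "30-40": 0.6,
                "40-50": 0.4, "50-60": 1.0, "60+": 1.7,
            },
        ),
        fertility=FertilitySpec(
            zone="LP", months=["2013-12", "2014-01", "2014-02", "2014-03", "2014-04"],
        ),
    )


SCENARIOS = {"hp-like": hp_like, "lp-like": lp_like}


# ---------------------------------------------------------------------------
# Full simulation runs
# ---------------------------------------------------------------------------

@dataclass
class SimulationRun:
    """A generated dataset plus the latent truth that produced it."""

    seed: int
    spec: ScenarioSpec
    urchins: list[UrchinRecord]
    quadrats: list[QuadratCount]
    assays: list[FertilityAssay]
    truth: dict


def _child_seeds(seed: int, k: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s) % 2**31 for s in state]


def scenario_truth(spec: ScenarioSpec) -> dict:
    """Latent parameters and the cascade they imply, via the pipeline's
    own cascade functions applied to the true means and densities."""
    scheme = SizeClassScheme()
    table = table_from_bin_densities(spec.zone, spec.population.bin_densities)
    class_density = fertile_class_density(table, scheme)
    classes: dict[str, dict] = {}
    per_class_totals: dict[str, tuple[float, float]] = {}
    for g in spec.gsi:
        if not scheme.fertile_flags.get(g.size_class, False) or not g.windows:
            continue
        density = class_density[g.size_class]
        events = []
        gos = []
        for w in g.windows:
            igo = individual_gamete_output(w.peak_mean, w.trough_mean)
            go = gamete_output_per_m2(igo, density)
            gos.append(go)
            events.append(
                {
                    "start_month": w.peak_month, "end_month": w.trough_month,
                    "pre_gsi": w.peak_mean, "post_gsi": w.trough_mean,
                    "igo": igo,
                    "magnitude_pct": spawning_magnitude(w.peak_mean, w.trough_mean),
                    "go": go,
                }
            )
        tgo, mgo = class_totals(gos)
        per_class_totals[g.size_class] = (tgo, mgo)
        classes[g.size_class] = {
            "density": density, "events": events, "tgo": tgo, "mgo": mgo,
            "individual_sd": g.individual_sd, "baseline_mean": g.baseline_mean,
        }
    pop_tgo, pop_mgo = population_totals(per_class_totals)
    return {
        "zone": spec.zone,
        "classes": classes,
        "pop_tgo": pop_tgo,
        "pop_mgo": pop_mgo,
        "bin_densities": dict(spec.population.bin_densities),
        "total_density": float(sum(spec.population.bin_densities.values())),
    }


def simulate_scenario(
    spec: ScenarioSpec, seed: int, deterministic_counts: bool = False
) -> SimulationRun:
    """Generate all three input tables plus the ground truth for one zone."""
    seeds = _child_seeds(seed, 2 + len(spec.gsi) + len(spec.fertility.months))
    urchins: list[UrchinRecord] = []
    for i, g in enumerate(spec.gsi):
        urchins.extend(
            simulate_gsi_records(
                g, spec.n_per_month, seeds[i], months=spec.months,
                allometry=spec.allometry,
            )
        )
    quadrats = simulate_quadrats(
        spec.population, seeds[len(spec.gsi)], deterministic=deterministic_counts
    )
    assays = [
        simulate_fertility(
            spec.fertility.p_fertilization, spec.fertility.n_eggs,
            seeds[len(spec.gsi) + 1 + j],
            zone=spec.zone, month=month, size_class=spec.fertility.size_class,
            p_pluteus=spec.fertility.p_pluteus, n_plutei=spec.fertility.n_plutei,
        )
        for j, month in enumerate(spec.fertility.months)
    ]
    truth = scenario_truth(spec)
    truth["seed"] = seed
    return SimulationRun(
        seed=seed, spec=spec, urchins=urchins, quadrats=quadrats,
        assays=assays, truth=truth,
    )


def write_scenario(run: SimulationRun, outdir: str | Path) -> dict[str, Path]:
    """Write urchins.csv, quadrats.csv, fertility.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "urchins": outdir / "urchins.csv",
        "quadrats": outdir / "quadrats.csv",
        "fertility": outdir / "fertility.csv",
        "truth": outdir / "truth.json",
    }
    write_urchin_records(run.urchins, paths["urchins"])
    write_quadrat_counts(run.quadrats, paths["quadrats"], PipelineConfig())
    write_fertility_assays(run.assays, paths["fertility"])
    paths["truth"].write_text(
        json.dumps(run.truth, indent=2, sort_keys=True), encoding="utf-8"
    )
    return paths
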