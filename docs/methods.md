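# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistics package's methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Gonadosomatic index and stratification

GSI = 100 · gonad wet weight / total wet weight (%), computed per individual
and aggregated per calendar month within a (zone, size class) stratum. Sexes
are pooled by default (sea urchin populations are typically near 1:1; a config
flag splits them). Months are calendar strata with no day-level weighting —
the design assumes roughly one collection per month. The SE of a month is the
sample SD over individuals divided by √n; a singleton month has SE 0 by
convention (n is carried so users can filter), so plotting and detection never
fail on sparse months. Months with no records inside the sampled span are
reported as gaps and skipped, never imputed: substituting values observed in
other years is not reproducible from the data at hand, so a missing November
stays missing. (Optional linear interpolation of single-month gaps exists for
detection context and is off by default.)

Size classes are half-open intervals in test diameter without spines: lower
bound inclusive, upper exclusive, so a 50.0-mm animal is commercial size. The
commercial lower bound defaults to the legal minimum landing size (50 mm) and
is configurable, as are the 10-mm census bins.

## Spawning-event detection

The field definition — the highest and lowest mean monthly GSI bracket the
spawning period — is operationalised as a reversal-confirmation (zigzag) scan
over the mean values only (SEs are ignored for detection):

* seeking a peak, the running maximum is tracked; a decline is confirmed once
  the series drops by ≥ `min_drop_pct` (default 30 %) of that maximum, and
  the peak is the earliest month attaining it;
* seeking a trough, the running minimum is tracked; the decline ends when the
  series rebounds by ≥ the same fraction of the rebound level, or at the end
  of the series, and the trough is the earliest month attaining the minimum.

Every reported event therefore drops by at least the threshold, events are
disjoint and time-ordered, and — importantly for noisy monthly means — a
sub-threshold mid-decline rebound can neither split one long decline into two
events nor promote a build-up wiggle into an event. A simpler rule that pairs
each local maximum with the next local minimum fails exactly there: with
realistic between-individual noise (monthly SE ≈ 0.3 GSI points at n = 8) a
long decline is split whenever a small rebound separates two sub-declines
that each pass the threshold. The zigzag semantics coincide with the simple
rule on noise-free series; the test suite checks the detector against
declarative event axioms (slice-extremum, threshold, disjointness and
completeness conditions) that characterise the zigzag output exactly.

The 30 % default separates reported spawning magnitudes (≈ 54–81 % in the
motivating data) from month-to-month fluctuation; it is a configurable
inference, not a measured constant. Ties between equal extremes resolve to
the earliest month, for determinism. `min_duration_months` (default 1
inter-month step) filters degenerate events.

## Densities and size frequency

Per-bin density is the ratio of totals (Σ counts / Σ area), which is unbiased
under unequal quadrat areas, rather than the mean of per-quadrat ratios. SEs
are computed across replicate blocks — quadrats grouped by (area, replicate),
matching a design of two 25-m² replicates per area — because that is the
grain at which such surveys report ± values; a flag switches to per-quadrat
blocks. Published ± values of this kind are not always labelled SD or SE; this
package's outputs are SEs. Frequencies are 100 · bin density / total density;
an empty census reports zero frequencies with a warning rather than NaNs.
Fertile-class densities are sums of whole census bins; a bin that straddles a
class boundary is a configuration error, not a silent proration.

## The cascade and rounding

IGO = (pre − post)/100, magnitude = 100·(pre − post)/pre, GO = IGO · density,
TGO/MGO = sum/mean of GO per class and year, popTGO/popMGO = sums over fertile
classes. popMGO is the **sum** of class MGOs, not their mean: the population
quantity answers "how much gamete mass does a m² of sea floor release in an
average event", which adds across classes. All intermediates stay at full
precision; presentation rounds half-up at 1 dp (%) / 2 dp (g g⁻¹). Rounding
intermediates and propagating (e.g. 0.04 · 2.7 = 0.108 instead of
0.042 · 2.7 = 0.1134) is detectably different and is not the computation
path. Units: g g⁻¹ denotes gonad wet mass released per unit body wet mass;
the cascade never converts to absolute grams per m², so GO-type quantities
are mass fractions scaled by animal density.

A class configured fertile is included in the population totals unless its
fertility assays fail: the gate is mean fertilization percentage across the
class's assays ≥ the success threshold (default 80 %, inclusive). Classes
with no assay data are assumed fertile, mirroring field practice where
commercial-size animals are not assayed. The Small-US class is carried
through GSI and density stages but never enters the cascade.

## Cochran's C

C = max(s²ᵢ) / Σ s²ᵢ over k cells with common replicate count n, bounded by
[1/k, 1] and scale-invariant. No p-value is computed; (C, k, n) is returned
for use with published critical-value tables, since the statistic serves as a
screening check before ANOVA-type analyses that this package deliberately
leaves to general statistics software.

## Synthetic-data generator

The generator is first-class, tested code that defines the conditions under
which the pipeline's recovery is demonstrated.

* **Latent GSI trajectory**: piecewise-linear build-up to each spawning
  window's peak and decline to its trough (not a sinusoid), matching the
  build-up/abrupt-decline shape of observed annual cycles and keeping the
  true pre/post months unambiguous. Outside windows the mean sits at a
  baseline. Individual GSI ~ Normal(latent mean, `individual_sd`), truncated
  at 0; at the signal-to-noise of interest (means ≥ 1 GSI point, sd ≤ 1) the
  truncation bias is negligible.
* **Bodies**: TD uniform within the class interval (commercial class within
  [50, 70] mm); total weight from TW = a·TD^b with a = 5·10⁻⁴ g mm⁻³, b = 3
  (≈ 62 g at 50 mm, realistic for the species and used only to give records
  plausible masses); gonad weight is derived from the sampled GSI, so the
  generator's truth is expressed in the statistic the pipeline estimates.
* **Censuses**: counts ~ Poisson(density · quadrat area) over 2 areas × 2
  replicates × 50 quadrats of 0.25 m² (200 quadrats, 50 m² per zone — half
  the motivating survey's area, plenty for the recovery studies at these
  densities). A deterministic mode replaces draws by expected totals spread
  across quadrats, enabling exact end-to-end identities.
* **Fertility**: binomial draws for fertilised eggs (default p = 0.92 of 300
  eggs) and plutei (p = 0.97 of 150), consistent with reported 87–96 %
  fertilisation and 95–100 % larval success.
* **Determinism**: one integer seed; all streams derive from it via
  `SeedSequence`, and identical seed + spec give byte-identical CSVs.

The bundled `hp-like` scenario carries one spawning window per fertile class
(CS 6.6 → 1.6, US 4.4 → 1.3, March → May) and bin densities summing to
10 ind m⁻² with US 2.7 and CS 0.6; `lp-like` carries two windows per class
(CS 6.7 → 2.5 and 5.4 → 2.5; US 5.2 → 1.0 and 4.0 → 1.2) with US 0.4 and
CS 2.7. The published account of the low-pressure zone is internally
inconsistent about the commercial-class density (per-bin values summing to
3.0 vs 2.7 used in its summary cascade); the generator follows the cascade
value (bins 1.0 + 1.7) so that the zero-noise end-to-end identity against
the summary is well defined. June baselines for the hp-like scenario (CS 5.5,
US 4.0) sit slightly below the low-pressure June peaks, reflecting the
reported "slightly different at the beginning" starting conditions; n = 8
individuals per month per class matches the balanced design used for the
motivating analysis of variance.

**What the generator does not emulate**: within-month sampling dates,
individual growth or mortality, spatial autocorrelation between quadrats,
overdispersed (non-Poisson) counts, sex differences in GSI, and
gonad-maturity histology. Passing recovery tests therefore demonstrate the
pipeline's correctness under idealised sampling, not robustness to every
field artefact.

## Problem sizes and numerical notes

Recovery studies use 20 seeded runs per scenario with n = 8 urchins per month
per class and 200 quadrats per zone; each run takes milliseconds, the whole
suite a few seconds. Tolerances: detection and cascade identities are exact
to float precision (asserted at 1e−9–1e−12); recovery checks allow ±5
percentage points on median magnitude and ±15 % relative on median popMGO,
reflecting peak-selection bias (the observed maximum of noisy monthly means
slightly overestimates the latent peak, by ≈ +1–2 magnitude points at these
noise levels) and Poisson census error (≈ 9 % SE on the undersized class per
run). Degenerate inputs are errors, not NaNs: zero surveyed area, empty
strata, declines with pre ≤ post, all-zero variance sets.

## Known limitations

* Event detection assumes at most one decline per confirmed peak and cannot
  represent overlapping spawning by subgroups within a stratum.
* The fertility gate uses mean fertilization across assays; with strongly
  month-dependent fertility a per-month gate might be preferable.
* The ± convention on published densities is assumed to be SE when a summary
  is entered directly; if a source reported SDs the uncertainty (not the
  point estimates) would be misread.
* GSI-based gamete output measures relative, not absolute, fecundity; no
  egg-count conversion is attempted.
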