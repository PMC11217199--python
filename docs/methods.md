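# Methods

## Model and scope

`microcost` implements a deterministic, closed-form mixed-costing model
for a diagnostic pathway: tariff pricing for clinical evaluation steps
and bottom-up microcosting for the laboratory and operations steps, over
a fixed budget horizon. There is no discounting, inflation adjustment or
depreciation schedule (the Brazilian budget-impact guideline the model
follows uses undiscounted acquisition-plus-maintenance accounting), and
no probabilistic sensitivity analysis — every output is arithmetic on
the inputs.

Pathway steps are identified by the strings `"1"`–`"8"` plus
`"operation"`, a pseudo-step holding administration and sample
logistics. Steps 1 and 8 are reimbursement-priced; 2–7 and operation are
microcosted. All per-exam figures are expected values per tested sample
(proband or relative), and money is carried at full float precision
internally — rounding to cents or integer percent happens only in the
reporting layer, which rounds half away from zero for percentages.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `overhead_rate` | 0.10 | indirect-cost markup per step (existing facility; 0.20–0.30 is the conventional band, swept in sensitivity analysis) |
| `sanger_fraction` | 0.5 | patients needing confirmatory Sanger sequencing |
| `horizon_years` | 5 | budget horizon for acquisition/maintenance/purchasing |
| `maintenance_rate` | 0.05/year | annual equipment maintenance, fraction of acquisition cost |
| `annual_multiplier` | 14.3 | monthly→annual wage factor under Brazilian labour law |
| `weekly_hours`, `weeks_per_year` | 40, 52 | denominator of the hourly wage rate |
| `prevalence_per_10k` | 4.0 | prevalent cases feeding year-1 demand |
| `cumulative_incidence_per_10k` | 3.46 over 15 y | incident cases feeding years 2+ |
| `sus_share` | 0.76 | fraction of the population using the public system |
| `family_members_per_proband` | 2 | trio analysis: samples per proband = 3 |
| sequencer spec | 240 × 2 × 22 / 2 | samples/flowcell × flowcells/run × workdays ÷ run days → 5,280/month |
| `km_per_liter`, `avg_speed_kmh` | 8, 30 | transport fuel and driver-time models |

Overhead is deliberately implemented as a markup on **each step's direct
cost**, not on the grand total: this is the only interpretation
consistent with every published per-step overhead cell (e.g. a direct
cost of 122.34 yields 12.23 of overhead). For the same reason, overhead
is **held at its baseline value** during component tornado scans;
rescaling it would inflate the equipment-doubling impact from 6.9 % to
7.6 % and contradict the published integer impacts.

Annual incidence for years 2+ is the cumulative incidence divided by its
age interval (3.46/10,000 over 15 years → 0.2307/10,000 per year), with
an explicit `annual_incidence_per_10k` override. Probands are rounded up
to whole persons per year *before* the family multiplier — people are
integral, and the ceiling is conservative in the same spirit as batch
purchasing. The catchment population is a configuration input, never a
constant.

## Scenarios and utilisation

A `Scenario` fixes the demand basis (epidemiological parameters or a
fixed horizon sample count), the overhead rate, and the equipment
utilisation rule: `shared` divides each machine's horizon cost by its
own annual throughput × horizon (a multi-disease hub), `dedicated`
divides by the pathway's horizon demand only (the worst case). Transport
is folded into the operation step: the horizon transport bill (fuel +
hired-driver time, with driver time = distance over an assumed 30 km/h
urban speed, since no time model is published) spread over every exam of
the horizon, with fuel reported under consumables and driver time under
staff.

## Component-mode ingestion and the published fixture

The model's raw supplementary price lists are unpublished. The package
therefore ships the published per-step component costs (consumables,
staff, equipment in USD, plus the two clinical tariffs) as a fixture,
and `component_mode_ingest` builds step costs from such a table while
*always recomputing overhead* from the direct components — so the markup
and aggregation layers are genuinely exercised. The fixture stores USD
values as printed; BRL figures are treated as display conversions at the
fixed rate 5.1686 BRL/USD. The fixture's Sanger column is taken as the
already probability-weighted expected cost (the published table does not
say; ingesting it unweighted would double-apply the 0.5 factor).

Because the printed cells are rounded to cents, their sums can differ
from the publication's own (internally unrounded) totals by a cent or
two: the reference scenario reproduces 527.835 against a printed 527.85,
and the alternative scenario 386.958 against a printed 386.98 — the
printed component row totals carry about 0.02 of hidden decimals that a
per-cell fixture cannot recover. No attempt is made to "correct" the
cells toward the printed totals.

## Synthetic catalogs and calibration

`generate_catalog` draws a structurally realistic random catalog
(batch-constrained consumables on steps 2–7 and operation, staff roles
with hands-on minutes, equipment with pro-rata shares that sum exactly
to one, clinical tariffs, and a 12-hospital transport network) from a
seeded `numpy` generator; identical seeds give identical catalogs.
Prices and wages are uniform draws within configured ranges — the
generator emulates the *structure* of real supplementary price lists
(batch granularity, shared machines, wage-derived hourly rates), not
Brazilian price distributions, turnover, procurement discounts or
exchange-rate movement. Tests passing on synthetic catalogs therefore
validate the engine's arithmetic and invariants, not the realism of any
particular price.

`calibrated_catalog` inverts the engine: given a target component table
it synthesises one unit-batch consumable, one staff role (one hour
hands-on at an hourly rate equal to the target) and one dedicated
equipment item per step whose bottom-up costing reproduces the target to
within a cent, proving the full purchasing/wage/equipment path can
realise the published figures. The confirmatory step's resources are
inflated by 1/`sanger_fraction` so the engine's weighting lands back on
the target.

## Numerical choices

- Batch counts use `ceil(round(x, 9))` to keep float noise from pushing
  an exact multiple over a batch boundary; demand ceilings likewise.
- Equipment share sums are validated to 1 ± 1e-9; the generator pushes
  any Dirichlet float residual onto the largest share.
- Zero horizon demand is an error (per-exam cost undefined), as is a
  zero diagnostic yield or a non-positive exchange rate.
- Currency conversion is an exact bijection pre-rounding; USD→BRL→USD
  round-trips to 1e-9.

## Problem sizes

Everything is closed-form, so the test suite and the acceptance script
run on desk-scale inputs: component tables with 7–9 steps, synthetic
catalogs of a few dozen items, demands up to a few thousand exams, and
brute-force purchase-simulator cross-checks on catalogs of ≤ 5 items and
≤ 50 exams where exhaustive simulation is exact.

## Known limitations

- No demographic projection (births, aging, migration); demand is static
  rates on a fixed base population.
- The published "operational cost per km", the dedicated-equipment
  worst-case total and the municipality's absolute annual demand depend
  on unpublished inputs (the hospital network's configured distances and
  the catchment population); the engine computes all three quantities
  from configuration but the package pins no expected values for them.
- The published top-consumable ±30 % scan varied an unspecified subset
  of expensive reagents; `tornado_top_consumables` supports top-*k*
  subset scans, but only a full-component scan is reproducible from the
  published component table.
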