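# Methods

## Problem and model

Food fortification must balance two population-level risks: inadequacy
(habitual intake below the recommended intake, RI) and toxicity (intake
above the tolerable upper intake level, UL). The package treats a
fortification plan as a vector of levels — µg of vitamin D added per 100 g
of each candidate vehicle — and evaluates it against both risks on a
population of individual dietary records.

For individual *i* with vehicle consumptions `grams_i(v)` (g/day), a plan
with levels `level(v)` (µg/100 g) adds

    added_i = (1/100) Σ_v grams_i(v) · level(v)   [µg/day]

and total intake is `baseline_i + added_i + supplement`, with the
supplement dose converted at 40 IU = 1 µg. The model is deliberately
linear: no bioavailability, cooking-loss or overage adjustments are made
(they are out of scope), so `added` is exactly proportional to both grams
and levels — a property the test suite checks against an independent
double-loop summation.

### Plan search

Plans live on a small discrete grid (default 1–4 µg/100 g, either one
shared level or one level per vehicle; 4 uniform plans or 4⁸ = 65,536
per-vehicle plans for eight vehicles — full enumeration, no heuristics).
The two published decision criteria are made precise as:

* **hard constraint** — a plan is feasible only if *no* individual's total
  intake exceeds the UL (one person over the UL invalidates the plan);
* **objective** — among feasible plans, minimize the fraction of the
  population outside the closed band [RI, UL]; boundary values count as
  within.

Ties are broken by the smallest total added µg across the plan's levels
(the cheapest equally-performing plan), then by enumeration order, so the
optimum is deterministic. When no plan is feasible the optimizer returns an
explicit "no feasible plan" result carrying the least-violating plan for
diagnostics rather than raising.

**Supplement asymmetry.** The safety constraint is evaluated under the
supplement scenario passed in (0, 400 or 1000 IU/day for everyone — the
worst case for toxicity), while the coverage objective is evaluated on
diet-only intake by default. The rationale: a fortification level must be
safe for people who *do* take supplements and adequate for people who do
*not*. Under a single scenario applied to both sides, any feasible plan at
a 1000 IU scenario would trivially have objective 0 (the supplement alone
clears the 10 µg RI and feasibility excludes UL exceedance), and the
tie-break would always select the lowest grid level — the reported optimum
would be unrecoverable in principle. The coverage scenario is an explicit
parameter for users who want a different convention.

Two threshold presets are shipped and always chosen explicitly:
`"paper-methods"` (RI = 40, UL = 250 µg/day) and `"iom"` (RI = 10,
UL = 100 µg/day, RDA = 20 µg) — the source literature uses both and does
not state which governed the simulation, so neither is hard-coded.

### Formula models

In IOM-RDA units (µg / 20):

    FA_Flynn     = (UL − CI95) / (fortified_fraction · portions · PFF)
    FA_Rasmussen = (UL − (CI95 + SI)) / (EI95 · PFF)

Defaults: UL = 5, CI95 = 0.05, portions = 42 (4200 kcal/day at the 95th
percentile in 100-kcal portions), fortified_fraction = 0.5, EI95 = 18.8,
PFF = 0.11, RDA = 20 µg. All of these are configuration values, not
literals. Flynn ignores supplement intake by definition; Rasmussen
subtracts it from the headroom. When SI = 0 and EI95 =
fortified_fraction × portions the two formulas coincide exactly (a tested
identity). Both are strictly increasing in UL and strictly decreasing in
CI95 and PFF (tested by property sweep).

The table generator takes PFF values explicitly and never derives them from
column labels such as "10%", because the published 10% column is actually
computed at PFF = 0.11 (8 foods of 70).

## Synthetic populations

The generator emulates the summary structure of the source cohort, not its
microdata:

* **baseline vitamin D** — log-normal parameterised by its *arithmetic
  mean* (default 4 µg/day) and a log-scale sd (default 0.6);
* **energy** — log-normal whose (µ, σ) are solved in closed form so that
  the mean (default 2000 kcal/day) and the 95th percentile (default
  4200 kcal/day) are matched exactly;
* **vehicle grams/day** — independent log-normals per vehicle, given by
  median and log-scale sd; an optional common per-person "appetite"
  multiplier (median 1) introduces positive cross-vehicle correlation and
  is off by default;
* **supplement** — a scenario constant (0/400/1000 IU/day) for every
  record; supplement prevalence is not modelled.

Log-normality is the standard working assumption for strictly positive
intake quantities; the source publishes no distributional detail. The
per-vehicle medians are package defaults chosen to resemble adult Iranian
staple consumption (≈ 120 g/day per bread, 50–100 g/day dairy drinks,
20 g/day cheese, 8 g/day butter); they are not cohort values, which are
unpublished. Vehicle energy densities are shipped verbatim from the
published comparison table, including the implausibly low 37.5 kcal/100 g
for bread — they are a fixture for reproducing that table, not a nutrient
database.

Two published 95th-percentile energy statements (4200 kcal/day = 42
portions vs EI95 = 18.8 portions) are mutually inconsistent; both are
carried as independent configuration constants — the generator calibrates
to 4200 kcal while the Rasmussen default uses EI95 = 18.8. Similarly, a
95th-percentile current intake of 1 µg/day is inconsistent with a mean of
4 µg/day (a percentile cannot sit below the mean of a positive
distribution); the generator calibrates to the mean, and the formula module
takes CI95 as a direct input so the published arithmetic is reproduced
regardless.

**What passing tests do and do not show.** The generator reproduces the
configured moments (±5% bands at n = 10,000 over several seeds, tested),
but real FFQ data have features it lacks: correlated vehicle consumption,
age/sex/energy dependence of intakes, reporting error, and supplement-use
heterogeneity. Results on synthetic populations validate the *machinery*
(constraint handling, objective, determinism), not cohort-specific numbers.

### The recovery fixture

The optimum-recovery experiment uses a documented calibrated fixture:
n = 2000 at seed 42, the IOM preset, a 1000 IU/day safety scenario, and a
heavy-consumer tail (per-vehicle log-scale sd 0.65, medians as above). The
calibration places the maximum consumer at ≈ 2000 g/day of summed vehicles,
so the 4 µg/100 g level pushes that individual's scenario intake above the
100 µg/day UL (max ≈ 108 µg) while 3 µg/100 g stays below (max ≈ 88 µg),
and diet-only adequacy still improves up to 3 µg. On this fixture the
uniform search returns 3 µg/100 g. This is a parameter-recovery
*reconstruction* of the published optimum — the cohort's per-level coverage
fractions were never printed, so no replication on real data is possible.

## Numerical choices

* Rounding for display follows round-half-up (`decimal`), matching how the
  published tables appear to round; stored values keep full precision.
  Known discrepancies are pinned at their *computed* values: the Flynn 100%
  cell computes 23.57 %RDA (printed: 23) and its µg equivalent 4.71
  (printed: 4.6). The published Rasmussen cells at 10%/5% PFF (210, 478)
  and the 1000 IU row (175) are not reproducible from the stated formula
  under any consistent input choice; the implementation pins the formula as
  written and does not reverse-engineer those cells.
* The method-2 basket total uses the published two-decimal kcal-portion
  multipliers (0.37, …, 9.0) by default so the printed 28.7 µg total is
  matched exactly; `use_printed_multipliers=False` switches to full-precision
  energy densities (total 28.77 µg).
* The standard basket is 100 g of each of the eight vehicles (the published
  800 g total implies equal portions); it is configurable.
* Coverage fractions are computed so that below + above + within sums to
  exactly 1 (within is the complement of the other two).
* Population CSVs are written with `%.17g` floats and read with pandas'
  round-trip parser, so write→read is bit-exact; identical parameters and
  seed give byte-identical files.
* The log-normal energy fit uses the smaller root of the percentile/mean
  quadratic (σ = z₉₅ − √(z₉₅² − 2 ln(p95/mean))), which exists whenever
  p95/mean < exp(z₉₅²/2) ≈ 3.87; parameters outside that range are rejected
  with a named error.

## Problem sizes

Default analyses run at n = 2000 individuals (the recovery fixture) with
4-plan uniform grids; calibration checks use n = 10,000 across five seeds;
the full 4⁸ per-vehicle grid is exercised for enumeration and on small
populations (n = 200) for optimizer cross-checks. These sizes give stable
sampling bands for every tested quantity while keeping the whole suite in
the tens of seconds on one CPU.

## Known limitations

* No bioavailability, cooking losses, seasonality, sun exposure or serum
  25(OH)D modelling — intake only.
* Adults 35–65 only; infants and children are outside the model.
* Only vitamin D constants ship; other micronutrients are supported
  structurally (every threshold and conversion is a parameter) but no
  nutrient database is included.
* The plan grid is discrete by design; continuous-level optimization, cost
  modelling and multi-objective analyses are non-goals.
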