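# Methods

## Problem and scope

`foodbanklp` models one week of food-bank provisioning as a continuous
linear program. The food bank buys bulk food-group masses at median market
prices, receives exogenous "effective" donations (donations net of spoilage),
and distributes both to beneficiary groups defined by sex and age band. The
model covers macronutrients and energy only; micronutrients are proxied by a
fruit-and-vegetable minimum, water is treated as a free good, and storage,
logistics and preparation costs are out of scope. Food quantities are
continuous (kg), which is accurate at the tonnage scale involved.

## Units

One convention is used everywhere: food masses kg/week; nutrient
requirements kg/person/week (energy kcal/person/week in the tables, Mcal
inside the LP); nutrient densities g per kg of food (energy kcal/kg);
prices EUR/kg; penalties EUR/kg of non-supplied nutrient. The energy slack
is measured in Mcal with a penalty in EUR/Mcal, keeping the requirement
constraints uniform across nutrients; in the bundled case study the energy
slack is zero at the optimum (a test asserts this), so its unit convention
does not affect any reported figure.

## Input preprocessing

**Density normalization.** Published per-kg nutrient contributions rarely
sum to exactly one kilogram because of rounding in the source tables. Each
row is therefore rescaled by a single factor `1000 / (mass sum incl.
water)`, applied uniformly to every column (masses, water, fatty-acid
sub-fractions, energy), which preserves all within-food nutrient ratios and
makes the operation idempotent. The omega-3 and omega-6 columns are
sub-fractions of the lipids column — counting them in the mass sum would
double-count fat — so they are flagged `counts_toward_mass=False` and
excluded from the target sum while still being rescaled.

**Donations.** Annual donation totals are spread uniformly over the 52
weeks of the year. This deliberately ignores seasonality (e.g. holiday
collection drives); the model is a steady-state weekly planner.

**Coverage.** Only a fraction of registered beneficiaries draws aid in any
given week; headcounts are multiplied by the coverage fraction (0.5 in the
Madrid dataset) and kept fractional, since the LP is continuous.

## Constraint design

The caloric caps deserve comment because the source material for this model
class states them ambiguously: the cap inequality is written with the food
index unsummed and a per-group right-hand side. This package resolves the
ambiguity by imposing one cap per (food group, population group, capped
nutrient): the energy a single food group may contribute to one population
group through protein, lipids or carbohydrates is at most `MCAL_r` of that
group's energy requirement. Besides being the literal reading, this scope
doubles as a dietary-variety device — no single food may dominate a
group's caloric budget through one macronutrient — and it reproduces the
2018 Madrid accounting figures, which the pooled alternative (one cap per
nutrient across all foods and groups, available as `cap_scope="total"`)
misses by a wide margin. `MCAL` values are not part of the published
tables; the defaults are the AMDRS upper bounds (carbohydrates 0.65,
lipids 0.35, protein 0.35) with Atwater caloric densities (4/9/4 kcal/g),
all configurable per nutrient.

The bioavailability constraint is implemented as animal protein ≥ AVSP ×
vegetable protein per population group (AVSP = 1/3: one gram of animal
protein per three grams of vegetable protein). Prose descriptions of this
rule sometimes state the inverse relation; the inequality used here is the
one consistent with both the equation form of the rule and the "1 g animal
per 3 g vegetable" phrasing.

The fruit-and-vegetable minimum is per person and scaled by the effective
headcount of each group; the printed form of the rule omits the headcount
factor, but a fixed 2 kg *per group* of tens of thousands of people would
be vacuous, and the per-person reading matches the reported tonnages.

Requirement constraints are soft (slack variables at 1000 EUR/kg); the
caloric caps, mass balances, fruit/vegetable minimum and bioavailability
floor are hard. An instance can therefore be infeasible only through the
hard constraints, and the solver surfaces that as a status rather than an
exception.

## Aggregate vs. split formulation

The mass balance comes in two equivalent forms: aggregate
(`Σ_p s_ap = c_a + DON_a − e_a`) and split, which introduces `c_ap`/`d_ap`
to distinguish purchased from donated deliveries per group. No constraint
or cost distinguishes the two delivery channels, so the optimal objective
is identical (a property test asserts agreement to 1e-6 relative); the
split form exists as the extension point for channel-specific constraints
such as expiry dates. Only the objective value is treated as unique:
alternate optima may distribute `s_ap` differently, so tests and reports
target objective-level and aggregate quantities.

## Reported figures

- purchase cost `Σ PRE_a·c_a`, and a donation valuation `Σ PRE_a·DON_a` at
  the same median prices (donations are a sunk cost; valuing them at
  purchase prices is the only pricing the data defines);
- total provisioning cost = purchases + donation valuation, with the
  shortfall penalty tracked separately as a social rather than monetary
  cost;
- total food mass handled `Σ s_ap`;
- per-person monthly cost = weekly total / effective persons × weeks per
  month (52/12 ≈ 4.333 by default);
- a shortfall table with absolute and relative (`cns / (NEC·CARD)`)
  non-supplied quantities;
- scenario deltas `(base − alternative)/base` for cost and mass, used for
  the zero-donation counterfactual.

On the bundled dataset the optimum distributes every donated kilogram
(`e_a = 0`), carries no nutrient shortfall, and prices out at ~70 EUR per
person per month; dairy and vegetables reach beneficiaries exclusively
through donations.

## Synthetic instances and the oracle

The generator works backwards from a hidden feasible allocation `s0`:
density rows are drawn from a water-weighted Dirichlet and scaled to
1000 g/kg, prices and headcounts are drawn uniformly, and every requirement
is set to `tightness × (what s0 delivers per person)`. The fruit/vegetable
minimum and protein-ratio floor are calibrated from the same plan scaled by
`min(tightness, 1)`, and the caloric caps are calibrated so the plan keeps
10% headroom with a tightness-invariant absolute ceiling. Consequences,
each covered by a test: every generated instance is feasible for any
tightness; for `tightness ≤ 1` a zero-shortfall optimum exists and — the
shortfall penalty being set two orders of magnitude above the cheapest
marginal source of any nutrient — is cost-minimal; for tightness well
above 1 the capped nutrients cannot be fully delivered and shortfalls
appear. What the generator does *not* emulate: realistic consumption
distributions, correlated prices, or seasonal donation patterns — passing
tests on synthetic instances demonstrate solver correctness, not
nutritional realism.

The independent oracle (`brute_force_solve`) enumerates all basic
solutions of instances with at most six variables — every intersection of
n active constraints drawn from the equality rows, inequality rows and
bounds — checks feasibility exhaustively and returns the best vertex. It
shares only the constraint assembly with the main path, never the solver;
agreement with HiGHS is checked on 200 random instances per test run.

## Numerical choices

- Feasibility tolerance 1e-6 absolute on returned solutions (asserted).
- Objective comparisons at 1e-6 relative plus 1e-9 absolute (vertex
  arithmetic can produce ±1e-12 around an exact zero).
- Oracle vertex feasibility tolerance 1e-7; near-singular bases are
  skipped rather than refined, which is safe because the optimum is also
  reachable through a well-conditioned basis in these tiny instances.
- Density row sums validated to ±0.01 g against the 1000 g target,
  matching the rounding of the published tables; full-precision values are
  written with shortest-round-trip `repr` so load/write round-trips are
  exact.
- Degenerate ties between alternate optima are reported as the solver
  returns them.

## Known limitations

- Single-week steady state: no storage, expiry, or seasonal dynamics.
- The shortfall penalty is a uniform policy knob, not an estimated health
  cost; results involving non-zero slacks should be read as "the model
  refuses to pay more than 1000 EUR/kg", nothing more.
- Published reference figures for this model class include small omega-3/6
  shortfalls at the optimum; under this implementation's cost structure the
  marginal cost of the omega fatty acids stays near 100 EUR/kg — well
  under the penalty — so the optimizer supplies them in full and the
  shortfall table is empty. The headline cost and mass figures are
  unaffected.
- Median prices are a single scalar per food group; no intra-group product
  substitution is modeled.
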