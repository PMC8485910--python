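# delta

A mass-balance model of the global food system that asks one question:
**if everything produced were shared equally, would the resulting diet meet
everyone's nutrient requirements?**

Scenario-level production of food groups (cereals, dairy, meats, oil
crops, ...) is disaggregated into individual commodities, run through a
deduction cascade — animal feed, supply-chain losses, nonfood uses, the
inedible portion, in-home waste — down to a per-capita daily allocation of
each food, then converted into nutrient supply and compared against
demographically weighted dietary reference values (DRVs). The package is
named for the side-by-side Δ comparison of scenarios it enables: change
production, waste, or the population year, and see which nutrient gaps
open or close.

It is written for researchers and analysts in sustainable-nutrition and
food-systems work who want a transparent, testable engine rather than a
hosted interface. It is not an optimisation tool: it evaluates scenarios,
it does not prescribe them.

## The model

For each food item *i* with farm-gate production $P_i$ (tons/yr, obtained
by distributing each group's production over its items by their baseline
shares):

$$C_i \;=\; \bigl(P_i - F_i - L_i - N_i\bigr)\,(1 - e_i)\,(1 - w_{g(i)})$$

where $F_i$ is feed use (coupled to animal-group production through
baseline feed attribution), $L_i$ supply-chain loss, $N_i$ nonfood use,
$e_i$ the inedible fraction, and $w_{g(i)}$ the population-weighted
in-home waste fraction of the item's food group. $C_i$ is the consumed
edible mass; dividing by the population and 365 days gives the per-capita
allocation $a_i$ in g/person/day. Nutrient supply is then

$$S_n \;=\; \sum_i \frac{a_i}{100}\; d_{i,n}\; \delta_{i,n}$$

with $d_{i,n}$ the density of nutrient *n* per 100 g edible portion and
$\delta_{i,n} \in [0,1]$ a digestibility coefficient that differs from 1
only for protein and the indispensable amino acids. Supply is compared
with the demographically weighted target
$T_n = \sum_s \pi_s \, \mathrm{DRV}_{n,s}$ (population shares $\pi_s$ over
region × sex × age-group strata), giving the gap
$\max(0, 100\,(T_n - S_n)/T_n)$ in percent of target — gaps above 5% are
flagged material. Scenarios with little or no animal-sourced production
automatically switch iron and zinc to their higher vegetarian/vegan
targets. A parallel account converts wasted and lost food into nutrient
terms, so that consumed plus wasted supply always equals a zero-waste run.

Baseline-year production is extrapolated from the multi-year commodity
balance history by a weighted least-squares line fit; all shares and
utilization fractions come from the pooled history.

## Worked example

No real datasets ship with the package; the fixture generator writes
self-consistent miniature worlds (the `analytic` shape has hand-checkable
round numbers — 2 food groups, 3 items, 10 000 people):

```bash
delta fixtures --out demo/world --shape analytic
delta run --data demo/world --out demo/baseline
```

```
scenario 'baseline' (vegetarian): population 10,000, total biomass 1,900 t, consumed edible 1,210 t
wrote demo/baseline/mass_report.csv
wrote demo/baseline/nutrient_report.csv
wrote demo/baseline/waste_report.csv
```

The nutrient report (rounded here for display):

```
nutrient_id unit  supply  target  pct_of_target  gap_pct
    calcium   mg  166.96  1000.0          16.70    83.30
     energy kcal  598.93  2000.0          29.95    70.05
       iron   mg    5.17    16.5          31.32    68.68
     lysine    g    0.60     2.0          29.79    70.21
    protein    g   17.17    45.0          38.15    61.85
```

Reading the first row: the world's three foods deliver 166.96 mg of
calcium per person per day against a demographically weighted target of
1000 mg — an 83% gap, flagged material. The scenario resolves to
*vegetarian* (its only animal-sourced group is dairy), so the iron target
shown is the higher vegetarian value (16.5 mg rather than 11 mg). A
scenario file then changes the system, e.g. halving in-home waste:

```yaml
# halved_waste.yaml
name: halved-waste
waste:
  in_home: 0.5
```

```bash
delta run --data demo/world --scenario halved_waste.yaml --out demo/halved
delta compare --run-a demo/baseline --run-b demo/halved --out demo/delta_report.csv
```

`delta_report.csv` lists, per nutrient, supply under both runs and the
change in supply and gap. Library use mirrors the CLI: `delta.run_directory`,
or `delta.load_dataset` / `delta.Scenario` / `delta.run` for programmatic
scenario sweeps.

## Layout

| module | role |
|---|---|
| `delta.data_io` | schema-validated CSV/YAML readers, report writers |
| `delta.baseline` | baseline-year extrapolation, shares, feed attribution |
| `delta.scenario` | scenario resolution, scaling/zeroing/reallocation, diet mode |
| `delta.massflow` | the deduction cascade to per-capita allocations |
| `delta.nutrition` | nutrient supply and nutrient-waste accounting |
| `delta.requirements_report` | weighted targets, adequacy report, Δ comparison |
| `delta.synthetic_fixtures` | world generators and the brute-force oracle |

See `docs/methods.md` for the modelling conventions, parameter defaults
and known limitations.
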