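# Methods

This note records the modelling conventions, defaults and numerical
choices behind the package, and what the shipped synthetic data can and
cannot demonstrate.

## Model structure and assumptions

The model is a yearly, global mass balance. Food-group production at the
farm gate is the scenario input; everything downstream is deterministic
arithmetic. Core assumptions:

- **Equal distribution.** The per-capita allocation divides global
  consumed mass by global population. If a scenario cannot nourish the
  average global citizen under equal distribution, it cannot do so under
  any real (unequal) distribution; the converse does not hold. Regional
  or individual-diet adequacy is out of scope.
- **Fixed within-group composition.** Scaling a food group scales every
  item in it by the baseline item shares; the model has no mechanism for
  substituting items within a group.
- **Proportions from the pooled history.** Item shares within groups and
  the feed/loss/nonfood fractions are pooled (summed) over all balance
  years rather than averaging yearly ratios; pooling is robust to years
  with zero production and makes the derivation invariant to rescaling
  all masses by a common constant.
- **No pre-farm-gate losses**, no trade, no price response.

## The deduction cascade

Per item, in order: feed → supply-chain loss → nonfood use → inedible
portion → in-home waste. The first three are all defined as fractions of
farm-gate production (not of sequential residuals), so their order cannot
change any result; the stated order is the conventional reading of the
supply chain. Two placement decisions were genuinely open and are fixed
as follows:

- **In-home waste applies to the edible mass**, i.e. after the inedible
  portion is removed. A household discards edible food; bones and peels
  are already excluded.
- **Supply-chain losses carry nutrients only in their edible share.**
  In nutrient-waste accounting the lost mass is multiplied by
  (1 − inedible fraction) before conversion to nutrients; inedible matter
  carries no nutrients by convention. Digestibility weighting applies in
  waste accounting exactly as in consumed supply, which makes the closure
  identity — consumed + wasted = zero-waste supply — hold by construction,
  per nutrient, and testable to 1e-6 relative.

Feed demand couples item flows to animal-group production: each feed
item's baseline feed tonnage is attributed across animal groups (an
explicit attribution table may be supplied and is normalized to the
item's baseline feed tonnage; the fallback attributes proportionally to
the animal groups' baseline production), then scaled by each group's
scenario-to-baseline production ratio. Zeroing meat production therefore
releases feed grain into the food supply automatically.

Infeasible scenarios — any negative intermediate, feed demand exceeding a
feed item's production, or an effective waste fraction above 1 — raise an
error naming the item and stage. Nothing is clamped: silent repair would
hide modelling mistakes.

Regional in-home waste fractions collapse to one global fraction per food
group by population weighting across regions at the scenario year. A
supply-weighted collapse is a conceivable alternative (config key
`massflow.waste_collapse`) but is not implemented; the model's outputs
are global and population weighting matches the per-capita framing.

## Baseline-year extrapolation

Baseline production (the year after the last balance-sheet year) is a
weighted least-squares line fit per item over its history, evaluated at
the baseline year. The weighting scheme rises linearly from 1 (oldest
year) to 2 (newest), favouring recent years while using the whole
history; it is configurable (`interpolation.weights`: linear | uniform |
custom). Any weighting reproduces an affine series exactly, which is the
scheme-independent property the tests pin down (the 2×2 normal equations
are solved on centred years for conditioning, so the exactness holds to
machine precision). Negative extrapolations clamp to zero with a logged
warning — mass non-negativity dominates trend fidelity. Single-year
histories are an error unless constant carry-forward is explicitly
allowed.

## Targets, diet modes and reporting

Targets are convex combinations of stratum DRVs: population shares over
region × sex × age-group (shares sum to 1 within 1e-12) weight reference
values that vary only by sex × age-group — regions contribute population
counts only, since reference values are not regional. Lower and upper
safe bounds are weighted identically and reported only when every stratum
carries them; a bound missing anywhere is reported as missing, not as 0.
Populations at untabulated years are linearly interpolated between the
nearest tabulated years; years outside the span are an error.

Diet mode switches iron and zinc to their alternate targets (the switch
is data-driven: it applies to any DRV row carrying alternate values, and
the shipped tables populate iron and zinc only). "Little or no
animal-sourced food" is quantified as every animal group below 1% of its
baseline production (configurable `diet_mode_threshold`); 1% separates
deliberate exclusion from rounding noise, which no data source pins down
more precisely. A world whose only animal-sourced group is dairy or eggs
classifies as vegetarian even at baseline — with no meat or fish in the
vocabulary, the diet simply is lacto/ovo-vegetarian; the analytic fixture
behaves this way by design. Users may force a mode.

Gap and excess percentages are carried at full precision; rounding to
integers and suppression of immaterial gaps (≤ 5% of target, configurable
`material_threshold_pct`) happen only in the display formatter. The
report always contains every nutrient. Nutrients without an upper bound
report excess as an empty cell, distinguishing "not applicable" from 0.

Nonfood use offers two scenario semantics: `per_capita_constant`
(baseline per-capita nonfood demand held fixed, tonnage scales with
population — the default, matching how biofuel-type demand tracks people
rather than harvests) and `proportional_to_production`.

Days per year is 365 (`massflow.days_per_year`); leap days are noise at
this precision.

## Synthetic data: what it shows and what it does not

The real commodity-balance, composition, DRV and demographic datasets are
not bundled; the generators emulate their **schemas and invariants**, not
their statistical structure. Random masses are log-uniform over
[1e3, 1e7] t to exercise a wide dynamic range; utilization and waste
fractions are Beta-distributed (feed B(2,8) on plant items, losses and
nonfood B(2,12), in-home waste B(2,10), inedible B(2,8)), rescaled so
feed+loss+nonfood never exceeds 90% of production; digestibility is
uniform on [0.3, 1.0]. The paper-shaped world fixes the study geometry —
15 food groups (6 animal-sourced, 9 plant-sourced), 121 commodities, 5
regions, 21 age groups, 2 sexes, 20 balance years — with randomized
values. Consequently the tests demonstrate the *mechanics* (conservation,
closure, weighting, switching, determinism) and cross-validate the entire
pipeline against an independent brute-force oracle to 1e-9 relative; they
do not reproduce published global nutrient gaps, which depend on the
external datasets. The deliberately naive oracle (stdlib csv + dict
loops, no shared code with the pipeline) is the repository's core
acceptance property.

The analytic world's closed forms, derived by hand once and frozen in
code and tests: wheat 1000 t − 200 feed − 100 loss − 50 nonfood = 650 t
to consumers; ×0.9 edible = 585 t; ×0.9 after in-home waste = **526.5 t
consumed** (144.2466 g/person/day at 10 000 people); apple 500 − 50 =
450, ×0.8 = 360, ×0.9 = **324 t** (88.7671 g/day); milk 400, ×1.0, ×0.9 =
**360 t** (98.6301 g/day).

The acceptance script runs ten mini worlds (3 groups, 8 items, 2 regions,
4 balance years) — sizes chosen so the whole check, generation included,
completes in seconds while still randomizing every code path.

## Known limitations

- Bioavailability is modelled only via protein/amino-acid digestibility
  and the iron/zinc target switch; mineral and vitamin absorption (e.g.
  phytate–zinc interaction) is not modelled.
- No unit conversion: composition and DRV tables must agree per nutrient,
  enforced at load time.
- The feed-attribution fallback (proportional to animal-group production)
  is a coarse stand-in for real ration data; supply an explicit
  attribution table when one exists.
- Scenario resolution applies group overrides, then zero-with-
  compensation, then remove-and-reallocate; compensation factors are
  user-supplied (a helper computes the biomass-preserving factor) rather
  than solved for.
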