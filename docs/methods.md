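# Methods

This note documents the model equations, the parameter defaults and why they
were chosen, the synthetic forcing, numerical conventions, and known
limitations. It is the design record for maintainers; the README gives the
user-facing overview.

## 1. Weather generator

The generator produces daily `tmin, tmax, tmean, precip, srad, rh, wind` on a
real calendar (leap days included) from a `ZoneClimateSpec`.

**Rainfall.** Occurrence inside the wet-season window follows a two-state
Markov chain (P(wet|wet) = 0.65, P(wet|dry) = 0.30), giving the rain-spell
persistence typical of the West African monsoon; wet-day amounts are
exponential. Each year's raw total is rescaled exactly to
`annual_rain_mm × y`, where `y` is a lognormal year factor with mean 1 and
coefficient of variation `cv_rain` (y ≡ 1 when `cv_rain = 0`). Rescaling
rather than relying on the law of large numbers keeps short runs on target
and makes the `cv_rain = 0` case exact. No rain falls outside the window.

**Temperatures and radiation.** Seasonal sine curves around the zone means
(amplitude 3.5/3.0 °C for tmax/tmin, hottest ~45 days before the monsoon
onset) plus N(0, 1 °C) noise; rain days are cooled by 1.5 °C and their
radiation damped to 75 % of the clear-sky seasonal curve. `tmean` is always
`(tmin + tmax)/2`. Humidity is high (≈70 %) inside the wet season window and
low (≈30 %) outside.

**Zone defaults.** Sahelian: 400 mm yr⁻¹, wet season DOY 160–269, tmax/tmin
36/22 °C, interannual CV 30 %. Sudanian: 900 mm yr⁻¹, DOY 130–299, 33/21 °C,
CV 20 %. These sit inside the zones' documented climatic ranges (150–600 and
600–1200 mm yr⁻¹; CV ≈ 25–43 % and 13–40 %); they are zone-level choices, not
per-site calibrations, because no site-level statistics were available to
fit.

**What the generator does not emulate:** multi-day synoptic organisation
beyond first-order persistence, temperature–radiation–humidity cross-
correlation beyond the wet-day flags, false monsoon onsets, and spatial
correlation between cells. Tests passing on this forcing therefore validate
the process implementations and their couplings, not site-specific skill.

## 2. Soil water and nitrogen

Each activity (every crop, and the grassland) has its own soil column —
whether crops and grass share soil is genuinely open; separate columns avoid
an artificial competition term. The default profile is a three-layer sandy
loam (0.2/0.4/0.6 m), water stored in mm per layer.

Daily order: rain splits into infiltration (up to `infiltration_capacity`,
default 50 mm d⁻¹) and runoff; infiltration cascades through the layers
filling each to field capacity, the bottom surplus leaving as drainage; soil
evaporation comes from the top layer only, transpiration from rooted layers
in proportion to plant-available water (`water − wp`), with partial layers
weighted by the rooted thickness fraction. Demands are capped at extractable
water, so the day closes to `|ΔS − (I − E − T − D)| < 10⁻⁶ mm` by
construction and no layer crosses its wilting point or saturation.

Reference ET is Hargreaves–Samani
(`ET0 = 0.0023 · Ra · (T_mean + 17.8) · √(T_max − T_min)`), chosen because it
needs only temperatures while the available humidity/wind fields are
synthetic anyway. The drought factor is the rooted-zone available-water
fraction relative to `p_crit` (default 0.5) of capacity, clamped to [0, 1].

Mineral N is a single pool per column: inputs (fertilizer at sowing, manure,
a background mineralization of 0.05 kg N ha⁻¹ d⁻¹) accumulate, crop uptake
is demand-capped by the pool, and leaching removes
`pool · λ · min(1, drainage / capacity)` with λ = 0.5. The N factor is
`uptake/demand`. This is deliberately minimal: the model needs only an
N-limitation signal and a leaching output, not a full C/N cycle.

## 3. Crops

Phenology: thermal time above `t_base`, stages sown → emerged → anthesis →
mature at cultivar thresholds; an optional `topt_ceiling` caps the daily
increment (off by default — cardinal temperatures were not available).
Growth: `ΔDM = RUE · f_int · 0.5·R_g · min(f_water, f_N)` (PAR = 0.5 of
global radiation, Liebig's minimum for combined stress), partitioned by a
development-stage table that shifts from leaf/root to storage after
anthesis; LAI grows as `SLA · Δleaf` and is seeded at sowing from a 1 g m⁻²
leaf reserve so the canopy can bootstrap. Harvest at maturity returns the
storage pool capped at `HI_max · AGB`; the residue is `AGB − yield`, half of
it (default) usable as livestock feed.

Sowing uses the regional rule: the first day in the window whose trailing
five-day rainfall sum reaches 20 mm, else the window's last day. The
accumulation window is the most recent five days including the current one
(a trailing, not centred, window); day-of-year is 1-based.

The three cultivar parameter sets (named for the regional reference
cultivars CIVT millet, EVDT97 maize, Kadaga sorghum) are **illustrative, not
field-calibrated**: RUE 2.4–3.2 g MJ⁻¹, maturity 1100–1350 °C·d, HI_max
0.35–0.50 are mid-range literature values for West African cereals. They
reproduce realistic low-input yield magnitudes (0.1–0.9 t DM ha⁻¹ under
water+N limitation) but no specific trial.

## 4. Grassland

One grass sward per cell, annual (Sahelian) or perennial (Sudanian). Growth
is the crop RUE scheme without a storage organ (65 % of ΔDM to shoot) and a
1 % d⁻¹ shoot senescence. The annual establishes when the sowing rule fires
and dies at the dry-season onset, its shoot entering the feed store as
standing hay. The perennial moves `reserve_fraction` (30 %) of its shoot to
a reserve at dormancy, releases the rest as hay, survives the dry season
with the reserve frozen, and on breaking dormancy transfers up to
3 g m⁻² d⁻¹ from reserve to shoot while water is available. Its roots reach
1.2 m against the annual's 0.5 m, which is what makes it the more
drought-tolerant sward. The dry-season onset is the first post-onset 30-day
window totalling < 5 mm — season boundaries are not defined anywhere
authoritative, so the rule is explicit and configurable. Grazing removes
shoot down to an ungrazable residual of 15 g DM m⁻² (prevents extinction
artifacts), rescaling LAI proportionally.

## 5. Herd

Six classes (juvenile/sub-adult/adult × male/female), real-valued counts
(daily sales can be a fraction of an animal). Annual rates convert to daily
by `/365` without compounding, which makes a constant-mortality class decay
exactly as `N₀(1 − m/365)^t` — a closed form the tests exploit. The daily
update applies, in order: births (adult females × parturition/365 ×
prolificacy, split by sex ratio), mortality (baseline + starvation-max ×
(1 − stress)), promotions (`γ = survival/duration`), then offtake/intake.
Promotion flows for all classes are computed simultaneously from
post-mortality counts, so no animal crosses two classes in one day and the
whole update is an exact linear map — its 6×6 projection matrix is assembled
independently in the tests and the simulated stationary class structure must
match its dominant eigenvector.

Weights change by `gain_max · stress − loss_max · (1 − stress)` per class,
floored at a minimum viable weight. Milk is adult females × lactating
fraction × potential × stress (linear shutdown under stress — the minimal
monotone choice); meat is sold live weight × carcass fraction (0.5); CH₄ is
`intake · 0.021 kg kg⁻¹ DM` (a standard enteric yield); manure N is 80 % of
feed N intake, routed 50/50 to cropland and grassland pools and applied the
next day to avoid a within-day circular dependency.

## 6. Feed and management

Feed-energy demand is metabolic-weight maintenance,
`Σ N_c · 0.45 MJ · W_c^0.75` (production demands folded into the single
coefficient); intake capacity is 2.5 % of live weight in DM. Supply draws
grass → residue → concentrate (cheapest first) until demand, capacity or the
pools bind; ME contents default to 8 / 6.5 / 11 MJ kg⁻¹ DM. Stress is
`min(1, supply/demand)`, 1 when demand is zero. Deficits trigger concentrate
purchases limited by cash; if a gap remains after purchasing — which implies
purchasing power is exhausted — and stress is below the sell threshold
(0.6), animals are sold from a priority list (adult males first), each class
contributing the fractional head-count whose removal closes the remaining
gap, revenue credited to cash. Residues decay at 0.1 % d⁻¹; concentrates do
not decay.

## 7. Engine, outputs, statistics

One cell per run; multi-cell studies are independent runs. Land-use shares
(grass/crop/tree/settlement/other, default 0.5/0.3/0.1/0.05/0.05 of a
1000 ha cell) weight the per-ha activity outputs; tree/settlement/other are
inert. Default crop mixes: millet 60 % + sorghum 40 % (Sahelian), maize
50 % + sorghum 50 % (Sudanian); maize gets 15 kg N ha⁻¹ at sowing, millet
and sorghum none. Production levels: `potential` (no water or N stress),
`water_limited`, and `nutrient_limited` (both stresses; the default). Note
that under `nutrient_limited` the manure-N feedback couples herd size to
crop yields, so strict crop–livestock decoupling (removing the herd leaving
crops bit-identical) holds only at the `water_limited` level.

The annual table carries per-crop yield and AGB, peak grass AGB, rainfall,
growing-season rainfall and transpiration, herd size, milk/meat/CH₄, leached
N, mean stress, and the sWSI computed from growing-season transpiration
minus precipitation (season = rains onset to dry-season onset). Sample
(n−1) standard deviations are used for sWSI and CV. The weighted RMSE
applies a square root so it carries data units; `apply_root=False` restores
the plain weighted mean of squared errors. A degenerate sWSI series (zero
interannual spread) raises rather than returning zeros.

Determinism: all randomness flows from the scenario seed; identical config +
seed reproduce output CSVs byte for byte (fixed float formatting).

## 8. Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` use 1–30-year single-cell runs,
20-seed ensembles for property checks, and 500–1000 randomized cases for the
statistics oracles — sizes chosen so the full analysis reruns in well under
a minute while leaving every mechanism exercised through multiple full
seasonal cycles.

## 9. Known limitations

- No transhumance or seasonal herd movement; the herd grazes one cell.
- No browse/tree fodder, feed-quality seasonality, price dynamics or credit.
- No CO₂ response, pests, heat stress beyond thermal-time acceleration, or
  photoperiod sensitivity in crops.
- The N pool has no explicit mineralization dynamics or organic pools.
- Cultivar, soil and demographic parameters are plausible defaults, not
  calibrated to field data; simulated magnitudes should be read as
  order-of-magnitude realistic, directionally meaningful — not predictive
  for any specific site.
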