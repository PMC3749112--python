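# Methods

This note describes the model implemented in `canesim`: its structure,
assumptions, parameter defaults, numerical choices, and limitations. It is
the reference for anyone interpreting simulation output or changing
constants.

## Scope and design stance

The package simulates a single point (per m²) on one of two Florida soils
through a savanna spin-up, fifteen years of grazed bahiagrass pasture, and
fifteen years (five 3-year cycles) of energy cane. The guiding design
choice is *transparent mechanism over fitted detail*: every process is a
small closed-form expression with named constants in packaged YAML, every
daily step conserves carbon and nitrogen exactly (the test suite closes
whole-run budgets to ~10⁻¹⁴ relative through a cumulative ledger), and a
single random seed — used only for weather — fully determines every output
byte.

## Weather generator

Daily Tmax/Tmin/precipitation for a subtropical climate (Highlands County
normals: ~1300 mm yr⁻¹, wet season June–September). Temperatures are
monthly normals interpolated linearly between month midpoints plus a shared
Gaussian daily anomaly (σ = 2.5 °C), which preserves Tmax ≥ Tmin. Rainfall
is an independent per-day Bernoulli wet/dry draw with exponential wet-day
amounts scaled so expected monthly totals equal the normals. This captures
the first-order statistics the soil water bucket and decomposition need; it
deliberately omits multi-day storm persistence, tropical-cyclone extremes,
and any temperature–rain correlation, so simulated interannual variance is
somewhat smaller than observed. Files use a 7-column whitespace text format
(day month year doy tmax tmin precip) that round-trips bit-exactly.

## Water

A single bucket over the 60 cm rooting zone (field capacity, wilting point
and saturation from the soil profile; the biogeochemistry itself is
referenced to 0–30 cm). Reference evapotranspiration is a Hargreaves-type
expression with a sinusoidal extraterrestrial-radiation proxy for ~27° N;
actual ET scales with relative water content. Excess above field capacity
drains the same day and carries NO₃⁻ (mobility factor 0.3 of the displaced
fraction). The 60 cm rooting-zone choice matters: cane roots access storage
below the plow layer, and with a 30 cm bucket the prescribed irrigation
calendar (monthly in the November–April dry season, bimonthly otherwise,
filling to field capacity) cannot keep an irrigated crop near field
capacity on sand.

## Plants

Three parameter sets: savanna grass mix (spin-up; includes 1.5 g N m⁻² yr⁻¹
symbiotic fixation), bahiagrass pasture, and energy cane. Daily
assimilation is `A_max · f(T) · f(water) · f(canopy) · f(N)`, each factor in
[0, 1]: Gaussian temperature response (optimum 30 °C, width 10 °C, C₄-like),
linear water stress between wilting point and field capacity, a canopy
factor `1 − exp(−(leaf C + 0.25·stem C)/ramp)` that makes establishment and
ratoon regrowth ramp up, and nitrogen limitation (below). A fixed 25% of
assimilate is respired belowground (root/autotrophic respiration); the rest
is allocated leaf/stem/root by fixed fractions — energy cane 0.38/0.40/0.22,
reflecting the reduced (60% → 40%) stem allocation appropriate to a
high-fiber cane.

Nitrogen: tissue C:N is bounded per pool (energy cane minimums 22.1 leaf /
30.5 stem; maximums 70 / 160, roots 110). The maximums are whole-season
dilution limits — mature harvested cane runs shoot C:N ≈ 80–140 — while the
minimums describe young, luxury-fed tissue. Growth is cut back exactly when
available N (internal reserve + accessible mineral N) cannot keep new
tissue at or below maximum C:N. Growing plants also capture surplus mineral
N into an internal reserve (cap 12 g N m⁻² for cane) at 25% of the mineral
pool per day; this is the mechanism by which a fertilizer pulse is taken up
ahead of nitrification and leaching and remobilized over the season. Tissue
is enriched toward the minimum C:N only when the reserve is more than 60%
full, so scarce N is spent on growth rather than on enriching biomass that
will be exported. Senescing leaf/stem N is resorbed to the reserve at 30%
(grasses 40%, cane 50%); standing dead sheds to surface litter at 1% day⁻¹;
roots slough at 0.25% day⁻¹.

Phenology is growing-degree-day driven (base 10 °C; emergence at
150 °C·day for cane). The degree-day clock restarts every January 1 and on
any kill/harvest event. After harvest the ratoon rebuilds its shoot by
remobilizing 2% of root C per day until leaves exceed 40 g C m⁻² —
harvested cane regrows from stubble and root reserves, which is why ratoon
years start faster than plant-crop years.

## Soil organic matter and nitrogen

Century-family pools over 0–30 cm: metabolic and structural litter
(k = 14.8 and 3.9 yr⁻¹), active (7.3 yr⁻¹), slow (0.2 yr⁻¹), passive
(0.0045 yr⁻¹); respired fractions 0.55/0.45/0.55/0.45/0.55; transfer
topology litter→active (structural also 30% to slow), active→slow (5% to
passive), slow→active (5% to passive), passive→active. Daily decay fraction
is `1 − exp(−k·mult/365)` with `mult = f(T)·f(water)·cultivation·drainage`;
by construction a pool with transfers disabled follows the analytic
exponential exactly, which the tests exploit. Temperature response is
Q₁₀ = 2 referenced to 20 °C on mean air temperature (no soil-temperature
submodel); moisture response is linear from wilting point to field
capacity. A plow event multiplies decomposition by 1.6 for 30 days.
Residue is split metabolic/structural by `fm = 0.85 − 0.013·(lignin:N)`;
structural carries N at C:N 150. Receivers are filled toward target C:N
(active 11, slow 16, passive 8); surplus N mineralizes to NH₄⁺, deficits
immobilize up to half the mineral pool per day.

Initialization sets pool C from the measured profile stocks (Spodosol
0.77 %C → 3350 g C m⁻²; Histosol 7.77 %C → 9324 g C m⁻² over 0–30 cm),
split 3/27/70% active/slow/passive, with every pool at the measured
whole-soil C:N so soil N capital matches the measured stock.

## Trace gases

Nitrification converts `0.10 · f(T) · f(w)` of the NH₄⁺ pool per day
(moisture optimum near field capacity, shut down toward saturation), with
2% of nitrified N emitted as N₂O-N. Denitrification activates above
WFPS = 0.60, scales with NO₃⁻, a Michaelis function of active-pool C
(half-saturation 300 g C m⁻²), and a quadratic WFPS term, partitioning
toward N₂ as the soil approaches saturation. On the wet, carbon-rich muck
this makes denitrification the dominant N₂O pathway; on drained sand
(WFPS ≈ 0.42 at field capacity) nitrification leakage dominates — the
mechanism behind the strong Histosol > Spodosol N₂O contrast in pasture.

CH₄ is an aeration- and temperature-dependent soil oxidation sink
(k = 0.0013 g C m⁻² d⁻¹, calibrated so an unstocked pasture takes up
0.1–0.6 g C m⁻² yr⁻¹) opposed by the enteric source of grazing cattle
(1 head ha⁻¹ × 90 kg CH₄ head⁻¹ yr⁻¹ → ≈ +3000 g CO₂eq m⁻² per 15 yr of
pasture). Oxidized CH₄-C is a gas-ledger entry only (< 1 g C m⁻² yr⁻¹, not
added to soil C). Saturated-soil CH₄ production is out of scope (fields are
drained).

## Histosol drainage and subsidence

Drained organic soils oxidize; undrained ones accumulate. A
drainage-intensity factor multiplies soil decomposition: 0.15 during the
savanna spin-up (native swamp — the muck accumulates, which is how it
formed), 0.30 under pasture (partially drained, no tillage), 1.0 under
cultivated cane. Each December 31 the year's net soil-pool C loss is
converted to soil mass (÷ 0.0777 g C per g soil), the surface drop follows
from bulk density (0.40 g cm⁻³), and the same soil mass is debited from the
30–100 cm reservoir, importing its C and N (C:N ≈ 15.5) into the active
column. Incorporated muck is routed 90%/10% into the slow/passive pools: a
deliberate design choice — material re-exposed to the aerated, disturbed
layer is again oxidizable, which is what sustains multi-decade subsidence
and the high N mineralization that keeps unfertilized Histosol cane yields
up. Annual (not daily) bookkeeping matches the annual reporting granularity
of all outputs. The subsidence ledger is exactly conservative and raises an
explicit error if the reservoir is exhausted.

## Accounting conventions

Ecosystem C storage = plant + standing dead + litter + SOM (0–30 cm).
Total system C flux is `−ΔC·44/12`, positive toward the atmosphere, with
harvested and grazed exports treated as returned to the atmosphere (a
burned biofuel feedstock and respiring cattle) rather than credited as
lateral sinks — with ~2 kg C m⁻² yr⁻¹ exported under cane, crediting
exports would dominate every budget and invert the soil-type contrast.
`total_system_c_flux` exposes an `exports_are_lateral` switch for the other
convention. Subsidence C additions enter storage (so a muck column
replenished from below shows a near-neutral 0–30 cm flux; the 0–100 cm SOC
series shows the true loss). Total GHG = total system C flux + CH₄ + N₂O in
CO₂ equivalents (mass-basis GWP 1/23/296; overriding the factors changes
CO₂eq outputs only). Report tables round half-away-from-zero to integers.

External N inputs: atmospheric deposition 0.7 g N m⁻² yr⁻¹ everywhere;
symbiotic fixation only in the savanna mix; fertilizer 50/50 NH₄⁺/NO₃⁻ by N
(ammonium-nitrate). Grazing removes the compounded monthly equivalent of
10%/yr live and 1.0%/yr standing dead shoots; half the removed mass returns
as manure to the metabolic litter pool (Century-style return), half is
exported as animal products/respiration.

## Calibration

Two constants were calibrated, once, against the experiment's stated
production and flux envelopes and then frozen: the energy-cane potential assimilation
(`max_daily_npp` = 26 g C m⁻² d⁻¹; `scripts/calibrate_npp.py` documents the
sweep) so the fertilized-Spodosol scenario's mean aboveground production
falls within the simulated range 1911–3153 g C m⁻² yr⁻¹, and the CH₄
oxidation rate (above). Bahiagrass potential (5 g C m⁻² d⁻¹) puts
unfertilized pasture near 200–270 g C m⁻² yr⁻¹ aboveground, giving the
~10× production contrast with cane.

## Problem sizes and numerical choices

The packaged spin-up default is 2000 years; the test suite and the
acceptance script run the same experiment at 150 and 400 spin-up years
respectively — the directional results (GHG sink on Spodosol, source on
Histosol, muck SOC decline, production contrast) are insensitive to spin-up
length beyond ~150 years, while the absolute Histosol muck stock grows with
it (as it does in nature). Spin-up weather is generated in ≤100-year blocks
with seeds derived from the climate seed; block year labels are arbitrary.
Sub-step order is fixed: events → water → phenology → production/uptake →
senescence → decomposition → N gases → CH₄ → leaching → ledger. Flows are
capped at pool size; a non-finite or negative state aborts with a state
dump. Annual summaries are exact sums of daily values and serialize to CSV
with repr-precision floats (bit-exact round trip).

## Statistics

Paired t (each simulation year a paired replicate, df = n − 1, two-sided),
Wilcoxon rank-sum (W = Mann-Whitney U of the first sample; exact p for
small untied samples), Fligner-Killeen (rank-based normal scores on
|x − median|, χ² with k − 1 df) — all delegated to scipy behind the module
interface and cross-checked against brute-force oracles in the tests.
Storey q-values are implemented directly: π₀ = #{p > λ}/((1 − λ)m) clipped
to 1 (λ = 0.5 by default), step-up q-values monotone in p; with π₀ < 1 they
are exactly π₀ × the Benjamini-Hochberg values. A single published summary
FDR for a matrix of mostly "<0.001" p-values is not recomputable and is not
targeted.

## Known limitations

The production model has no photosynthesis/stomatal mechanism, LAI, pests,
disease, lodging, or compaction — so the Spodosol ratoon yield decline
emerges from N depletion only, and absolute trajectories (a specific year's
yield, the exact SOC time course) are not expected to match any particular
field or any larger process model; the package targets the
conserved budgets, the calibrated production envelope, and the sign
structure of the soil-type contrast. Soil temperature is proxied by air
temperature; the water bucket is single-layer; no freeze/thaw; no CH₄
production under saturation; no fossil-fuel displacement credit or
life-cycle terms in the GHG budgets. The weather generator's simplifications
are listed above; passing tests therefore demonstrate internal consistency
and faithful implementation of the experiment's design, not predictive skill
for real fields.
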