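# Methods

This note documents the model, its parameters, the synthetic study system,
and the numerical and design choices behind `paleocarb`.

## Domain and time axis

The domain is the spherical cap north of 23°N on a regular 1° grid
(67 × 360 cells), cell centers at half-degree offsets, edges
inclusive-lower/exclusive-upper. Cell areas use the spherical band formula
with R = 6371.0 km; the summed cap area equals 2πR²(1 − sin 23°) to
rounding error (≈1.55 × 10⁸ km²). Time is integer ka BP running 21 → 0;
"the change at millennium t" means stock(t) − stock(t+1 ka). Each
millennium is represented by a single climate slice; sub-millennial
averaging windows in the source climate simulations have no counterpart in
the emulator and are deliberately not modeled.

The default runs operate at the full 1° resolution: the northern cap is
small enough that every stage is vectorised numpy and completes in seconds
to tens of seconds, so no coarsened grid is needed. The `--quick` profile
instead shrinks the statistical work (classifier ensemble 60 trees instead
of 500, 120 training sites per slice instead of 500), which leaves all
stock totals unchanged because densities, not sample counts, carry the
signal.

## Synthetic world

The generator emulates the statistical structure of the study inputs with
known ground truth. It makes no attempt to mimic real spatial patterns of
any particular climate model; only the features the downstream stages
consume:

* **Climate.** Two ensembles ("reference" and "biased") share one smooth
  spatial anomaly field and one deglacial warming trajectory
  (piecewise-linear weight w(t): full glacial until 17 ka, most warming
  17–10 ka, slow approach to PI). MAAT at PI decreases poleward at
  0.75 °C per degree from 20 °C at the 23°N edge; LGM cooling is 9 °C at
  domain scale with polar amplification (0.6× south to 1.4× north).
  Seasonal amplitude grows poleward (14 → 26 °C) so the synthetic treeline
  (warmest month 10 °C) sits near 63–66°N at PI, and continuous permafrost
  survives to the present on the northernmost land — both features the
  downstream rules depend on. The biased ensemble is the reference minus a
  constant 5 °C on all temperature fields, mirroring the systematic bias
  the permafrost stage must correct; precipitation is shared. Glacial
  climates are 35 % drier. Determinism: all fields are exact functions of
  (scenario, seed).
* **Ice and shorelines.** Ice retreats monotonically poleward in a North
  American and a European sector from a 48°N margin at 21 ka, finishing by
  5 ka; a Greenland-analogue residual persists throughout. Cold-based ice
  is a 3°-wide band inset 1° poleward of the margin — a stylised stand-in
  whose only role is a plausible area chronology (stock ≈ 129 Pg C at
  21 ka, zero from 5 ka). Shelf cells north of the modern coast carry a
  bathymetry proportional to distance from the coast and drown as sea
  level rises from −120 m to 0 along a fixed schedule; all LGM shelf is
  ocean again at 0 ka. Ice-dammed-lake areas are treated as soil; no
  Caspian-Sea analogue exists in the default world.
* **True biomes.** A deterministic decision list over (MAAT, warmest-month
  temperature, annual precipitation): desert below 140 mm, tundra below a
  10 °C warmest month, open vegetation below 320 mm split by MAAT at
  13 °C, then boreal/temperate/warm-temperate/tropical forest by MAAT
  bands (1/11/17 °C). The decision-list representation makes the rule set
  complete and non-overlapping by construction; threshold coherence is
  validated.
* **Training points.** Pollen-style samples are drawn per slice from
  unglaciated land with replacement (duplicates are a property of the real
  compilations), 500 per slice by default, with 10 % label noise (uniform
  over the other 7 classes) and 10 % flagged "protected". The noise level
  is the generator's stand-in for interpretation error in biomised pollen;
  it bounds attainable holdout accuracy near 0.9.
* **Loess.** Four rectangular regions (US, Central Europe, Central
  Siberia, China) with per-region deep-deposit thickness (6–20 m below
  2 m, including the extra metre of original deposit that compensates for
  biome stocks only covering 0–2 m) and frozen/thawed volumetric C
  densities (thawed = 10 % of frozen). Densities are rescaled by a common
  factor so the summed 21-ka stock equals the configured 363 Pg C; the
  resulting ~10–19 kg C m⁻³ are Yedoma-like values.
* **Peat.** Normalised logistic accumulation curves (stock midpoint 8 ka,
  scale 2.2 ka; area midpoint 9 ka, scale 2.5 ka), clamped to 0 at and
  before 16 ka and exactly 1 at 0 ka; PI totals 450 Pg C and
  3.7 × 10⁶ km². The PI extent map concentrates peat in the wet boreal
  belt (Gaussian in latitude around 58°N weighted by precipitation) and is
  rescaled to the PI area total. Initiation ages follow deglaciation where
  cells were glaciated, default 14 ka elsewhere; cells south of 38°N
  without initiation data are assigned 12 ka.

## Biome classification

`RandomForestClassifier` (500 trees, unlimited depth, fixed seed; both
config-exposed) on seven features: the six climate variables plus a fixed
synthetic elevation surrogate. Training hygiene: unprotected tundra rows
with site MAAT > 5 °C are removed; training is split into deglacial
(21–10 ka) and Holocene (9–0 ka) sets whose deliberate 10–9 ka overlap is
honored, with the 10-ka slice scored by the deglacial model and 9 ka by
the Holocene model; desert augmentation adds 242 synthetic desert sites at
0 ka (Holocene set), copies 6-ka desert rows into the deglacial set, and
adds 40 desert sites at 21 ka. Site covariates are taken from the same
regridded reference-model fields used for prediction (the alternative —
independent site climatologies — is not represented in the emulator).
Vote fractions are the per-cell biome area fractions; argmax ties break
toward the lower index in the fixed class ordering (this affects accuracy
scoring only, never stocks).

What passing recovery tests shows: the pipeline can invert its own
generative process (threshold-rule biomes + label noise) at ≥ 0.8 mean
holdout accuracy. It does not show that real pollen biomisation is this
clean; real training data carry spatial autocorrelation, taphonomic bias,
and nomenclature translation error that the generator does not emulate.

## Permafrost

Fraction f(T) = 1/(1 + exp((T − T₀)/s)), T₀ = −6 °C, s = 1.5 °C. The
external MAAT–permafrost relationship this follows is published as a
curve, not a formula; the two-parameter logistic is this package's
parameterisation, config-exposed. Continuous permafrost is f ≥ 0.99 (the
numerical stand-in for "100 % coverage"). Adjustments: +5 °C base offset
for the biased ensemble (0 for the reference), plus a ramp reading
"−1 °C per millennium between 10 and 17 ka" as cooling older slices — 0 at
t ≤ 10 ka growing to −7 °C at t ≥ 17 ka. The alternative anchoring (−1 °C
already at 10 ka) is selectable by config, and the ramp is applied
additively with the base offset (whether the source procedure replaced or
added the offsets over 17–10 ka is not documented; additive is this
package's choice). `calibrate_offsets` grid-searches the base offset in
0.5 °C steps against a present-day reference delineation and reports
residual misfits at 6 and 21 ka; the ramp is never tuned, and scoring can
be restricted to a sub-mask (the European-priority choice for glacial
calibration).

## Carbon ledger

* **Mineral soils (0–2 m).** Cell stock = area × [(1 − peat − slope) ·
  Σ_c frac_c · TF(c, state) + slope_frac · 3 kg m⁻²]; state is the
  continuous-permafrost delineation (the permafrost/no-permafrost
  dichotomy). Default transfer functions are field-plausible densities
  (tundra 40/22 kg m⁻² with/without permafrost, boreal 25/15, temperate
  18/12, warm-temperate 10/9, tropical 8, grassland 15/10, savanna 7/6,
  desert 3). Stocks are computed per climate model and averaged; the
  inter-model gap is reported as a percentage of the pool SD. Soil C is
  assumed in equilibrium with its biome within each millennium. The 2–3 m
  depth interval of non-loess soils is excluded domain-wide.
* **Exposed and inundated shelf.** Shelf cells (land at t but not at PI)
  get biome-based densities from the same classifier prediction — they are
  treated like land mineral soil, which is why shelf stocks can grow
  before drowning. On inundation the cell's stock moves, conserved
  exactly, into the inundated pool; 30 % (range 0–66 %) of the transferred
  carbon is additionally recorded as cycled through the atmosphere,
  counted in net changes but never in stocks. Shelf re-emergence and ice
  readvance are rejected rather than handled; they do not occur in the
  modeled interval.
* **Deep loess.** Two modes. The default "anchors" mode interpolates the
  total deep-loess stock linearly between isochrone anchor points — the
  reduction of per-section chronological control to configured anchors —
  with defaults 363 Pg C at 21 ka, a 398 Pg C peak at 17 ka (syngenetic
  deposition of 8.75 Pg C per millennium over 21–17 ka), a decline shaped
  to per-millennium losses of ~42/49/88 Pg C at 17–16/15–14/12–11 ka, and
  57 Pg C remaining at 0 ka. The "permafrost" mode drives per-region
  frozen stocks with the modeled continuous-permafrost masks (thaw
  fraction averaged over the two models): stock thawing in a millennium
  loses 90 % of its carbon within that millennium (retention 0.1,
  config-exposed). The mask mode is the mechanistic sensitivity option; in
  the default synthetic climate the mid-latitude US/China sectors never
  sit in continuous permafrost, so only the anchored mode reproduces the
  four-region chronology. Regional uncertainty combines independent area,
  depth and density variances by first-order propagation.
* **Peat.** Pool total = 450 Pg C × stock_fraction(t), distributed over
  cells initiated by t proportionally to their PI extent and scaled so
  total area = PI area × area_fraction(t); no cell exceeds its PI extent
  before the final step (saturation only at 0 ka). Uncertainty combines
  ±10 % (extent) and ±36 % (stock) with a back-in-time ramp from 0 at PI
  to ±50 % at 16 ka, by root-sum-of-variances.
* **Post-glacial accrual.** Deglaciated cells accrue C(t) = Ce(1 − e^(−kt))
  for three millennia, Ce from the biome transfer functions (0–1 and 1–2 m
  halves), k = 1.1 ka⁻¹ for forests and tundra (≥ 95 % of equilibrium at
  3 ka) and 0.5 ka⁻¹ for grassland-type classes (deliberately short of
  equilibrium); after three millennia the cell transfers to the
  biome-based stocks.
* **Subglacial.** Stock = cold-based area × (40 kg m⁻² high-arctic tundra
  soil + 1 m of peat at 50 kg m⁻² over 1 % of the area); released as an
  immediate loss on retreat.
* **Net and gross changes.** Net change per millennium = Σ pool deltas −
  cycled flux (losses negative); the decomposition is exact, and
  cumulative net losses exceed the stock drawdown by exactly the
  cumulative cycled flux. Gross gains/losses are sums of signed per-cell
  deltas of the combined mineral+peat maps.

## Uncertainty and CO₂

V = σ²/μ and E_Δ = ½(V_t + V_{t+1})·|Δ| are implemented exactly as
printed, although σ²/μ is not the conventional dimensionless coefficient
of variation — it carries units of Pg C and makes E_Δ scale with pool
size. With this package's pool magnitudes and relative SDs the resulting
E_Δ values are large multiples of the net changes; they are reported as
defined, not reinterpreted. Independent components combine as √Σe²; the
cycled-flux error is 50 % of the flux (the 0–66 % range around the 30 %
central estimate).

Conversion: ppm = ΔC × response / (M_atm/M_air × 10⁻⁶ × M_C × 10⁻¹⁵) with
M_atm = 5.15 × 10²¹ g, M_air = 28.966 and M_C = 12.011 g mol⁻¹ (the molar
masses are this package's constants, config-exposed), i.e. ≈ 2.13 Pg C
per ppm. Asymmetric response: 25 % airborne fraction for net releases,
13 % for peat-dominated uptake. Both a per-millennium mode (signed net per
interval) and a cumulative mode (factor applied to the cumulative sum; the
mode behind the headline deglacial-52-ppm and Holocene-23-ppm figures) are
provided. Ice-core millennial differencing sums consecutive-point
differences within each 1-ka bin (telescoping to youngest minus oldest);
bins with fewer than two points are reported missing, never zero.

## Numerical choices

* Tolerances: biome fractions sum to 1 within 1e-9 on land; per-cell maps
  reconcile with pool totals within 1e-6 Pg; shelf transfers conserve to
  1e-9 Pg.
* Degenerate inputs raise (not warn): non-monotone retreat schedules,
  thawed ≥ frozen loess densities, empty training periods, missing site
  climate, peat demand with no eligible cells, negative stocks.
* Absent classes in a training period are recorded as warnings in the
  classifier metadata and surface in the run provenance.
* All randomness flows through `numpy.random.default_rng(seed)` with
  stage sub-seeds drawn once per run; identical config + seed reproduces
  every table bit-for-bit.

## Known limitations

* The synthetic world is stylised: no orbital forcing, meltwater pulses,
  realistic coastlines, or spatially correlated label error. Passing
  tests demonstrate internal consistency and recoverability, not fidelity
  to any real reconstruction.
* Pool trajectories at full scale (e.g. an LGM→PI change of order
  ±100 Pg C, a stock minimum near 11 ka) are emergent properties of the
  default scenario, not calibration targets; only the loess chronology,
  the peat totals, and the CO₂ conversions are pinned to configured
  values.
* Phytomass, fire, lakes, human land use, CH₄ partitioning and
  Siberian-shelf ice-complex degradation are out of scope by design.
* The per-region loess SD construction is under-specified in its source;
  independent area/depth/density variances with first-order propagation
  are this package's interpretation.
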