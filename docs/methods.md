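# Methods

This note documents the models implemented in `fugrisk`, the defaults they
ship with, the reasoning behind design choices that were genuinely open,
and what the synthetic study conditions can and cannot demonstrate.

## Scope and intent

The package performs *screening-level* prioritization: it ranks substances
in a release inventory by exposure, hazard and risk potential in an
evaluative (hypothetical) regional environment. It is not a site-specific
exposure model: releases are treated as diffuse and steady, and the summed
national-scale rates are applied to the 100 000 km² region without scaling
(an optional `rate_scaling` factor exists for sensitivity analyses).
Inorganics, disposal streams (landfill, underground injection, ...) and
hydrolysis are deliberately out of scope; the release reader rejects
disposal compartments outright.

## Evaluative environment

Only the geometry's headline figures are fixed by the study design: a
100 000 km² region, 90% land and 10% water with underlying sediment. All
other geometry, phase composition and transport parameters are
EQC-style regional defaults representative of temperate North America and
ship in `src/fugrisk/data/environment.yaml`; every value can be overridden
per run. Key defaults: air height 1000 m, water depth 20 m, soil depth
0.1 m, active sediment 1 cm; aerosol volume fraction 2×10⁻¹¹; organic
carbon 2% in soil solids, 4% in sediment solids, 20% in suspended solids;
advective residence times 100 h (air) and 1000 h (water); precipitation
0.85 m/yr with scavenging ratio 2×10⁵; the usual two-film mass-transfer
coefficients (air side 5 m/h, water side 0.05 m/h, sediment-water
10⁻⁴ m/h, in-soil air/water diffusion 0.02 and 10⁻⁵ m/h). Temperature is
fixed at 298.15 K; no temperature correction of partitioning or half-lives
is applied.

## Level III fate engine

Fugacity capacities: `Z_air = 1/RT`, `Z_water = Z_air/K_AW`, sorbed solids
via `K_OC = 0.35·K_OW` (L/kg, config constant) times the phase organic
carbon fraction, aerosol via a K_OA-proportional rule with 20% organic
matter, biota via lipid·K_OW. Bulk capacities are volume-fraction-weighted
sums. All reactions are first order (`k = ln2/HL` per medium, applied to
the bulk compartment); losses are reaction, advective outflow of air and
water, and sediment burial. The 4×4 linear balance is solved directly
(`numpy.linalg.solve`); the matrix is structurally an M-matrix, so
nonnegative emissions give nonnegative fugacities (tiny negative round-off
is clipped). A singular balance — a reachable compartment with no loss
pathway — raises an explicit no-steady-state error rather than returning
garbage; a zero-emission scenario returns an all-zero field with undefined
(NaN) persistence.

Overall persistence `P_OV` is total steady-state mass over the total
reaction-loss rate; the overall residence time additionally counts
advection and burial. The loss budget is reported in kg/h and closes
against the emission rate to machine precision (the acceptance suite
enforces 10⁻⁹ relative over randomized chemicals).

**Vegetation** is a receiving sub-model, not a fifth balance compartment:
foliage exchanges gas with bulk air through a K_OA-scaled capacity
(octanol-equivalent fraction 2%) and intercepts 20% of the particle-bound
deposition flux, against a first-order foliage loss (10⁻³ h⁻¹ for growth
dilution and cuticle erosion); root crops equilibrate with soil pore water
scaled by the Briggs-style root concentration factor
`RCF = 0.82 + 0.03·K_OW^0.77` L/kg. The consequence of this one-way
coupling is that vegetation does not deplete the air or soil balance — an
approximation that slightly overstates air burdens for strongly
foliage-sorbing chemicals.

### Numerical checks

The steady-state solver is verified against an independent oracle that
integrates the dynamic mass balance (`scipy` Radau with analytic Jacobian)
until the relative change over a 20% time extension is below 10⁻¹⁰;
agreement is within 10⁻⁶ relative in every compartment over randomized
chemicals drawn from the full property ranges. The equilibrium ("Level
II") limit is exercised by inflating the five diffusive mass-transfer
coefficients a million-fold, which drives compartment fugacities within
0.1% of each other for a median-parameter chemical under air or water
emission. Inflating the *one-way* advective intermedia flows (rain
dissolution, particle deposition, runoff) as well would not produce
equifugacity — the limit of an unbalanced exchange matrix is a
deposition-weighted stationary state — which is why the limit is defined
on the diffusive coefficients. Soil emission converges more slowly (the
in-soil diffusion MTCs are orders smaller), so the limit check uses air
and water entry.

## Food-web bioaccumulation

Each non-plant receptor is a steady-state one-compartment toxicokinetic
model, linear in all concentrations:

* uptake — respiratory (efficiency × ventilation × dissolved water or
  gaseous air concentration), dietary (gut efficiency × feeding rate ×
  diet-weighted prey/plant/soil concentrations) and drinking water for
  air-breathers;
* elimination — respiratory (uptake clearance over the body–medium
  partition ratio `K_BW = lipid·K_OW + 0.7`), fecal egestion, urinary
  excretion (air-breathers, clearance over `K_BW`), biotransformation,
  growth dilution, and lactation (dairy cow) or egg production (hen).

Gut absorption efficiency is the standard hyperbolic function of K_OW,
`E_D = 1/(3×10⁻⁷·K_OW + 2)`; respiratory efficiencies are constants (0.8
gill, 0.7 lung). Egestion is modelled as a first-order loss proportional
to the dietary uptake clearance (factor 0.25) rather than a full
gut-fugacity sub-model — a deliberate simplification that keeps the system
linear and preserves the qualitative biomagnification behaviour (dietary
equilibrium magnification factor 1/0.25 = 4). Active transport is assumed
negligible.

Biotransformation half-lives are supplied at two reference body masses —
0.01 kg for water-respiring ectotherms and 70 kg for birds and mammals —
and rescaled allometrically on the rate constant with exponent −¼, so the
reference half-life is recovered exactly at the reference mass.

The default roster (`src/fugrisk/data/roster.yaml`) comprises foliage and
root-crop vegetation, an aquatic invertebrate, planktivorous and
piscivorous fish, an aquatic bird, a small herbivorous rodent, a
terrestrial carnivore, a dairy cow, a laying hen and a 70 kg adult human
as terminal consumer. Physiological rates are round literature-typical
values, declared, editable and *not* claimed to replicate any specific
published parameterization. The diet matrix must be acyclic; the food web
is evaluated in topological order, which is exact because every balance is
linear — the test suite confirms equality with a simultaneous
linear-system solve on randomized webs to 10⁻⁹ relative.

The human receptor's reported exposure is the absorbed intake rate
(mg/kg/day), matching the intake-type threshold used for risk; for
birds and mammals the same intake basis applies.

## Screening metrics

* **EAF** (exposure assessment factor, unit 1 kg/h emission): steady-state
  chemical mass in each receptor's population biomass per unit emission,
  over a fixed normalization mass (default 1 kg); the reported EAF is the
  maximum over receptors. Rankings are invariant to the normalization
  constant, and absolute EAF values are comparable only within a run.
  Population biomasses are roster defaults (e.g. 5×10¹⁰ kg foliage,
  10⁷ kg planktivorous fish) chosen as order-of-magnitude figures for the
  region.
* **HAF** (hazard assessment factor): the maximum receptor risk ratio at
  the same unit emission — a combined persistence/bioaccumulation/toxicity
  metric.
* **RCR** per receptor at actual emission rates: whole-body concentration
  (mmol/L) over the taxon's aquatic effect threshold `C_T` for autotrophs,
  invertebrates and fish (vegetation uses the autotroph threshold against
  whole-tissue concentration), or absorbed intake over the intake-rate
  threshold `IR_T` (mg/kg/day) for birds, mammals and the human.
* **RAF** = max RCR; the receptor attaining it is reported as the most
  sensitive.

The unit-emission mode of entry for EAF/HAF defaults to the substance's
actual inventory split when one exists (falling back to 100% air), which
makes `RAF = HAF × E` exact; a config switch forces 100% air instead.
Missing toxicity thresholds follow the `skip-receptor` policy by default
(the receptor is excluded from max/sum — conservative in the sense of
never inventing potency); a `baseline-narcosis` policy can instead fill
missing aquatic thresholds from `log(1/C_T[mol/L]) = 0.85·logK_OW + 1.39`,
optionally capped. Argmax ties resolve by roster order, documented for
reproducibility.

## Ranking, aggregation, trends

Rank 1 is the largest metric; ties share the smallest applicable rank with
a deterministic secondary sort by substance id. "Total risk" per province,
sector or year is the plain sum of all per-receptor RCRs of all substances
in the group, computed from that group's own emission scenarios (not
prorated national rates); outputs carry an explicit caveat that additivity
strictly holds only for baseline-narcosis modes of action. Time trends are
ordinary least-squares slopes per year — chosen over a qualitative reading
because it is reproducible and unit-bearing. `risk_per_tonne` decomposes
trend behaviour by mode of entry: the summed RCR of one tonne/yr released
wholly to one compartment.

## Synthetic study conditions

The generator emulates the structure of a national PRTR extract and an
organic-chemical property database. Sampling ranges default to the spans
of the target substance population: log K_OW ∈ [−3.8, 12.1], log K_AW ∈
[−14.3, 2.5], half-lives log-uniform within per-medium ranges (air
0.19–10⁶ h, water 55–7.2×10⁴ h, soil 110–1.4×10⁵ h, sediment
494–6.5×10⁵ h), biotransformation half-lives log-uniform within their
reference-mass ranges, annual tonnages lognormal (ln-median ≈ 55 t,
σ = 2.5), and the air/water/land split Dirichlet-distributed. Aquatic
toxicity is coupled to hydrophobicity through the narcosis relation with
0.5 log₁₀ units of lognormal noise, clipped to the per-taxon ranges, with
per-taxon missingness probabilities (0.43/0.15/0.07) mirroring partial
threshold coverage in real databases. Distribution *families* are the
generator's own choice; only ranges and medians are externally anchored.

Two deterministic archetypes anchor the qualitative contrasts: the
`solvent-like` record (high volume, hydrophilic, rapidly degraded, weakly
toxic) and the `dioxin-like` record (trace volume, group listing carrying
representative-congener properties, half-lives and biotransformation
half-lives at the persistent extreme of the configured ranges, thresholds
at the potent extreme). Placing the persistent archetype at the bounds is
what makes it the exposure/hazard extreme of any sampled population, so
the headline inversion — top-ranked by EAF/HAF yet bottom-ranked by
quantity, with the solvent archetype mirrored — is a structural property
of the fixture set rather than a seed accident. A third fixture, the
`semivolatile-like` foliage binder (log K_OW 5, log K_AW −5), exists for
the mode-of-entry experiment: its huge K_OA loads foliage (and foliage
grazers) from air emissions while soil releases stay sorbed, giving a
~3000-fold air-over-soil risk-per-tonne asymmetry. The drift fixture grows
its tonnage 10%/yr while shifting the release split from 90% to 10% air;
the counterfactual keeps identical tonnages with a frozen split.

What passing on these conditions shows: the pipeline's mechanics — mass
conservation, linearity, metric contracts, ranking determinism — and its
ability to produce the qualitative phenomena (quantity/risk rank
divergence, trend flattening by mode-of-entry shift). What it does not
show: agreement with any real inventory or any published model's absolute
outputs; real property databases, receptor parameterizations and release
data would be needed for that, and the CSV readers accept them directly.

## Problem sizes and numerical conventions

Default study sizes are 20 substances, 40 facilities, 6 regions, 6
sectors, 10 years — compact enough that the full pipeline (two model runs
per substance: unit and actual) completes in seconds while still
exhibiting all the phenomena above. Internal units are mol, mol/h, Pa and
mol·m⁻³·Pa⁻¹; conversions to kg, mg/L and mg/kg occur only at reporting
boundaries. Half-lives are stored in hours everywhere. Property tables and
release tables round-trip bit-identically (floats are written as their
shortest round-trip representation and parsed with exact rounding). All
randomness flows from a single integer seed; identical seed and config
give byte-identical outputs.

## Known limitations

* Diffuse steady-state releases: near-field gradients around point sources
  are not represented, so risk proximal to stacks/outfalls is
  underestimated.
* Vegetation does not feed back on the air/soil balance.
* No temperature or seasonal dependence; no hydrolysis.
* Egestion and urinary excretion are first-order surrogates, not
  mechanistic gut/kidney models.
* RCR additivity across substances ignores mode-of-action differences
  (flagged in aggregate outputs).
* EAF absolute values depend on assumed population biomasses; only ranks
  are robust to that choice.
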