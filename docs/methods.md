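# Methods

## Exposure model and assumptions

The package evaluates the standard three-pathway dust exposure model for a
chronic receptor: average daily doses for ingestion, inhalation and dermal
contact, each linear in the dust concentration `Cs` (μg/g ≡ mg per kg of
dust).  The inhalation pathway converts dust mass to air volume through the
particulate emission factor (PEF, m³/kg) and therefore carries no μg→mg
factor; the ingestion and dermal pathways multiply by 1e-6.  Hazard
quotients divide the non-carcinogenic dose by a reference dose that is
unified across pathways (RfD_dermal = RfD_oral × ABS_GI with ABS_GI = 1 by
default; both the gastrointestinal fraction and a pathway-specific
inhalation RfD can be overridden per compound).  The hazard index is the
plain sum of the three quotients, accumulated in the fixed order
inhalation, ingestion, dermal so floating-point results are reproducible.
Cancer risk applies only to compounds with a slope factor (BBP here):
lifetime doses use the carcinogenic averaging time and sum over population
groups, so the engine generalises to residential (child + adult) scenarios;
the packaged occupational scenario marks the child group inactive, which
contributes exactly zero.

Assumptions inherited from this model family: exposure factors are constant
over the exposure duration, pathways are additive and independent, dose
response is linear for carcinogens, and no bioaccessibility adjustment is
applied beyond ABS/ABS_GI.

## Parameters

The packaged `yazd_adult` scenario (data/yazd_adult.toml) carries the adult
occupational point factors: IRing 50 mg/d, IRinh 15.7 m³/d, EF 300 d/y,
ED 30 y, BW 70 kg, PEF 1.36e9 m³/kg, SA 4000 cm², AF 0.07, ABS 0.001;
reference doses DMP 10, DEP 0.8, IBP 0.512, DBP 0.1, BBP 0.2, DOP 0.4
mg/kg/day and CSF(BBP) 0.0019 (mg/kg/day)⁻¹.  BEHP and the second di-octyl
entry (DiOP) have no reference dose and are excluded from risk with a
logged warning.

**Averaging time.**  The survey's parameter tables print AT = 365 d
(deterministic) and AT = 900 d (probabilistic), but neither reproduces its
own published hazard-quotient tables.  Inverting the ingestion dose
equation against the published quotients shows the tables were computed
with AT = ED × 365 = 10950 d; the package adopts that as the
non-carcinogenic default (and the conventional 70 × 365 d for carcinogens),
both overridable in the scenario file.  Internal consistency was preferred
over the printed value.

**Probabilistic factors.**  BW ~ LN(68.9, 8.9) kg, IRinh ~ LN(32.73, 1.14)
m³/d, SA ~ N(20700, 3440) cm² truncated at zero, all other factors point.
LN/N parameters are arithmetic means and SDs (the published convention);
lognormal log-scale parameters come from moment matching, σ² = ln(1+s²/m²).
The published probabilistic ingestion-rate entry, LN(1.4, 1.56) L/day, is a
fluid-intake figure whose units are incoherent with the mg/day dust term;
the packaged scenario keeps the 50 mg/day point value and retains the
published entry, inactive, under `[reference]` in the scenario file.  For
sensitivity analyses of the ingestion pathway,
`stochastic_ingestion_scenario()` re-applies the published *relative*
spread (CV = 1.56/1.4 ≈ 1.11) to the unit-coherent 50 mg/day mean.

**Risk bands.**  HI > 1 flags non-cancer concern.  Cancer risk below 1e-6
is negligible; the 1e-4 upper bound of the "acceptable-concern" band is the
conventional extension (the study conditions state only the 1e-6 bound).

## Monte Carlo design

One master seed; each factor samples from its own substream derived from
the seed and the factor name (`SeedSequence([seed, crc32(name)])`), so runs
are bitwise reproducible and adding a factor never perturbs the others'
draws.  Factors are drawn independently — no correlation structure is
specified for them.  Draws are threaded through the *same* dose functions
as the deterministic engine (they accept arrays), so an all-point scenario
degenerates to the deterministic result exactly; the summary snaps to exact
constants (sd = 0) when the output vector has zero range.  A stochastic
exposure duration drags the non-carcinogenic averaging time along
(AT = ED × 365); the carcinogenic averaging time stays fixed.

Concentration is a fixed per-compound input by default (mean of the
observed station × step values, optionally one station): the study
conditions give no concentration distribution, so the published
probabilistic ranges — which depend on that unstated input — are treated as
order-of-magnitude context only, not as reproduction targets.  An optional
bootstrap mode resamples the observed values per iteration, which is how
concentration enters the sensitivity ranking.

Default problem sizes: 10,000 iterations for reported summaries (the
survey's own replicate count), 100,000 for the known-truth recovery check,
and a 1,000,000-draw brute-force oracle in the convergence test; at these
sizes the full pipeline runs in seconds.

## Sensitivity analysis

Spearman ρ (midranks for ties) between each retained factor column and the
simulated output; constant columns are dropped with a warning since rank
correlation is undefined for them; zero-variance inputs yield an absent
(not zero) ρ.  The "contribution" bar is signed normalised ρ² — an
emulation of the contribution-to-variance display of commercial risk
packages, whose exact algorithm is unpublished.  No p-values are attached.
Expected signs follow the dose algebra: numerator factors (concentration,
intake rates, SA) positive, body weight (denominator) negative.

## Synthetic data generator

`generate_dust_dataset` emulates the structure of a station-resolved dust
survey: per-compound lognormal concentrations (geometric mean and GSD),
repeated sampling steps, left-censoring below a detection limit (recorded
as zeros, the survey's 0.00 convention; LOD/2 substitution is an option
that keeps the censored flag), and hotspot station × compound pairs with a
fixed multiplier (default: BEHP × 20 at station S8, mirroring a
textile-industry source).  Default profiles are stylised to bracket the
published summary's orders of magnitude (BEHP gm 10 μg/g, DMP gm 0.05 μg/g
with LOD 0.01); they are not fitted to it.  What the generator does *not*
emulate: spatial autocorrelation between stations, temporal structure
across sampling steps, inter-compound correlation, and measurement error —
so passing recovery tests demonstrate correctness of the dose/MC/SA
machinery, not field realism.

The recovery harness checks three analytically known facts: the
deterministic ingestion HQ equals its closed-form product; the Monte Carlo
mean matches the analytic mean using E[1/BW] = (1+s²/m²)/m for the
moment-matched lognormal; and the sensitivity stage ranks the only
stochastic ingestion factor (BW, negative) first.

## Numerical choices

* Printed-table comparisons use 1e-3 relative tolerance (the tables carry
  5–6 significant digits with visible rounding); equation-chain
  reproduction uses 5e-3, i.e. agreement at 3 significant figures.
* Concentration CSVs are written with pandas' shortest-round-trip float
  formatting and read with `float_precision="round_trip"`, so write→read
  is value-identical; derived results tables are written at 12 significant
  digits.
* The step-to-station aggregation statistic is an explicit parameter of
  `run_deterministic` (default: mean over sampling steps) because the
  published tables do not state which statistic fed them; validation
  against those tables therefore back-derives concentrations from the
  published ingestion quotients instead of guessing.
* Degenerate inputs: empty tables are a validation error at read time and
  an empty result (with warning) inside the engine; all-zero concentrations
  give exactly zero risk; lognormal truncation uses rejection resampling
  and fails loudly if the bounds reject essentially all mass.

## Known limitations and data caveats

* **Published inhalation quotients for IBP, DBP and BBP are internally
  inconsistent.**  At every station their ratio to the ingestion quotient
  is exactly 0.64, 0.125 and 0.25 times the closed-form value — i.e.
  RfD_oral/0.8: those columns were evidently computed against a reference
  dose of 0.8 (DEP's value) rather than the compound's own, contradicting
  the stated unified-RfD convention.  The engine follows the stated
  convention; the acceptance checks that compare against those three
  published columns therefore fail by construction, and a dedicated unit
  test pins the deviation to exactly the RfD substitution factor.
* The published per-compound Mean rows are mutually consistent across the
  four hazard tables but are not the arithmetic means of the printed
  station rows (≈8% off for DMP), suggesting they were computed from a
  different concentration statistic; summary checks therefore assert the
  cross-table identities and the cancer-risk table's station means, which
  do hold.
* A handful of printed exponents in the packaged fixtures were restored
  (mantissas untouched) where the tables' own identities prove the printed
  decade wrong; each CSV header itemises the affected cells.
* Station-level cancer risks are not derivable from any printed
  concentration and averaging time (they imply an unstated effective
  lifetime divisor); cancer-risk validation rests on the table's internal
  identities (pathway ratios, station means).
* The "allowable concentration" column of the concentration summary is
  stored but never used in computation (its provenance is unstated).
* No age-integrated residential cancer risk, no non-dust media, no spatial
  interpolation, and no correlated or quasi-random (Latin hypercube)
  sampling.
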