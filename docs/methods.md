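# Methods

## The estimation model

The package implements a deliberately simple two-part accounting model
for global avian insectivory, of the kind used when a field is too
data-poor for anything spatially explicit.

**Standing biomass.** Seven terrestrial biomes partition the ice-free
land surface (13,380 × 10⁶ ha): tropical forests; temperate and boreal
forests; tropical grasslands and savannas (with Mediterranean shrubland
folded in, as its primary production and bird densities are similar);
temperate grasslands; cropland; deserts; Arctic tundra. Per biome, the
avifauna's standing biomass is D × W × Y (density × mean body mass ×
area), computed unrounded; the reporting layer rounds half-up to the
nearest 10⁶ kg, which reproduces the published per-biome subtotals
row-for-row while the global total is always the sum of *unrounded*
subtotals.

**Insectivore deduction.** Insectivore fractions are 0.9 for
temperate/boreal/arctic biomes and 0.6 for tropical biomes *and*
deserts. Deserts are not tropical, but the 60% figure is the documented
choice for non-tropical desert habitats; with either 0.6 or 0.9 the
deduced total rounds to 3 million tons, so the choice is not
load-bearing. We default to 0.6.

**Consumption harmonization.** Raw per-hectare records carry explicit
flags saying which adjustments their source had already applied;
harmonization applies, in order and only if not yet applied, (i) the
insectivore fraction, (ii) the arthropod-diet fraction (0.75 temperate
forests and grasslands, 0.95 cropland, 0.85 deserts, 1.0 where the
record already refers to arthropod intake of the whole community), and
(iii) for breeding-season records, annualization by ×(1 + 0.075) — the
midpoint of the 5–10% non-breeding/breeding consumption ratio assumed
for temperate and cold climates. Tropical records are annual totals and
are never annualized. Harmonization is idempotent by construction (the
output record carries all-applied flags).

**Pooling and scaling.** Per biome, the harmonized annual values are
pooled into an arithmetic mean and a standard error using the n−1
sample standard deviation (SE ≡ 0 at n = 1; the source material does
not define its SE, so the ordinary sample-variance convention is
adopted). The area subtotal multiplies the mean *rounded to one
decimal* by the biome area: this is the only convention under which the
published per-biome subtotals are bit-exactly self-consistent
(112.5 × 1750 × 10⁶ = 196,875 × 10⁶); the unrounded mean is carried
alongside in all reports.

**Energy equivalent.** The energy-demand → food direction divides by
assimilation efficiency × dry energy density × dry fraction
(0.75 × 22.5 × 0.30 = 5.0625 kJ per g fresh). The reverse, global
figure (consumed prey mass → energy) deliberately omits the
assimilation factor: it reports the gross energy content of the prey
removed from ecosystems (mass × 0.30 × 22.5 kJ g⁻¹), which is the only
convention consistent with the published energy equivalent of the
global consumption total. The asymmetry is intentional and tested
(round-trip returns E / 0.75). The kcal→kJ factor is 4.184
(thermochemical calorie), applied exactly once, immediately after the
allometric equation. Whether the metabolic-reconstruction source
applied the assimilation correction before converting to food is not
documented in the source material; the package applies the full
conversion chain uniformly in both source-2 and source-3 paths.

**Scenario bounds.** The base estimate annualized every temperate/cold
subtotal with ×1.075, so each such subtotal decomposes uniformly into a
breeding component B = subtotal/1.075 plus 0.075·B. The minimum
scenario re-assembles the total with no non-breeding consumption
(×1.0), the maximum with 50% of the breeding value (×1.5); tropical
subtotals are never rescaled. The temperate/cold set is {temperate &
boreal forests, temperate grasslands, cropland, deserts, Arctic
tundra}. This uniform decomposition gives 393,446 / 467,715 × 10⁶ kg —
within 1% of the originally published bounds, which were computed from
a per-record seasonal decomposition that only exists in the
non-machine-readable supplementary document. The records CSV schema
exposes the decomposition, so the published bounds can be matched
exactly once that supplement is transcribed; we do not guess the
decomposition. (The published bounds carry a "million tons" unit label
that must be read as 10⁶ kg for the bounds to bracket the base total;
the package adopts the kg reading.)

**Stopover heuristic.** Prey eaten at migration stopover sites is
estimated as n_migrants × stopover_days × daily fresh-mass requirement
of a mean-mass bird × arthropod fraction of the stopover diet. Defaults
(15 × 10⁹ migrants — midpoint of the 10–20 billion range — 0.030 kg
mean mass, 30 stopover days, arthropod fraction 0.4) land at ≈ 3.8
million tons yr⁻¹, inside the 3–5 Mt range the estimate is meant to
represent; days and diet fraction are order-of-magnitude guesses with
no published measurement behind them, which is why this quantity is
quarantined behind explicit parameters and never enters the global
total.

## Rank statistics

Biome differences in consumption rates are tested on midranks
(tied values share the mean of the ranks they span). The Kruskal–Wallis
statistic uses the tie correction C = 1 − Σ(t³−t)/(N³−N) and a
chi-square reference distribution with k−1 df; an all-tied pooled
sample (C = 0) is *defined* as H = 0, p = 1 rather than an error, so
degenerate synthetic draws (e.g. zero dispersion) never crash a
pipeline run. Dunn's pairwise z uses the pooled-variance form with the
matching tie term; the default p-adjustment is none — matching how the
pairwise comparisons were originally reported — with Holm and
Bonferroni available by flag. The consumption–NPP association uses
Spearman rank correlation by default (the claim is monotone
association and there are only seven biomes); Pearson is available by
flag. The chi-square p-value is an asymptotic approximation; at the
dataset sizes involved (N ≈ 100) it is adequate, and a property test
checks that it orders small datasets the same way an exhaustive
permutation p does.

## Synthetic data

The 103 raw per-hectare records exist only in a non-machine-readable
supplement, so tests and demonstrations run on a generator that mirrors
the published per-biome summary: record counts (7, 44, 7, 11, 8, 18, 8),
means (112.5, 44.1, 15.8, 7.5, 20.9, 4.1, 4.6 kg ha⁻¹ yr⁻¹), and a
dispersion (CV) back-solved per biome as SE·√n/mean so the SE of the
sample mean at the published n matches the published SE in expectation.
Values are lognormal by default — consumption rates are strictly
positive and span two orders of magnitude across biomes — with a gamma
alternative; both are parameterized directly by (mean, CV). Deserts and
tundra records are tagged source-type 3 (metabolic reconstruction),
other biomes 25% source 1 / 75% source 2. All draws flow from a single
integer seed through one `numpy.random.Generator`.

What the generator does *not* emulate: the bibliographic clustering of
the real records (several values per study), spatial autocorrelation,
and any within-biome covariate structure. Passing tests therefore show
that the pipeline arithmetic and the statistical machinery behave
correctly under the assumed marginal structure — not that the original
103 literature values satisfy lognormality.

**Parameter recovery.** Over 200 seeded replicates, each biome's pooled
mean must fall within 2 SE of the generator's true mean, where SE is
the *design* SE (true_mean × CV / √n). The design SE is used because
the property under test is whether the generator and pooling stage
recover known truth at the nominal ≈95% rate (observed: ≈96%); the
plug-in sample-SE interval is a different object — it is known to
undercover for skewed data at n ≈ 8 (observed ≈89% overall, ≈79% for
the high-CV cropland biome) and would measure the deficiency of that
interval estimator rather than any property of the package. The test
threshold is ≥90%. The omnibus-test power check (rejection at α = 0.05
in >90% of 200 replicates under the default, strongly separated biome
means) was frozen at 90% after a pilot showed rejection at ≈100%.

## Numerical conventions and edge cases

- Rounding for printed-precision reporting is half-up (ties away from
  zero), via `decimal`, at 1 decimal for per-hectare means and at the
  nearest 10⁶ kg for subtotals; all sums and downstream computations
  use unrounded values except the area subtotal, as described above.
- Validation is fail-fast at construction: non-positive masses and
  areas, fractions outside (0, 1], multipliers outside [0, 1], unknown
  or duplicated biome labels all raise `ValueError` naming the field or
  biome.
- CSVs are UTF-8, decimal-point, headers with units in column names;
  floats are written with shortest round-trip repr (lossless beyond 12
  significant digits).
- CLI exit codes: 0 success, 2 validation error, 3 numeric failure.

## Problem sizes

Everything except the synthetic-replicate checks operates on 7-row
tables and runs in milliseconds. The replicate checks use 200 seeds ×
103 records, which keeps the whole suite and the acceptance script in
the low seconds; the permutation-sanity property test enumerates label
permutations only at N = 6.

## Known limitations

- Biome means are treated as fixed once pooled; no uncertainty is
  propagated from the per-biome SEs into the global total.
- No within-biome heterogeneity, no time trends in density, and no
  adjustment for recent bird-population declines (explicitly out of
  scope).
- The exact published scenario bounds and the published omnibus
  chi-squared (51.179, df 6) require the per-record supplementary
  dataset; the package ships a transcription-template CSV
  (`aviprey.fixture_path("esm1_template")`) and activates the checks
  when a filled copy is supplied. Until then the loader reports the
  pending state explicitly.
- The packaged per-biome NPP reference values are standard textbook
  figures included for the rank correlation only; the correlation's
  sign, not its magnitude, is the supported claim.
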