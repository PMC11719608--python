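# Methods

## Scope and model structure

`chocrisk` implements a single-contaminant (cadmium), single-commodity
(chocolate) dietary risk assessment for seven consumer groups: toddlers,
other children, adolescents, adults, the elderly, pregnant women and
vegetarians. The assessment has three layers:

1. **Deterministic indices** per sample × group: estimated weekly intake
   (EWI), %PTWI, hazard quotient (HQ) and lifetime cancer risk (CR).
2. **Probabilistic propagation**: a seeded Monte Carlo re-evaluation of HQ
   and CR with distributions on the inputs, reported as percentiles.
3. **Sensitivity**: signed contribution-to-variance of each stochastic
   input, the convention used by spreadsheet risk simulators for tornado
   charts (squared Spearman rank correlations normalized to 100 %, with the
   correlation's sign reattached).

## Equations and unit conventions

With C the Cd concentration, IngR the ingestion rate and the toxicological
constants listed below:

    EWI    = IngR_w · C                      [µg/kg bw/week]
    %PTWI  = 100 · EWI / PTWI
    HQ     = EF·ED·C·IngR_d·CF / (AT_nc·RfD)
    CR     = EF·ED·C·IngR_d·CF·CSF / AT_c

* `IngR_w` is in kg chocolate per kg body weight per week; the daily rate is
  `IngR_d = IngR_w/7 · 1000` g/kg bw/day. Each sample is always evaluated
  under the ingestion rate matching its own chocolate type (milk or dark).
* `AT_nc = 365·ED` days is **always derived** from the exposure duration,
  never configured independently. Consequently HQ is exactly invariant to
  ED (the factors cancel); CR, averaged over the fixed `AT_c`, is linear in
  ED. This cancellation is asserted to machine precision in the tests.
* `CF = 10⁻³` converts grams of chocolate to kilograms so that
  `C [mg/kg] · IngR [g/·/day] · CF` is a dose in mg per day (per kg bw in
  per-bw mode).
* Two evaluation modes exist. *Per body weight* (default for the
  deterministic layer): IngR is per kg bw and BW is omitted. *Absolute*
  (default for the Monte Carlo layer): IngR is in g/day — the per-bw rate
  times the group's nominal body weight — and the indices are divided by a
  body-weight variable. Only in absolute mode is a stochastic body weight
  meaningful, which is why the probabilistic layer uses it.

## Constants, with defaults and provenance

| symbol | default | units | note |
|---|---|---|---|
| PTWI | 2.5 | µg/kg bw/week | EFSA tolerable weekly intake for Cd |
| RfD | 1e-3 | mg/kg/day | USEPA chronic oral RfD for dietary Cd; an **assumption** of this package (commonly cited for Cd in food) |
| CSF | 6.1 | (mg/kg/day)⁻¹ | oral cancer slope factor for Cd |
| CF | 1e-3 | – | g → kg conversion |
| EF | 350 | days/year | exposure frequency |
| AT_c | 25550 | days | 70-year cancer averaging time, all groups |
| ED | 2/5/7/30/15/30/30 | years | toddlers … vegetarians, in the group order above |
| MRL | 0.1 / 0.3 / 0.8 | mg/kg | EU 2023/915 bands: cacao < 30 %, 30–< 50 %, ≥ 50 % |

MRL band boundaries belong to the **upper** category (a 30 %-cacao product
falls in the 0.3 mg/kg band), matching the regulation's "≥" wording; the
band intervals are half-open and partition [0, 100] with the top band closed
at 100.

Nominal body weights (12, 23, 43.4, 70, 70, 70, 70 kg) are EFSA default
body weights — an assumption, since the assessment otherwise works per kg
body weight and needs BW only for the absolute-mode simulation.

Weekly ingestion rates (kg/kg bw/week), milk chocolate:
0.00703, 0.00589, 0.00350, 0.00259, 0.00179, 0.00186, 0.00322; dark:
0.00525, 0.00547, 0.00157, 0.00154, 0.00134, 0.00214, 0.00211 — from the
EFSA Comprehensive Food Consumption Database (Serbia), in the group order
toddlers, other children, adolescents, adults, elderly, pregnant women,
vegetarians. This ordering is the only mapping of the published rate lists
consistent with the elderly having the lowest minimum %PTWI (0.72 %).

Analytical QC: LOD = 3·σ_blank/slope and LOQ = 10·σ_blank/slope, so
LOQ/LOD = 10/3 identically. Concentrations below the LOQ are accepted as
reported by default; an optional `half_loq` substitution policy replaces
them with LOQ/2.

## Synthetic survey generator

The survey behind the built-in configuration published only per-band
summary statistics (three cacao bands with n = 3, 98, 49 and printed
min/max/mean/median), not per-sample values. The generator reconstructs a
per-sample dataset per band:

1. Fit a lognormal from the printed arithmetic mean and median:
   µ = ln(median), σ = √(2·ln(mean/median)). This follows from
   mean = exp(µ+σ²/2), median = exp(µ); a mean below the median is
   infeasible for a lognormal and raises an error.
2. Draw n values from that lognormal **truncated to the printed
   [min, max] by rejection** (never clamping, so no boundary atoms); a
   rejection acceptance rate below 10⁻⁴ aborts with the band named.
3. Pair each concentration with a cacao content uniform within the band
   (cacao % affects only MRL classification, not the risk indices).

Degenerate bands (min = max) collapse to a constant. Each band draws from
its own seed substream, so bands are independent and stable under changes
elsewhere; identical seeds reproduce the dataset byte-for-byte.

The lowest band's printed median (0.031 mg/kg) exceeds its own printed
maximum (0.030 mg/kg) — an inconsistency in the source table — so that band
is fitted from its mean and the range midpoint instead, with a logged
notice. Truncation shifts the realised moments slightly below the fitted
targets (the upper tail is cut); at large n the generated mean and median
sit within ~10 % of the printed values, which is the documented tolerance
of the moment-recovery test.

What the generator does **not** emulate: correlation between cacao % and Cd
within a band, brand or origin structure, measurement error, censoring at
the LOQ. Passing tests on the synthetic data therefore demonstrate the
pipeline's correctness and the summary-level safety claims, not per-sample
agreement with the unpublished survey data.

## Probabilistic model

Distribution families per input: concentration lognormal, ingestion rates
triangular, EF triangular, ED point, BW lognormal, AT/CF/RfD/CSF point.
Milk and dark exposures carry separate concentration and ingestion-rate
variables and are summed per iteration into one intake term
`C_milk·IngR_milk + C_dark·IngR_dark`. All draws are independent (no
correlations are modelled). Plain Monte Carlo, default 10 000 iterations;
no variance-reduction schemes.

The source assessment named these families but published **no spread
parameters**, so the spreads are this package's own documented defaults,
all configurable via `SpreadConfig` and echoed into results:

* ingestion rates: triangular (0.9, 1.0, 1.1) × nominal. Consumption-survey
  rates are population averages and comparatively well determined; a ±10 %
  spread (CV ≈ 4.1 %) keeps them subordinate to the exposure-frequency
  uncertainty, which reproduces the published qualitative factor ordering
  (BW > EF > IngR). A wider ±20 % spread would push the ingestion rates
  above EF in contribution and contradict that ordering, which is why it
  was not adopted.
* EF: triangular (300, 350, 365) days/year — most consumers eat chocolate
  most days, bounded above by the calendar.
* BW: lognormal with CV 0.2 about the nominal mean (typical anthropometric
  variation).

Concentration distributions: for user-supplied data, per-type lognormals
are fitted from the sample table's mean and median (`concentration_specs`).
For reproducing the built-in study, `table1_concentration_specs` fits them
directly from the published per-band summaries (pooled milk mean 0.0279,
milk median 0.023 from the dominant band; dark 0.057/0.042). The published
summaries are exact knowledge of the study's concentration distribution, so
the study-level simulation should not re-estimate them from one finite
synthetic draw — doing so adds generator sampling noise (at n = 49 dark
samples the fitted log-sd fluctuates by ±0.1 and more) to every downstream
percentile and, in particular, washes out the small milk/dark sensitivity
distinction.

Randomness: one root seed; every symbol draws from a substream derived
deterministically from (seed, CRC32(symbol name)), so adding or removing a
symbol never perturbs the other symbols' draws, and point symbols consume
no random state. Draws for strictly positive denominators (RfD, BW, AT,
CSF) are redrawn while non-positive, with a log notice.

Percentiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention) — stated explicitly because spreadsheet
simulation tools do not document theirs.

## Sensitivity analysis

For each input X: ρ = Spearman(X, output); contribution = sign(ρ)·100·ρ² /
Σρ². Constant inputs are set to 0 before normalization, so absolute
contributions always sum to 100 % when the output varies; a zero-variance
output returns an all-zero, `degenerate`-flagged result. Rankings are by
absolute contribution with alphabetical tie-breaks.

In absolute mode BW enters the denominator, so its contribution is negative
(heavier consumers receive a smaller dose per kg) while typically being the
largest consumption/exposure factor — concentration variability itself
dominates the total variance under the lognormal concentration model.

A caution on resolution: the ingestion-rate contributions are small
(≈ 0.15 %), and distinguishing IngR_dark from IngR_milk for adults requires
far more iterations than percentile estimation does. The test suite runs
that one ordering check at 3 × 10⁶ iterations; at the standard 10⁴ the two
factors' estimates overlap within Monte Carlo error.

## Numerical and design choices

* Chocolate type is stored explicitly rather than derived from cacao %
  (consumption data are per product type; MRLs are per cacao band); a
  type/cacao mismatch logs a warning but is not an error.
* CSV writers emit shortest round-trip float representations and readers
  parse with round-trip precision, so dataset round-trips are exact and
  seed reproducibility is byte-for-byte.
* Risk-class boundaries are inclusive on the safe side: HQ ≤ 1 safe;
  CR ≤ 10⁻⁶ negligible; CR ≤ 10⁻⁴ moderate; above that unacceptable.
* Pooled group summaries evaluate each sample under its own type's
  ingestion rate and summarize over all samples; per-type summaries are
  also exposed, since a published combined-table mixing rule cannot be
  recovered from summary statistics alone.
* The pipeline writes a manifest (seed, config, input hashes, package
  version, timings); a failed stage removes its partial outputs.

## Known limitations

* Single contaminant, single commodity: no hazard index across analytes,
  no total-diet context.
* The synthetic generator matches summary statistics, not the unpublished
  empirical distribution; whether that distribution is truly lognormal is
  unverifiable, though lognormality is also the probabilistic model's own
  assumption.
* Published combined-group means and exact simulation percentiles are not
  reproducible without the raw per-sample data and the original tool's
  spread parameters; the package reproduces printed boundary values exactly
  and distributional behaviour qualitatively.
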