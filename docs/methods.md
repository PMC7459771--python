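# Methods

## Model

The method treats deficiency of an essential element in drinking water as a
threshold-type health risk, mirroring the US EPA hazard-quotient framework
with the ratio inverted. All doses are average daily doses per kg body
weight under a fixed exposure scenario:

    dose = concentration * IR * ED * EF / (BW * AT)

With the default adult scenario (BW 70 kg, IR 2 L/day, EF 365 days/year,
ED 1 year, AT 365 days) the exposure factor is exactly 2/70 (L/kg/day), so a
concentration in mg/L maps to a dose in mg/kg/day (hardness, carried in
mmol/L, maps to mmol/kg/day). The three doses are the required dose ADRD
(from the minimum required concentration MRC), the accepted dose ADAD (from
the measured concentration CW) and their difference ADMD. The deficiency
hazard quotient HQ_d = ADRD/ADAD equals MRC/CW identically — the exposure
factors cancel — which is why group summaries can be computed from
concentration statistics alone.

A negative ADMD (CW > MRC, a surplus) is returned as-is rather than clamped,
so the difference identity ADMD = ADRD − ADAD holds exactly; callers wanting
a "missing amount" take `max(0, admd)`. No hazard index is offered across
elements: summing deficiency quotients for Ca and Mg has no defensible
interpretation, and the assessment is reported per element.

## MRC derivation

Two provenances:

* **standard** — the MRC is a drinking-water standard or guideline value,
  taken as-is.
* **derived** — an ecological comparison of a deficient group against the
  national baseline. For each cause-specific relative-mortality indicator
  (ReC oncological, ReI circulatory, ReJ respiratory, ReK digestive, deaths
  per 100,000), cross-multiplication gives the limit value
  LV_i = CW_group · HI_group,i / HI_national,i — the concentration at which
  the group's indicator would scale to the national value, under an assumed
  proportionality between concentration and indicator. The LVs are combined
  as a weighted average over causes of death and multiplied by an
  uncertainty factor UF.

Parameters that matter:

* **Cause weights** (dimensionless, default {ReC 0.50, ReI 0.25, ReJ 0.06,
  ReK 0.07}, normalised by their 0.88 sum). The case study's prose quotes
  national mortality shares of ~25% oncological and ~50% circulatory, which
  contradict the published limit-value table; only the assignment above
  reproduces every published cell (e.g. Ca LV 31.21 rather than the ≈32.88
  the quoted shares give). The package defaults to the table-reproducing
  vector, logs a warning when defaults are used, and accepts any
  nonnegative weight vector. Weights for indicators absent from the input
  are dropped and the rest renormalised, with a warning.
* **Uncertainty factor** (dimensionless, default 2.0, permitted range
  [1, 10]). Absorbs lifestyle, genetic and inter-individual variability;
  2.0 encodes the assumption that roughly half the population is sensitive
  to the deficiency. It is applied once, after weighting, not per
  indicator. Values below 1 are rejected: they would lower the protective
  bound.
* **Display rounding** (default on in reproduction contexts). The published
  MRCs equal 2 × the limit values *as printed* (16.66 = 2 × 8.33, not
  round(16.6668) = 16.67), so reproduction mode rounds the weighted LV to
  two decimals before applying UF. Analysis of new data should switch it
  off; the full-precision Mg chain gives 16.6668 mg/L.

## Risk classification and group summaries

HQ_d is classified on a four-level chronic-disease scale with *strict* lower
bounds: ≤0.1 without risk, (0.1, 1] low, (1, 4] medium, >4 high; a value
exactly at a threshold falls in the lower class. A zero accepted dose is a
distinct unbounded-risk outcome (an exception at the single-assessment
level, `inf` in group summaries), never a silent division.

Two group-summary conventions are implemented:

* **transform-of-summary** (default, the case study's): summary statistics
  (mean, median, min, max) of CW are computed first and mapped through ADAD
  and HQ_d; since HQ_d is strictly decreasing in CW, the maximum HQ_d comes
  from the minimum CW and vice versa.
* **per-municipality**: HQ_d is computed per municipality and then
  summarized — the statistically conventional choice. By Jensen's
  inequality (c ↦ MRC/c is convex) its mean HQ_d is never below the
  transform-of-summary mean. Reports label the convention used.

Because the derived MRC is proportional to the source group's mean CW, the
source group's transform-of-summary mean HQ_d is (up to LV rounding) just
UF × (weighted indicator ratio) — independent of the concentrations
themselves. This is a property of the method, not an artefact.

## Numerical and reproduction notes

Published-table cells that cannot be reproduced to ±0.01 from the printed
inputs are treated as "loose" in the case-study diff: the HQ_d medians
(printed from an unrounded MRC: 16.6668/4.45 → 3.75, while 16.66/4.45 →
3.74; the soft-water Ca median 3.01 is unreachable under either precision,
62.42/20.7 = 3.0155) and the soft-water hardness average (printed 2.95,
consistent only with pre-rounded doses 0.065/0.022; the direct ratio
2.26/0.77 gives 2.94). The soft-water Ca maximum HQ_d is printed to one
decimal (11.6) and compared at that precision. Everything else — every
limit value, MRC, dose and the remaining 60+ summary cells — reproduces to
±0.01 (most to ±0.005).

Hardness may be supplied as a measured column (preferred) or reconstructed
as Ca/40.078 + Mg/24.305 mmol/L from IUPAC molar masses; the published
measured averages differ from the reconstruction by ~1% and the measured
value always takes precedence.

## Synthetic data generator

`generate_group` emulates the municipality-selection design: per-element
concentrations are drawn from log-normals truncated (jointly, by rejection)
to the group bounds — soft: Ca < 30 mg/L, Mg < 10 mg/L, hardness <
1.0 mmol/L; hard: Ca > 50, Mg > 25, hardness > 2.5 — with hardness derived
from Ca and Mg via molar masses so the columns are consistent. Default
(mu, sigma) are moment-matched to the published group summaries with
sigma = sqrt(2 ln(mean/median)); for the hard group, whose printed means do
not exceed the medians (infeasible for a log-normal), sigma falls back to
ln(max/min)/4, reading the printed range as ±2 sigma on the log scale.
Populations are uniform on 500–5,000, the selection band the study used.

Municipality indicators follow a multiplicative response
HI_i = national_i · k_i · ε with ε log-normal, mean 1, coefficient of
variation `indicator_cv`; group indicators are the population-weighted mean
(equal weighting optional). Defaults: k_i equal to the published
group/national ratios for the chosen template; CV = 0.15 — the study
publishes no municipality-level indicator dispersion, so this dispersion is
the package's own synthetic choice and is never asserted against published
values. At CV = 0 the full chain recovers the configured MRC exactly; at
CV > 0 the recovery error shrinks as the group grows (≈ n^−1/2), which the
tests check at n = 10, 100, 1,000 averaged over 15 replicate seeds.

What the generator does **not** emulate: Bayesian shrinkage of small-count
municipality mortality, spatial/geological correlation between neighbouring
sources, correlation between Ca and Mg beyond joint truncation, and any
real dose–response nonlinearity. Passing tests on synthetic groups
therefore demonstrate the pipeline's internal consistency and the method's
parameter-recovery behaviour, not the epidemiological validity of the
ecological comparison.

## Packaged fixtures and problem sizes

The published inputs (group concentration statistics, indicator rows,
exposure defaults, expected derived tables) ship as in-package constants
(`slovak_tables()`); the per-municipality water-chemistry tables are not
published, so the packaged 34-row soft and 21-row hard CSVs are synthetic
stand-ins generated by this package's own generator (fixed seeds, labelled
synthetic in filename and header) and are used only to exercise the CSV
pipeline, never as a source of published numbers. Test and acceptance runs
use the study's own scale — 34 + 21 municipalities, four indicators, three
elements — plus generator runs up to n = 1,000 for the convergence check;
the whole suite completes in a few seconds.
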