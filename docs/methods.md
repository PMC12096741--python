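# Methods

This note records the models, conventions, and numerical choices behind
`pahkit`, and what the synthetic-data tests do and do not demonstrate.

## Data model and censoring

A sample table holds one row per site-day: date, site, PM2.5 (µg/m³),
the 16 priority PAHs (ng/m³), and optional temperature, pressure and
relative humidity. The species catalogue fixes per-species ring count,
molecular-weight class (LMW = 2–3 rings, MMW = 4, HMW = 5–6), toxic
equivalency factor, and method detection limit (MDL). TEFs follow the
Nisbet–LaGoy scheme (0.001 for Nap, Acy, Flu, Ace, Phe, Flua, Pyr; 0.01
for Ant, Chr, BghiP; 0.1 for BaA, BbF, BkF, IcdP; 1 for BaP, DahA); the
default TEFs sum to 2.437. Default MDLs are typical HPLC substitution
constants (e.g. Nap 0.06, Acy 0.01, Ace 0.15 ng/m³); both tables are
overridable through a catalogue CSV. Published campaign tables rarely
print per-species detection limits, so these defaults are inferred
working values, not measured ones.

Observations strictly below the MDL are substituted and flagged.
Policies: `substitute-mdl` (default — reproduces the constant low
medians seen in real campaign summaries), `substitute-half-mdl`,
`leave-zero`. Substitution is idempotent; already-flagged values are
never re-substituted.

Back-trajectories are read from HYSPLIT `tdump` endpoint files (header
block, then one endpoint per line). Because tdump timestamps carry
2-digit years and no site label, a sidecar CSV (`traj,date,site`) maps
trajectory numbers to arrival site-days; without it the arrival date is
taken from the age-0 endpoint. Coordinates are decimal degrees, WGS84
assumed; samples are whole 24-h days.

## Descriptive conventions

- Quantiles: linear interpolation between order statistics.
- Exceedance: strict (`value > limit`); a day exactly at the limit does
  not exceed. Rates are `100·n_exceed/n_total` rounded to 2 decimals.
- Rank tests: Mann–Whitney U for two groups (exact when both n ≤ 8 and
  tie-free; otherwise tie-corrected normal approximation without
  continuity correction, so identical groups give p = 1 under
  mid-ranks); Kruskal–Wallis for more than two. Two monitoring sites
  are carried through the data model but pooled downstream once the
  between-site test is non-significant.
- Correlations: Spearman rank, pairwise complete cases, constant
  variables yield flagged NaN entries rather than exceptions.

## Diagnostic-ratio classification

Each ratio a/(a+b) is undefined when a+b = 0 or both components are
censor-substituted; a ratio with one censored component is computed but
flagged low-confidence, since substitution constants can dominate it.
Band boundaries: exact lower cut-offs (0.1, 0.2, 0.4) belong to the
higher class; band endpoints (0.35, 0.5) belong to the closed middle
band. Classification is total on [0, 1] ∪ {undefined}.

## PMF

The uncertainty matrix uses the standard error-fraction construction:
censored cells `s = (5/6)·MDL`; observed cells
`s = sqrt((EF·x)² + (0.5·MDL)²)` with error fraction EF (default 0.10).

The solver minimizes `Q = Σ((x − GF)/S)²` subject to `G, F ≥ 0`:

1. **Search** — `n_starts` (default 20) random initializations
   (uniform(0,1) scaled to the data magnitude), each run through
   weighted multiplicative updates (monotone in Q) until the relative Q
   change drops below `tol` (default 1e-6) or `max_iter` (2000).
2. **Polish** — the best `polish_starts` (default 3) candidates are
   refined by alternating weighted NNLS (exact per-row/per-column
   nonnegative least squares) at a 1000× tighter relative tolerance.
   The deep polish matters: near-tied rotational basins differ by tiny
   Q margins, and a loose stop returns whichever rotation the search
   happened to enter.

Scale indeterminacy is fixed by normalizing profile rows to sum 1 and
absorbing scale into G; factors are sorted by contribution percentage
(`100·Σ_i Σ_j g_ik f_kj / Σ`), which sums to 100. `q_expected = nm −
k(n+m)` is reported as a goodness reference. Factor labels are assigned
by the highest mean species-normalized loading over marker sets
(biomass: Chr, BaA, BaP; gasoline: Flu, BkF, BaP, BghiP, IcdP; steel:
Ace, DahA, IcdP; coal: Phe, Flua, Pyr, Chr; diesel: Ant, BaA, BghiP);
ties are reported as ambiguous. Labels are heuristic annotations, never
asserted ground truth. No rotational tools (FPEAK-style) are provided.
`factor_scan` reports Q and Q/Q_expected across candidate factor
counts to justify the chosen dimension (five by default).

**Known limitation.** When the smallest factor carries only a few
percent of the mass and its marker species sit near the detection
limit, occasional data realizations produce two minima whose Q values
tie to ~12 significant digits but differ in the rotation of that
factor; no Q-based criterion can disambiguate them. The recovery tests
use uncertainties matched to the generating noise (`s = cv·x`), the
statistically correct weighting for multiplicative noise; the EPA
MDL-floor construction remains the default for censored field-style
data, where it is the appropriate conservative choice.

## PSCF

A trajectory increments a cell's `n` once if it has ≥ 1 endpoint inside
(per-trajectory de-duplication, the common convention; an endpoint-count
mode exists because "trajectories passing through" is ambiguous in
parts of the literature). Trajectories whose arrival site-day exceeds
the PM2.5 threshold (default 35 µg/m³, strict) likewise increment `m`;
`PSCF = m/n` where n > 0 and is undefined (not zero) elsewhere. Default
grid 0.5°, auto-fitted to the endpoints with a one-cell margin;
endpoints outside an explicit domain are dropped with a logged count.
Weighting: `W = 1.0` for `n > 3·mean`, 0.7 for (1.5·mean, 3·mean], 0.42
for (mean, 1.5·mean], 0.05 for ≤ mean, with the mean taken over
nonempty cells. Multi-site runs pool trajectories; the arrival
site-day's PM2.5 decides the flag.

## Risk model

Units are chosen to close dimensionally to a unitless risk: TEQ ng/m³,
CSF 3.14 (kg·d)/mg, IR m³/d, EF d/a, ED a, CF 10⁻⁶ mg/ng, BW kg, AT
25550 d (70 a). The Monte Carlo draws a daily TEQ (empirical resampling
by default; a fitted lognormal optionally) and each exposure factor per
iteration (default 10,000), evaluates the formula, and reports
{min, P5, P25, median, P75, P95, max} plus the 1e-6 acceptable-risk
reference. Default exposure factors (adult IR 15.7 m³/d, BW 60.6 kg,
EF 350 d/a, ED 24 a; child 8.7, 21.7, 350, 6) are configurable
placeholders in the range of the Chinese exposure-factor handbooks —
the handbooks themselves are not reproduced, so computed risk levels
characterize the method, not any specific population. IR and BW are
zero-truncated normals with CV 0.2; EF and ED fixed. Sensitivity is the
Spearman correlation of each varying input with ILCR, normalized to
variance contributions `100·ρ_k²/Σρ²` (tornado-chart style); constant
inputs are excluded.

TEQ uses daily values (not annual medians) by default; the alternative
is a configuration choice.

## Synthetic generator

The generator emulates the structure the receptor model assumes, with
parameters chosen to resemble a mid-size northern-Chinese city
campaign:

- 446 sampled days per site over 6 years × 2 sites = 892 records.
- Five factors with marker-based profiles (flat 0.004 background before
  normalization — real profiles are sparse, and near-zero off-marker
  loadings are also what makes the factorization identifiable), total
  mean mass 12 ng/m³ split 20/21/6/37/16% across biomass, gasoline,
  steel, coal, diesel.
- Contributions: independent lognormal activity (CV 0.6) × a shared
  daily dispersion multiplier (CV 0.6, reproducing the median ≪ mean
  skew of real series) × per-factor seasonal cycles — coal peaks
  mid-January (heating), biomass burning in late autumn (agricultural
  residue), steel mildly in winter, traffic flat. Seasonal amplitude
  0.9 at the coal factor.
- Noise: multiplicative lognormal, CV 0.3 by default (0.1 in recovery
  experiments); mean-corrected so E[noise] = 1.
- Meteorology: sinusoidal temperature (summer maximum) with 3 °C noise,
  so total PAH is rank-anticorrelated with temperature (ρ ≈ −0.4 to
  −0.6); winter-peaking pressure; uninformative humidity.
- PM2.5 = ΣPAH / 0.3 + N(0, 8) µg/m³, floored at 1 — giving a median
  near 30 µg/m³ and ~40% exceedance of the 35 µg/m³ daily standard.
- Trajectories: one per site-day, 24 endpoints, straight line from the
  origin to the receptor plus a Brownian-bridge meander (per-step SD
  0.8°, zero at origin and arrival) so each path takes its own corridor.
  Polluted-day origins are drawn uniformly inside designated emission
  sectors by weight; clean-day origins uniformly over the domain.

What the generator does **not** emulate: autocorrelated multi-day
pollution episodes, wind-direction-dependent arrival headings, real
dispersion meteorology, between-site differences, instrument drift, or
species-correlated measurement error. Passing tests therefore
demonstrate correctness of the estimators under the assumed model, not
performance on real monitoring data — in particular, PMF on real data
faces rotational ambiguity and uncertainty misspecification that the
matched-uncertainty recovery test deliberately removes.

The end-to-end PSCF check uses a compact 2°×2° emission zone and a full
446-day campaign: with a broad sector, the transport corridor between
sector and receptor is statistically indistinguishable from the sector
itself (the well-known PSCF trailing artifact), and the argmax cell can
land just outside the boundary; clean-day dilution over a long campaign
separates a compact zone from its corridor.

## Pipeline

`run_all` executes describe → mdr → pmf → pscf → risk from one config.
The global seed fans out per stage through
`numpy.random.SeedSequence([seed, stage_index])`, so stages are
independently reproducible; outputs are written once per run directory
and stamped with a config hash (output location excluded), seed, and
package version. A missing trajectory path skips the PSCF stage with a
notice; any stage failure aborts with the stage name, preserving
completed outputs.

## Problem sizes in tests and the acceptance script

The suites use scaled-down campaigns chosen to exercise every code path
with comfortable statistical margins: 150-sample recovery experiments
(the smallest size at which all five profiles are reliably identified
at 10% noise), 30–80-sample fits for solver contracts, 446-day
single-site campaigns for PSCF geolocation, and 10,000 Monte Carlo
iterations for risk (seed-to-seed median spread < 2%).
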