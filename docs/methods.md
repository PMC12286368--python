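# Methods

## Exposure and risk model

The package implements the EPA deterministic ingestion-risk chain for
dietary exposure to toxic elements in bread. For each element with bread
concentration C (mg/kg dry weight) and a cohort with ingestion rate IR
(kg/day), exposure frequency EF (days/year), exposure duration ED (years),
body weight BW (kg) and averaging time AT (days):

    CDI = C · IR · EF · ED / (BW · AT)         [mg/kg/day]
    HQ  = CDI / RfD                            [-]
    HI  = Σ_elements HQ                        [-]
    CR  = CDI · OSF                            [-]
    TCR = Σ_carcinogens CR                     [-]

Assumptions: ingestion is the only route (no dermal or inhalation terms); the
slope-factor cancer model is linear with no age-dependent adjustment factors;
element risks combine additively (no interaction); the consumed product is
bread, so only bread-stage records enter dietary exposure — flour and dough
serve source apportionment and group testing. The regional concentration is
the arithmetic mean of bakery-level bread values; because CDI is linear in C,
the CDI of the mean equals the mean CDI.

### Default parameters

| parameter | adult | child | unit | note |
|---|---|---|---|---|
| IR | 0.420 | 0.210 | kg/day | per-capita bread consumption (Iran ≈ 420 g/day) |
| EF | 365 | 365 | days/year | daily staple |
| ED | 70 | 6 | years | |
| BW | 70 | 20 | kg | |
| AT | 10550 | 2100 | days | |

The adult (ED, AT) pair is internally inconsistent (70 years ≈ 25,550 days,
not 10,550); the defaults reproduce the parameter set of the survey the
package emulates verbatim rather than repairing it, since users supply their
own `ExposureParams` when they need a coherent set. One visible consequence:
with these defaults the child:adult CDI ratio is 0.01095/0.014531 ≈ 0.754,
so child hazard sits *below* adult hazard, whereas surveys that report child
hazard above adult hazard evidently used a different (unrecoverable)
parameter set. The published-aggregate checks therefore anchor on identities
among reported outputs (HI as the sum of HQs, TCR as the sum of CRs, means
and ratios of reported rows), never on recomputing those outputs from
concentrations.

Oral reference doses (mg/kg/day): As 0.003, Cd 0.001, Al 0.7, Co 0.0004,
Cu 0.04, Fe 0.7, Hg 0.0004, V 0.009, Zn 0.3, Cr 0.003, Ni 0.2, Pb 0.0035.
Oral slope factors ((mg/kg/day)⁻¹): As 1.5, Pb 0.0085, Cd 0.38. Thresholds:
HQ/HI limit 1.0 (strict >), cancer risk de minimis 10⁻⁶ and unacceptable
10⁻⁴, all config-overridable. Classification uses "at risk when HQ/HI > 1",
the standard EPA reading.

## Left-censored data

Below-detection values are carried as an explicit censored flag plus the
limit of detection, never as sentinel numerics. Four policies: `exclude`
(default — censored cells are dropped, so an element censored in every
record, like Hg and Pb in the emulated survey, vanishes from risk),
`zero`, `half_lod`, `full_lod`. The substitution policies exist for
sensitivity checks; no maximum-likelihood censored estimation is attempted
(with 100% censoring for the affected elements there is nothing to estimate).

## Compliance screening

Regional stage means are compared against a user-supplied limits CSV
(element, authority, limit). Exceedance is strict (`mean > limit`); equality
does not exceed. Elements lacking a limit are reported with an absent flag.
The bundled `limits_synthetic.csv` contains illustrative placeholder values
sized against the synthetic generator — not actual WHO/FAO or national
limits — because real limit tables are jurisdiction-specific and the user
must supply them for substantive screening.

## Source apportionment

The bread burden of each element is decomposed by increments of the stage
means f (flour), d (dough), b (bread): shares (f, d−f, b−d)/b, clipped at
zero (measurement noise can make increments negative) and renormalised to
100%. This is the simplest mass-balance reading of a flour → dough → bread
chain; it assumes dry-weight comparability across stages and does not model
individual dough additives separately. Shares are scale-invariant and sum to
100 per element. The per-element table uses region-pooled means; the grand
mean excludes elements missing a stage (e.g. fully censored ones).

## Group statistics

Per element, a one-sample Kolmogorov–Smirnov test against a normal law with
sample-estimated mean/sd gates the location test: one-way ANOVA if normality
is not rejected, Kruskal–Wallis otherwise. KS with estimated parameters is
the Lilliefors situation and is conservative (it under-rejects normality);
this is accepted and documented rather than corrected, because both branch
tests are valid under the null — the gated procedure's empirical type-I
error stays within 0.05 ± 0.02 (checked over 1000 null replicates). With the
synthetic defaults' mild lognormal skew the gate usually selects ANOVA; the
Kruskal–Wallis branch is exercised directly by the tests (including its
invariance under monotone transformations). No multiplicity correction is
applied by default, matching common practice in survey reports; a Holm
adjustment is available via a flag. α defaults to 0.05. Tests run on
bread-stage values by default (config-overridable).

## Monte Carlo uncertainty

Each uncertain input is a `DistSpec` (point, normal, lognormal, triangular,
uniform). Defaults: lognormal for concentrations (fitted by MLE on logs to
the usable bread values), point masses for exposure parameters — minimal
assumptions, every variable overridable. Inputs are drawn independently (no
correlation structure is modelled); draws are generated in a fixed sorted
order from one `numpy` Generator so that identical (distributions, n, seed)
give bit-identical results. n defaults to 10,000 iterations. The degenerate
case (all point masses) reproduces the deterministic HI/TCR bit-exactly: the
simulation evaluates the intake equation with the same operation order as
the deterministic path. Percentiles use `numpy`'s linear-interpolation
quantile; the cumulative curve is the ECDF prepended with a (min, 0) point
so it spans probability 0 to 1. The 95th percentile is the conventional
reporting measure.

## Sensitivity analysis

Contribution to variance is the squared Spearman rank correlation between
each stochastic input and the output, normalised across inputs to sum to
100% — the documented convention of spreadsheet risk simulators' tornado
output. Rank-based, hence invariant under monotone rescaling of inputs;
negative correlations contribute by their square with the direction reported
in a separate sign column; zero-variance inputs contribute exactly 0. Against
linear toy models the estimator agrees with large-sample oracles within
Monte Carlo error (tested at n = 10⁶).

## Synthetic survey generator

The generator emulates the motivating study design: 5 regions × 18 bakeries
× 3 stages × 12 elements = 3,240 records (270 per element). Flour
concentrations are lognormal with per-element medians and per-region
multipliers; dough and bread are the flour value times deterministic stage
factors (derived from target flour/dough/oven shares) times lognormal noise
(σ = 0.05 per step). Censoring is structural: Hg and Pb are emitted censored
at their LODs regardless of the draw. Bread types are assigned per bakery
and never influence concentrations, so type-wise comparisons are true nulls.

Default calibration (chosen once, from the design goals):

- bread-level medians (mg/kg dw): Fe 20, Zn 4.2, Al 3.5, Cu 0.9, Ni 0.25,
  Cr 0.12, As 1.0, Cd 0.03, Co 0.012, V 0.02 — Fe/Zn/Al largest, Co/V
  smallest, and As sized so its adult HQ (≈ 4.8 per mg/kg intake factor
  0.014531/0.003) exceeds 1 while every other element's HQ stays below 1;
- lognormal σ (log scale): 0.20 for the region-varying elements
  {As, Co, Cr, Ni, V}, 0.25 for the homogeneous ones. Region multipliers
  span 0.82–1.30 and were sized analytically so each varying element's
  one-way ANOVA noncentrality at 18 bakeries/region is ≳ 27, giving ≥ 95%
  joint detection of the five in 200-replicate checks, while {Al, Cu, Cd,
  Fe, Zn} have no regional structure;
- stage shares 83/14.5/2.5 (flour/dough/oven) for every element except Co
  (55/30/15), so flour dominates (> 70%) everywhere but Co and the grand
  mean flour share is ≈ 80%;
- the bundled illustrative limits are set so exactly {Al, As, Cr, Fe} exceed
  them in every region.

What the generator does **not** emulate: spatial correlation between nearby
bakeries, inter-element correlation within a bakery, seasonal drift,
measurement error beyond the lognormal spread, partial censoring (elements
are censored everywhere or nowhere), and the real survey's concentration
values themselves (its supplementary tables are not public). Passing tests
therefore demonstrate that the pipeline recovers designed structure of this
kind — not that any real city's bread matches these numbers.

## Numerical conventions

- Risk tables carry full double precision; rounding happens only at report
  time.
- `RiskTable` construction enforces HI = ΣHQ and TCR = ΣCR and
  non-negativity; report CSVs round-trip losslessly (`%.17g`).
- Exceedance and HQ flags use strict inequality at the boundary.
- Quantiles: linear interpolation; ECDF: right-continuous step.
- Problem sizes used by the acceptance script: published tables as printed
  (10 HQ components × 10 rows; 5 regions); 2,000 iterations for the
  degenerate-equivalence check; 10,000 draws for fit recovery and the
  symmetric sensitivity toy; 10⁶ draws for sensitivity oracles; 10,000
  bakeries for generator recovery; 1000 null replicates (size) and 200
  survey replicates (power) for the gated comparison.
- All randomness flows from a single integer seed; derived seeds stay below
  2³¹.

## Known limitations

- The deterministic risk depends on the printed exposure-parameter set,
  including its inconsistent adult (ED, AT) pair (see above).
- The apportionment decomposition is one of several defensible conventions
  (the emulated survey does not state how its contribution percentages were
  computed); medians, per-bakery pairing, or moisture correction would give
  different splits.
- Monte Carlo inputs are independent; rank-correlation structure between
  inputs is not modelled.
- No post-hoc pairwise group comparisons, no dose-response modelling beyond
  the linear slope factor, no wet/dry weight conversion.
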