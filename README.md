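# breadrisk

Human health risk assessment of arsenic and other potentially toxic elements
in bread, for food-safety scientists and exposure assessors working with
bakery survey data (flour, dough and baked bread sampled across city
regions).

Bread is a staple — in Iran the average person eats about 420 g of it a day —
so even modest element concentrations translate into meaningful chronic
doses. `breadrisk` takes a long-format concentration table (one row per
region × bakery × production stage × element, mg/kg dry weight, with explicit
below-detection flags) and computes the full EPA ingestion-risk chain:

```
CDI  = C · IR · EF · ED / (BW · AT)      chronic daily intake, mg/kg/day
HQ   = CDI / RfD                         target hazard quotient
HI   = Σ HQ                              hazard index (concern above 1)
CR   = CDI · OSF                         incremental lifetime cancer risk
TCR  = Σ CR                              total cancer risk (10⁻⁶–10⁻⁴ band)
```

where C is the bread concentration, IR the ingestion rate (kg/day), EF the
exposure frequency (days/year), ED the exposure duration (years), BW body
weight (kg), AT the averaging time (days), RfD the oral reference dose and
OSF the oral slope factor, per cohort (adult, child).

Around that core the package provides:

- **censoring policies** for below-detection values (exclude, zero, LOD/2,
  LOD) — elements censored everywhere, such as Hg and Pb in the motivating
  survey, drop out of risk under the default policy;
- **compliance screening** of regional means against permissible-limit
  tables;
- **source apportionment** splitting each element's bread burden into flour,
  dough-stage additions and baking/oven contact by increment decomposition;
- **group statistics**: a Kolmogorov–Smirnov normality gate choosing between
  one-way ANOVA and Kruskal–Wallis for region- and bread-type comparisons;
- **Monte Carlo uncertainty**: seeded propagation of fitted input
  distributions through the risk equations, percentile risk measures (the
  95th by convention) and cumulative risk curves;
- **contribution-to-variance sensitivity** (normalised squared Spearman rank
  correlation, tornado-style);
- a **calibrated synthetic survey generator** reproducing the study design
  the package was built against (5 regions × 18 bakeries × 3 stages × 12
  elements), so the entire pipeline is testable without any external data.

## Worked example

```python
import breadrisk as br

study = br.generate_study(br.default_config(seed=0))   # synthetic survey
model = br.BreadRiskModel(study)                       # defaults: adult+child,
results = model.fit()                                  # EPA RfD/OSF, exclude
print(results.summary())
```

prints (abridged):

```
Hazard index by region and cohort:
cohort   adult   child
region
Center  7.7319  5.8265
East    8.0110  6.0369
North   6.4057  4.8271
South   7.8873  5.9436
West    7.1324  5.3747

adult: mean HI 7.434 (range 6.406-8.011); mean TCR 2.222e-02 (range 1.777e-02-2.459e-02)
child: mean HI 5.602 (range 4.827-6.037); mean TCR 1.674e-02 (range 1.339e-02-1.853e-02)
rows with HI above 1.0: 10/10; CR classes: {'unacceptable': 10}
```

Every region × cohort row has a hazard index well above 1 (arsenic's HQ alone
is ~4–5) and a total cancer risk above the 10⁻⁴ unacceptability threshold —
the qualitative picture the synthetic defaults are calibrated to. The
Monte Carlo layer quantifies the uncertainty around those point estimates:

```python
mc = model.simulate(n=10_000, seed=0)
print(mc.summary())
```

```
cohort endpoint    mean     p05     p50     p95
 adult       HI   7.437   5.774   7.319   9.464
 adult      TCR 0.02223 0.01518 0.02166 0.03112
 child       HI   5.604   4.351   5.515   7.132
 child      TCR 0.01676 0.01144 0.01632 0.02345

top variance contributor per endpoint:
cohort endpoint variable  contribution_pct
 adult       HI     C_As              94.3
 adult      TCR     C_As              99.8
```

The 95th-percentile HI stays above 1 and the 95th-percentile TCR above
10⁻⁴ for both cohorts, and arsenic concentration dominates the variance of
both endpoints.

The same pipeline is scriptable from the shell:

```sh
breadrisk report --seed 7 --out-dir out/   # generate + risk + mc + sensitivity
breadrisk risk --input my_survey.csv --limits my_limits.csv --out-dir out/
```

writing `hq_hi_by_region.csv`, `cr_tcr_by_region.csv`, `cdi_by_region.csv`,
`compliance.csv`, `apportionment.csv`, `stats_report.csv`, `mc_summary.csv`,
`cdf_points.csv` and `sensitivity.csv`, each stamped with the seed and a
configuration hash.

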