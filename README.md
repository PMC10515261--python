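# riskcast

Return-level forecasting for multi-region annual health time series, built
on a system-reliability view of extreme values.

## The problem

Public-health surveillance often produces a short annual series (a few
decades) for each of many regions — say, national death rates from one cause
for ~195 countries. The planning question is about rare events: *what rate
level is expected to be reached once in 100 years, anywhere in the group of
regions?* Classical extreme-value tools work one series at a time and only
asymptotically; with 30 annual points per country they are starved for data
and ignore the strong cross-country correlation.

riskcast treats the regions as components of one multi-degree-of-freedom
system. Each component series is scaled by its hazard limit η_r (so every
component fails at level 1), all components' maxima are merged into a single
time-ordered synthetic series R₁…R_N, and the tail of that series is
estimated by conditional exceedance rates

    p̂_k(λ) = #{windows: previous k−1 values ≤ λ, current value > λ}
             ─────────────────────────────────────────────────────
             #{windows: previous k−1 values ≤ λ}

with the conditioning number k chosen by a convergence diagnostic. Above a
cut-on level λ0 the tail is fitted by the sub-asymptotic form
p(λ) ≈ q·exp{−a(λ−b)^c} (weighted least squares in log space), and the
T-year return level is read off as

    λ_T = b + (ln(q·T·m) / a)^{1/c},      m = relevant events per year,

with a 95% band obtained by fitting the same form to the pointwise
confidence curves. A classical Gumbel block-maxima fit provides the
baseline answer to the same question, and a second-order difference plot
(SODP) gives a quick quality-control view of the series. A Gaussian-copula
simulator with known marginals supplies exact ground truth for validating
the whole chain.

Audience: biostatisticians and risk analysts working with multi-region
surveillance panels (mortality, incidence, environmental health), and
anyone needing return-level estimates from short, correlated annual series.

## Worked example

Forecast the 100-year level for a synthetic 195-nation, 31-year panel whose
rates sit on the scale of national annual death rates (percent of local
population):

```python
import riskcast as rc

cfg = rc.RunConfig(
    sim=rc.SimConfig(n_regions=195, n_years=31, start_year=1990,
                     marginal=rc.Marginal("gumbel", 0.01, 0.004),
                     rho=0.5, seed=11),
    merge_strategy="pointwise", k=3, cut_on=0.024, grid_size=50,
    return_period=100.0, seed=11, outdir="demo_out")
report = rc.run_pipeline(cfg)
print(open("demo_out/report.txt").read())
```

prints

```
riskcast pipeline report
regions analysed: 195 (excluded: 0)
merge strategy: pointwise (31 events, 31-year span)
conditioning number k: 3
cut-on level: 0.024
events per year: 1.0
tail parameters (q, a, b, c): (0.522649, 4.01695e+15, 0.00652464, 10)
100-year return level: 0.0380994 (95% CI 0.0299554 .. 0.0396842)
Gumbel baseline level: 0.0506823 (95% CI 0.0419973 .. 0.0593673)
SODP descriptors: sd1=0.0131368, sd2=0.00689119
seed: 11
```

Reading the numbers: the merged series holds 31 annual events (one per
year, the worst region that year). The advocated method extrapolates the
conditional exceedance tail above 0.024% to a 0.038% rate with a 100-year
return period, with a noticeably narrower 95% band than the Gumbel
block-maxima baseline (0.042–0.059 around 0.051) — the behaviour the method
is designed for on short multi-region records. All artifacts (merged
series, exceedance table, forecast and Gumbel JSON, SODP table) land in
`demo_out/`.

The same run from the shell:

```
riskcast run --config run.yaml
```

and the individual stages are exposed as `riskcast load | simulate | merge |
acer | predict | gumbel | sodp`. Real panels enter as long-format CSV
(`Entity,Code,Year,<value>`), e.g.

```
riskcast load --csv deaths.csv --value-col Deaths --units count \
    --pop-csv population.csv --exclude Afghanistan --exclude Kiribati \
    --out panel.csv
```

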