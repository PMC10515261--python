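# Methods

## Problem and model

riskcast forecasts rare, high-severity levels of an annual rate observed
across many regions at once — the motivating case is national cause-specific
death rates (percent of local population per year) for ~195 countries over
~30 years. The regions are treated as the components X(t), Y(t), Z(t), … of
one multi-degree-of-freedom system. Estimating the joint distribution of the
component maxima directly is hopeless at that dimensionality, so the method
reduces the system to a single scalar series and works with conditional
exceedance rates:

1. **Hazard scaling.** Each component is divided by its critical (hazard)
   limit η_r, so all components share the failure level 1. When rates are
   already expressed as percent of local population, the natural η_r is the
   critical percentage itself and scaling is optional.
2. **Merging.** All components' local maxima are assembled into one
   time-ordered synthetic series R₁…R_N. Two reductions are implemented:
   *pointwise max* (one event per year, the maximum across regions observed
   that year — the default for synchronous annual panels) and *interleave*
   (all events kept in non-decreasing time order; time-coincident events
   collapse to their componentwise maximum, so no event is lost). For a
   synchronous annual panel interleaving degenerates to the pointwise max,
   which is why the pointwise form is the default there.
3. **Conditional exceedance.** For a level λ and conditioning number k,

       p̂_k(λ) = a_k(λ) / b_k(λ),

   where b_k counts windows of k consecutive events whose first k−1 values
   are ≤ λ and a_k counts those windows ending in a value > λ. k = 1 is the
   empirical survival function; larger k absorbs serial clustering. The
   working k is the smallest at which successive p̂_k agree within a relative
   tolerance on the tail grid (default 10%); for independent events k = 1–2
   suffices, for strongly clustered series the diagnostic reports the
   disagreement profile. Ties (R_j = λ) count as non-exceedance.
4. **Tail fit and extrapolation.** Above a cut-on λ0 the exceedance function
   is modelled as p(λ) ≈ q·exp{−a(λ−b)^c} with q ∈ (0,1], a > 0, b < λ0,
   c ∈ [0.1, 10]. The T-year return level at m relevant events per year is
   the solution of p(λ) = 1/(T·m):

       λ_T = b + (ln(q / p_T) / a)^{1/c}.

5. **Baseline.** A classical Gumbel block-maxima fit to the same annual
   series answers the same return-level question for comparison.

## Estimation details

**Weighted log-space least squares.** Parameters minimise
Σ_j w_j (ln p̂(λ_j) − ln q + a(λ_j − b)^c)² over usable grid points
(λ_j ≥ λ0, a_k > 0), with w_j = (ln ci_hi − ln ci_lo)^{-2} so points with
tight count-based confidence bands dominate. For fixed (b, c) the model is
linear in (ln q, a) and solved in closed form; the outer search over (b, c)
runs Nelder–Mead from the best point of a deterministic coarse grid
(b = λ0 − δ, δ geometric over 0.01–10 grid spans; c geometric over 0.25–4).
The fit is deterministic given the data. Individual parameters can trade off
(e.g. q against b at c = 1); the fitted function is the contract, not the
tuple.

**One point per empirical step.** The empirical p̂ is a step function; an
equally spaced grid samples long flat steps — for instance the stretch
between the two largest observations — many times, and each duplicate
carries the same counts. Left in, those duplicates multiply the weight of a
single observation and can visibly bend the fitted curvature when the sample
maximum is an outlier. Only the first grid point of each (a_k, b_k) run
enters the fit.

**Pointwise confidence bands.** The normal approximation for rare-event
counts, p̂·(1 ± 1.96/√a_k), clipped to [0, 1] and undefined where a_k = 0.
Where the lower band clips to zero, the weight computation substitutes the
log-symmetric width 2·(ln ci_hi − ln p̂); widths are floored at 10⁻⁶ so
degenerate (noise-free) inputs fall back to equal weighting.

**Extrapolated bands.** The same parametric form is fitted separately to the
empirical ci_lo and ci_hi curves (where positive) and inverted at the target
probability. This keeps the band monotone in the target and mirrors how the
central fit treats the data; no delta-method linearisation is involved.
In a repeated-sampling check (200 replicates of 20,000 i.i.d. exponential
events — a 100-year record at 200 events/year — cut-on at the p ≈ e⁻³
level), the band contains the true 100-year level in ≈92% of replicates.

**Return-period translation.** The T-year level has per-event exceedance
probability 1/(T·m). For pointwise-max merges m = 1 event/year; for
interleaved merges m = N divided by the record span in years. Both are
recorded in the forecast, and m can be overridden.

**Gumbel baseline.** Moments (β = s√6/π, μ = m̄ − γβ) or MLE via
`scipy.stats.gumbel_r.fit` with moments initialisation. MLE intervals use
the delta method with covariance from the numerically inverted observed
information (central differences, relative step 10⁻⁴); moments intervals
use a seeded nonparametric bootstrap (default 1,000 resamples).

**SODP quality control.** The second-order difference plot scatters
consecutive first differences (Δ_n, Δ_{n+1}); descriptors are the standard
Poincaré-style dispersions perpendicular to and along the identity diagonal,
sd((Δ_{n+1} ∓ Δ_n)/√2). Differencing makes the summary shift-invariant and
absolutely homogeneous, which the suite asserts exactly.

## Synthetic data generator

The simulator stands in for the observed multi-national panel. A latent
standard-normal field with exchangeable cross-region correlation ρ and AR(1)
temporal persistence φ (plus an optional linear Gaussian-scale drift) is
pushed through the normal CDF and the inverse CDF of a chosen marginal
(Gumbel, lognormal or exponential). At φ = 0 and trend = 0 each region's
values are an exact i.i.d. sample from the marginal, so every true return
level is a closed-form quantile (`true_return_level`), which is what makes
end-to-end accuracy and coverage checks possible.

What it does *not* emulate: age structure and cohort effects, reporting
artefacts, heterogeneous per-region marginals, non-exchangeable (e.g.
spatially decaying) dependence, and heavy-tailed measurement error. Values
are clamped at zero after the marginal map to honour the non-negativity of
rates; for the rate-scale defaults this clamp binds with negligible
probability, but it means a marginal with substantial mass below zero is not
reproduced exactly. Passing tests therefore demonstrate correctness of the
machinery under controlled dependence and known tails — not that any real
surveillance series satisfies those assumptions.

## Default parameters

| parameter | default | units | why |
|---|---|---|---|
| merge strategy | pointwise | — | synchronous annual panels; interleave retained for staggered event data |
| maxima mode | all_values | — | one value per region-year; strict interior maxima would discard most of a 31-point series |
| k | 3 | events | small enough to keep windows plentiful on short series; the convergence diagnostic justifies smaller k when the data allow |
| cut-on λ0 | 0.024 | percent of population | the level above which the parametric tail is assumed for rate panels on the national-mortality scale |
| grid size | 100 | levels | equally spaced from λ0 to the sample maximum |
| return period | 100 | years | the planning horizon of interest |
| c bounds | [0.1, 10] | — | degeneracy guard on tail curvature |
| CI z | 1.96 | — | pointwise 95% bands |

## Numerical choices and degenerate inputs

Missing years stay missing: maxima extraction and pointwise merging skip
them, and a year unobserved in every region is dropped, never imputed.
Duplicate (region, year) rows, non-numeric cells and missing mandatory
columns fail loudly at load time. Constant samples are rejected by the
Gumbel fit (scale undefined); series shorter than 3 are rejected by the
SODP; k larger than the event count is a window error; fewer than 4 usable
tail points is an insufficient-tail error. The estimator's p̂_k is exactly
non-increasing in λ for k = 1; for k ≥ 2 monotonicity is typical but not
guaranteed pointwise on finite samples (newly qualifying windows at a higher
level can exceed at a higher rate), so it is asserted only for k = 1.

## Problem sizes used in the checks

The suite and the reproduction script use sizes chosen to make Monte-Carlo
error small relative to the asserted tolerances while staying desk-scale:
10⁵ events for tail-recovery (5 replicates), 5×10⁴ for k-convergence, 200
replicates of 2×10⁴ events for band coverage, 100 random sequences up to
N = 1000 for count-exactness, and a 195-region × 31-year panel for the
study-scale demonstration.

## Known limitations

The tail form q·exp{−a(λ−b)^c} is an assumption, not a theorem; it nests
Gumbel-like exponential tails (c = 1) but cannot represent heavy power-law
tails well. The extrapolated band reflects only the sampling uncertainty
visible in the pointwise count bands, not model uncertainty in the tail
family or in the choice of cut-on. The conditional-exceedance construction
treats the merged series as a single stationary stream; strong temporal
trend violates that and should be handled (or at least inspected) before
fitting — the SODP and the k-convergence profile are the provided
diagnostics, not a remedy.
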