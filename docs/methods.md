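# Methods notes

This note records the statistical models, the conventions the package
commits to where several defensible choices exist, what the synthetic data
do and do not emulate, and known limitations.

## Reaction-norm models

Each species × trait combination is fitted separately. The linear predictor
is `(β₀ + a_k) + (β₁ + b_k)·t`, with `t` the treatment temperature z-scored
over the observation rows of that fit (sample SD, ddof = 1); the raw °C
column is retained so that slopes can be reported per °C by dividing by the
temperature SD. The population random effects `(a_k, b_k)` carry an
unstructured 2×2 covariance; the experimental replicate adds an independent
random intercept crossed with population.

* **Gaussian traits** (phenologies, height, √flower count) are fitted by
  profiled maximum likelihood: for a candidate relative covariance factor
  Λ(θ) the random-effect modes, fixed effects and residual variance have
  closed forms via one penalised least-squares solve, so the optimiser works
  on θ alone (3 population parameters + 1 replicate parameter). ML rather
  than REML is used so AIC is comparable across random-effect structures.
* **Germination** is a binomial-logit model on per-dish (germinated,
  viable) counts, fitted by the Laplace approximation: penalised Newton
  iterations (PIRLS) find the random-effect modes inside a quasi-Newton
  optimisation over (β, θ) jointly. Adaptive quadrature is not offered; the
  2-D correlated random effect per population would make it expensive, and
  Laplace is accurate at the dish counts used here (~25 trials per row).

Variance parameters are box-constrained at zero; a fit whose population SD
lands at (or within 1e-4 of) the boundary is returned with `boundary=True`
rather than raising, and plasticity extraction proceeds with zero
deviations. `theta_fixed` lets callers condition on known variance
parameters (used, e.g., to study shrinkage of the conditional modes, which
is monotone in the residual SD only when the variance parameters are held
fixed — re-estimated ML variances are themselves noisy and can break the
monotonicity in single realisations).

Counting parameters for AIC: fixed effects + variance parameters
(+ residual σ for Gaussian). The random-slope support statistic is
ΔAIC = AIC(intercept-only) − AIC(intercept+slope), "supported" above 2.

**Plasticity** is |fixed slope + population deviation| per °C. The
fixed+deviation total (not the deviation alone) is used, since the
reported per-population response ranges straddle the fixed estimate. The
absolute value is taken on the per-°C scale; because the scaling factor is
a positive constant per fit, orderings are identical on either scale.

The percentage-point conversion for germination slopes uses the finite
difference `100·[p(η₀) − p(η₀ − β)]` with `p` the inverse logit — the
derivative form `100·p(1−p)·β` agrees to two decimals at the published
values and is treated as the documented approximation. Prediction bands
come from the fixed-effect covariance on the link scale; for the binomial
family the interval endpoints are inverse-logit-transformed (keeping
probabilities inside (0, 1)) rather than delta-method-propagated.

## Trait preparation

Cut-test viability excludes empty and infested seeds only; moldy and full
seeds count as viable. The germination inclusion filter is strict
(pooled germinated/viable > 5%; exactly 5% is excluded) and is applied on
the population's pooled counts; per-treatment filtering is available via
the per-dish summaries if wanted. Weekly census phenology is recorded at
the census day (7/14/21/28); interval censoring is not modelled. Flower
abundance is square-root transformed before fitting.

## Range-position metrics

DRE splits the range-boundary segments at the site's latitude into a
northern and a southern part (segments crossing the latitude are cut at the
crossing) and reports the smaller of the two point-to-segment distances, in
planar km. Distances are to segments, not vertices. All coordinates are
assumed planar/projected; no geodesy is performed, so real-world input must
be pre-projected.

DCE z-scores the climate variables on the range cells (dropping
zero-variance variables with a warning), extracts the first two principal
axes of the cell cloud, orients each axis so its largest-magnitude loading
is positive, projects the sites with the cell-derived scaling and loadings,
and measures the Euclidean distance from the site score to the nearest edge
segment of the convex hull of cell scores. Sites outside the hull return
the same minimum distance flagged `exterior=True`; no sign convention is
imposed.

## Heterogeneity metrics

All three metrics are computed on the set of whole cells whose centres fall
in the closed square [x±500 m, y±500 m] (cell-centre dialect). SHDI is
−Σ pᵢ ln pᵢ over class proportions by cell count. Patches are connected
components of equal class under 8-connectivity by default (4 selectable);
patch perimeter counts every cell side adjacent to a different class, a
different patch, or the buffer boundary (clipped patches are closed at the
edge), and PAR is the unweighted mean of perimeter/area over patches. ARE
is the mean absolute deviation from the buffer's mean elevation (the
surface-roughness parameter Sa), without planar detrending; detrending was
considered and left out as the default since the buffer is small relative
to regional slopes, and the z-shift/scale equivariance of the undetrended
form is what the tests pin down.

## Driver models

Per trait, the driver table joins per-population plasticity with the five
site metrics, freshly z-scored across exactly the included rows (so means
are zero after any exclusion). The 12 candidate OLS models (2 RP × 3 EH ×
±interaction) are ranked by Gaussian AIC with k = coefficients + 1
(residual variance counted); ties beyond the ΔAIC ≤ 2 support band break by
lowest AIC, then fewest parameters. Species are pooled, matching the main
analysis design; a species-level random effect is out of scope.

LMG relative importance treats every regressor column — the interaction
column included — as an ordinary regressor and averages its sequential R²
increment over all t! orderings (computed by the subset-sum identity, exact
for the t ≤ 3 models used; refused above t = 10). Shares are reported
against total variance with an explicit unexplained = 1 − R² component, so
partition rows sum to one. Spearman correlations among the metrics are
screened with a |ρ| ≥ 0.7 flag.

## Synthetic data

The generator emulates the experimental design: four daytime temperature
treatments (16/20/24/28 °C), two replicates, up to 10 potted plants per
population × treatment for Gaussian traits, and 25-seed dishes for
germination; three species with ~8–18 populations each sampled from a
noisy-ellipse range with a north–south climate gradient. Population slopes
follow `b_k = s_k · max(0, |β₁| + γ_rp·RP + γ_eh·EH + γ_int·RP·EH + e_k)`:
plasticity (an absolute value) is the causally driven quantity, the random
sign s_k allows both response directions, and the floor at zero keeps the
magnitude well-defined (a generator convention, relevant only when the
drivers push the magnitude negative). Landscapes are smoothed Gaussian
random fields whose correlation length shrinks as the heterogeneity knob
rises — land cover by quantile thresholding into classes, elevation by
scaling the field amplitude with the knob — so expected SHDI and ARE are
increasing in the knob, with knob = 0 yielding a one-class flat landscape.

A second generator, `simulate_random_regression`, draws population slopes
as plain Gaussians around the fixed slope with no sign/floor mechanism —
the textbook generating model of the random-regression fit — and is what
the parameter-recovery and power studies use.

What the synthetic data do *not* emulate: spatially autocorrelated gene
flow, seed dormancy physiology, the real land-cover class structure, and
any within-replicate error structure beyond a replicate random intercept
plus independent Gaussian residuals (the independence is an assumption; the
experimental design gives no information to identify more). Passing tests
therefore demonstrate correctness of the estimators under the assumed
generating model, not robustness to real-data violations of it.

Default study sizes in the test suite (e.g., 50-rep recovery at 20
populations, 100/200-rep selection and support studies, 600-cell climate
grids, 120-cell rasters at 10 m) were chosen as the smallest designs at
which the targeted statistical properties are stable.

## Numerical conventions

* z-scores use sample SD (ddof = 1) everywhere, matching the usual `scale()`
  semantics; the four-treatment balanced design has temperature SD 5.164 °C
  at one row per treatment.
* The Gaussian profiled deviance floors the penalised residual sum of
  squares at 1e-300 so exactly noiseless inputs stay finite; such fits
  return the exact fixed effects with σ → 0.
* Optimisation: L-BFGS-B with a Nelder–Mead fallback from a shrunk start;
  binomial outer iterations warm-start the random-effect modes.
* Convex hulls come from Qhull, normalised to counterclockwise vertex
  order; collinear inputs raise a degenerate-hull error.
* Patch labelling is deterministic: classes in sorted order, components in
  raster scan order.

## Known limitations

* Reaction norms are strictly linear in temperature; nonlinear (quadratic
  or spline) norms are out of scope.
* Binomial fits rely on the Laplace approximation; with very small dish
  counts (<5 trials) its variance estimates can be biased.
* The driver models are OLS with pooled species; no model averaging,
  bootstrap CIs for LMG shares, or mixed-model driver regressions.
* Raster I/O is plain ASCII grid only; inputs in other formats must be
  converted upstream, and no reprojection/resampling or no-data handling is
  provided beyond erroring.
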