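# Methods

## The screening problem

Given right-censored survival data — observed times `T̃ᵢ = min(Tᵢ, Cᵢ)`,
event indicators `Δᵢ = I(Tᵢ ≤ Cᵢ)` and an `n × d` covariate matrix with
`d` possibly far larger than `n` — the task is to rank the covariates by
their association with survival so that a small set of candidate markers
can be carried into a multivariable model. Marginal (one-covariate-at-a-
time) screens ignore the dependence between covariates: strongly
correlated covariates whose effects oppose each other ("antagonistic"
variables) mask one another, and null covariates that are merely
correlated with influential ones inherit spurious marginal associations.

## The CARS score

The package's core statistic treats the log survival time `Y = log T`
under a lognormal accelerated failure time (AFT) model
`Y = β₀ + xᵀβ + ε`, `ε ~ N(0, σ_ε²)`. The population score is the CAR
(correlation-adjusted regression) score

    θ = P_X^{−1/2} P_XY ,

the vector of correlations between `Y` and the *decorrelated* covariates
`P_X^{−1/2} x`, where `P_X` is the covariate correlation matrix and
`P_XY` the vector of marginal correlations. `θᵀθ = P_XYᵀ P_X^{−1} P_XY`
is the share of `Var(Y)` explained by the best linear predictor, so `θ`
apportions the explained variance among covariates; null covariates get
`θⱼ = 0` exactly, however strongly they correlate with influential ones.

Under right-censoring the sample correlations of `x` with `log T̃` are
biased, so the empirical score replaces them with inverse-probability-of-
censoring (IPC) weighted moments:

* `Ĝ`, the censoring survival function `P(C > t)`, is estimated by the
  Kaplan–Meier product-limit estimator with the flipped indicator
  `1 − Δ`; weights are `wᵢ = Δᵢ / Ĝ(T̃ᵢ⁻)` (zero at censored rows).
* Weighted mean/variance of `log T̃` and the weighted covariances with
  each covariate use a `1/n` normalization; covariate variances use the
  usual `n − 1` divisor. This mixed normalization is kept exactly as the
  estimators are defined (it cancels asymptotically); its visible trace
  is that with no censoring and one covariate the score equals Pearson's
  `r` times `√((n−1)/n)`.
* The correlation matrix is estimated by linear shrinkage
  `R_shrink = λI + (1−λ)R_X`, with
  `λ = Σ_{j≠k} Var̂(r_jk) / Σ_{j≠k} r_jk²` clamped to `[0, 1]`; the
  pairwise variance uses the unbiased product-moment estimator
  `n/(n−1)³ Σᵢ (w_ijk − w̄_jk)²`, `w_ijk` the product of standardized
  entries. The whitening `R_shrink^{−1/2}` is applied through the
  eigenpairs of `R_X` obtained from an SVD of the standardized data
  (dense eigendecomposition below d = 64), so no `d × d` matrix is ever
  formed; cost is `O(n²d)`.

The final score is `θ̂ = R_shrink^{−1/2} R_XY`; covariates are ranked by
`|θ̂|` (ties broken by column order).

### Numerical choices

* `Ĝ` is evaluated at the left limit `T̃ᵢ⁻`, with survival events ordered
  before censoring events at ties, so an event is never down-weighted by a
  censoring at its own time point. The estimate is computed on the raw
  time scale (identical to the log scale by monotonicity) and floored at
  `ν = 10⁻⁸`, reflecting the positivity assumption `G > ν > 0` that the
  consistency theory requires.
* Marginal correlations are clamped to `[−1, 1]` with a warning; IPC
  weighting can push small-sample ratios slightly outside.
* `λ = 0` is allowed only when `R_X` has full rank; otherwise the
  operator would be singular and the constructor raises.
* A per-sample vector of externally estimated `Ĝ(T̃ᵢ⁻ | xᵢ)` values can be
  injected in place of the Kaplan–Meier step (hook for covariate-dependent
  censoring models); no conditional model is implemented here.

## Cox-score comparator

The baseline screen fits a univariate Cox proportional-hazards model per
covariate and scores it by the Wald statistic `z = β̂/se(β̂)` (the
"standardized coefficient"). Newton–Raphson on the Breslow partial
likelihood, at most 50 iterations, convergence at score `< 10⁻⁹`;
covariates are sd-scaled internally for conditioning (z is
scale-invariant). A monotone likelihood (e.g. a covariate that perfectly
orders the risk sets) is detected when `|β̂|` per sd exceeds 15 and
reported as non-converged with `|z|` capped at 37. Breslow tie handling
is sufficient because the simulated event times are continuous; the cap
and tie rule matter only for pathological or heavily tied real data.

## FDR-based marker selection

Scores are symmetrized (`|θ̂|`) and modelled as a two-component mixture:
a null proportion `η₀` following a half-normal with scale `σ`, plus an
alternative. The null is fitted by truncated maximum likelihood:
candidate truncation points are the 50th–95th percentiles (step 5) of
the absolute scores; for each candidate the half-normal scale is the ML
fit to the scores below it, and the candidate whose implied null CDF
`η₀·F₀` is closest (Kolmogorov distance) to the empirical CDF over the
span up to the 95th-percentile candidate wins, smallest candidate on
ties. The distances are deliberately computed on that common span: the
lower half of a half-normal identifies its scale only weakly, so judging
each candidate against its own truncated subsample systematically
rewards overfitted low truncations (we observed fitted scales from 0.7×
to 6× the truth that way).

The empirical distribution used in the tail-area ratio is smoothed by
the least concave majorant of the ECDF of `|scores|` (the Grenander
construction: its slopes are the canonical decreasing density estimate).
Tail-area q-values are

    q(s) = min over thresholds t ≤ s of  c_d · η₀ · F̄₀(t) / F̄(t) ,

clipped to `[0, 1]`; the running minimum makes q monotone non-decreasing
as `|score|` decreases. `c_d = Σ_{i≤d} 1/i` is the harmonic correction
that keeps false-discovery-rate control valid under arbitrary dependence
between the tested statistics. It is on by default because the score
vectors this tool thresholds are dependent by construction — correlated
covariates yield correlated screening statistics — and because without
it the plain tail-area ratio assigns q ≈ 0.01–0.02 to the single most
extreme of ~1000 null scores (≈ 3.9 σ), so isolated extreme nulls enter
every selection; the correction prices them at q > 0.05 while leaving
genuinely separated signals (8 σ and beyond, q ≈ 10⁻¹²) untouched.
Selection keeps covariates with `q < α₁`. A local false-discovery rate
(`η₀ f₀ / f̂` with `f̂` the Grenander density) is reported alongside but
not used for selection.

Fitting requires at least 20 scores; below that, threshold `|θ̂|`
directly.

## Synthetic-data generator

The generator emulates a gene-expression-like screening benchmark:

* **Covariates**: multivariate normal, zero mean, block correlation
  structure with three equal blocks of within-block correlation
  magnitude 0.25 / 0.50 / 0.75 and zero between-block correlation. Every
  covariate carries a sign `sⱼ ∈ {±1}` (first half of each block `+`,
  second half `−`) and the correlation of a within-block pair is
  `|ρ| sⱼ s_k`, so ≈ 50% of within-block correlations are negative while
  each block remains an exact, positive-definite
  equicorrelation-with-signs matrix. Assigning entry signs independently
  instead makes the matrix massively indefinite, and its nearest valid
  correlation matrix has entries shrunken to a fraction of the nominal
  `ρ` — which silently turns the high-correlation scenario into a
  near-independence one. The nearest-correlation repair (Higham
  alternating projections with Dykstra correction, tolerance 10⁻⁷, final
  eigenvalue-clip + rescale cleanup) remains in the pipeline as a guard
  and for user-supplied structures.
* **Effects**: a fraction `relVar` of covariates, the leading columns of
  a designated block, receive coefficients equidistant in `[−0.9, 1]`
  (`k = 1` gives `1`). Influential covariates are therefore mutually
  *positively* equicorrelated, which is precisely the configuration that
  defeats marginal screening: the shared group effect masks influentials
  whose own coefficient opposes it and elevates the correlated nulls.
  When the equidistant grid hits 0 exactly (e.g. `k = 20`), that
  covariate is still labelled influential, with a logged warning.
* **Survival**: lognormal family `log T = Xβ + ε` with
  `σ_ε² = βᵀΣβ (1−expVar)/expVar` (closed form, targets the explained
  log-scale variance), or Weibull family `T ~ W(Φ = e^{Xβ}, φ)` with the
  shape calibrated by bisection on a pilot draw to a signal-to-noise
  ratio `Var(E[log T|x]) / Var(log T − E[log T|x])` (default 0.5; the
  closed form `φ = π √(snr / (6 βᵀΣβ))` serves as a cross-check). The
  Weibull family satisfies AFT and proportional-hazards assumptions
  simultaneously.
* **Censoring**: lognormal censoring times with fixed log-sd 1 and the
  log-mean calibrated by bisection on a pilot draw so that the *total*
  censoring fraction — random plus an administrative cutoff at the 90%
  pilot quantile of `T` — hits the target rate within 0.01. The cutoff is
  computed once per scenario and held fixed. Pilot size defaults to 10⁵
  (configurable), which reproduces cutoffs within ~2% across pilot seeds.
* **Options used by the consistency studies**: `admin_quantile=None`
  removes the administrative cutoff and `cens_log_sd=None` matches the
  censoring log-sd to the pilot sd of `log T`. Both matter for studying
  consistency rather than benchmark performance: a hard cutoff sets
  `G = 0` beyond it, so IPCW converges to cutoff-truncated moments (the
  theory's `G > ν > 0` assumption fails and the estimand itself changes),
  and a censoring tail much lighter than the outcome tail (log-sd 1
  vs. sd(log T) ≈ 2.5 in the d=10 design) produces weights of 15–30 whose
  variance freezes the sup-norm error near 0.08 regardless of `n`. With
  matched scales the error decreases monotonically (≈ 0.047 at n = 4000,
  ≈ 0.025 at n = 16000, medians over ≥ 20 seeds).

What the generator does **not** emulate: heavy-tailed or discrete
expression distributions, covariate-dependent censoring, tied event
times, batch structure, or missing values. Passing results on this
generator therefore demonstrate correctness of the estimators and the
claimed qualitative orderings under the model's own assumptions, not
performance on any particular real cohort.

## Evaluation

Rankings are scored against the ground-truth influential set by the area
under the precision–recall curve using the average-precision estimator:
thresholds sweep the distinct score values descending, tied scores are
collapsed into one group, and every positive in a group receives the
group-level precision. No linear interpolation is used (linear PR
interpolation is known to be biased), so values are comparable across
implementations of the same estimator but may differ by a few points
from trapezoidal variants. With all scores equal the value equals the
prevalence — the random-classifier baseline; note the estimator is biased
above prevalence for randomly ordered *small* score vectors (noticeable
below d ≈ 50). Ranking quality against effect sizes uses Spearman
correlation with average-rank ties.

`run_study` replicates scenario grids: per-scenario structure and
calibration constants are computed once and shared across replicates
(the administrative cutoff "remains fixed"); per-replicate seeds derive
deterministically from the base seed.

## Study sizes used by the shipped checks

The packaged acceptance checks scale the original cluster-scale grid
(hundreds of replicates over dozens of scenarios at d up to 2000) to
desk scale as the package's standard verification sizes: consistency at
d = 10 with n up to 16000 (20–40 seeds), the screening comparison at
n = 500, d = 99 with 50 replicates per scenario, and FDR calibration at
d = 1000 over 50 seeds. At d = 99 < n the absolute PR-AUC values of both
screens are higher than in a d ≫ n setting, but the qualitative contrast
(decorrelation wins under high correlation, and the CARS-vs-Cox margin
widens as correlations grow) is preserved and is what the checks assert.

## Known limitations

* IPC weighting discards censored observations and re-weights events;
  when the censoring distribution's tail is much lighter than the
  outcome's, weight variance grows quickly and scores at moderate `n`
  are noisy. This is a property of the estimator, not the
  implementation.
* The population score's closed form (`Σ_XY = Σβ`) is exact only for the
  lognormal AFT family; for Weibull scenarios a Monte-Carlo oracle is
  the appropriate reference.
* The mixture-model selection step is a concrete, documented variant of
  the adaptive-FDR approach; marker *counts* at a given `α₁` are
  sensitive to its internals (truncation search, smoothing, dependence
  correction) even when the underlying ranking is identical.
* Scores come with no standard errors or confidence intervals.
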