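# Methods

## Model

The hazard of the event of interest is modelled on the log scale as an
additive function of several time-scales and covariates.  One scale is
the *reference* scale on which entry and exit are recorded (time since
surgery in the illness-death design, attained age in the matched design);
every other scale is the reference time minus a per-subject offset
(`t2 = t1 − r` for time since an intermediate event at `r`;
`t2 = t1 − a0` for time since diagnosis at age `a0`).  A secondary scale
may be *gated* by a 0/1 indicator so that its terms act only after a
transition; the indicator itself enters as a jump term by default
(`gate_jump=False` removes it and forces hazard continuity at the
transition).  Covariates enter linearly or through their own spline
expansion, and covariate × time-scale interaction columns provide
non-proportional hazards when requested.

Each time function is a restricted cubic spline: piecewise cubic,
continuous up to the second derivative, linear beyond the boundary knots.
The basis is the unscaled restricted truncated-power basis
(`v1(u) = u`, `v_j(u) = (u−k_j)₊³ − λ_j(u−k_1)₊³ − (1−λ_j)(u−k_K)₊³`,
`λ_j = (k_K−k_j)/(k_K−k_1)`), deliberately not orthogonalised or
rescaled so that coefficients are directly comparable between the
quadrature-based and Poisson fits.  Knots sit at equally spaced centiles
of the event times *measured on the scale in question* (for a gated
scale: events occurring while the gate is on), with boundary knots at the
first and last event times; centiles use linear interpolation of the
empirical CDF (numpy's default, type-7).  This boundary rule is applied
to every scale — the option of using the data range instead exists only
through explicit knots.  A reference scale is typically modelled on log
time; a scale with `n_knots=0` contributes no columns (constant hazard on
that scale), which yields the exponential model as a degenerate case.
Covariate-spline knots use centiles of the covariate over subjects
(unique ids), not over episodes.

With all gates off the model collapses to an ordinary one-time-scale
flexible parametric model on the log-hazard scale.

## Likelihood and fitting

For episode `i` with entry `a_i`, exit `b_i`, event `d_i` and design row
`z_i(t)`,

```
ℓ(θ) = Σ_i [ d_i z_i(b_i)'θ − ∫_{a_i}^{b_i} exp(z_i(u)'θ) du ]
```

— the standard left-truncated, right-censored survival likelihood;
delayed entry is nothing more than `a_i > 0`.  The integral has no closed
form for spline log-hazards and is evaluated by Gauss–Legendre
quadrature.  Because a restricted cubic spline is only C² at its knots,
a single rule per episode converges only algebraically; the integrator
therefore cuts each episode at every knot location falling inside it (on
the natural time axis, including gated-scale knots shifted by the
subject's offset) and applies Gauss–Legendre per piece.  Each piece is
then analytic and the default order (30 nodes for a single piece, 15 per
piece otherwise) is accurate to near machine precision — episode
splitting leaves the likelihood unchanged to 1e−10 and doubling the node
count moves fitted coefficients by far less than 1e−5 on cohorts of the
sizes used here.  One caveat: with a log-time basis, episodes that start
exactly at the time origin have an integrand behaving like `t^γ1` near 0,
whose derivative singularity is not removed by knot cuts; the residual
quadrature error there (~1e−6 relative) is orders of magnitude below the
statistical error and is shared by any fixed-order rule on the natural
axis.  Interior nodes also mean a log-time basis never sees `t = 0`.

`ℓ` is strictly concave (the event term is linear in θ and the integral
term is a positive combination of exponentials), so a damped Newton
iteration with the exact gradient and Hessian converges in a handful of
steps.  Starting values are the exponential-model fit (intercept =
log(events/person-time), all else 0).  Convergence is declared on the
affine-invariant Newton decrement (tolerance 1e−8) — column scales of an
unscaled cubic basis span several orders of magnitude, which an absolute
gradient norm would mishandle.  The observed information is
`Σ w exp(z'θ) z z'` evaluated with the same quadrature nodes; its inverse
at the optimum is the coefficient covariance, and 95% intervals are Wald
intervals on the coefficient scale, exponentiated for rates and ratios.

## Poisson comparator

Splitting follow-up into short intervals and treating the event count in
each as Poisson with mean `person-time × h(midpoint)` gives a likelihood
equivalent to the rate model's.  `PoissonTimeSplit` splits episodes on a
fixed-width grid (default two days, converted at 365.24 days/year),
evaluates all time-scale columns at interval midpoints, and maximises the
Poisson likelihood with the identical Newton core.  The grid is anchored
at multiples of the width on the reference scale — the behaviour of
standard splitting tools — with the partial first and last intervals
kept, so person-time and event counts are conserved exactly
(entry-anchored splitting is available via `anchor="entry"`; on the
breast-cancer cohort the two differ by under 2e−4 per coefficient).
Knots come from the *unsplit* episodes, so both fits use the same basis.
Two-day splits of cohort data reach tens of millions of rows; the fitter
streams the split in chunks of episodes, accumulating score and
information without materialising the design, and accepts a warm start
(e.g. the quadrature fit's coefficients) — a run-time convenience only,
since the concave likelihood has a unique maximum.  As the width shrinks
the piecewise-constant bias vanishes: at two days the two routes agree to
|Δ| ≤ 0.01 per coefficient and within 2% on standard errors; at one month
they visibly drift.

## Predictions

Rates (per 1000 person-years) and rate ratios exponentiate the linear
predictor; their intervals use the delta method on the log scale, which
is exact in form here because the gradient is the design row itself.
Under proportional hazards the gated-versus-ungated rate ratio depends
only on the secondary-scale value, `RR(t2) = exp(jump + s0(t2))`; with
all-positive knots every spline column vanishes at `t2 = 0`, so
`RR(0) = exp(jump)`.  Requesting this ratio from a non-proportional
specification is an error, with hazard predictions at explicit time pairs
as the suggested alternative.

Survival along a piecewise-constant covariate path is
`S(t) = exp(−∫_0^t h)`, accumulated between path change-points and
spline-knot crossings with the same quadrature; the hazard jumps at a
gate flip but `S` stays continuous.  Non-monotone numerical output raises
an error rather than being clipped.  "Survival since the intermediate
event" is the conditional ratio `S(r+Δ)/S(r)` along a path whose gate
flips at `r` — because the pre-`r` hazard cancels, this equals the pure
post-transition survival started at `r`, so the two candidate readings of
that phrase coincide.  Published cross-sectional summaries of this
quantity index it by the *evaluation* time `r + Δ` ("Δ-year survival
since the event at x years of follow-up" means the event occurred at
`x − Δ`); the prediction API takes `r` explicitly, so either indexing is
available.

Survival intervals use the bias-corrected percentile bootstrap
(B = 1000 by default), resampling whole subjects so all episodes of a
subject move together; resampled subjects receive fresh ids.  The
bias-correction factor `z0` comes from the fraction of replicates below
the point estimate; endpoints are the `Φ(2z0 ± 1.96)` percentiles.  The
jackknife acceleration term (full BCa) is available via
`accelerated=True` but off by default, matching the plain bias-corrected
method; replicates on which the statistic fails are dropped with a
warning, and more than 5% failures abort.  Delta-method intervals for
survival are deliberately not provided — bootstrap only.

## Synthetic cohorts

Two generators define the validation conditions; their defaults are the
study conditions, not tuning knobs.

**Illness-death** (`simulate_tvc_cohort`, default n = 3000, censoring at
10 years): pre-event mortality is a power-of-time hazard
(`log h = −4.93 + 0.2·log t1` plus 0.02 per year of age over 50 and 0.32
for treatment, prevalence 1/3), calibrated to a crude mortality around
10/1000 person-years before transition.  The intermediate event follows
a decreasing Weibull hazard (shape 0.65, scale 18), giving roughly half
the cohort an event within follow-up and a median time to it near 2.4
years.  The transition multiplies mortality by `exp(3.19 + s(t2))` with
`s(t2) = 1.05(1−e^{−t2/1.5}) − 0.09·t2` — a rate ratio in the twenties at
transition, rising above forty and then declining.  Event times invert
the path cumulative hazard: analytically where closed forms exist
(Weibull, power, Gompertz), otherwise by vectorised bisection on the
quadrature-evaluated integral (`invert_survival` exposes the scalar
bracketed-root version, tolerance 1e−10).

**Matched cohort** (`simulate_matched_cohort`, default n_cases = 5000):
diagnosis ages Normal(70, 10) truncated to [40, 92], half the sets
female, four comparators per case sharing age and sex; everyone enters 30
days after diagnosis (delayed entry on the attained-age scale) and is
censored 10 years after it.  Background mortality is Gompertz in attained
age (39/1000 at 70, +9.5%/year), with −0.33 for women; exposure
multiplies it by `exp(1.56 + v(t2))`, `v(t2) = −0.64(1−e^{−t2/0.8})`, an
early excess settling to a long-run ratio near 2.5.

All draws come from one seeded generator per cohort, so outputs are
bit-reproducible from the seed.  What these cohorts do *not* emulate:
real registry confounding, matching on calendar time with period effects,
informative censoring, or covariate measurement error — passing recovery
tests here demonstrates correctness of the estimator, not robustness to
those features.  One known approximation: the true secondary-scale
effects are smooth saturating curves, not splines, so the fitted jump
coefficient (the log rate ratio at the scale origin) carries a small
spline-extrapolation bias below the first knot — about two standard
errors at n_cases = 5000 for the matched defaults — which shrinks with
more knots, not with more data.

## Numerical and design choices

* Times are stored in years; day-denominated inputs convert at 365.24
  days/year.
* An intermediate event recorded at the exact exit time yields no gated
  risk time; the episode stays ungated (no interior split point).  The
  Rotterdam loader instead backdates such transitions by one day, so a
  death on the relapse date is attributed to the post-relapse state —
  the convention the published analysis used.
* The published coefficient table anchors the log-time linear column at
  its upper boundary knot; this re-parameterisation moves only the
  intercept (by `γ1·k_K`).  The package keeps the plain `v1 = ln t`
  column; comparisons with the table transform the intercept
  accordingly.
* The Rotterdam example data is rebuilt from the R `survival` package's
  copy of the cohort: censoring at 10 years, and the 43 subjects with a
  recorded death beyond their disease-free follow-up censored at the
  disease-free time.  Deaths, relapse counts and the median time to
  relapse match the published descriptives exactly; total person-years
  differ by 2.5 in ~20,000 (unit rounding in the original analysis
  file), which is the precision floor for coefficient reproduction
  (~0.01 on two of twenty-eight coefficients).
* Degenerate inputs: no events, zero-length episodes, gates outside
  {0,1}, gated scale values non-positive at exit, non-monotone survival,
  singular information (too many knots) — all raise errors naming the
  offending scale or rows rather than proceeding.
* Test problem sizes (cohorts of 400–6000 subjects, 5000 matched cases,
  bootstrap B a few hundred) were chosen to hold Monte-Carlo error well
  below the tolerances they are tested at.

## Limitations

Interactions *between* time-scales are not implemented (no contract for
them is defined here); penalised or B-spline bases, frailty terms, and
the log-cumulative-hazard parameterisation are out of scope.  Knot
placement is the usual flexible-parametric weak point: estimates are
robust to reasonable choices, but a gated scale with very few events can
place boundary knots badly — the error messages say which scale to
simplify.
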