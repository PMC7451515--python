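# Methods

## Scope and data model

One observation is a flask of *Corylus avellana* cell suspension culture
elicited with one fungal elicitor type (CE, CF or CW) at a dose in % v/v
(0 = vehicle control), with or without methyl-β-cyclodextrin (MBCD, mM),
elicited on a given culture day and harvested on a later day, with
paclitaxel measured in µg l⁻¹. Models are fitted per elicitor type on the
four numeric inputs (dose, MBCD, adding day, harvest day); the table
format deliberately carries a single total-paclitaxel response rather
than separate intracellular/extracellular channels. Times are stored on
the culture-day scale; conversion to "h and min after elicitation"
(`elapsed_after_elicitation`) multiplies elapsed days by 24 and rounds
the total to the nearest minute, which is the convention used when
reporting optimal harvest times.

Data are split 75/25 into training and testing subsets by a uniform
unstratified permutation; the training count is `round(0.75·n)` with
ties to even, so a fixed seed fixes the split exactly.

## Synthetic ground truth

The generator reproduces the factorial randomized-complete-block design:
doses {0, 1, 2.5, 5, 10} % v/v, MBCD {0, 50} mM, elicitation at mid
(day 13) or late (day 17) log phase, harvests every 2 days after
elicitation until day 23, three blocks — 240 rows per elicitor. The
response surface multiplies a dose bell and an elapsed-time bell
(generalized-bell kernels, the same functional family as the fuzzy
memberships, though the fitted network never sees their parameters) with
linear MBCD-synergy and adding-day multipliers:

    y = β₀ + A·B(conc; c*, a_c, b_c)·B(Δt; τ*, a_t, b_t)
          ·(1 + s·MBCD/50)·(1 + δ·(adding − 13)/4)

Defaults β₀ = 30, A = 300, c* = 3 % v/v (a_c = 2.5, b_c = 1.5), τ* = 6 d
(a_t = 3, b_t = 2), s = 0.6, δ = 0.15 place the true optimum at an
interior dose and elapsed time and on the boundary for MBCD (50 mM) and
adding day (17), the pattern typical of reported elicitation optima. The
noiseless maximum is 582 µg l⁻¹ at (3, 50, 17, harvest 23). Noise is a
shared Normal(0, 5²) block effect plus i.i.d. Normal(0, 15²) residuals,
truncated at zero because responses are concentrations (truncation, not
resampling — a concentration measurement below noise floor reads ~0).

What the generator does *not* emulate: measurement heteroscedasticity,
elicitor-type-specific surface shapes, culture-age drift beyond the
linear adding-day term, or any mechanistic taxane kinetics. Passing the
recovery tests therefore shows the pipeline is correct and calibrated on
a realistic design geometry and noise scale, not that the fitted surface
transfers to any particular wet-lab system.

Two oracles come with the surface: a chunked brute-force grid maximizer
(`true_optimum`) and the mean main-effect range per input
(`oracle_partial_effect_ranges`, the average over a grid of the other
inputs of the response range as one input sweeps its bounds). On the
default surface the main-effect ranking is dose > harvest time > MBCD >
adding day; the sensitivity analysis is checked against this ranking
rather than against any externally asserted ordering.

## ANFIS

Grid partition with (default) two membership functions per input — 16
rules and 80 consequent parameters for d = 4, comfortably below the 180
training rows of the default design. The default membership is the
generalized bell 1/(1 + |(x−c)/a|^(2b)); a Gaussian option exists. Bell
memberships are strictly positive, so rule firing never vanishes and the
normalization layer is always well defined.

Inputs are min–max scaled to [0, 1] from the training ranges and the
response is centered and scaled by its training SD; all public
predictions are back on original scales. Premise initialization spreads
centers evenly over [0, 1] with width a = half the center spacing and
shape b = 2.

Hybrid learning per epoch: (1) exact linear least squares for all
consequents given the premises, on the stacked regressors w̄_k·(x, 1),
with a ridge of 1e-8 guarding rank deficiency from weakly firing rules
(set `ridge=0` for the exact solve — the ridge leaves a ~1e-5-scale bias
that matters only to exact-recovery checks); (2) one full-batch gradient
step on the premises with analytic gradients (validated against central
finite differences to 1e-7). The step is `learning_rate` × the
per-observation average gradient (dSSE/n), so step sizes do not scale
with the dataset; widths and shapes are clipped at 1e-6 to stay
positive. Defaults: 100 epochs, learning rate 0.01. The returned model is
the best (premises, consequents) snapshot over the trajectory, which
guarantees the final training RMSE never exceeds the initial one even if
a late gradient step overshoots; the full per-epoch RMSE history is kept.

Degenerate inputs: a constant input column gets unit normalization width
(memberships then see a constant and the consequents absorb it); a
constant response trains to an exact constant model.

## Regression baselines

MLR and OLSR are the same ordinary-least-squares estimator reported under
two names (their comparison-table rows are identical by construction).
Stepwise uses bidirectional p-value search, α_enter = 0.05 <
α_remove = 0.10, which terminates without cycling; an empty selection
returns the intercept-only model. PCR standardizes columns, regresses on
the top-k principal components and back-transforms; its default k is the
smallest explaining ≥95 % of predictor variance. PLSR wraps the NIPALS
implementation of scikit-learn; its default k minimizes leave-one-out
RMSE. All baselines are main-effects-only on the raw input columns — the
point of the comparison is precisely that main-effects linear models
cannot represent a curved dose–time surface.

## Genetic algorithm

Real-valued chromosomes (conc, MBCD, adding day, elapsed days); the
elapsed-time parameterization makes harvest > adding structural.
Roulette selection on min-shifted fitness f − min(f) + ε (ε = 1e-9 ×
range; uniform when all fitness is equal), two-point crossover with
interior cut points (the only admissible segment for d = 2 is the second
gene), per-coordinate uniform-redraw mutation, elitism 1 (monotone
best-so-far history), fixed generation count. The generation loop is
vectorized but distribution-identical to the scalar operators it exposes.

**Extrapolation guard.** The default search box (adding ∈ [13, 17],
Δt ∈ [2, 10] d) admits harvest days up to 27 while the harvest schedule
stops at day 23. A surrogate has no support beyond the last observed
harvest, and an unconstrained search reliably chases the extrapolated
tail (recovered Δt drifts to ~8.5 d instead of 6). `optimize_model`
therefore accepts `max_harvest_day` — the pipeline passes the last
observed harvest day — and evaluates over-late candidates at that cap,
so the reported optimum always lies inside the data region. This is a
deliberate design choice: optimizing a surrogate outside its training
support is not a meaningful recommendation for a follow-up experiment.

## Sensitivity analysis

VSE of input j is the model RMSE "without" that input; VSR divides by
the full-model RMSE. Two readings of "without" are provided:
`retrain_excluded` (default) retrains on the remaining columns —
an input whose information is duplicated elsewhere correctly scores
VSR ≈ 1 — and `mean_substitute` freezes the column at its training mean
in the full model, which is cheaper but conflates importance with
redundancy. VSE is evaluated on the training subset by default
(configurable), and an irrelevant noise input lands in a narrow band
around VSR = 1 (empirically ≈ 1.06–1.18 over 20 seeds at n = 150).

## Problem sizes and runtime

Default runs use the 240-row design per elicitor (180 training rows), a
16-rule network trained for 100 epochs (~0.2 s), GA with 200 × 1000
evaluations of the vectorized forward pass (~1 s), and sensitivity with
five retrainings per elicitor. The full pipeline for one elicitor
completes in a few seconds; the whole test suite in about half a minute.

## Known limitations

* The fuzzy network's premise training is plain gradient descent; no
  line search or adaptive steps. The best-snapshot rule makes it safe,
  not fast.
* MBCD is binary in the default design, so the surrogate's behaviour at
  intermediate MBCD levels is pure interpolation between two arms.
* With two membership functions per input the network captures one
  curvature per axis; sharper multi-modal surfaces need
  `mfs_per_input=3+` and correspondingly more data.
* Stepwise selection at α = 0.05 admits a spurious column in roughly one
  run in seven when three null candidates are available — inherent to
  p-value stepwise, not a defect of the implementation.
* The "Pr > F" for the fuzzy network is the observed-vs-predicted
  regression F-test; for linear models this coincides with the usual
  overall F-test, for the network it is a reporting convention.
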