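# Methods

This note records the measurement conventions, model choices and synthetic
data assumptions behind `volscroll`, and what the test suite does and does
not establish.

## Display-state model of a scroll log

A viewer logfile is an ordered stream of time-stamped events; display
events carry the viewing axis and a 1-based slice index. The displayed
(axis, slice) at time `t` is that of the latest display event at or before
`t`, holding until the next display event or until the question is left
(`question_end_ms`). Time intervals are half-open `[t, t′)` with the final
interval closed at the question end, so interval durations add up to the
total question time exactly. Normalization shifts times so the first event
sits at 0 and, among display events sharing a timestamp, keeps the last
(display state is single-valued); it is idempotent. Pan/zoom/window-level
events (`event_kind=other`) are parsed and preserved but carry no slice
semantics; every metric is invariant to them by construction and by
metamorphic test.

## Run segmentation

Runs are defined per *episode* — a maximal single-axis stretch of the
trajectory — because slice-number differences across axes are meaningless.
Within an episode, repeated slice values collapse to the plateau's first
timestamp before reversal detection, so sampled piecewise-constant logs
yield no spurious extrema. The first and last distinct displayed positions
are extrema; interior extrema are direction reversals. Run *k* spans
consecutive extrema and lasts from the timestamp of extremum *k* to that
of extremum *k+1*; consecutive runs therefore share boundary instants and
tile the episode. Trailing dwell after the last extremum, and fully
stationary episodes, are emitted as zero-span stationary runs — never full
runs — which makes run durations sum to `question_end_ms` exactly
(conservation is asserted on random trajectories).

A run is **full** when its slice span strictly exceeds half the slice
count of *its own axis* (`Δ > 0.5·N`): a span of exactly half the stack is
not a full run. For multi-axis questions the threshold is evaluated
per-axis; the alternative (always thresholding on the axial count) would
make cross-axis spans incommensurable and is not offered.

## Relevant-area timing

Relevance is evaluated only on the currently displayed axis: each
piecewise-constant display interval accrues to relevant time iff the
displayed slice lies in a relevant interval of the displayed axis, and an
axis with an empty interval list contributes only irrelevant time.
Per-axis interval lists are required inputs (how an expert-marked axial
region projects onto sagittal/coronal indices is study metadata, not
something the package can derive). The relevant volume fraction used by
question selection is computed on a reference axis, axial by default since
that is the viewer's default direction.

## Cohort assembly

Question selection keeps items that (1) concern a single CT scan,
(2) require a diagnosis and (3) have a relevant volume fraction strictly
below 0.5 (focal disease); unevaluable items are flagged, never silently
dropped. Training time uses whole-day date arithmetic and stays continuous
everywhere except in explicitly illustrative binned tables. Aggregation to
resident × test rows takes unweighted means of the scroll percentages over
available questions (a missing logfile simply removes that question — 
missing listwise), while the accuracy counts `n_correct`/`n_questions`
skip formats in `exclude_formats` (marker questions by default, because
their relevance–accuracy coupling differs qualitatively from the
choice-based formats); the scroll averages deliberately keep all formats
so both variants of the published analysis are reproducible. Test
difficulty is the mean item P value of the selected questions minus 0.5.

## Models

Both ladders use full maximum likelihood so deviances of nested rungs are
comparable; forward selection uses likelihood-ratio tests at α = .05 with
ties resolved toward the simpler model.

*Linear ladder* (scroll outcomes): unconditional means → `+TrTime` →
`+DRPTdiff` → `+random TrTime slope`, occasions within residents, fitted
with statsmodels `MixedLM`. The random slope rung uses an unstructured
2×2 covariance (the intercept–slope covariance is freely estimated).
Optimization tries Powell first and BFGS as a backstop, keeping the better
log-likelihood: BFGS stalls when the random-intercept variance sits near
its boundary, which the relevant-area outcome (small σ²u0 relative to σ²e)
routinely produces. Fixed-effect standard errors are cluster-robust
(sandwich) by resident,
`cov(β̂) = A⁻¹(Σⱼ sⱼsⱼᵀ)A⁻¹` with `A = Σⱼ XⱼᵀVⱼ⁻¹Xⱼ` and
`sⱼ = XⱼᵀVⱼ⁻¹(yⱼ − Xⱼβ̂)`, guarding against mild level-1 non-normality;
on clean homoscedastic simulations they agree with model-based standard
errors within sampling error (tested). The effect size is the level-1
explained variance against the unconditional means model, floored at 0.

*Binomial ladder* (accuracy): `n_correct` of `n_questions` per occasion
with a logit link and a Gaussian resident random intercept — level-1
variance fixed by the binomial assumption. The likelihood is integrated by
adaptive Gauss–Hermite quadrature with 20 nodes: the integrand is
re-centred at its per-cluster mode (Newton, vectorized across clusters)
and scaled by the curvature there. On a seed-fixed synthetic cohort the
implementation matches `lme4::glmer(..., nAGQ = 20)` to about five decimal
places in coefficients, standard errors and the variance component (the
frozen oracle test), and fitting aggregated binomial rows equals fitting
exploded Bernoulli rows (sufficiency test). Runaway coefficients
(|b| > 15, i.e. separation or degenerate outcomes) flag the fit as
non-converged and exclude it from selection. The ladder adds `TrTime`,
then `DRPTdiff` and the two scroll averages; a random-slope rung for the
binomial model would need two-dimensional quadrature and is out of scope —
the reported best accuracy model has a random intercept only.

Marginal effects are reported as `b·Δ` on the linear outcome scale and as
`OR^Δ` on the odds scale.

## Synthetic data

The generator exists so every stage is testable without the (non-public)
progress-test logs; it emulates the study conditions, not individual
behaviour.

*Trajectories.* A question log is synthesized as (i) one or two initial
full sweeps through the whole stack whose total duration matches the
full-run target, (ii) an oscillation confined to the relevant interval
sized so total relevant dwell (including the sweeps' pass through the
region) matches the relevance target, and (iii) remaining dwell on
irrelevant slices, placed last so the persisting tail state is irrelevant.
Oscillations are anchored at the interval end nearest the previous
segment's slices, with their span capped so the approach movement merged
with the first oscillation leg never exceeds half the stack — otherwise
segment transitions would manufacture spurious full runs. Infeasible
target pairs (e.g. full-run time whose pass-through alone exceeds the
relevance target's complement) raise an explicit error. Synthesis is exact
up to event quantization; the pipeline recovers zero-noise targets within
~2 percent points, and the discrepancy shrinks as noise does (tested).
Defaults: 60-slice axial stacks, a 122.9 s mean question time, a 30 ms
minimum per-slice step. What this does *not* model: saccade-level timing,
pan/zoom behaviour, axis switching mid-question, or any dependence of
trajectory shape on question content — so passing tests certify the
measurement pipeline, not behavioural realism.

*Cohorts.* Resident × test records are drawn from the published two-level
models: per-resident random intercepts, Gaussian occasion residuals for
the scroll outcomes, and binomial accuracy whose linear predictor includes
the simulated scroll averages. Default fixed effects and variance
components are the published Model 2 estimates for each outcome. The study
calendar is fixed: nine semi-annual tests from September 2013 to April
2018 with the failed autumn-2015 test absent. Enrolment dates are uniform
over a window wide enough that relative training time spans (0, 5];
calendar durations are uniform on 5–6.5 years (part-time pace), and each
eligible resident sits a given test with probability 0.86, reproducing the
unbalanced panel (1–9 tests per resident, mean ≈ 4.1, roughly 300
participants per test). Test difficulty is Normal(0.14, 0.07) truncated to
[0.02, 0.24]; questions per test are 2 + Binomial(7, 3/7), giving mean 5
on the observed 2–9 range. Gaussian outcome draws are left untruncated:
the generating linear model does not respect percentage bounds, and
truncation would bias slope recovery; pipeline-derived records always lie
in [0, 100], and the bounds are enforced there.

*Micro-cohorts* compose the two levels: each macro record's scroll
averages become per-question trajectory targets (question-level jitter,
sd 4 percent points by default, clipped to the question's feasible range),
each question gets one focal relevant interval covering 10–35% of its
stack, and item correctness is Bernoulli under the accuracy model. The
whole fixture can be written to disk in the package's table and logfile
dialects.

## Numerical and reporting conventions

Times are integer milliseconds; slice indices 1-based inclusive;
percentages are kept at full precision internally and rounded only at
reporting boundaries. Scatter trend lines are ordinary least squares with
the slope annotated to two decimals — a visual aid, not inference. All
simulation entry points take explicit seeds and are bit-reproducible given
one.

## Problem sizes used in the checks

Parameter-recovery checks use twenty replicates of 650-resident cohorts
(the study's analysable cohort size); the end-to-end sign-recovery check
uses twenty micro-cohorts of 120 residents with 20 s mean question time,
large enough that both generating slope signs are recovered with high
probability per replicate. The level-1 R² comparison is deliberately loose
(order-of-magnitude bands plus the ordering between outcomes): the
published R² values depend on the study's within-resident training-time
dispersion, which is reported only as a binned histogram, and the
generator's panel reproduces it only approximately.

## Known limitations

* The logfile dialect is a reconstruction of the information content the
  study describes; the original viewer's raw schema is unpublished.
* Whether total question time should include revisits after navigating
  away and back is undocumented; logs are treated as one visit (the sum of
  all display episodes in the file).
* Heterogeneous level-1 variance (modelling σ²e as a function of training
  time) is a documented non-goal, as is any three-level model with items
  as the lowest level — the unbalanced wave structure confounds
  within- and between-resident comparisons at that level.
* No DICOM or pixel handling: stack geometry is metadata only.
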