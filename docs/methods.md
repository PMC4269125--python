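# Methods

## Task environment

The task is a two-stage Markov decision problem. Stage-1 action *a* leads to
stage-2 state `common(a)` with probability `p_common = 0.70` and to the other
state otherwise; the action→common-state map is the identity and fixed for
the session. Each of the four stage-2 (state, action) pairs pays a 0.20 EUR
reward with probability following an independent Gaussian random walk,
reflecting at 0.25 and 0.75. Reflection is implemented as fold-back
(v < lo → 2·lo − v, v > hi → 2·hi − v, re-applied until interior), the
standard construction for a reflecting boundary.

Two walk parameters are not published for this variant of the task and are
package defaults, both configurable: the per-trial step s.d.
(`walk_sd = 0.025`, matching the slow drift of the original paradigm) and
the session length (`n_trials = 201`). Walk starting points are drawn
uniformly inside the reflecting interval. An externally supplied probability
sequence can be loaded from CSV (`walks_from_csv`) when the original
sequence is available. Fifty practice trials are part of the task protocol
but excluded from every analysis; the monetary payout is one third of
winnings clamped to [3, 10] EUR.

## Agent

The hybrid agent holds a shared stage-2 value table `q2` (2×2) and stage-1
model-free values `q_mf` (2). After each trial:

    δ₁ = q2(s₂,a₂) − q_mf(a₁);  q_mf(a₁) += α₁·δ₁
    δ₂ = r − q2(s₂,a₂);         q2(s₂,a₂) += α₂·δ₂
    q_mf(a₁) += α₁·λ·δ₂

Model-based stage-1 values are computed on the fly from the *true* transition
probabilities (participants are instructed about the transition structure,
so no transition learning is modelled):

    Q_MB(a) = p_common·max_a' q2(common(a),a') + (1−p_common)·max_a' q2(rare(a),a')

Stage-1 choice is softmax over `β₁·[ω·Q_MB + (1−ω)·q_mf]` plus a
perseveration bonus `p` on the previous stage-1 action only (first-order
perseveration); stage 2 is softmax over `β₂·q2(s₂,·)`.

Design choices where the literature leaves freedom: Q-values initialise at
0.5 (the midpoint of the reward-probability band, unbiased for rewards
bounded in [0.25, 0.75]); no forgetting/decay of unchosen options; stage-2
model-free and model-based values coincide (the planner's leaves are the
learned `q2`). All three are the conventional choices for this model family.

The likelihood of an observed log replays the updates on the observed
sequence and accumulates the log softmax probabilities of the chosen actions
at both stages. `negloglik` accepts pre-unzipped arrays and runs in pure
scalar arithmetic (~0.2 ms per 201-trial evaluation), which keeps the
hierarchical fit tractable without compiled extensions.

## Hierarchical estimation

Parameters are fitted on an unconstrained scale — log for β₁, β₂, logit for
α₁, α₂, λ, ω, identity for p — under an independent Gaussian population
prior per transformed parameter (a diagonal covariance; the correlation
structure of the population is not estimated). Per subject, the penalised
objective `negloglik(θ) + ½‖(θ−μ)/σ‖²` is minimised by L-BFGS-B from
multiple seeded starts (default 10: the prior mean plus perturbations of
half a prior s.d.) inside a generous box on the unconstrained scale
(log β ∈ [−8, 8], logits ∈ [−12, 12], p ∈ [−20, 20]) that prevents overflow
in flat directions and is non-binding for plausible subjects. The Laplace
covariance is the inverse of a central finite-difference Hessian
(step 1e-4), repaired to positive-definite by flooring eigenvalues at 1e-6.

EM alternates these MAP fits (E-step) with moment updates
`μ_k = mean(θ̂_ik)`, `σ_k² = mean(θ̂_ik² + Σ_ikk) − μ_k²` (M-step), flooring
σ at 1e-3 against collapse, stopping when `max|Δμ| < tol` (default 1e-2) or
`max_iter`. After the first iteration each subject warm-starts from its
previous MAP plus one fresh prior-mean start, which cuts runtime several-fold
at no measurable cost in the optima found (50-start checks find the same
optima as 10-start ones). A per-subject Laplace evidence
(−objective − Σ log σ + ½ log det Σ) is available as a convergence
diagnostic and is non-decreasing across iterations up to approximation
slack.

Population summaries report both conventions — across-subject mean/SD of the
MAPs on the model scale, and the fitted prior (μ, σ) on the unconstrained
scale — because group tables in this literature mix the two. Note that a
between-subject SD of 0.80 for ω is only possible on the unconstrained
scale (a [0,1]-bounded variable with mean 0.49 cannot have SD 0.8), which is
why the synthetic generator interprets published SDs as unconstrained-scale
quantities.

## Stay-probability analysis

From trial 2 onward, `stay = 1{a₁(t) = a₁(t−1)}` is modelled on the previous
trial's reward (±0.5), transition (±0.5) and their product. The full
mixed-effects logistic model with maximal random effects is replaced by a
two-stage summary-statistics procedure: per-subject penalised
maximum-likelihood logistic fits (Newton solver; ridge 0.1 on the three
slopes, never the intercept, guaranteeing finite coefficients under the
complete separation that single-subject factorial designs produce), followed
by group-level one-sample t-tests and, for ability moderation, OLS
regressions of each per-subject coefficient on the z-scored ability score
(plus its square when a quadratic term is requested; non-significant
quadratic terms can be dropped, mirroring the stepwise simplification used
in this literature). Coefficients from this procedure are comparable to
mixed-effects estimates in sign and pattern, not numerically. Posterior
simulation intervals are replaced by t-based intervals.

Simple indices are computed from the 2×2 stay table: the model-free index
`P(stay|rewarded) − P(stay|unrewarded)`, the model-based index
`rewarded-common − rewarded-rare − unrewarded-common + unrewarded-rare`,
and `w_repeat = interaction − reward` as a relative preference score.
Missing cells make the indices NaN rather than silently imputing.

FDR correction is Benjamini–Hochberg (statsmodels' step-up implementation
behind the package's `fdr_adjust` surface), applied over the family of 10
moderation tests (5 measures × linear/quadratic). Median/tertile splits are
rank-based with stable tie-breaking.

## Ability statistics

Pearson correlations carry Fisher-z intervals `tanh(atanh r ± z*/√(n−3))`
and t-test p-values; partial correlation correlates OLS residuals with the
degrees of freedom reduced by the number of controls. The processing-speed ×
working-memory analysis median-splits the span score and regresses the
unconstrained (logit-scale) weight on z(DSST) × group, reporting the
interaction, R², and within-group simple slopes, optionally with the other
ability scores as covariates and/or HC3 robust standard errors. Analyses of
ω are on the unconstrained scale throughout, consistent with the Gaussian
assumptions of the fitting procedure.

The a-priori power computation draws bivariate-normal samples and applies
the exact two-sided Pearson rejection threshold
`|r| > t*/√(df + t*²)`, vectorised over replications. The design-relevant
numbers: r = 0.45 gives ≈71% power at n = 29 and ≈66% at n = 27 — the
recruited/analysed distinction matters by about five points, so both sample
sizes are exposed as parameters.

## Synthetic cohorts

The generator emulates the study conditions: 27 subjects × 201 trials by
default, all subjects facing one shared reward-probability sequence (as in
the study; per-subject walks are available for robustness checks).

Ability scores come from a Gaussian copula with the published pairwise
correlations, each marginal moment-matched: the latent mean/SD are solved
numerically so the *clipped* (range-truncated) variable hits the published
mean/SD, and the latent correlations are inflated by per-measure attenuation
factors (computed by Gauss–Hermite quadrature, accounting for clipping and
integer rounding) so the observed correlations land on target. Scores are
rounded where the instrument is integer-valued (DSST, digit span, MWT).
Only the published moments, ranges and pairwise correlations are honoured —
the instruments' true distributions (skews, floors, discreteness of
TMT times) are unknown and not emulated, so passing tests show the analyses
behave correctly under the assumed Gaussian-copula structure, not that they
are robust to real psychometric distributions.

Agent parameters are Gaussian on the unconstrained scale at the published
population estimates (means on the model scale, SDs unconstrained, see
above). The model-based weight is linked to processing speed:
`ω' = μ + σ(c_g·z(DSST) + √(1−c²(1+m²))·ε)` with `c = linkage_r = 0.42`
(the published correlation) and `c_g = c(1±m)` by working-memory median
split. The moderation strength `m = 0.8` (slope ratio 9:1 between subgroups)
is a one-time choice mirroring the strong published subgroup asymmetry; with
balanced groups the construction gives corr(DSST, ω') = c exactly and leaves
the marginal variance of ω' untouched.

A consequence worth knowing: the linkage is set at the *parameter* level.
Between-subject heterogeneity of the other six parameters plus single-subject
estimation noise attenuate it to corr(DSST, b_interaction) ≈ 0.16 at the
stay-coefficient level, so per-cohort significance of the moderation at
n = 27 is weak (~12% power) even though the pooled effect across cohorts is
decisively positive. The test suite asserts the pooled effect; the null
calibration (linkage 0) stays within its 10% false-positive budget.

## Parameter recovery

`parameter_recovery` simulates a cohort, refits it hierarchically, and
reports per-parameter correlation and bias between true and recovered
values. At the default conditions (30 subjects × 201 trials, published
population moments) recovery of ω is data-limited: across pilot cohorts the
true-vs-MAP correlation ranges roughly 0.4–0.8 (median ≈ 0.6), while the
recovered population mean of ω stays within ±0.07 of truth. Fifty-start
optimisation finds the same optima as ten-start, so the ceiling is the
information in 201 trials, not the optimiser. Problem sizes in the test
suite (30 subjects, 6 EM iterations, 8 starts) are the package's chosen
desk-scale defaults.

## Numerical notes

- Softmax log-probabilities use the stable `log(1+exp(d))` form with a
  cutoff at d = 35.
- The per-subject logistic Newton solver adds 1e-10 to the Hessian diagonal
  and stops at step-size 1e-10; with ridge 0 a constant-outcome design
  raises instead of diverging.
- Degenerate Fisher intervals (|r| ≥ 1 − 1e-12) return [±1, ±1]; partial
  correlation of a variable fully explained by its controls is defined as 0
  with p = 1.
- All randomness flows from `numpy` `SeedSequence` spawning, making cohorts
  bit-reproducible from (config, seed); generated artifacts embed the seed
  and a config hash.

## Known limitations

- No response-time modelling, no transition learning, no alternative
  arbitration schemes (uncertainty- or value-of-information-based).
- The two-stage stay analysis trades the efficiency of a joint GLMM for
  robustness and transparency; its coefficients are not numerically
  comparable to mixed-effects estimates.
- Synthetic ability scores reproduce moments and pairwise correlations only;
  higher-order joint structure of real psychometric data is not represented.
- ω recovery at 201 trials is intrinsically noisy at the single-subject
  level; population-level quantities are recovered much more tightly.
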