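# Methods

`mslrl` implements the computational core of a developmental multisensory
learning paradigm: two probabilistic association-learning tasks, an
information-theoretic surprise model of their statistical structure, and a
reinforcement-learning drift-diffusion model (RLDDM) of choice and reaction
time, together with the machinery to fit, select, and validate these models
and to export trial-wise fMRI regressors.

## Task structure

**Discriminative choice.** 4 auditory/tactile × 4 visual stimuli, 44 trials
per run. Each trial shows two visual symbols with one sound/vibration; the
participant picks the matching side. Sound *i* matches visual *i* and the
matching symbol is always on screen, so only the identity of the
*non-matching* symbol carries statistical structure: per sound, the three
non-matching partners appear on 7, 3 and 1 of its 11 trials (63.6%, 27.3%,
9.1%) in a cyclic arrangement across sounds. Every sound occurs on 11
trials; every visual is on screen 22 times.

**Match recognition.** 3 × 3 stimuli, 42 trials. One symbol is shown with a
sound/vibration and the participant judges match vs. non-match. Per sound:
7 matching trials (50%), 5 with the frequent non-matching partner (35.7%),
2 with the rare one (14.3%); every stimulus occurs on 14 trials.

Generated runs realize these counts *exactly* for every seed; ordering is a
seeded permutation with the matching side counterbalanced 22/22 in the
discriminative choice task. No ordering constraints (e.g. repetition
limits) are imposed beyond the counts.

**Feedback reversal.** A fraction of trials (0, 5, 10 or 20% per run) has
feedback valence inverted for difficulty calibration; omitted responses
always receive neutral feedback. The reversal count is `round(rate × n)`
(half-up: 0.2 × 44 → 9) and is allocated round-robin over the
auditory/tactile stimuli in random order, so per-stimulus counts differ by
at most 1.

**Timing.** Each trial is ITI → stimulus (2 s) → ISI → feedback (1.8 s
children, 2 s adults). ITI/ISI are gamma distributed (shape fixed at 4)
truncated to the task's printed range, with the scale solved numerically so
the *truncated* mean equals the printed mean (discriminative choice: ITI
1.87 s [0.76–3.45], ISI 3.45 s [2.28–4.83]; match recognition children:
2.05/[0.76–3.45] and 3.28/[2.04–4.90]; adults: 2.06/[0.79–3.39] and
2.67/[1.11–4.34]). Sampling is by inverse CDF restricted to the range, so
the draw count is deterministic. These defaults reproduce the total run
durations of roughly 401 s (discriminative choice), 383 s and 367 s (match
recognition, children/adults).

## Surprise

The probability of the trial-*t* stimulus combination *x* is its
Laplace-smoothed relative frequency over the run so far,
`p(x_t) = (1 + count) / (n + t)`, giving `p = 1/n` on each combination's
first occurrence; surprise is `I_t = −ln p(x_t)` in nats (the base is a
choice; it rescales regressors linearly). The tracked event is the
(sound, visual) pair with n = 9 in match recognition and the unordered
sound-plus-two-visuals triplet with n = 16 in the discriminative choice
task — n = 16 is the sound × visual combination count and is kept as the
convention even though only 12 distinct triplets can occur (a
`n_override` switch allows 12 for sensitivity analyses). A variant tracks
only the non-matching (sound, visual) pair with n = 4, since the matching
symbol is always present and carries no surprise.

## Learning model

Association values V, one per (sound, visual) pair, start at 0.5 and
follow the delta rule `V ← V + η (target − V)` with η ∈ [0, 1]. Four
variants:

| model          | updates                                                      | rates (DC / MR) |
|----------------|--------------------------------------------------------------|-----------------|
| simple         | chosen/presented pair toward the learning signal             | 1 / 1           |
| simple_asym    | as simple, separate rates after positive/negative feedback   | 2 / 2           |
| transfer       | plus non-chosen pair (DC) or all overlapping pairs (MR) toward the complement | 2 / 2 |
| transfer_asym  | transfer with valence-specific rates                         | 4 / 3           |

In the match recognition task the presented pair's learning signal is the
*match evidence* R′ = 1 when feedback confirms the pair is a match
(responded "match" ∧ positive, or "non-match" ∧ negative), else 0; the
asymmetric rate is chosen by the delivered feedback's valence. Transfer
updates move the other pair toward the complement of the signal — this
follows the verbal account (the alternative pair's value is *decreased*
after a confirmed association) rather than a literal same-target update,
and implies that after a correctly rejected non-match the overlapping
pairs move toward 1. Match-recognition transfer fires only after positive
feedback, which is why its asymmetric variant has three rates, not four.
Omissions trigger no update. With η ∈ [0, 1] and binary targets all
values remain in [0, 1].

For the discriminative choice task the two competing pair values are
combined by odds-ratio normalization
`n_c = V_c(1−V_o) / [V_c(1−V_o) + V_o(1−V_c)]` (values clamped to
[1e−6, 1−1e−6] first; outputs sum to 1) and the drift rate is
`v = (n_c − n_o) · vmod` in a fixed left-minus-right frame. Match
recognition uses the raw presented-pair value, `v = (2V − 1) · vmod`, in a
match-minus-nonmatch frame. The drift weight `vmod` is the behavioural
sensitivity to value differences.

## Choice model and likelihood

Choices and RTs follow a two-boundary diffusion `dX = v dt + dW` from
`X(0) = z·a` with absorbing boundaries {0, a}; the starting point is fixed
at z = 0.5 (no response bias) and the non-decision time τ shifts all RTs.
The first-passage density at the lower boundary is the classic series
`f(t|v,a,z) = (π/a²) exp(−vaz − v²t/2) Σ_k k exp(−k²π²t/(2a²)) sin(kπz)`;
the upper boundary follows by (v, z) → (−v, 1−z). Because the large-time
series converges slowly for small t, evaluation switches to the
image-charge small-time expansion whenever it needs fewer terms, with the
term count chosen adaptively for truncation error below 1e−10 — far below
any fitting tolerance. Correctness is established against independent
oracles: total absorption mass = 1 by quadrature (within 1e−4), the
closed-form boundary-split probability, and Euler–Maruyama first-passage
histograms (2×10⁵ paths at dt = 1e−4) within Monte-Carlo error.

A trial's likelihood is the density of `rt − τ` at the observed boundary
(upper = left response / "match"). Responses at or below τ, and
underflowing densities, are floored at 1e−10 so the negative
log-likelihood is finite on the whole bounded parameter box.

## Simulation

The forward simulator composes the pieces generatively: drift from the
current values, an Euler–Maruyama first passage (dt = 1e−3 by default for
speed; the finer dt = 1e−4 is used when the sampler itself is under
test), feedback by correctness and the trial's reversal flag, then the
learning update. Responses slower than the response window — the 2 s
stimulus duration plus the trial's ISI, since feedback follows the ISI —
are omissions with neutral feedback. Cohorts draw per-run parameters from
truncated normal populations whose default means/SDs are the fitted group
statistics of the study the paradigm comes from (e.g. children, match
recognition, audio-visual: η 0.38 (0.33), τ 0.89 (0.44) s, vmod 1.96
(2.26), a 2.48 (0.42)), truncated to η ∈ [0.01, 1], τ ∈ [0.1, 1.5] s,
vmod ∈ [0.1, 20], a ∈ [0.3, 5].

What the generator does *not* emulate: fatigue, lapses, attention drift,
stimulus-complexity effects, and RT–surprise coupling beyond what the
value dynamics induce. Passing recovery tests therefore shows the
estimator works when the model is true; it cannot certify behaviour on
real children's data.

## Fitting and model selection

Each run × variant is fitted independently by maximizing the likelihood
over the free parameters (learning rate(s), vmod, a, τ; z and initial
values fixed) inside η ∈ [0, 1], vmod ∈ [0, 20], a ∈ [0.3, 5],
τ ∈ [0.1, min observed RT − 0.01] s. The optimizer is seeded differential
evolution (Sobol initialization, population ≥ 8 × dimension serving as
parallel restarts, L-BFGS-B polish); refits with the same seed are
bit-identical. Trials excluded from RT analyses (omissions, rt < 200 ms,
beyond 3 SD) contribute no likelihood term but still drive value updates.
Variants are compared per run by BIC = k ln N − 2 ln L̂ with N the number
of likelihood trials; ties go to the simpler model.

Recovery harnesses simulate-and-refit: at 420 trials per fit (10
concatenated runs) the recovered-vs-true correlations exceed 0.9 for all
four parameters over 50 replicates, RMSE shrinks markedly from 42 to 420
trials, and data generated from the simple learner is assigned back to it
by BIC in ~98% of replicates. Identifiability at a single 42-trial run is
substantially weaker (that is a property of the design, not a defect of
the optimizer) and is reported rather than asserted.

## Behavioural analyses and regressors

Trial exclusion is one-pass: omissions and rt < 200 ms are removed, then
the mean ± 3 × sample SD criterion is applied once to the remainder
(iterating or using the population SD are defensible alternatives; the
single pass is the conservative reading). Runs with more than 20%
omissions are excluded outright. Note that the one-pass 3 SD rule can
only ever trigger with ≥ 11 RTs, since the maximum attainable |z| in a
sample of n is (n−1)/√n. Bins are thirds by original trial index
(15/15/14 or 14/14/14) and summarize mean correct-trial RT, accuracy
(correct / non-omitted) and mean |drift|; empty bins are NaN, not zero.
The RT~surprise association is a per-run OLS slope with a one-sample
t-test on slopes across runs — a deliberately simple summary; a mixed
model over the tidy per-trial table is the natural extension and is left
to standard statistics packages.

Regressor export writes BIDS-style `events.tsv` and three-column
(onset, duration, weight) timing files. The surprise modulator covers
*every* stimulus onset (statistical learning is implicit, so behavioural
exclusions do not apply); the prediction-error modulator covers feedback
onsets of clean response trials only, with omissions in a
neutral-feedback nuisance regressor and excluded response trials in an
RT-outlier nuisance regressor — the three sets partition the run. Both
modulators are mean-centred per run, the standard convention for
parametric modulation.

## Numerical choices and limitations

* WFPT series tolerance 1e−10; value clamp 1e−6 before normalization;
  likelihood floor 1e−10.
* Euler–Maruyama first-passage sampling carries O(√dt) discretization
  bias (boundary crossings inside a step are missed); tests and the
  acceptance script use dt = 1e−4 where the sampler is the oracle.
* The reversal rounding/allocation rule and the response deadline are
  package choices where the original task appendix is not available;
  alternatives would change the schedule by at most one trial per
  stimulus.
* Inter-trial variability parameters (sv, sz, st), collapsing bounds,
  hierarchical priors, and group-level mixed models are out of scope.
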