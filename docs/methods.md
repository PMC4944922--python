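# Methods

## The task and its Markov decision process

Each trial of the modelled task plays out a fair lottery paying 20 c on a
win and 0 c on a loss. Before the outcome is shown, the participant chooses
to watch one of two five-card arrays revealed at a constant rate. The
*informative* array's majority colour perfectly predicts the outcome; the
*non-informative* array is colour-random. Watching the informative array
costs `c ∈ {0, 1, 3, 5}` cents, deducted from winnings only on a win, so
the information can never cause a monetary loss — and, crucially, it is
non-instrumental: it cannot change the outcome or its probability, so its
decision-analytic expected value of sample information is zero (or negative
once the cost is counted).

The trial is represented as a finite MDP (`infoseek.task`). States
aggregate card configurations by colour count `(n_revealed, n_black)`;
card order carries no information about the outcome, so this aggregation
is lossless. Each branch therefore holds 21 card states (counts
`0 ≤ b ≤ n ≤ 5`, including the pre-reveal entry state shown during the
choice-information screen) plus shared win/loss terminals, with six
full-array states per branch. Every card draw is Bernoulli(1/2). Posterior
win probabilities in the informative branch are exact binomial tail sums
over the remaining cards; their denominators are powers of two, so all
beliefs (and the belief martingale) are exact in double precision. Rewards
attach to the transition from a full-array state into a terminal outcome;
all other transitions carry zero reward.

Timing: the total choice-to-outcome delay is `(n_cards + 1) × rate` — five
card reveals plus one outcome-reveal interval — reproducing 6 s, 18 s and
30 s at rates 1, 3 and 5 s/card. The root choice state and the 2 s
choice-information screen are not penalised states; the branch entry state
is where each action deterministically lands.

## Valuation models

All models share the MDP and one backward induction (`infoseek.valuation`);
they differ in how a transition into successor `s'` contributes. Values are
in cents; the softmax inverse temperature absorbs the scale.

* **EVI** (expected value of information): the plain Bellman backup
  `R + V(s')`. Closed form: `Q(N) = w/2`, `Q(I) = (w − c)/2` with
  `w = 20` — indifference at zero cost, avoidance at any positive cost.
* **UP** (uncertainty penalty): `R + V(s')·exp(−k·H(s'))` on every card
  reveal, with `H` the binary entropy of the successor's win posterior.
  Time spent in uncertain states shrinks the value passed back; because the
  informative branch's entropy collapses quickly, it is penalised less,
  producing a willingness to pay for non-instrumental information when
  `k > 0` (and an aversion when `k < 0`). `k = 0` reduces to EVI on the
  identical code path. The penalty multiplies only `V(s')`, not the
  transition reward, following the model's defining equation literally;
  outcome states carry zero entropy so the final reward is never
  entropy-discounted anyway. In the non-informative branch all five card
  states sit at maximal entropy, giving the closed form
  `Q(N) = 10·e^(−5k)` used as an independent check.
* **Information bonus**: the additive reparametrisation
  `R + k̂·(H(s) − H(s')) + V(s')` — each card reveal earns a bonus
  proportional to the uncertainty it resolves. The bonus is credited on
  card reveals only, not on the final outcome reveal: the outcome resolves
  the same residual uncertainty in both branches, and crediting it would
  telescope the total bonus to `k̂·H(root)` identically for both actions,
  making the model vacuous. With that convention the undiscounted gap is
  exactly `Q(I) − Q(N) = k̂ − c/2`.

  We note the defining equations of this parametrisation can be read with
  the opposite sign (a bonus for *increasing* entropy); we follow the
  stated interpretation — a positive weight rewards uncertainty reduction.
* **Discounted information bonus**: each reveal's bonus is scaled by
  `γ^(elapsed seconds)`, with elapsed time `n × rate` at the n-th reveal.
  `γ = 1` reproduces the undiscounted model exactly; `γ < 1` makes slowly
  delivered information less valuable, reproducing the direction of the
  information-rate effect (weaker informative preference at 5 s/card than
  at 1 s/card). Only the bonus is discounted, not the monetary reward:
  reward timing is identical for both actions and would cancel. No exact
  functional form for the discounted extension is canonical; this is one
  defensible choice and is labelled as such.

**Oracle.** `enumerate_action_values` recomputes every model's Q-values by
explicit summation over all 32 card sequences with no recursion; the
backward induction agrees with it to 1e−10 across a (model × cost ×
parameter) grid. A third, closed-form layer (`action_values_fast`) is
derived once from the path summaries of the built tree (win-path entropy
sums; per-step expected entropy drops) and is used inside likelihood
evaluation, where the recursion would dominate fitting time; it agrees with
the oracle to 1e−12.

**UP vs information bonus.** The two parametrisations agree on the sign of
the information preference for matched positive weights, but are *not*
related by an exact parameter mapping on this tree: the UP gap
`(20 − c)·h(k) − 10e^(−5k)` is nonlinear in cost (slope `−h(k)`), while the
bonus gap `k̂ − c/2` has fixed slope `−1/2`. They coincide exactly only at
`k = k̂ = 0`. The equivalence is ordinal/qualitative, and we verify it
numerically rather than assume it.

**Non-monotonicity of the UP gap.** `Q(I) − Q(N)` rises with `k` only up to
a peak (k ≈ 0.29 at zero cost, ≈ 0.42 at 5 c) and then declines: a large
enough penalty crushes the informative branch's early uncertain states too.
Monotonicity holds throughout the moderate regime relevant to behaviour and
is property-tested there.

## Choice rule and likelihood

Action values map to an informative-choice probability by a softmax with
inverse temperature `β ≥ 0`, computed overflow-safely from the value
difference, then through a lapse mixture: with probability `ε ∈ [0, 0.5]`
the button press is undirected, bounding predictions in
`[ε/2, 1 − ε/2]`. Because the models are static within a participant ×
condition cell, the data reduce to per-condition sufficient statistics
`(n_i, m_i)` and the likelihood is a product of binomials over the four
cost conditions (twelve cost × rate cells for rate-varying sessions;
rate-unaware models predict identical probabilities across rates of a
cost). The log binomial coefficient is included by default so −LL totals
follow the full binomial density; it is parameter-free and cannot affect
the fit (tested), and a flag removes it for comparison with
implementations that drop it. Missed responses are excluded before
counting; catch trials keep their recorded choice and are counted.
Predicted probabilities of exactly 0 or 1 with discordant counts yield a
−∞ log-likelihood, returned rather than raised.

## Fitting

Per participant the free parameters are `β` (EVI), `(β, k)` (UP),
`(β, k̂)` (bonus) or `(β, k̂, γ)` (discounted); one lapse rate ε is shared
across the cohort. Defaults: bounds `β ∈ [0, 10]`, `k, k̂ ∈ [−2, 2]`,
`ε ∈ [0, 0.5]`, `γ ∈ [0.5, 1]`; 10 optimisation restarts.

Given ε the likelihood separates across participants, so the group
optimum is found by profile likelihood: a bounded 1-D search over ε
(tolerance 1e−4) with exact inner per-participant fits at each candidate —
equivalent to the joint maximisation over all `P × d + 1` parameters, at a
fraction of the cost, and deterministic given the seed. Inner fits use
bounded L-BFGS from (i) a model-specific informed start obtained by
solving the concave auxiliary problem — for the rate-unaware models the
choice probability depends on the parameters only through a logistic
intercept/slope pair in cost, whose MLE is then inverted analytically to
`(β, k)` — (ii) a deterministic neutral start (β = 1, zero information
weight), and (iii) the seeded random restarts. On worst-case participants
the result was verified against a 400 × 400 brute-force grid.

Model comparison: group BIC `2·(−LL) + p·ln(N)` with `p = P·d + 1`;
likelihood-ratio tests for nested pairs with `df = P × (parameter-count
difference)`; McFadden's pseudo-R² against the random-choice null
(Pr = 1/2 every trial — the null definition is recorded in output, and no
printed R² from other null conventions is asserted anywhere). Per-
participant best-fit tallies use individual BICs with `d` parameters on
the participant's own trial count, holding ε at the group estimate
(alternative ε treatments are config options).

Known limitation: with per-participant nuisance parameters and a shared ε,
the ε MLE carries a small negative finite-sample bias (an incidental-
parameter effect), of order −0.01 at 40 × 112 trials in our recovery runs.

## Synthetic data

The generator (`infoseek.simulate`) emulates two session designs: a
fixed-rate session (7 blocks × 16 trials, four trials per cost per block,
3 s/card) and a rate-varying session (6 blocks × 12 trials, block rate in
{1, 3, 5} s/card with no two adjacent blocks alike, three trials per cost
per block). Outcomes are pseudo-randomly scheduled so every cost (× rate)
cell wins exactly half its trials — equivalent in law to drawing i.i.d.
fair arrays and rejecting until the cell balances, since conditioning
i.i.d. fair outcomes on their total makes all arrangements equally likely.
Informative-stimulus identity and screen side are counterbalanced; 10% of
trials (rounded) are flagged as catch trials, which are generated but not
behaviourally modelled. Choices are Bernoulli draws from the analytic
model chain; missed responses are a condition-independent Bernoulli
(default 1.5%, matching the observed order of magnitude), reflecting the
exclusion rule rather than a model of omission. Cohort defaults — 40
participants, k ~ U[0, 0.5], β ~ U[0.5, 3], shared ε = 0.03 — yield ≈ 4.4k
valid choices per cohort.

What the generator does *not* emulate: response times, learning or block-
order effects, the catch-trial penalty economy, sequential dependencies,
or any perceptual process. Passing recovery tests therefore demonstrates
estimability of the models under their own assumptions, not correctness on
real behaviour.

A consequence of the default parameter ranges worth knowing: roughly half
of the drawn participants sit above ceiling-level preference at zero cost
(predicted probability > 0.95). For such saturated response patterns the
(β, k) likelihood forms a flat ridge and the MLE of k is only weakly
ordered, which limits cohort-level rank correlation between true and
recovered k (≈ 0.74 ± 0.10 across seeds in our runs) even with the
optimiser verified at the global optimum. Model *recovery*, by contrast,
is essentially perfect in both directions, and the shared ε is recovered
to within ±0.02 for most seeds.

## Numerical choices

Probabilities exact-in-floats where the arithmetic allows (power-of-two
denominators); probability-conservation and oracle tolerances 1e−12 and
1e−10; uncertainty-penalty exponents clipped at ±700 with a warning;
optimiser ties across restarts resolve to the earliest start; ε profile
tolerance 1e−4; degenerate inputs (empty conditions, zero-trial cells)
contribute zero likelihood; a cohort fit refuses an empty participant set.
Seeds: every stochastic stage takes an explicit integer seed; identical
seeds give byte-identical output files.

## Problem sizes used in the test suite

Unit and property tests run on single trees and single participants in
milliseconds. Cohort-level checks use the full default conditions —
40 participants × 112 trials, 10 restarts — for parameter recovery, model
recovery (both generating directions) and the qualitative cost curve;
together they complete in a few minutes on one CPU.
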