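# Methods

This note documents the model, the numerical choices, and what the
synthetic-data-driven tests do and do not establish.

## Pure-DDM first-passage statistics

The accumulator `dx = mu dt + sigma dW`, `x(0) = x0`, absorbed at `±z`, is
handled entirely in the scaled parameterization `z~ = z/mu` (s),
`x~0 = x0/mu` (s), `mu~ = (mu/sigma)²` (1/s). The drift is positive toward
the correct boundary by convention; `|x~0| < z~` strictly.

Error rate and unconditional mean decision time use the standard two-barrier
results. The correct/error-conditional mean decision times are obtained from
the backward boundary-value problems

    m h±' + (s²/2) h±'' = −π±(x),   h±(−a) = h±(a) = 0,

with `π±` the splitting probabilities, and `DT_correct = h+/π+`,
`DT_error = h−/π−`. We solved these boundary-value problems in closed form
ourselves rather than transcribing display equations, whose typeset nesting
is easy to corrupt; the derivation is validated numerically three
ways (finite-difference ODE residuals ≈ 1e−8, the decomposition identity
`(1−ER)·DT_c + ER·DT_e = DT` to 1e−8 relative on a parameter grid, and
agreement with the stochastic oracle below).

**Numerical form.** All expressions are rewritten in decaying exponentials
of `z~·mu~` (`E = e^{−4 z~ mu~}`, `E1 = e^{−2 mu~ (z~+x~0)}`), so products
`z~·mu~` of several hundred evaluate without overflow; naive `sinh²`
versions fail above `z~·mu~ ≈ 350`. Precision degrades by cancellation only
for `z~·mu~ ≲ 1e−4`, far below the working range (fitted values give
`z~·mu~ ≈ 4–11`). When ER is exactly 0 (or 1) the corresponding conditional
mean is reported as NaN, never as a number. When upstream clamping would put
`|x~0| = z~`, the starting point is shrunk inside by a relative margin of
1e−9 (the conditional means degenerate on the boundary).

## Monte-Carlo oracle

`mc_first_passage_oracle` is an independent Euler–Maruyama simulator of the
unscaled process used as the numerical reference for every closed form. Two
choices matter:

* **Brownian-bridge absorption.** Naive Euler misses within-step boundary
  touches, biasing ER and DT by O(√step) — larger than 3 Monte-Carlo
  standard errors at 2×10⁵ paths. Each step therefore applies the exact
  bridge touch probability `exp(−2 d_before d_after / (sigma² step))` per
  boundary; the exponentials are skipped when the path is more than a few
  step-standard-deviations from both boundaries.
* **Adaptive step.** The default step is 1/500 of the characteristic
  passage time `min(z/mu, z²/sigma²)`, capped at 1e−4 s. A fixed 1e−4 s
  step leaves a visible O(step) discretization bias for parameter draws
  whose mean decision time is ~10 ms.

Paths not absorbed within the horizon (default `200·z/mu` s) are counted
and excluded, with a warning above 0.1%. Absorption times are recorded at
the end of the absorbing step, an O(step) truncation that is negligible
relative to the Monte-Carlo standard errors at the default settings.

## Trial-to-trial mechanisms

The repetition memory is the exponential filter
`M(n) = Δ·M(n−1) + (1−Δ)·1[repetition]`, which keeps `M ∈ [0,1]` and makes
`Δ` a memory-length parameter (`Δ = 0.5` → four-trial memory, `0.5⁴ =
0.0625`). The alternative reading of the update — reset to 0 on an
alternation — was rejected: it discards the graded history that the priming
mechanism needs and contradicts the memory-length interpretation.

Starting-point priming ties both signs in
`x~0 = ±k(M − 1/2) ± x~offset` to a single `s ∈ {+1, −1}` given by the
upcoming trial's transition type; the alternative of a fixed-direction
offset is possible under the bare notation but conflicts with the stated
sign convention, so it is not implemented.

Sequencing within a run: trial 1 is unprimed (`x~0 = 0`, no transition);
`M` is held at 1/2 through trial 2, so trials 2–3 start at `±x~offset`
only; the memory update applies from trial 3 on. The threshold starts at
`z~max` (conservative initialization) and steps by `−z~down`/`+z~up` after
correct/error outcomes, clamped to `[k/2 + x~offset, z~max]` so the
starting point can never lie outside the thresholds.

Per trial the model is *deterministic given correctness*: ER comes from the
closed form at the current `(z~, x~0)`, correctness is a Bernoulli draw,
and RT is `T_nd` plus the correct- or error-conditional mean decision time.
No sampling from the full RT distribution is performed; consequently the
model's RT *variance* within a cell is not meaningful, only cell means are.

State re-initializes at every block boundary (blocks are separated by
breaks and may change `P_A`); carrying state across blocks is available via
`reset_per_block=False`. Randomness uses one root seed with per-(pass,
block) child streams, so extending the number of passes never reshuffles
earlier passes.

## Synthetic data

The generator emulates two session designs: 13 blocks × 120 trials at
`P_A = 0.5` (unbiased control), and 9 blocks × 200 trials with
`P_A ∈ {0.1, 0.5, 0.9}`, three blocks each. The block order of the biased
design is a seeded balanced permutation per subject; a full Latin square
across subjects counterbalances human fatigue and is irrelevant to the
model. The first stimulus of a block is equiprobable. Response-to-stimulus
intervals are not generated: the model consumes no RSI.

Ground-truth subjects are single model passes over such schedules with the
generating parameters stored in a JSON sidecar. The default parameter sets
(`EXPERIMENT1_FIT`, `EXPERIMENT2_FIT`) are reference fits for the two
session designs and give session-level error rates near the mechanism equilibrium
`z~down/(z~down + z~up)` (≈ 14% and ≈ 2%).

What passing tests on this data do **not** show: the generator produces no
contaminant RTs (outliers arise only if `T_nd + DT` leaves the 0.1–0.9 s
window), no within-subject parameter drift, no RSI or fatigue effects, and
its RT spread within a cell is degenerate (see above). Results on real data
therefore depend on assumptions the synthetic data cannot probe.

## Analysis conventions

Transitions and three-stimulus sequence labels (RR/AR/RA/AA, attributed to
the final trial) are stimulus-based, never response-based; correctness
splits refer only to the labeled trial. Labels never cross block
boundaries. Outliers (RT < 100 ms or > 900 ms, configurable) are excluded
from every RT/ER summary but still sort their successors' sequences. Empty
label×correctness cells are carried as missing (NaN), never zero. Error
triplets use every error whose two neighbors lie in the same block,
regardless of the neighbors' correctness (no single exclusion rule is standard;
alternatives are available by filtering the table first), and
each of the three means drops outlier entries pairwise. Summaries are
trial-pooled; per-subject averaging can be had by grouping the table before
summarizing.

The condition summary vector has the fixed 19-element order: overall /
correct / error mean RTs for RR, AR, RA, AA; the four ERs; pre-, on-,
post-error mean RTs. Seconds and decimal fractions keep element magnitudes
comparable, so the fitting objective is left unweighted.

## Fitting

The objective simulates the model on the *same* per-block stimulus
sequences as the data, summarizes identically, and sums squared differences
over elements defined in both vectors; elements missing in the data are
dropped (with the compared count `N` reduced accordingly), elements defined
in the data but empty in the model contribute a fixed penalty of 1.0 so the
residual vector keeps a constant length for the optimizer.

Minimization is bounded trust-region-reflective least squares
(`scipy.optimize.least_squares`, method `trf`). Choices that matter:

* **Common random numbers.** Each evaluation replays one pre-drawn set of
  per-trial uniforms, making the stochastic objective quasi-deterministic so
  finite differences see signal, not resampling noise.
* **Passes.** The default is 10 passes per evaluation (the procedure
  requires at least 5); more passes smooth the coin-flip discontinuities
  left by the common-random-number scheme and measurably improve recovery.
* **Finite-difference step** `diff_step = 1e-2` (relative), large enough to
  step across individual Bernoulli flips.
* **Coordinates.** The ceiling is optimized as the slack
  `z~max − (k/2 + x~offset)` so box bounds can never produce an empty
  threshold range.
* **Multi-start.** One objective evaluation costs ~1 ms, so a pool of ~32
  seeded log-uniform candidates is scored first and the best few (default
  4, including the fixed central start) are polished. Bounds default to
  generous boxes around the reference-fit magnitudes
  (`mu~ ∈ [1, 80]` 1/s, `T_nd ∈ [0.05, 0.6]` s, `Δ ∈ [0.01, 0.99]`, ...).

Information criteria use the Gaussian-residual least-squares forms
`AIC = N ln(Err/N) + 2p`, `AICc = AIC + 2p(p+1)/(N−p−1)` (undefined when
`N − p − 1 ≤ 0`), `BIC = N ln(Err/N) + p ln N`, with `N` the number of
compared summary elements (19 or 57), matching the "number of means being
compared" convention. `replicate_and_average` reruns a fitted model 10
times (by default) and reports per-element means and standard errors.

**Identifiability.** On single-subject synthetic data (1800 trials),
`T_nd` and `Δ` recover within a few percent and `mu~` within ~10–20%
median; `x~offset` (≈ 3 ms) and the individual threshold-step sizes are
weakly identified — their effects trade off against `k` and `z~max` — and
recovery studies should report their spread rather than point accuracy.

## Problem sizes used in the packaged checks

The test suite and the acceptance script run at desk scale on one CPU:
oracle comparisons use 2×10⁵ paths per draw (20 draws in the suite, 8 in
the script); parameter recovery uses 10 (suite) or 4 (script) ground-truth
subjects on the full 1800-trial blocked design; qualitative-pattern checks
use 10-pass simulated sessions (15 600 / 18 000 trials). These sizes give
the quoted tolerances comfortable margins while keeping full runs in
minutes.

## Known limitations

* Only cell means of RT are modelled; RT distributions, quantiles and
  variance effects are out of scope.
* Thresholds are symmetric and collapse-free; drift and non-decision time
  are fixed within and across trials.
* The comparison accumulator models from the sequential-effects literature
  (leaky competing accumulators with conflict signals) are not
  re-implemented; information criteria here score only this model family.
* Headline values from human studies (absolute RT/ER levels, fitted-score
  tables, inferential statistics) depend on participant data not packaged
  here and are not targeted; the packaged checks validate
  structure, internal consistency and qualitative signatures instead.
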