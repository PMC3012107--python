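# Methods

## Model and procedure

SGoF treats the S observed p-values as draws from a two-group mixture:
a fraction π₀ of true nulls with Uniform(0,1) p-values and a fraction
1 − π₀ of effects whose p-values concentrate near zero. For a working
threshold γ it compares the observed count K(γ) = #{pᵢ ≤ γ} with its
complete-null distribution Binomial(S, γ) through the exact one-sided
tail p(γ) = P(Binomial(S, γ) ≥ K(γ)). Rejection of the intersection null
at level α licenses the declaration of the N_α(γ) = K(γ) − b_α(γ) + 1
smallest p-values, where b_α(γ) is the binomial critical count. The
procedure controls the FWER at α in the weak sense only: the guarantee is
the probability of any declaration under the complete null, not a
per-hypothesis error bound. Individual tests are assumed independent (or
exchangeable enough that the binomial null is adequate); dependence-aware
variants are out of scope.

The step-wise formulation — repeatedly test K, K−1, K−2, … against the
binomial tail until significance is lost — is implemented as
`sgof_sequential` and is provably identical to the closed form
max(K − b + 1, 0) with fixed S; the suite checks the equivalence on
randomised instances. (An alternative reading would also shrink S while
iterating; the closed form with fixed S is taken as normative.)

## Parameters

- **γ** (working threshold, default 0.05): defines which p-values count as
  "small". Power typically peaks at an interior γ somewhat above the
  effect-p-value mass; the trace exists precisely because no single γ is
  best a priori.
- **α** (weak-FWER level, default 0.05): level of the exact binomial
  meta-test. The trace's maximum eFDR is quite insensitive to α.
- **capped** (default off): caps declarations at K(α) so that no p-value
  above α is ever declared, trading power for interpretability; weak FWER
  control is unaffected.

## Numerical and edge-case choices

- **Critical count.** The "100(1−α)% percentile" of a discrete
  distribution is ambiguous; we define b_α(γ) = min{b : P(X ≥ b) ≤ α}, the
  unique convention under which "reject iff K ≥ b" yields weak FWER ≤ α
  exactly. Boundary p(γ) = α counts as rejection for consistency. b may be
  S + 1 (no attainable rejection) for tiny S·γ.
- **Exact tails.** All binomial tails use scipy's stable survival
  function — no normal approximation — and are validated against direct
  pmf summation for all S ≤ 60 at relative error ≤ 1e−12. Underflow is
  floored at 1e−300 so log-scale plots stay finite.
- **Ties.** q_α(γ) is the N-th smallest p-value. When ties straddle the
  cut, #{p ≤ q} can exceed N; N stays authoritative and the achieved count
  is reported alongside. Declared identifiers follow input order among
  equal p-values (stable sort), so reruns are deterministic.
- **π₀ estimator.** eπ₀ = mean(−log(1 − pᵢ)), the simplest member of a
  beta-mixture family of estimators; E[−log(1−U)] = 1 under the null.
  p = 1 is clamped to 1 − 1e−15 with a warning rather than dropped (S must
  not change silently). The raw value may exceed 1 and is reported raw;
  it is truncated to 1 only inside the eFDR formula, and eFDR itself is
  clipped to [0, 1].
- **Degenerate inputs.** K = 0 gives p(γ) = 1 and N = 0 with threshold and
  eFDR absent (`NA` in tables, `None` in the API). Empty p-value sets are
  rejected with a validation error.

## Synthetic-data generator

`generate_pvalues` emulates S independent one-sided normal tests:
round(S · effect_proportion) effects (fixed per trial) draw
p = 1 − Φ(Z + w), Z ~ N(0,1), where w is the standardised distance between
null and alternative means; the remainder are Uniform(0,1). This captures
the mixture structure that drives SGoF — a near-zero mode of effect
p-values over a uniform floor — but not features of real screens:
correlated tests, discretely supported p-values (permutation tests),
composite or conservative nulls, or heterogeneous effect sizes. Passing
benchmarks therefore demonstrate correctness of the procedure under
independence, not robustness to dependence.

## Simulation study

Each trial draws one p-value sample shared by SGoF (at every γ of the
grid) and BH, so methods are compared on identical data. Per-test power is
TP / #effects and the per-trial false-discovery proportion is
FP / max(R, 1) (a no-rejection trial contributes 0); summaries are plain
averages over trials with Monte-Carlo standard errors attached. The
benchmark "FDR" columns are these realised FDP averages computed from the
known truth labels, not the eFDR plug-in estimate. Classical step-up BH is
used, for which the averaged FDP sits at π₀ · (nominal level) under
independence — visibly below nominal in high-effect-fraction scenarios.
The default scenario sizes follow the benchmark design: S = 1000 tests,
effect fractions 10%/30%, w ∈ {1, 1.5, 2}, 1000 trials (the test suite
uses a 200-trial mode with proportionally wider tolerances); the complete
null S = 1000 / 2000-trial run verifies weak FWER control at
γ ∈ {0.05, 0.26, 0.5}. RNG streams are spawned per trial from a single
master seed, so any individual trial is reproducible in isolation.

The driver uses a sorted-order fast path (bisection for K(γ), cumulative
truth counts for TP) that is algebraically identical to calling the
single-γ routine per trial; the equality is asserted in the suite.

## Trace

The default grid is γ = 0.01, 0.02, …, 0.99; "let γ vary continuously" is
realised as this configurable finite grid. Panel A uses the natural
logarithm (a base change only rescales the axis) with a dashed reference
at log α. On ties in max N the summary reports the smallest attaining γ,
since a smaller γ gives a stricter p-value threshold at equal power. π₀ is
estimated once from the full p-value set, not per γ.

## Known limitations

- Weak FWER control only; no per-hypothesis adjusted p-values, and the
  declared set has no strong-sense error guarantee.
- eFDR is a plug-in estimate whose accuracy inherits the bias of eπ₀
  (conservative when effects are plentiful).
- Only the Dalmasso-type n = 1 estimator of π₀ and the classical BH
  baseline are provided; q-value-style adaptive procedures are not.
- Automatic selection of a single optimal γ is deliberately not offered;
  the trace is the decision aid.
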