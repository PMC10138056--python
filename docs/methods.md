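# Methods

## Statistical model

Study `i` reports an effect estimate `y_i` on an additive pooling scale
(log odds ratio throughout the examples) together with a within-study
variance `σ_i²` that is treated as a *known constant*. This is the
classical simplifying assumption for analytic work on meta-analytic
testing: with known variances the pooled z-statistic
`θ̂√Σw_i` is exactly standard normal under `H₀: θ = 0`, so one-sided
p-values and the selection analysis below need no asymptotics. Estimated
variances (and the resulting non-normal null) are out of scope.

Fixed-effect model: `y_i ~ N(θ, σ_i²)`, weights `w_i = 1/σ_i²`.
Random-effects model: `y_i ~ N(θ, σ_i² + τ²)`, weights
`w_i = 1/(σ_i² + τ̂²)` with the DerSimonian–Laird estimate

```
τ̂² = max(0, (Q − (S−1)) / (Σw⁰ − Σ(w⁰)² / Σw⁰)),
Q = Σ w⁰_i (y_i − ȳ⁰)²,   w⁰_i = 1/σ_i²,
```

where `ȳ⁰` is the fixed-effect pooled mean of the same study set. A single
study returns τ̂² = 0 with a logged warning: the estimator's denominator is
0/0 and one study carries no between-study information. No other τ²
estimators (REML, Paule–Mandel) or Hartung–Knapp adjustments are provided.

Decisions use the one-sided right-tailed `p_meta = Φ(−θ̂√Σw_i)` for
`H₁: θ > 0` (left-tailed and two-sided variants are exposed via
`pooled_p_value(..., sided=)`); confidence intervals are the usual
two-sided normal intervals `θ̂ ∓ z_{α/2} (Σw_i)^(−1/2)`. Both conventions
coexist deliberately: the CI describes the estimate, the one-sided p
drives the significance decisions being manipulated.

`I²` is reported in the *typical-variance* form `τ²/(τ² + s²)` with `s²` a
representative within-study variance (0.17 under the simulation design
below). The Q-based Higgins form is intentionally not implemented — the
typical-variance form is the one consistent with the package's
heterogeneity arithmetic (0.70/0.87 ≈ 80%), and offering both invites
silent confusion.

## Adversarial selection

The adversary retains `S` of `K` studies. The greedy rule ranks studies by
the per-study one-sided p-value `p_i = Φ(−√w_i · y_i)` — equivalently by
the standardised effect `z_i = √w_i · y_i` — and keeps the top-`S`
smallest p (overstate) or largest p (understate). Ranking is by a stable
sort, so exact ties keep input order; results are otherwise independent of
row order. The ranking key follows the per-study p-value literally
(`−√w_i·y_i`), not the unnormalised `w_i·y_i`, which avoids scale
ambiguity between studies of different precision.

τ² policy under the random-effects model:

* `full_set` (default): τ̂² is estimated once from all `K` studies and then
  held fixed for ranking, subset pooling and the full-set analysis. This
  is the regime in which the analytic conditions below remain applicable,
  since the weights do not co-move with the subset choice.
* `subset`: ranking still uses the full-set τ̂² (a subset τ² cannot exist
  before the subset does), but the retained subset's pooled p re-estimates
  τ̂² on the subset — per candidate subset in exhaustive mode, which makes
  that mode markedly more expensive.

`exhaustive_best_subset` enumerates all C(K, S) subsets (refusing beyond a
200 000-subset budget) and returns the one extremising the pooled p. It
exists as an optimality oracle for the greedy rule, not as part of the
selection model. Candidates are compared on the pooled z scale rather than
the p scale, because `Φ(−z)` underflows to exactly zero for strongly
significant subsets and would create spurious ties; z is strictly monotone
in p, so the optimum is identical. Exact z-ties resolve to the
lexicographically smallest sorted label tuple. With equal weights the
greedy subset is provably optimal (the pooled p is monotone in the subset
effect sum at fixed S); with unequal weights greedy may be slightly
suboptimal, so both values are reported rather than adjudicated.

`can_flip` is true only for genuine flips: the subset reaches the
direction's target *and* the full set concludes the opposite.

## Cherry-pickability conditions

Both conditions are stated in `α ∈ (0, ½)`, `δ ∈ (0,1)`, a
retention-fraction parameter `ε`, and the weight imbalance
`η = w_max/w_min ≥ 1`.

Condition 1 (force significance; `ε ∈ (0, ⅓)`): if `S/K ≤ ε` and

```
S ≥ max{ η Φ⁻¹(α) / Φ⁻¹(½ − ε²/2),
         ε log(1/δ) / (2(½ − 3ε²/2)²) − 2 },
```

then greedy selection achieves `p_meta(D_S) ≤ α` with probability at least
`1 − δ` even under `θ = 0`. The first term diverges as `ε → 0⁺`
(`Φ⁻¹(½ − ε²/2) → 0⁻`) and grows linearly in η; the bound is monotone
nondecreasing in η and in `1/δ`.

Condition 2 (force non-significance; `ε ∈ (0,1)`): if `1 − ε ≤ S/K ≤ 1`
and

```
η Φ⁻¹(α) / Φ⁻¹(1 − ε²/2)  ≤  S  <  (1−ε) log(1/δ) / (2(1 − ε/2)²) − 2,
```

then `p_meta(D_S) ≥ α` is achievable with probability at least `δ`. Two
asymmetries are intentional and surfaced in every report: the guarantee is
the weak `δ`, not `1 − δ`, and since `Φ⁻¹(α) < 0` the lower expression is
negative — it loosens (the admissible interval widens) as η grows. The
interval is frequently empty (`s_low ≥ s_high`, e.g. whenever δ is not
very small); this is reported, not raised.

Numerical conventions: the analytic bounds are real-valued; the integer
gates are `S ≥ ceil(s_min)` and `s_low ≤ S < s_high`. η is defined over
the retained subset, which is unknown a priori, so reports default to the
conservative all-`K` ratio; `subset_weight_ratio` recomputes it post hoc.
Both displays are conservative sufficient conditions. They are locked in
empirically: `empirical_guarantee_check` simulates ensembles from the
generator below, applies greedy selection, and verifies the stated success
frequency (the acceptance test does this at 1 000 replicates with binomial
slack `2√(δ(1−δ)/reps)`). These checks are one-sided — they would expose a
transcription that is too weak, not one that is too conservative — which
is the appropriate direction for a sufficient condition.

## Simulation design

`sample_within_variance` draws `σ_i² ~ 0.25·χ²₁` truncated to the open
interval (0.009, 0.600) by exact rejection (acceptance ≈ 0.728); the
truncated mean is ≈ 0.17, so the τ² grid {0, 0.01, 0.10, 0.50, 0.70}
spans typical-variance I² from 0% to ≈ 80%. Effects are
`y_i ~ N(θ, σ_i² + τ²)`; each study reports `σ_i²` only, as a real trial
would. A scenario is `(S, ratio = S/K, θ, τ², α, model, reps)` with
`S ∈ [2, 30]`, ratio grid {⅓, ⅕, ⅒}, θ grid {0, 0.5, 1.0}, α = 0.05,
`K = ⌊S/ratio + 0.5⌋` (nearest, ties up — the rounding direction is a
convention the design itself leaves open). `θ = 0` scenarios apply
overstate selection and count `p_meta(D_S) ≤ α` as a false conclusion;
`θ > 0` scenarios apply understate selection and count `p_meta(D_S) > α`.
Counting is unconditional on the full-set analysis by default;
`conditional=True` restricts to genuine flips. Random-effects scenarios
use the `full_set` τ² policy.

Default `reps = 200` keeps a full 3 × 5 × 3 × 29 grid on one CPU in
minutes with Monte Carlo SE ≤ √(0.25/200) ≈ 0.035; `reps = 1000` is a
config option for smoother curves. Reproducibility: `run_grid` derives one
`SeedSequence` substream per scenario from the master seed *and the
scenario's own parameters*, so results are invariant to scenario order and
shared-seed paired comparisons across τ² values are meaningful.

What the generator does *not* emulate: estimated within-study variances,
non-normal effect distributions, correlated studies, publication bias, and
any dependence of σ_i² on θ. Passing tests therefore demonstrate the
selection mechanics and the conditions' guarantees under the stated
homogeneous-normal design, not robustness of real meta-analyses to every
selection mechanism.

## Data handling

Study CSVs require `label, effect` plus exactly one of `se`/`variance`;
`se` is squared on ingestion, malformed rows are rejected with their file
line number, and floats are parsed round-trip so write→read is lossless.
2×2 event tables convert to log-OR studies with the Woolf variance
`1/a + 1/b + 1/c + 1/d`; a table containing any zero cell gets 0.5 added
to all four cells (Gart correction) — applied per table, not per cell. The
`benefit_positive` orientation negates the log-OR so a protective
treatment (fewer events in the treated arm) maps to `θ > 0`, matching the
one-sided alternative; this mirrors the common clinical convention of
reporting protective effects as OR > 1 after inverting the ratio.
`export_forest_table` emits the tidy per-study rows (effect, normal CI at
the analysis α, weight %) plus the pooled row that a forest plot renders;
publication-quality plotting is out of scope (a diagnostic line-plot
helper for simulation grids is included).

## Numerical and testing conventions

Floating comparisons in tests are at 1e−9 relative unless an example's
own precision dictates otherwise. Statistical tests are seeded and sized
so that their null rejection probability is negligible (e.g. coverage at
±1% with 10⁴ replicates; KS uniformity at level 0.001). statsmodels'
`combine_effects` serves as an independent oracle for pooled estimates
and the DL estimator (its untruncated τ² is clamped at 0 for comparison);
the package itself never calls it. StudySets are stored columnar with
lazily generated positional labels so that condition-validation ensembles
(K ≈ 10⁵ per replicate) stay vectorised.

## Known limitations

* The conditions treat τ² as fixed; re-deriving τ² jointly with the
  subset choice inside the guarantees is not attempted (the `subset`
  policy provides the empirical sensitivity analysis instead).
* Greedy optimality is exact only under equal weights; the exhaustive
  oracle is limited by its enumeration budget (default 2×10⁵ subsets).
* `S > 30` grid points and `K < S` augmentation scenarios are excluded
  from the scenario type; heuristic search for large-K exhaustive
  problems is not provided.
* The clinical worked examples in the literature require externally
  transcribed trial tables; the package ships only synthetic fixtures and
  the conversion/orientation machinery needed to reproduce such analyses
  from user-supplied tables.
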