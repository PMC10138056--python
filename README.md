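# metapick

Cherry-picking vulnerability diagnostics for inverse-variance meta-analysis.

A meta-analysis pools the estimates of `K` independent trials, but the
analyst also chooses the inclusion/exclusion criteria — and thereby which
`S ≤ K` trials are pooled. `metapick` quantifies how exposed a given body of
evidence is to that choice: it implements the standard fixed-effect and
random-effects pooling machinery, adversarial top-`S` subset selection that
tries to force a (non)significant pooled conclusion, analytic conditions
under which such manipulation is almost guaranteed to succeed, and a Monte
Carlo harness that measures how often it succeeds in practice. It is aimed
at methodologists, reviewers and readers of meta-analyses who want to ask:
*could this conclusion have been cherry-picked?*

## Model

Each study `i` reports an effect `y_i` (on a pooling scale such as the log
odds ratio) with known within-study variance `σ_i²`. Under the fixed-effect
model `y_i ~ N(θ, σ_i²)`; the random-effects model adds between-study
variance, `y_i ~ N(θ, σ_i² + τ²)`, with τ² estimated by the
DerSimonian–Laird moment estimator. With weights `w_i = 1/(σ_i² + τ²)` the
pooled estimate is

```
θ̂ = Σ w_i y_i / Σ w_i ,     se(θ̂) = (Σ w_i)^(-1/2) ,
```

and the one-sided pooled p-value for `H₁: θ > 0` is
`p_meta = Φ(−θ̂ √Σ w_i)`. An adversary who may retain any `S` studies ranks
them by the per-study one-sided p-value `p_i = Φ(−√w_i · y_i)` and keeps the
`S` smallest (to overstate a null treatment) or largest (to understate a
real one). Two analytic conditions in `(α, δ, ε, η)` — where
`η = w_max/w_min` is the weight imbalance — state when this succeeds with
probability at least `1 − δ` (forcing significance) or at least `δ`
(forcing non-significance); see `docs/methods.md` for the exact displays
and their caveats.

## Worked example

`scratch/trials.csv` style input — ten synthetic trials with `label,
effect, se` columns on the log-OR scale. Pooling all ten:

```
$ metapick pool --input trials.csv --model fixed
{
  "theta_hat": 0.30077567226559937,
  "se": 0.1549892596450264,
  "ci_low": -0.0029976946291795925,
  "ci_high": 0.6045490391603783,
  "p_one_sided": 0.026152030593828705,
  ...
}
```

The full evidence base is (one-sidedly) significant at α = 0.05:
θ̂ = 0.301, p = 0.026. Can a reviewer who keeps only five trials make the
treatment look ineffective?

```
$ metapick cherrypick --input trials.csv --s 5 --direction understate
{
  "selected": ["bertschat1989", "singh1990", "pereira1990",
               "golf1991", "thogersen1991"],
  "pmeta_selected": 0.7399099983332529,
  "pmeta_full": 0.026152030593828705,
  "flipped": true,
  "can_flip": true,
  ...
}
```

Yes: retaining the five trials with the largest one-sided p-values moves
the pooled p from 0.026 to 0.740 — the significant conclusion was one
inclusion criterion away from disappearing. The analytic screen works the
other way around, from design parameters alone:

```
$ metapick bounds --theorem 1 --alpha 0.05 --delta 0.1 --epsilon 0.2 \
      --eta 1.5 --s 50 --k 400
{
  "theorem": 1,
  "satisfied": true,
  "s_min": 49.19449957473365,
  "notes": "requires S/K <= 0.2 (got 0.125) and S >= ceil(49.19); ..."
}
```

i.e. with 400 comparable studies available and weight imbalance η ≤ 1.5, a
reviewer free to keep 50 of them can force significance of a null
treatment with ≥ 90% probability.

Other subcommands: `simulate` (false-conclusion proportion grids, tidy CSV
output) and `convert2x2` (2×2 event tables → log-OR studies, with a
`benefit-positive` orientation for protective treatments). Everything is
also available as a library; see the module docstrings.

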