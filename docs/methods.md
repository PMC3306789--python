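# Methods

## Model

Per-gene mean treatment effects y₁,…,yₙ (treatment minus control replicate
means, log scale) are treated as one i.i.d. sample from N(μ, σ²). This is a
*population* model across genes, not a per-gene model: the information that
rescues the small-replicate setting comes from pooling all n effects, so
the method's power does not degrade with n_c = n_t = 4 the way per-gene
tests do. The price is the i.i.d. assumption across genes — dependence
between genes and gene-specific variances are not modelled.

The conjugate normal–inverse-gamma prior
μ | σ² ~ N(μ₀, σ²/λ), σ² ~ IG(τ/2, β/2) yields a closed-form posterior and
a location-scale Student-t predictive density for a new effect with

- location μ* = (n/(n+λ))ȳ + (λ/(n+λ))μ₀,
- degrees of freedom τ* = τ + n + 1,
- scale β*(n+λ+1)/(τ*(n+λ)), with β* = β + (n−1)s² + nλ(ȳ−μ₀)²/(n+λ).

Two deliberate readings are worth flagging:

1. **τ\* = τ + n + 1.** The textbook conjugate update gives τ + n. The
   extra unit is kept as the method's stated form; the constant is isolated
   in one helper so the textbook variant is available via
   `tau_star_rule="standard"` for sensitivity analysis. At the n ≈ 1000
   scale of the benchmark the difference is far below Monte-Carlo noise.
2. **Interval half-width.** The predictive interval is
   μ* ± t_{1−α/2,τ*}·√Var(Y_new|y). Taking the square root of the variance
   is the only dimensionally coherent choice (the half-width must be in y
   units); it is recorded here because the interval can also be met written
   with the variance un-rooted.

## Sequential identification

Effects are visited in increasing numerical order (ties broken by original
gene index — measure-zero under the model but kept deterministic). At each
step the reference sample is every effect except the current gene and all
previously called genes; the predictive location is forced to μ* = 0 and
the gene is called iff |y_(g)| exceeds the predictive-interval half-width.
Called genes never re-enter the pool; non-called genes do. A single pass is
made — no revisiting of earlier non-calls after the pool shrinks.

Decisions taken where the procedure is underdetermined:

- **β is fixed once** from the full effect vector (β = (τ−2)R², R the
  range of all n effects) and does not shrink with the pool. A prior should
  not depend on which genes end up called; only ȳ, s², n are recomputed on
  the shrinking reference set.
- **Visiting order matters** because of the sequential exclusion. The
  increasing order is the stated one and the default; an extremity-first
  order (decreasing |y|) is exposed as `order="extremity"` for sensitivity
  analysis only.
- **Sign-flip behaviour.** Negating all effects reverses the visiting
  order, so the excluded set at a given gene's step differs and borderline
  genes can flip calls (≈1 % of genes in generic noise). This is a property
  of the sequential procedure itself, not an implementation artefact;
  clearly differential genes are stable under the flip.

The implementation maintains the pool's count, sum and sum of squares
incrementally (O(1) per step, O(n) per dataset after the sort) with a
memoised t-quantile per distinct degrees of freedom. The test suite pins
call-equivalence against a from-scratch scalar re-execution of the
criterion over 500 random instances.

## Baseline tests

- **Welch t (TT):** per-gene variances, fractional Welch–Satterthwaite df
  (no integer rounding), two-sided p.
- **Cyber-t (CT):** ν₀ = k − n_g pseudo-observations with k = 10, prior
  variance σ₀² = ((n_g−1)/n_g)s_g² where s_g² is the sample variance of the
  pooled 2-condition vector of that gene; per-condition shrunk variance
  σ̃ₕ² = (ν₀σ₀² + (nₕ−1)sₕ²)/(ν₀+nₕ−2); df = ν₀ + n_c + n_t − 2. For
  n_g ≥ 10 (outside the benchmark grid) ν₀ is floored at 0. The
  window-of-neighbouring-genes variant of σ₀ is deliberately not
  implemented: only per-gene information is used.
- **Bayesian t (BTT):** ν₀ = n_g, σ₀² = s_g² (same pooled variance),
  ν_n = ν₀ + n_c + n_t − 2, σ_n² the ν₀/s²-weighted combination, statistic
  Δx̄/(σ_n√(1/n_t+1/n_c)), two-sided tail from t_{ν_n}.

With per-gene σ₀², CT is conservative at n_c = n_t = 4 (null rejection
≈ 0.024–0.030 at α = 0.05, below TT's ≈ 0.040); this ordering is part of
the benchmark's expected behaviour.

## Simulator

Control replicates: N(μ_c, σ_c²) with μ_c = −14, σ_c² = 0.8 — the average
observed log-scale mean and variance of a real bacterial control condition,
so the null scenario is anchored to realistic numbers. Differential genes
(exactly round(n·p_over/100) up, round(n·p_under/100) down; membership
redrawn each replicate) get treatment replicates
N(μ_c ± δσ_c, (γσ_c)²); δ multiplies the standard deviation √0.8, not the
variance. Everything is generated directly on the log scale.

What the generator does *not* emulate: mean–variance dependence,
gene–gene correlation, heavy tails, missingness, normalisation artefacts.
Passing benchmarks therefore demonstrate correctness of the procedures and
their relative behaviour under the stated normal mixture — not performance
on raw array data, which needs upstream normalisation and may violate the
i.i.d.-across-genes assumption.

Seed policy: a scenario seed plus replicate index feed a spawned
`SeedSequence`, so any single replicate of any cell is regenerable in
isolation and all streams are independent.

## Scoring and benchmarking

Per replicate: TPR = called∧true / true, FPR = called∧null / null,
TDR = called∧true / called (undefined when nothing is called; such
replicates are dropped from the TDR mean — they are rare on the benchmark
grid). Cell aggregates are means over S replicates with Monte-Carlo
standard errors (sd/√S). All methods run on the same dataset within a
replicate (paired design), which tightens method contrasts.

Problem sizes: benchmark cells use n = 1000 genes and S = 100 replicates —
the study conditions themselves, which are light enough (a few seconds per
cell) that no scaling down is needed. The full factorial grid is
2 sample sizes × 3 p-splits × 9 δ × 3 γ = 162 cells.

## Numerical choices

- Sample variances use the n−1 denominator throughout.
- The incremental pool variance clamps tiny negative round-off to 0.
- Predictive variance requires τ* > 2; violations raise a degeneracy error
  rather than returning NaN.
- Welch with both sample variances zero, zero effect range for the default
  β, and a reference pool shrinking below 2 are all hard errors with
  descriptive messages (CLI exit code 3, validation errors exit 2).
- Floats are written at 6 significant digits; TSV round-trips are tested.

## Limitations

- No multiplicity control: α is a per-gene working level, not an FDR; the
  sequential criterion controls nothing family-wise.
- The across-gene pooling assumes exchangeable effects; strong asymmetry
  between up- and down-regulation with a non-zero μ₀ would bias thresholds.
- Cyber-t is implemented in its per-gene-prior form only.
- The sequential pass is order-dependent by construction (see above).
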