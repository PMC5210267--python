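# Methods

## Model and procedures

We test m null hypotheses simultaneously from their p-values. Among the R
rejected hypotheses, V are false discoveries and S = R − V true ones; m₀
of the m nulls are true. The error rates involved are

- FDR = E(V/R | R > 0)·Pr(R > 0), with the convention V/R := 0 when R = 0;
- pFDR = E(V/R | R > 0), conditional on at least one rejection;
- E(V), the expected count of false discoveries.

Four procedures operate on the raw p-value vector:

**Benjamini-Hochberg (BH).** Step-up at level α: sort p-values ascending,
find the largest i with p₍ᵢ₎ ≤ (i/m)α, reject all smaller. Implemented via
adjusted p-values — p₍ᵢ₎·m/i, running minimum from the top, capped at 1 —
so that thresholding at any α reproduces the step-up rule at that α.

**Storey q-values.** The same step-up rule with threshold (i/(m·π̂₀))α.
Elementwise the q-values equal min(1, π̂₀ · BH-adjusted), which the suite
asserts as an exact identity.

**Bonferroni E(V) control.** Reject pᵢ ≤ γ/m. γ is a *budget of expected
false discoveries*, not a probability: summing marginal rejection
probabilities of the m₀ uniform nulls gives E(V) = m₀γ/m ≤ γ, with no
independence needed for the bound.

**Bon-EV.** A single-step rule for pFDR control at α: reject

    pᵢ ≤ α · r̂ / π̂₀,   r̂ = #{BH-adjusted pᵢ ≤ α} / m.

r̂ is the plug-in estimate of Pr(P\* ≤ α), the probability that a
BH-adjusted p-value falls at or below α. Dividing by π̂₀ (as in Storey's
procedure) recovers power relative to BH; multiplying by the BH rejection
fraction (rather than running a second step-up pass) keeps the realized
false-discovery proportion and the variance of R below Storey's. The
procedure inherits an i.i.d.-mixture assumption from its derivation; we
apply it under correlation as well and verify FDR control empirically in
the simulation study.

The rejection sets nest — BH ⊆ Bon-EV ⊆ Storey at every α when both
Storey and Bon-EV share a π̂₀ capped at 1 — because the BH step-up index k
satisfies p₍ₖ₎ ≤ kα/m ≤ α·r̂/π̂₀, and the Bon-EV rejection count then
bounds Storey's step-up index from below. This forces the power ordering
Storey ≥ Bon-EV ≥ BH in every simulation iteration, exactly, not just on
average.

### Adjusted p-values for Bon-EV

The rule above defines only a rejection set. For uniform tabular output we
report adjustedᵢ = min(1, pᵢ·π̂₀/r̂) when r̂ > 0, so that thresholding at α
reproduces the rule, and 1 for every hypothesis when r̂ = 0 (where the
cutoff is 0 and no p-value can be 0, since an exact zero would itself
force a BH rejection and hence r̂ ≥ 1/m).

## Estimating π₀

π̂₀(λ) = #{pᵢ > λ} / ((1−λ)m). Under the complete null p-values are
uniform and E π̂₀ = 1; alternatives concentrate near 0, making the
estimator conservatively biased upward. Two variants:

- **fixed λ** (default λ = 0.5): fully reproducible, the package default;
- **smoother** (grid 0.05–0.95 in steps of 0.05): evaluates π̂₀(λ) on the
  grid, fits a cubic polynomial by least squares, and returns the fitted
  value at the largest λ, where the alternatives' contamination is
  smallest. The cubic least-squares fit is the deterministic smoothing
  choice — it has no free smoothing parameter, so results are
  machine-reproducible; a smoothing spline would require a tuned roughness
  penalty for no benefit at this grid size.

Both outputs are floored at 1/m (prevents division blow-up in the Bon-EV
cutoff) and capped at 1 (preserves the nesting property). The uncapped
value is retained on the estimate object for diagnostics.

## Simulation engine

One simulation **cell** fixes (m, n per group, correlation mode, π₁, α,
iteration count). Defaults follow the study conditions: unit-variance
multivariate normal expression, control means 0, the first
round(m·π₁) genes mean-shifted in the treatment group by effect sizes
equally spaced from 1 to 3 (a single effect gene gets 1), pooled
two-sample t-tests (df = n₁+n₂−2; Welch available via `equal_var=False`),
all procedures at α = 0.05, and the π₁ grid
0.005…0.80. Correlation enters through a latent factor per sample:

- **equicorrelated**: x = √ρ·w + √(1−ρ)·ε gives every gene pair
  correlation ρ exactly (ρ ∈ {0, 0.4, 0.8} in the study grid);
- **random**: per-gene loadings bⱼ ~ Uniform(0, √0.8), drawn once per
  dataset, give pairwise correlations bⱼ·bₖ ∈ (0, 0.8). A full matrix of
  independent Uniform(0, 0.8) pairwise correlations is generally not
  positive semidefinite; the rank-one construction honors the intended
  range while remaining a valid distribution.

Effect genes share the correlation structure of the nulls; effects enter
only through the mean shift.

Per iteration we record R, V, S and FDP = V/R (0 when R = 0) for BH,
Storey and Bon-EV, with π̂₀ computed once and shared by Storey and Bon-EV.
Per cell we report the estimated FDR (mean FDP, with its Monte-Carlo
standard error), power (mean S/(m−m₀), undefined at π₁ = 0), stability
(SD of R across iterations, sample n−1 denominator), and mean R.

Two shipped profiles: **desk** (m = 2,000 genes, 300 iterations), the
default problem size for tests and the acceptance script, chosen so a
full cell runs in about a second on one CPU while leaving Monte-Carlo
standard errors on the FDR near 0.1 percentage points; and **paper**
(m = 10,000, 1,000 iterations), the full study scale.

**Seeding.** Iteration i of cell c draws its generator from
`SeedSequence(entropy=base_seed, spawn_key=(c, i))`, so cells and
iterations are independently reproducible and trivially parallelizable,
and two runs with the same base seed are bitwise identical.

## Bootstrap stability

For a real (or synthetic) samples×features matrix with a two-level group
label, each of B resamples draws samples with replacement *within* each
group, preserving group sizes, reruns the per-feature test, applies each
procedure at α, and records R. Stability is SD(R) over the B resamples
(n−1 denominator). Everything — π̂₀ and the BH rejection fraction
included — is re-estimated on every resample, so the distribution of R
reflects the full pipeline's variability. The per-feature test is
pluggable (default: pooled t-test); count-model p-value generators can be
plugged in without changing the resampling logic, which keeps the module
testable without any RNA-Seq-specific machinery (CPM filtering, TMM
normalization and negative-binomial GLM fitting are out of scope).

## Numerical choices and degenerate inputs

- p-values exactly 0 or 1 are legal (discrete tests produce them); NaNs
  are rejected at construction, with an opt-in drop-with-logged-warning
  policy in the table reader. Silent imputation would hide data problems.
- Step-up ties are handled stably: hypotheses sharing a rejected p-value
  are rejected together.
- A gene with zero variance in both groups gets p = 1 with a warning when
  the group means agree, and raises when they differ; such data cannot
  arise from the normal generator, so this guards external inputs only.
- γ = 0 in Bonferroni-E(V) rejects only exact zeros; r̂ = 0 in Bon-EV
  rejects nothing and reports all adjusted values as 1.
- Output tables use shortest-round-trip float formatting; reading them
  back through the package reproduces values to machine precision.

## What the synthetic generator does and does not emulate

The generator reproduces the study conditions: normal margins, unit
variances, equicorrelated or rank-one random correlation, and mean-shift
alternatives. Real expression data differ in ways the generator does not
model: count-based margins with mean-variance dependence, block or
network correlation structure rather than a single shared factor, and
effect sizes not laid out on a regular grid. Passing tests therefore
demonstrate correctness of the procedures and the claimed orderings under
the stated model, not performance guarantees on arbitrary real data; the
bootstrap module exists precisely to measure stability on a dataset of
interest.

## Known limitations

- The MSE-minimizing λ selection sometimes used with q-values is not
  operationalized here; the fixed-λ and cubic-smoother estimators are the
  two offered methods.
- Bon-EV's pFDR control derivation assumes i.i.d. p-value/hypothesis
  pairs; under strong correlation control is verified empirically (the
  simulation suite) rather than guaranteed.
- Group sizes are equal in the simulation engine (the bootstrap module
  accepts arbitrary sizes); one-sided tests, weighted/hierarchical FDR
  and FWER-type procedures are out of scope.
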