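# Methods

## Model

The exponentiated Gumbel (EG) family used throughout is
`F(x; α, λ) = exp(−α e^{−λx})` on the whole real line, i.e. the α-th
power of a Gumbel (maximum) CDF — a proportional reversed hazard
family. `α > 0` is the shape, `λ > 0` a rate (units 1/time). Strength
`X ~ EG(α, λ)` and stress `Y ~ EG(β, λ)` are independent with a
*common* λ; then the stress–strength reliability is exactly
`R = P(X > Y) = α/(α+β)`. The common-λ assumption is what makes `R`
free of λ; it is supported in the worked steel data by the two
full-sample fits giving nearly equal rates (0.0071 vs 0.0085), and it
is an assumption, not a tested hypothesis.

Data are *lower record values*: the first observation and every later
one strictly smaller than all predecessors. Ties are not records
(strict inequality). For an EG parent, `α e^{−λX_s}` of the s-th record
is the s-th arrival of a unit-rate Poisson process — Gamma(s, 1) —
which gives the record density, the record CDF (regularized upper
incomplete gamma), the χ²(2n) pivot for the last record, and an exact
O(n) simulator (`X_s = −(1/λ) ln(G_s/α)` with `G_s` a cumulative sum of
standard exponentials). Simulation uses this representation rather than
rejection from long i.i.d. streams: it is exact and has no unbounded
loops.

## Maximum likelihood

From records `x₁ > … > x_n`, `y₁ > … > y_m` the likelihood depends on
the data only through the sums and the last records, giving closed
forms: `λ̂ = (n+m)/(n(x̄−x_n) + m(ȳ−y_m))` — the record-count-weighted
harmonic mean of the two single-sample rate estimates — then
`α̂ = n e^{λ̂x_n}`, `β̂ = m e^{λ̂y_m}`, `R̂ = α̂/(α̂+β̂)`. λ is not
identifiable when both samples hold a single record (the denominator
vanishes); this raises an error rather than returning a boundary value.

The expected information `I(θ)`, `θ = (α, β, λ)`, has closed-form
entries in digamma ψ and trigamma ψ′ (evaluated by scipy's special
functions, valid for large record counts); `I₁₂ = 0`, and the
α–λ / β–λ entries are `(n/(αλ))(ψ(n+1) − ln α)` etc. The covariance
`U = I⁻¹` is computed by generic numerical inversion; the explicit
adjugate/determinant formulas for this sparsity pattern serve as a test
oracle, not as the implementation. The delta method gives
`V(R̂) = CᵀUC` with `C = (β, −α, 0)/(α+β)²`.

### The confidence-interval divisor

The reference convention for the normal interval is
`R̂ ± z_{1−γ/2} √(V(R̂)/n)` with `n` the *strength-record count*. This
is unusual — `V` already decays with sample size through `I⁻¹` — and
the extra `/n` shrinks the interval by √n, so its frequentist coverage
collapses as record counts grow (≈ 0.37 at n = m = 15 for a nominal
0.95). It is nevertheless the convention under which the worked
steel-data interval `(0.4117, 0.7737)` reproduces, so it is the default
for data analysis, with `ci_divisor="none"` exposing the plain
delta-method interval. The simulation harness defaults to `"none"`,
whose coverage approaches nominal as n, m grow (≈ 0.92 at n = m = 30);
at small record counts (n = m ≤ 15) even the plain interval
under-covers somewhat (≈ 0.65 at n = m = 3, ≈ 0.89 at n = m = 15), the
familiar small-sample behavior of Wald-type intervals.

## Bayesian inference

Independent gamma priors (shape/rate) on α, β, λ; defaults
`a_i = b_i = 10⁻⁴`, near-noninformative proper gammas chosen so the
data dominate. α and β have exact gamma full conditionals,
e.g. `α | λ, data ~ Gamma(n + a₁, b₁ + e^{−λx_n})`; λ's conditional is
nonstandard and is updated by one random-walk Metropolis step per sweep
with a `N(λ^(t−1), σ₀²)` proposal. The proposal is symmetric, so the
acceptance probability is the ratio of conditional densities; negative
proposals get log-density −∞ and are simply rejected, which preserves
the target on (0, ∞) without folding. Defaults: T = 55 000 sweeps,
K = 5 000 burn-in, λ initialized at the record MLE (shortens burn-in),
and σ₀ tuned by short pilot runs (doubling/halving toward a 20–45%
acceptance rate; ≈ 0.26 acceptance on the steel records). All
randomness flows through one `SeedSequence`, so a seed makes the whole
run — pilots included — reproducible.

Posterior summaries use the plain chain averages: mean of
`R^(t) = α^(t)/(α^(t)+β^(t))` and the 1/N (not 1/(N−1)) variance. The
HPD interval sorts the post-burn-in R draws and takes the narrowest
window of `⌈(1−γ)N⌉` consecutive order statistics (ties broken at the
lowest start index); the ceiling convention resolves the ambiguity in
the usual index arithmetic.

On the steel records the posterior of R under the default priors has
standard deviation ≈ 0.17 — consistent with the delta-method √V ≈ 0.18
and with the known-λ closed form — so the 95% shortest-window HPD is
wide, ≈ (0.26, 0.90). A much narrower interval would be obtained as
`mean ± z·√(Var/n)` in analogy with the `/n` confidence-interval
convention above, but that is not an HPD interval and the package does
not report it as one.

## Known-scale results

When λ is known the data are rescaled (`x → λ₀x`) so the λ = 1 formulas
apply verbatim. `2αe^{−X_n} ~ χ²(2n)` and independence give
`(R/(1−R))·((1−R̂)/R̂) ~ F(2n, 2m)` exactly, hence an exact interval
with endpoints `1/(1 + (m e^{y_m}/(n e^{x_n})) F_{q; 2m, 2n})` at
`q = 1−γ/2, γ/2` (percentile convention: `F_q` is the 100q-th
percentile). Under gamma priors the posteriors of α and β are
independent gammas and `R = A/(A+B)` has the tilted-Beta density
`c·r^{sₓ−1}(1−r)^{s_y−1}(1−zr)^{−(sₓ+s_y)}` with
`z = 1 − rate_x/rate_y < 1` (often negative). Moments follow from the
Euler integral as `₂F₁` expressions; evaluation relies on scipy's
`hyp2f1` (which continues the series for z < 0 internally), with a
Pfaff transformation as a fallback, and all gamma/beta factors in log
space. Sampling from this posterior uses the exact gamma-ratio
construction by default; an accept–reject sampler with a
Beta(sₓ, s_y) envelope (bound `(1−z)^{−(sₓ+s_y)}` for z > 0, 1
otherwise) is provided as the documented indirect alternative and is
required by the tests to agree in distribution.

## Numerical choices

* All EG density/CDF evaluations clip the inner exponent at 709 before
  exponentiating, so extreme left-tail arguments underflow to 0 instead
  of overflowing.
* The full-sample MLE profiles the likelihood — `α(λ) = n/Σe^{−λxᵢ}` —
  and maximizes over λ with a bounded Brent search (xatol 10⁻¹³) on
  `[10⁻⁸, 10/mean|x|]`, widening the bracket on boundary hits.
  Degenerate (constant) samples and n < 3 are rejected.
* K-S p-values use scipy's one-sample conventions (exact for small n).
  With plug-in estimated parameters the test is conservative; this is
  documented, not corrected.
* `fisher_information` raises with a condition-number diagnostic only
  when inversion genuinely fails or produces non-finite entries;
  extreme-but-finite parameter ratios (common at tiny record counts)
  are allowed through.

## Synthetic data and what the tests show

Simulated studies draw record sequences directly from the EG
gamma-arrival representation — they emulate exactly the data-generating
process the model assumes (i.i.d. EG parents, common λ, strict-tie-free
continuous data). Passing distributional and coverage tests therefore
validates the *inference machinery*, not the adequacy of the EG model
for any real data; real sequences with ties, drift, or dependence
between stress and strength are outside what the tests exercise.
Operating-characteristic defaults (e.g. 20 000 pivot replicates, 5 000
coverage replicates, n, m between 3 and 30) were chosen to make
Monte-Carlo error small relative to the effects being checked.

## Limitations

* Upper records, k-th records, inter-record times, and censoring
  schemes are out of scope.
* Only the delta-method interval is offered on the ML side (no
  bootstrap/profile intervals), and only acceptance-rate plus trace
  export on the MCMC side (no formal convergence diagnostics).
* The `/n` interval convention is retained for reproduction despite its
  poor frequentist calibration; use `ci_divisor="none"` for coverage.
* Prior hyperparameters, chain length, and proposal scale for the
  worked example are package defaults (the analysis is robust to them
  only in the vague-prior regime).
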