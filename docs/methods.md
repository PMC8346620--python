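# Methods

## Model and decision rule

Every causal question "does Y drive X (given Z)?" is cast as a
model-selection problem between two nested linear autoregressions of
the target X, fitted equation-by-equation by OLS (the Gaussian MLE of
the coefficients): the restricted model (X on p lags of itself and of
each conditioning node in Z) and the unrestricted model (the same plus
p lags of Y). Each fitted model is assigned a description length in
nats; Y → X is declared iff the unrestricted description is strictly
shorter. No intercept is fitted by default — the benchmark generator is
zero-mean — and a `--intercept` flag adds one for real data.

All models in one comparison see the same response sample: designs are
trimmed by the maximum lag order, and `n` in every code-length formula
is the post-trimming row count `n_eff`, the sample size the likelihood
actually describes.

## Coding schemes

**NML** (default). The stochastic complexity of the Gaussian regression
family, obtained by normalizing the maximized likelihood over the data
region whose MLEs fall in the ball β'Sβ ≤ R, τ ≥ τ₀ (S = X'X the Gram
matrix). With the Fisher determinant |I(β,τ)| = |S|/(2τ^{k+2}) and the
closed-form integral of its square root over that region, the code
length evaluated at the MLE plug-ins τ̂₀ = RSS/n and R̂ = β̂'Sβ̂/n is

    L = (n/2) ln(2π τ̂₀) + n/2 + (k/2) ln(n/2) − ln Γ(k/2)
        + (k/2) ln(R̂/τ̂₀) − 2 ln k .

The (k/2) ln(R̂/τ̂₀) term prices parameters by the signal-to-noise
ratio of the fit; −2 ln k and −ln Γ(k/2) come from the volume of the
k-ball. We rederived this expression from the normalized-likelihood
integral and it matches term-for-term up to an additive constant
(3/2) ln 2 that is common to all models and cancels in every decision.

**TP** — crude two-part code, (n/2) ln(RSS/n) + (k/2) ln n: fit cost
plus half a log-n per parameter.

**MIX** — mixture / SIC (Laplace-approximated Bayes marginal),
(n/2) ln(RSS/n) + (1/2) ln det(S/τ̂₀).

All logarithms are natural, uniformly. A uniform base change rescales
every code length by the same factor and cannot flip the sign of a
difference; mixing bases within one formula could, so none are mixed.
Γ(k/2) is evaluated through the log-gamma function.

**GCA baseline** — the classical conditional Granger F-test,
F = ((RSS_r − RSS_u)/q)/(RSS_u/(n_eff − k_u)), edge iff the
F(q, n_eff − k_u) tail probability is below α. It uses the same lag
order as the MDL schemes for a fair comparison.

## Network assembly

For every ordered pair (i, j) the pair decision runs with conditioning
set Z = all remaining nodes (`conditional`, default) or Z = ∅
(`pairwise`). Conditional is the default because pairwise Granger
analysis detects genuine two-step predictive flow: in the benchmark
network six null pairs (1→4, 1→5, 1→6, 2→3, 2→6, 4→6) sit on two-step
paths and carry real pairwise information at lag 2, so pairwise mode
reports them as edges — they are information flows, just not direct
ones. Decisions i→j and j→i are independent (the benchmark contains
reciprocal pairs), F = 0 exactly yields no edge, and degenerate fits
(zero residual, detected at a 1e−12 relative floor against the model's
explained scale) yield "no edge" with a warning rather than aborting a
network loop. Fits are memoized per (target, predictor-set), which cuts
a 6-node conditional network from 60 to 36 regressions.

## Lag order

The benchmark uses order 2 everywhere — the generator's own order.  For
real data, `order="mdl"` selects, per model, the uniform order in
1..p_max (default 5) minimizing that model's own code length, with all
candidates trimmed at p_max rows so they describe the same sample.  On
the benchmark, order selection changes the Monte-Carlo metrics by well
under the replicate noise.

## Synthetic benchmark

`simulator` implements the fixed 6-node order-2 VAR (nine cross-node
influences; spectral radius of its 12×12 companion matrix ≈ 0.93) plus
a generic coefficient-specified VAR. Innovations are independent
zero-mean Gaussians; each node's noise **variance** is drawn uniformly
per replicate from a configurable range — low [1.5, 2], moderate
[2.5, 3], high [5.5, 6]. Simulation starts from rest and discards 500
burn-in samples (enough for the autocorrelation, which decays on a
~15-step scale, to forget the origin). A fixed seed gives bit-identical
output (numpy PCG64).

What the generator does *not* emulate: cross-correlated or heavy-tailed
innovations, nonstationarity, observation noise, and hemodynamic
filtering/downsampling of the kind fMRI data adds. Passing benchmarks
here therefore demonstrates correctness of the decision machinery on
well-specified linear Gaussian data, not robustness to those real-data
effects.

Because the decision statistics depend on the data only through
scale-free ratios (RSS ratios, R̂/τ̂₀, |S/τ̂₀|), multiplying all noise
variances by a common factor leaves every decision unchanged; only the
*heterogeneity* of per-node variances matters, and that effect is
small.

## Benchmark metrics

TPR and TNR are micro-averages over edge decisions pooled across
replicates (9 true edges and 21 true absences per replicate); the
ground-truth rate is the fraction of replicates whose whole 30-entry
network is exact. Failed replicates count as all-false networks so
denominators stay fixed. The mutual information between two networks
treats their paired off-diagonal indicators as samples from a joint
binary distribution (0·log 0 = 0, natural log); this choice of sample
space — edgewise pairing — is this package's definition.

## Reference values and known deviations

At 1000 replicates, length 1000, low noise, conditional mode, order 2,
this implementation yields (seed 1): NML TPR 100, TNR 98.9, exact-match
rate ≈ 79%; F-test (α = 0.05) TNR 95.1, exact-match ≈ 37%. Published
figures for this benchmark report NML exact-match rates above 90% with
TNR ≈ 99.7 that are roughly constant in data length, a behaviour no
ln(n)-growing MDL penalty reproduces at small n (our NML keeps TPR ≈ 98
at length 150 where a markedly stronger penalty would trade recall for
specificity). We implement the NML expression exactly as derived above
and report what it produces; no constant is tuned toward published
tables. The TP/MIX baselines use the standard crude-two-part and SIC
forms stated above, which at these dimensions penalize slightly more
heavily than NML.

## Numerical choices

- OLS via SVD-based least squares; rank-deficient designs fall back to
  the minimum-norm solution with a warning (keeps Monte-Carlo loops
  alive on pathological draws).
- Negative F statistics from round-off are clamped to 0.
- MIX uses `slogdet`; a non-positive determinant raises a degenerate-fit
  error.
- Explosive simulations (state magnitude beyond 1e100 or non-finite)
  raise immediately rather than overflowing silently.

## Problem sizes used by the test suite

The bundled acceptance checks run the Monte-Carlo tables at 300
replicates per condition and the calibration check at ~4200 F-test
decisions; `scripts/acceptance.py` runs the full 1000-replicate
protocol. These sizes put the Monte-Carlo standard error of an
exact-match rate near 1.5–2.5 percentage points (300 replicates) and
below 1.5 points (1000 replicates).
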