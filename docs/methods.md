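# Methods

## Problem and model

`privimpute` performs regression analysis on incomplete tabular data that is
jointly held by mutually distrusting parties (the motivating case is
electronic-health-record cohorts spread across institutions).  The statistical
procedure is multiple imputation with chained equations (MICE): each
incomplete variable is regressed on the remaining variables using the
currently complete rows, its missing entries are replaced by model
predictions (plus noise for continuous variables), and the pass moves on to
the next column, re-using freshly imputed values.  The whole pass is repeated
`k` times (default 5) with independent noise draws; a final-analysis
regression of the outcome on each completed dataset yields `k` coefficient
vectors whose arithmetic mean — Rubin's rules in their simplest form — is the
pooled model.  For inference we complete the rule with the standard total
variance `T = W̄ + (1 + 1/k)·B` (mean within-imputation sampling variance
plus inflated between-imputation variance) and two-sided normal-approximation
Wald p-values.  No Barnard–Rubin degrees-of-freedom correction is applied.

Everything after the initial sharing happens on protected values.  Missing
data positions (the 0/1 mask) are public by design: the protocols leak where
data is missing, never what it is.  The adversary model is honest-but-curious
throughout.

## Cryptographic layer

**Fixed-point ring.**  Reals are encoded as `round(x·2^32)` in the ring
Z_{2^192}: 32 fractional bits, 64 bits for a whole fixed-point value, and 64
padding bits as the statistical-security margin.  A power-of-two modulus
makes two's-complement embedding and truncation cheap.  Encoding is exact to
2^-32; values must stay below 2^31 in magnitude (regression inputs are
row-normalized and/or standardized, so this is comfortable).

**Sharing and multiplication.**  Additive secret sharing between two
computing parties plus a trusted dealer: the dealer distributes correlated
randomness (matrix Beaver triples — one triple per matrix product to keep
round counts low) and never sees a data share.  Multiplication opens the two
Beaver-masked differences, which are uniform on the ring.  Triples are
single-use; reuse raises.

**Truncation.**  After each product the double-scale result is divided by
2^32 with the two-party local probabilistic protocol (one party shifts its
share, the other applies the complement trick).  The result is within one
unit in the last place of exact division except with probability about
2^-64 per element, provided the shares are uniformly distributed — for this
reason *every* shared value in the engine, including shared public constants
and shared zeros, is created with fresh randomness.  The protocol is
inherently two-party; the engine raises for other party counts.  Measured
drift over 1000 chained multiplications is below 1e-7.

**Sigmoid.**  Secure protocols cannot evaluate exp, so logistic regression
uses a Chebyshev interpolant of the sigmoid, evaluated with the Clenshaw
recurrence on shares (degree d costs d elementwise Beaver products).  The
default is degree 11 on [-8, 8] — the smallest degree whose uniform error is
below 1e-2 (measured 6.2e-3); degree 9 is slightly cheaper but misses that
bound (1.3e-2).  The approximant is monotone on [-5.5, 5.5] and its values
on [-8, 8] stay inside [-0.02, 1.02].  Plaintext evaluation clips inputs to
the interval; clipping is impossible on shares, so callers keep `X·w` inside
the interval by standardizing features (see below).  A degree-9 log
approximant on [0.01, 1] is available for loss reporting only.

**Small-matrix inversion.**  The closed-form regression path inverts the
(at most 3×3) row-normalized Gramian under sharing: the adjugate is
polynomial in the entries (18 elementwise Beaver products for the 3×3
cofactors), and the determinant reciprocal comes from 20 Newton–Raphson
iterations `r ← r(2 − d·r)` seeded with the public value `2/B`, where
`B = 2·(tr/d)^d` upper-bounds the determinant of an SPD matrix by AM–GM.
Only the trace is revealed, rounded up to 16 fractional bits (configurable);
this is the protocol's one extra leakage beyond the public mask and the
standardization moments, and it is deliberate.  Convergence degrades when
`B/det` is very large, i.e. for badly conditioned Gramians; MICE Gramians on
standardized simulation data have condition numbers well inside the safe
range (achieved accuracy ~1e-9, contract 1e-3).

## Regression

Both regressions run identically in the plaintext and secure engines.

* **Linear.**  `C = X̃ᵀX̃/m`, `R = X̃ᵀy/m` (bias column appended last).  With
  fewer than four columns the normal equations are solved via the inverse
  above; otherwise gradient descent `w ← w + (R − C·w)·η` runs on the
  precomputed moments.  Normalizing by the row count makes the update the
  mean-squared-loss gradient, so the stable step range is sample-size
  independent.  Defaults η = 0.1, 500 epochs: for standardized data the
  spectrum of `C` lies in roughly [0.5, 2], giving a contraction of
  ~0.95^500 ≈ 1e-11 — i.e. convergence to the closed form well below the
  fixed-point resolution.  A mini-batch option recomputes per-batch moments.
* **Logistic.**  Full-batch gradient descent on the mean cross-entropy
  gradient `X̃ᵀ(σ̃(X̃w) − y)/m` with the polynomial sigmoid σ̃, defaults
  η = 1.0, 200 epochs.  Features are standardized by column moments first;
  the moments are computed under sharing and *revealed* as aggregate
  statistics (documented leakage), which keeps `X̃w` inside the sigmoid's
  interval.  Fitted weights are mapped back to the raw feature scale.
* **Prediction.**  Linear predictions optionally add per-entry normal noise
  (the imputation-noise parameter is a variance, default 0.01, i.e. sd 0.1),
  drawn in plaintext by the coordinating party and added to its share.
  Logistic predictions are probabilities; they are *not* thresholded inside
  the pipelines, because thresholding a shared value would need a secure
  comparison.  Binary imputation quality is assessed by thresholding at 0.5
  at evaluation time, after decoding.
* A divergence detector (weight norm above 1e6) guards plaintext gradient
  descent; under sharing a norm check would leak, so divergence surfaces at
  decode time instead.

## The plaintext reference as oracle

The reference pipeline executes the same operation sequence in float64,
including the Chebyshev sigmoid (the exact sigmoid is available as an
option).  Its role is to isolate the cryptographic layer: with shared noise
draws, any plaintext/secure difference measures fixed-point quantization and
truncation alone.  Measured end-to-end agreement of pooled coefficients is
~1e-9 on all six scenarios at n = 500, against a stated tolerance of 1e-2.

## Partitioned (aggregation-style) variant

The second protocol family mirrors multiparty-homomorphic-encryption
dataflow: each party keeps its horizontal partition in the clear, computes
local Gramians/bias columns/complete-row filters itself, and only aggregated
values circulate in protected form.  The backend is a contract (slot count
8192 and scale 2^34 as metadata, an operation log for aggregations and
plaintext×protected vs protected×protected products); its default
implementation is the secret-sharing engine, so a lattice scheme honoring
the surface could replace it without touching the callers.  Design points:

* vertical × horizontal products are computed locally (zero communication)
  and yield additively partitioned results; products with one aggregated
  operand are the only other multiplication shape needed;
* linear gradient descent re-aggregates the weights each epoch while parties
  update additive weight summands locally; the closed form aggregates the
  Gramian and inverts it under sharing (aggregate-then-invert);
* logistic regression aggregates the bias-extended data matrix and its
  transpose exactly once before the loop — aggregating data rather than
  weights, which the operation log verifies (2 aggregations regardless of
  epoch count);
* in chained imputation each party receives back only the imputed entries of
  its own rows and stores them in the clear like the rest of its partition;
  per-party complete-row counts are therefore visible, a documented leakage
  of the partitioned design.

Pooling equivalence — distributed fit equals centralized fit on pooled data
for any 1–4-party split — is the variant's defining correctness property and
is tested directly.

## Synthetic scenarios

Six designs, all with a single incomplete variable (column 0) and outcome
`Y = 1 + Σᵢ Xᵢ + ε` computed *before* masking, with heteroscedastic noise
`ε ~ N(0, |1 + ΣᵢXᵢ|/100)` per row — the absolute value is required for the
variance to be well defined row-wise:

| id | variables | incomplete variable | mechanism | rate |
|----|-----------|---------------------|-----------|------|
| 1  | 10 i.i.d. N(0,1) | continuous | MCAR | 0.30 |
| 2  | as 1, col 0 ~ Bernoulli(0.5) | binary | MCAR | 0.30 |
| 3  | X₂ ~ U(−3,3), X₁ ~ N(0.2−0.5X₂, 1) | continuous | MAR (selection on X₂) | 0.50 |
| 4  | as 3, X₁ ~ Bernoulli(σ(0.2−0.5X₂)) | binary | MAR | 0.50 |
| 5  | as 3 | continuous | MNAR (selection on X₁) | 0.55 |
| 6  | as 4 | binary | MNAR | 0.60 |

MAR/MNAR selection is logistic with unit slope and an intercept calibrated
by bisection to the target rate; slope and rate are configurable.  The ten
scenario-1 variables are mutually independent.  The binary variable of
scenarios 4/6 uses the same conditional-mean structure as scenario 3 (a
self-consistent Bernoulli success probability in (0,1)).  A balanced binary
outcome variant (median-centered linear predictor through a sigmoid) serves
the logistic final-analysis path.

What the generator does *not* emulate: correlated predictors in scenarios
1–2, site heterogeneity (covariate shift between partitions), more than one
incomplete variable, non-logistic selection functions, and real-EHR feature
distributions.  Passing tests therefore demonstrate protocol correctness and
the stated statistical limits under these designs, not imputation quality on
real clinical data.

## Evaluation metrics

Coefficient recovery over repeated runs is summarized by
`bias = ‖EΘ − Θ̃‖₂`, `sd = sqrt(E‖Θ − EΘ‖₂²)` and
`rmse = sqrt(E‖Θ − Θ̃‖₂²)`; `rmse² = bias² + sd²` holds identically.
Imputation error is restricted to originally missing entries (absolute-error
mean/sd for continuous, 0.5-threshold accuracy and Mann–Whitney AUC for
binary).  Final-analysis error uses the pooled coefficients on the completed
data.  The discrepancy count between a base and a target analysis is the
number of variables with base p ≤ 0.05 whose target p exceeds 0.05 or whose
coefficient changes sign; the definition is directional, and the bias term
is excluded.

## Numerical and design choices

* Column visit order in the chained pass is ascending index; one sweep per
  imputation (configurable).  "Complete rows" means fully observed under the
  current, partially updated mask.  Prediction inputs are `(D ∘ M)` with the
  loop-time mask, so still-unimputed later columns enter as zeros — this is
  the chained pass's literal definition and differs from some MICE
  conventions that use all current values.
* The outcome is never an imputation predictor.  With the fits deterministic,
  fresh imputation-noise draws are the only stochastic difference between
  the k imputations.
* Problem sizes in the test-suite and acceptance runs: scenario studies at
  n = 500 (all modes), the large-sample imputation-error study at n = 5000
  with 100 plaintext repetitions and 5 repetitions per secure mode, and the
  analytic-limit check at n = 100 000 in plaintext.  These match the study
  designs the scenarios define while keeping secure-mode arithmetic (Python
  big-integer ring operations) at a few minutes end to end.
* The coefficient-recovery check on the informative collinear design
  (X₁ = 2X₂ + N(0, 0.1), 30% MCAR) runs with imputation-noise variance 0:
  conditional-mean imputation is the regime in which the final analysis
  recovers the generating coefficients exactly in expectation.  With noise
  matching the conditional residual spread, covariate imputation that
  excludes the outcome attenuates the orthogonal component of the
  coefficient (a known property of y-free imputation models), which is
  visible as bias on strongly collinear designs.
* Seeds: one global seed derives per-run data seeds, imputation-noise seeds,
  and per-mode cryptographic seeds (blake2s, below 2^31).  Plaintext runs
  are byte-reproducible; secure runs are decode-equal across repeats.

## Known limitations

Two computing parties (the truncation protocol is two-party); semi-honest
security only, no MACs or malicious-security verification; no constant-time
guarantees (this is a research artifact, not hardened crypto); MAR-oriented
imputation only (scenarios 5–6 measure behaviour under MNAR, the model does
not correct for it); binary columns are imputed with probabilities, so
downstream fits see values in [0,1] rather than hard labels; the
lattice/CKKS backend is a contract with a secret-sharing stand-in, not an
implementation of lattice cryptography.
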