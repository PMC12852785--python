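# privimpute

Multiple imputation with chained equations (MICE) under secure multiparty
computation — for biostatisticians and privacy engineers who need to impute
and analyze incomplete tabular data that is jointly held by parties who
cannot pool it in the clear (the canonical case: patient records spread
across hospitals).

The statistical core is standard MICE with Rubin's-rules pooling.  Each
incomplete variable Xⱼ is regressed on the remaining variables using the
currently complete rows, its missing entries are filled with predictions
X̃w (+ N(0, 0.01) noise for continuous variables, a logistic model for
binary ones), and the pass continues column by column, re-using freshly
imputed values.  This is repeated k = 5 times; a final regression of the
outcome y on each completed dataset gives coefficient vectors Θ⁽¹⁾…Θ⁽ᵏ⁾,
pooled as their arithmetic mean, with total variance
T = W̄ + (1 + 1/k)·B for Wald inference.

What makes the package distinctive is that the whole procedure runs on
**additively secret-shared data**: reals are fixed-point encoded in the ring
Z₂¹⁹² (32 fractional bits, 64 padding bits of statistical security), shared
between two computing parties aided by a trusted dealer, multiplied with
Beaver triples, and passed through a Chebyshev-polynomial sigmoid for
logistic steps — only the missingness mask and the pooled final model are
ever revealed.  A second, aggregation-style variant keeps horizontal data
partitions local in the clear and protects only aggregated values, mirroring
multiparty-homomorphic-encryption dataflow behind a pluggable backend.  A
bit-compatible plaintext reference pipeline executes the identical operation
sequence in float64 and serves as the correctness oracle: with shared noise
draws, secure and plaintext pooled coefficients agree to ~1e-9.

## Worked example

Impute and analyze simulation scenario 3 (X₂ ~ U(−3,3),
X₁ ~ N(0.2 − 0.5X₂, 1) with 50% of X₁ missing at random,
Y = 1 + X₁ + X₂ + ε) at n = 500, in both the plaintext reference and the
secret-shared pipeline:

```python
import numpy as np
from privimpute import gen_scenario, ScenarioSpec
from privimpute.pipeline import run_once
from privimpute.metrics import imputation_error

ds = gen_scenario(ScenarioSpec(scenario_id=3, n_individuals=500, seed=7))
task = ds.task()
plain = run_once("plaintext", task, k=5, seed=11)
secure = run_once("smc", task, k=5, seed=11)
print("plaintext pooled coefficients:", np.round(plain["pooled"], 4))
print("secure    pooled coefficients:", np.round(secure["pooled"], 4))
print("max |difference|: %.2e" % np.max(np.abs(plain["pooled"] - secure["pooled"])))
mean, sd = imputation_error(secure["imputed"][0], ds.X_complete, ds.mask)
print(f"masked-entry |imputed - truth|: mean={mean:.3f} sd={sd:.3f}")
print("protocol cost:", secure["protocol"])
```

prints

```
plaintext pooled coefficients: [1.0031 0.9766 0.9517]
secure    pooled coefficients: [1.0031 0.9766 0.9517]
max |difference|: 2.25e-10
masked-entry |imputed - truth|: mean=0.783 sd=0.627
protocol cost: {'messages': 1794, 'opens': 897, 'triples': 440}
```

The pooled coefficients sit near the generating values Θ̃ = (1, 1) with
intercept 1 (order: X₁, X₂, bias); the secure run reproduces the reference
to fixed-point resolution.  The masked-entry absolute error ~0.78 reflects
the conditional spread of X₁ given X₂ (sd 1): imputation recovers the
predictable part of X₁ and the half-normal residual remains.  The protocol
log counts the messages, masked openings, and Beaver triples the run
consumed.

The same studies are available from the shell:

```bash
privimpute simulate --scenario 1 --n 500 --seed 3 --out data/
privimpute run --mode smc --scenario 3 --n 500 --reps 2 --k 5 --seed 1 --out report.json
privimpute benchmark --scenarios 1,3 --sizes 500 --modes plaintext,smc,mhe --reps 5 --out table.csv
```

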