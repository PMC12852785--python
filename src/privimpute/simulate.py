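"""Synthetic-study generators: six missing-data simulation designs.

Scenarios (one incomplete variable each, always column 0):

1. ten i.i.d. standard-normal variables; column 0 missing completely at
   random at rate 0.30;
2. as 1 with column 0 ~ Bernoulli(0.5);
3. two variables, X2 ~ U(-3, 3) and X1 ~ N(0.2 - 0.5 X2, 1); X1 missing at
   random (selection logistic in the observed X2) at rate 0.50;
4. as 3 with X1 ~ Bernoulli(sigmoid(0.2 - 0.5 X2)), rate 0.50;
5. as 3 but missing *not* at random: the selection is logistic in X1
   itself, rate 0.55;
6. as 4 with MNAR selection in X1, rate 0.60.

The outcome is ``Y = 1 + sum_i X_i + eps`` with a heteroscedastic per-row
noise variance ``|1 + sum_i X_i| / 100`` (the absolute value makes the
row-wise variance well defined for negative linear predictors), computed on
the complete data *before* masking.  MAR/MNAR selection uses unit slope and
an intercept calibrated by bisection to hit the target rate in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chebyshev import sigmoid
from .mice import BINARY, CONTINUOUS, ImputationTask

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "gen_scenario",
    "gen_binary_outcome",
    "CalibrationError",
    "DEFAULT_MISSING_RATES",
]

DEFAULT_MISSING_RATES = {1: 0.30, 2: 0.30, 3: 0.50, 4: 0.50, 5: 0.55, 6: 0.60}
_MECHANISMS = {1: "MCAR", 2: "MCAR", 3: "MAR", 4: "MAR", 5: "MNAR", 6: "MNAR"}
_BINARY_SCENARIOS = {2, 4, 6}


class CalibrationError(RuntimeError):
    """Selection-intercept bisection could not reach the target rate."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Design parameters of one simulation scenario."""

    scenario_id: int
    n_individuals: int = 500
    seed: int = 0
    missing_rate: float | None = None  # None -> the scenario's stated rate
    selection_slope: float = 1.0
    noise_variance: float = 0.01  # imputation-noise variance carried to the task

    def __post_init__(self) -> None:
        if self.scenario_id not in DEFAULT_MISSING_RATES:
            raise ValueError("scenario_id must be in 1..6")
        rate = self.rate
        if not 0.0 < rate < 1.0:
            raise ValueError("missing rate must lie strictly in (0, 1)")

    @property
    def rate(self) -> float:
        if self.missing_rate is not None:
            return self.missing_rate
        return DEFAULT_MISSING_RATES[self.scenario_id]

    @property
    def n_variables(self) -> int:
        return 10 if self.scenario_id in (1, 2) else 2

    @property
    def mechanism(self) -> str:
        return _MECHANISMS[self.scenario_id]

    @property
    def column_kinds(self) -> tuple[str, ...]:
        first = BINARY if self.scenario_id in _BINARY_SCENARIOS else CONTINUOUS
        return (first,) + (CONTINUOUS,) * (self.n_variables - 1)


@dataclass
class SimulatedDataset:
    """Ground-truth matrix, missingness mask, outcome, and the truth record."""

    X_complete: np.ndarray
    mask: np.ndarray
    y: np.ndarray
    theta: np.ndarray  # (n_variables + 1,), intercept first
    spec: ScenarioSpec
    outcome_kind: str = "continuous"
    column_kinds: tuple[str, ...] = field(default=())

    def task(self, noise_variance: float | None = None) -> ImputationTask:
        """Zero-fill the masked entries and package everything for imputation."""
        data = self.X_complete * self.mask
        return ImputationTask(
            data=data,
            mask=self.mask,
            y=self.y,
            column_kinds=self.column_kinds,
            noise_variance=(
                self.spec.noise_variance if noise_variance is None else noise_variance
            ),
        )


def calibrate_intercept(v: np.ndarray, slope: float, rate: float,
                        tol: float = 1e-10) -> float:
    """Bisection for ``a`` such that ``mean(sigmoid(a + slope v)) = rate``."""
    lo, hi = -60.0, 60.0
    f = lambda a: float(np.mean(sigmoid(a + slope * v))) - rate
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError(f"target rate {rate} unreachable by intercept shift")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _draw_variables(spec: ScenarioSpec, rng) -> np.ndarray:
    n = spec.n_individuals
    sid = spec.scenario_id
    if sid in (1, 2):
        X = rng.standard_normal((n, 10))
        if sid == 2:
            X[:, 0] = rng.binomial(1, 0.5, n)
        return X
    x2 = rng.uniform(-3.0, 3.0, n)
    mean1 = 0.2 - 0.5 * x2
    if sid in (3, 5):
        x1 = mean1 + rng.standard_normal(n)
    else:  # 4, 6: binary incomplete variable with the same mean structure
        x1 = rng.binomial(1, sigmoid(mean1)).astype(float)
    return np.column_stack([x1, x2])


def _draw_mask(spec: ScenarioSpec, X: np.ndarray, rng) -> np.ndarray:
    n = spec.n_individuals
    if spec.mechanism == "MCAR":
        p = np.full(n, spec.rate)
    else:
        driver = X[:, 1] if spec.mechanism == "MAR" else X[:, 0]
        a = calibrate_intercept(driver, spec.selection_slope, spec.rate)
        p = sigmoid(a + spec.selection_slope * driver)
    missing = rng.uniform(size=n) < p
    mask = np.ones(X.shape, dtype=int)
    mask[missing, 0] = 0
    return mask


def gen_scenario(spec: ScenarioSpec) -> SimulatedDataset:
    """Generate one dataset: variables, missingness mask, and linear outcome.

    Fully deterministic from ``spec.seed`` (a single generator consumed in a
    fixed order: variables, selection, outcome noise).
    """
    rng = np.random.default_rng(spec.seed)
    X = _draw_variables(spec, rng)
    mask = _draw_mask(spec, X, rng)
    theta = np.ones(spec.n_variables + 1)
    lp = theta[0] + X @ theta[1:]
    eps = rng.normal(0.0, np.sqrt(np.abs(lp) / 100.0))
    y = lp + eps
    return SimulatedDataset(
        X_complete=X,
        mask=mask,
        y=y.reshape(-1, 1),
        theta=theta,
        spec=spec,
        outcome_kind="continuous",
        column_kinds=spec.column_kinds,
    )


def gen_binary_outcome(spec: ScenarioSpec) -> SimulatedDataset:
    """Variant with a balanced binary outcome, for the logistic final analysis.

    The linear predictor is median-centered before the Bernoulli draw, so the
    outcome prevalence is ~0.5 by construction.
    """
    ds = gen_scenario(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    lp = ds.theta[0] + ds.X_complete @ ds.theta[1:]
    prob = sigmoid(lp - np.median(lp))
    ds.y = rng.binomial(1, prob).astype(float).reshape(-1, 1)
    ds.outcome_kind = "binary"
    return ds
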