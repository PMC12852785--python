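"""Benchmark driver: one entry point per study, shared by the CLI and tests.

``run_once`` executes a full multiple-imputation analysis in one of three
modes -- ``plaintext`` (the float64 reference), ``smc`` (every value secret
shared) or ``mhe`` (horizontally partitioned, aggregation-style) -- and
decodes the results.  The imputation-noise seed is shared across modes, so
runs with the same seed differ only by their arithmetic layer; the
cryptographic randomness is derived separately per mode.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .distributed import ShareBackend, mhe_mice_analyze
from .engine import PlainEngine, SecureEngine
from .fixedpoint import DealerContext
from .metrics import (
    RunMetrics,
    imputation_error,
    prediction_error,
    summarize_analysis,
    theta_stats,
    discrepancy_count,
)
from .mice import BINARY, CONTINUOUS, FitSpec, ImputationSpec, multiple_impute_analyze
from .simulate import ScenarioSpec, SimulatedDataset, gen_binary_outcome, gen_scenario

__all__ = ["run_once", "run_study", "benchmark"]


def derive_seed(seed: int, *tags) -> int:
    """Deterministic sub-seed below 2^31 from a global seed and string tags."""
    text = ":".join([str(seed), *map(str, tags)])
    return int.from_bytes(hashlib.blake2s(text.encode()).digest()[:4], "big") % (2**31)


def run_once(
    mode: str,
    task,
    k: int = 5,
    seed: int = 0,
    parties: int = 3,
    imputation_spec: ImputationSpec | None = None,
    final_spec: FitSpec | None = None,
    keep_imputed: bool = True,
):
    """One impute-and-analyze study; returns decoded arrays plus protocol stats."""
    final_spec = final_spec or FitSpec("linear")
    if mode == "plaintext":
        eng = PlainEngine()
        res = multiple_impute_analyze(
            eng, task, imputation_spec, final_spec, k, seed, keep_imputed
        )
        pooled = np.asarray(res.pooled, dtype=float).ravel()
        coef_rows = np.asarray(res.coefficients, dtype=float)
        imputed = res.imputed_datasets
        protocol = {}
    elif mode == "smc":
        eng = SecureEngine(DealerContext(seed=derive_seed(seed, "smc")))
        res = multiple_impute_analyze(
            eng, task, imputation_spec, final_spec, k, seed, keep_imputed
        )
        pooled = eng.reveal(res.pooled).ravel()
        coef_rows = eng.reveal(res.coefficients)
        imputed = [eng.reveal(d) for d in res.imputed_datasets] if keep_imputed else None
        log = eng.ctx.log
        protocol = {
            "messages": log.messages,
            "opens": log.opens,
            "triples": int(sum(log.triples_issued.values())),
        }
    elif mode == "mhe":
        backend = ShareBackend(DealerContext(seed=derive_seed(seed, "mhe")))
        cuts = np.array_split(np.arange(task.shape[0]), parties)
        res = mhe_mice_analyze(
            [task.data[c] for c in cuts],
            [task.y[c] for c in cuts],
            [task.mask[c] for c in cuts],
            task.column_kinds,
            backend=backend,
            imputation_spec=imputation_spec,
            final_spec=final_spec,
            k=k,
            seed=seed,
            noise_variance=task.noise_variance,
            keep_imputed=keep_imputed,
        )
        pooled = backend.decrypt(res.pooled).ravel()
        coef_rows = backend.decrypt(res.coefficients)
        imputed = (
            [np.vstack(blocks) for blocks in res.imputed_datasets]
            if keep_imputed
            else None
        )
        protocol = dict(backend.oplog)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "pooled": pooled,
        "coef_rows": coef_rows,
        "imputed": imputed,
        "protocol": protocol,
    }


def _make_dataset(scenario: int, n: int, seed: int, binary_outcome: bool,
                  noise_variance: float) -> SimulatedDataset:
    spec = ScenarioSpec(scenario, n, seed=seed, noise_variance=noise_variance)
    return gen_binary_outcome(spec) if binary_outcome else gen_scenario(spec)


def _imputation_metrics(result, ds: SimulatedDataset, task) -> dict:
    """Masked-entry imputation quality averaged over the k completed datasets."""
    out = {}
    kinds = np.array(task.column_kinds)
    incomplete = (task.mask == 0).any(axis=0)
    for label, is_binary in ((CONTINUOUS, False), (BINARY, True)):
        cols = np.where(incomplete & (kinds == label))[0]
        if cols.size == 0:
            continue
        vals = [
            imputation_error(
                d[:, cols], ds.X_complete[:, cols], task.mask[:, cols], binary=is_binary
            )
            for d in result["imputed"]
        ]
        a, b = np.mean(vals, axis=0)
        out.update(
            {"accuracy": a, "auc": b} if is_binary else {"abs_mean": a, "abs_sd": b}
        )
    return out


def _final_metrics(result, task, logistic: bool) -> dict:
    vals = [
        prediction_error(result["pooled"], d, task.y, logistic=logistic)
        for d in result["imputed"]
    ]
    a, b = np.mean(vals, axis=0)
    return {"accuracy": a, "auc": b} if logistic else {"abs_mean": a, "abs_sd": b}


def run_study(
    mode: str,
    scenario: int,
    n: int,
    reps: int = 1,
    k: int = 5,
    seed: int = 0,
    parties: int = 3,
    noise_variance: float = 0.01,
    binary_outcome: bool = False,
    base_mode: str | None = None,
) -> dict:
    """Repeated runs of one scenario; per-run metrics plus the aggregate.

    Each repetition draws a fresh dataset (seed derived from the global seed
    and the run index).  When ``base_mode`` is given, a reference analysis in
    that mode is run on the same data/seed and the discrepancy count of this
    run's analysis against it is reported.  Failed runs are recorded and
    skipped.
    """
    final_kind = "logistic" if binary_outcome else "linear"
    runs, failures, pooled_rows = [], [], []
    for r in range(reps):
        data_seed = derive_seed(seed, "data", r)
        noise_seed = derive_seed(seed, "noise", r)
        ds = _make_dataset(scenario, n, data_seed, binary_outcome, noise_variance)
        task = ds.task()
        try:
            result = run_once(
                mode, task, k=k, seed=noise_seed, parties=parties,
                final_spec=FitSpec(final_kind),
            )
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as err:
            failures.append({"run": r, "error": str(err)})
            continue
        metrics = RunMetrics(
            scenario=scenario, n=n, method=mode, seed=data_seed,
            imputation=_imputation_metrics(result, ds, task),
            final_analysis=_final_metrics(result, task, binary_outcome),
            protocol=result["protocol"],
        )
        if base_mode is not None:
            base = run_once(
                base_mode, task, k=k, seed=noise_seed, parties=parties,
                final_spec=FitSpec(final_kind),
            )
            summary = summarize_analysis(
                result["coef_rows"], result["imputed"], task.y, logistic=binary_outcome
            )
            base_summary = summarize_analysis(
                base["coef_rows"], base["imputed"], task.y, logistic=binary_outcome
            )
            metrics.discrepancies = discrepancy_count(base_summary, summary)
        runs.append(metrics)
        pooled_rows.append(result["pooled"])
    aggregate = {"scenario": scenario, "n": n, "method": mode, "reps_done": len(runs)}
    if pooled_rows and not binary_outcome:
        ds0 = _make_dataset(scenario, n, 0, binary_outcome, noise_variance)
        bias, sd, rmse = theta_stats(
            np.vstack(pooled_rows), np.r_[ds0.theta[1:], ds0.theta[0]]
        )
        aggregate.update({"theta_bias": bias, "theta_sd": sd, "theta_rmse": rmse})
    for key in ("imputation", "final_analysis"):
        if runs:
            names = getattr(runs[0], key).keys()
            for name in names:
                aggregate[f"{'imp' if key == 'imputation' else 'final'}_{name}"] = float(
                    np.mean([getattr(m, key)[name] for m in runs])
                )
    if runs and runs[0].discrepancies is not None:
        aggregate["discrepancies"] = int(sum(m.discrepancies for m in runs))
    return {"runs": [m.to_dict() for m in runs], "failures": failures,
            "aggregate": aggregate}


def benchmark(
    scenarios,
    sizes,
    modes,
    reps: int = 5,
    k: int = 5,
    seed: int = 0,
    parties: int = 3,
    noise_variance: float = 0.01,
) -> list[dict]:
    """Aggregate rows mirroring the simulation-table layout, one per
    (scenario, size, mode); secure modes report discrepancies against the
    plaintext base."""
    rows = []
    for scenario in scenarios:
        for n in sizes:
            for mode in modes:
                report = run_study(
                    mode, scenario, n, reps=reps, k=k, seed=seed, parties=parties,
                    noise_variance=noise_variance,
                    base_mode="plaintext" if mode != "plaintext" else None,
                )
                rows.append(report["aggregate"])
    return rows
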