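"""CSV/JSON readers and writers and the run configuration.

Datasets are exchanged as three comma-separated files sharing row/column
order -- ``data.csv`` (complete or zero-filled matrix, header ``x0..x{n-1}``),
``mask.csv`` (0/1 integers, 0 = missing) and ``outcome.csv`` (single column
``y``) -- plus ``truth.json`` holding the generating parameters when the data
is simulated.  Floats are written with 17 significant digits, so a
write-read round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mice import BINARY, CONTINUOUS, ImputationTask
from .simulate import SimulatedDataset

__all__ = [
    "RunConfig",
    "write_dataset",
    "read_task",
    "load_config",
    "write_json",
]

FLOAT_FORMAT = "%.17g"


@dataclasses.dataclass
class RunConfig:
    """Everything one benchmark invocation needs, mergeable from a config file."""

    mode: str = "plaintext"  # plaintext | smc | mhe
    scenario: int | None = None
    n: int = 500
    data: str | None = None
    mask: str | None = None
    outcome: str | None = None
    k: int = 5
    reps: int = 1
    parties: int = 3
    seed: int = 0
    noise_variance: float = 0.01
    binary_outcome: bool = False
    out: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("plaintext", "smc", "mhe"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reps < 1:
            raise ValueError("need at least one repetition")
        if self.scenario is None and self.data is None:
            raise ValueError("either a scenario id or input files are required")
        if self.mode == "mhe" and self.parties < 1:
            raise ValueError("need at least one party")


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a flat dict of RunConfig fields."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _frame(matrix: np.ndarray, prefix: str = "x") -> pd.DataFrame:
    matrix = np.atleast_2d(matrix)
    return pd.DataFrame(matrix, columns=[f"{prefix}{j}" for j in range(matrix.shape[1])])


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict:
    """Write data/mask/outcome CSVs and the truth record; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "data": out / "data.csv",
        "mask": out / "mask.csv",
        "outcome": out / "outcome.csv",
        "truth": out / "truth.json",
    }
    _frame(ds.X_complete).to_csv(paths["data"], index=False, float_format=FLOAT_FORMAT)
    _frame(ds.mask.astype(int)).to_csv(paths["mask"], index=False)
    pd.DataFrame({"y": ds.y.ravel()}).to_csv(
        paths["outcome"], index=False, float_format=FLOAT_FORMAT
    )
    truth = {
        "scenario_id": ds.spec.scenario_id,
        "n_individuals": ds.spec.n_individuals,
        "seed": ds.spec.seed,
        "missing_rate": ds.spec.rate,
        "mechanism": ds.spec.mechanism,
        "theta": ds.theta.tolist(),
        "column_kinds": list(ds.column_kinds),
        "outcome_kind": ds.outcome_kind,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def read_task(
    data_path: str | Path,
    mask_path: str | Path,
    outcome_path: str | Path,
    column_kinds=None,
    noise_variance: float = 0.01,
) -> ImputationTask:
    """Assemble an imputation task from CSV inputs.

    Unless given, column kinds are inferred: a column whose observed entries
    are all 0/1 is treated as binary.  Masked entries are zero-filled.
    """
    data = pd.read_csv(data_path, float_precision="round_trip").to_numpy(dtype=float)
    mask = pd.read_csv(mask_path).to_numpy(dtype=int)
    y = pd.read_csv(outcome_path, float_precision="round_trip").to_numpy(dtype=float)
    if column_kinds is None:
        column_kinds = []
        for j in range(data.shape[1]):
            obs = data[mask[:, j] == 1, j]
            column_kinds.append(
                BINARY if obs.size and np.isin(obs, (0.0, 1.0)).all() else CONTINUOUS
            )
    return ImputationTask(
        data=data * mask,
        mask=mask,
        y=y,
        column_kinds=tuple(column_kinds),
        noise_variance=noise_variance,
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
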