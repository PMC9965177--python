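"""Reading and writing of process recordings and run results.

Time-series files are plain CSV (comma, ".", UTF-8) with a header row and
the columns ``time_s, do_pct, ph, y_o2_pct, y_co2_pct, conductivity_ms,
phase`` (``ph``, ``conductivity_ms`` and ``phase`` optional), sampled on a
uniform grid — the same shape as a process-database export.  Simulator runs
additionally carry a ``<name>.truth.csv`` sidecar with the ground-truth
state, which :func:`read_timeseries` attaches when present.  All writes use
fixed numeric formatting so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ProcessSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_run",
    "write_summary",
    "SchemaError",
    "NonUniformGridError",
    "MissingChannelError",
]

MANDATORY_COLUMNS = ("time_s", "y_o2_pct", "y_co2_pct")
OPTIONAL_COLUMNS = ("do_pct", "ph", "conductivity_ms", "phase")
FLOAT_FORMAT = "%.8g"


class SchemaError(ValueError):
    """File does not follow the expected delimited-text schema."""


class MissingChannelError(SchemaError):
    """A mandatory channel column is absent."""


class NonUniformGridError(SchemaError):
    """Timestamps are not strictly increasing on a uniform grid."""


def read_timeseries(path: str | Path) -> ProcessSeries:
    """Load a recording, validating schema and the uniform 15-s-style grid.

    Percent-scaled gas and DO columns are kept in percent; downstream code
    converts to mole fractions where needed.  A ``<stem>.truth.csv`` sidecar
    written by the simulator is attached as ``metadata['truth']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed text
        raise SchemaError(f"{path}: not parseable as CSV: {exc}") from exc
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise MissingChannelError(f"{path}: missing mandatory columns {missing}")
    unknown = [c for c in df.columns
               if c not in MANDATORY_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise SchemaError(f"{path}: unknown columns {unknown}")

    t = df["time_s"].to_numpy(dtype=float)
    if len(t) == 0:
        raise SchemaError(f"{path}: empty series")
    if len(t) > 1:
        steps = np.diff(t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0],
                                                 rtol=1e-6, atol=1e-6):
            raise NonUniformGridError(f"{path}: timestamps not on a uniform grid")

    metadata: dict = {"source": str(path)}
    sidecar = path.parent / (path.stem + ".truth.csv")
    if sidecar.exists():
        metadata["truth"] = pd.read_csv(sidecar)

    return ProcessSeries(t=t, data=df.drop(columns=["time_s"]), metadata=metadata)


def write_timeseries(series: ProcessSeries, path: str | Path) -> Path:
    """Write a recording as CSV; deterministic formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = series.data.copy()
    out.insert(0, "time_s", series.t)
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def write_run(sim_output, out_dir: str | Path, name: str = "series") -> dict[str, Path]:
    """Write a simulated run: recording, truth sidecar, per-batch truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["series"] = write_timeseries(sim_output.series, out_dir / f"{name}.csv")
    truth = sim_output.truth.copy()
    truth.insert(0, "time_s", sim_output.series.t)
    truth_path = out_dir / f"{name}.truth.csv"
    truth.to_csv(truth_path, index=False, float_format=FLOAT_FORMAT)
    paths["truth"] = truth_path
    batches_path = out_dir / f"{name}.batches.csv"
    sim_output.batches.to_csv(batches_path, index=False, float_format=FLOAT_FORMAT)
    paths["batches"] = batches_path
    return paths


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_summary(run_result, path: str | Path, extra: dict | None = None) -> Path:
    """Serialise an across-batch run summary as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "batch_numbers": run_result.batch_numbers,
        "mu_sequence": run_result.mu_sequence,
        "durations_h": run_result.durations,
        "generations": run_result.generations_sequence,
        "ccd_trajectory": run_result.ccd_trajectory,
        "ccd_total": run_result.ccd_total,
        "stable_index": run_result.stable_index,
        "mu_stable": run_result.mu_stable,
        "relative_fitness": run_result.relative_fitness,
        "discarded_batches": run_result.discarded_batches,
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")
    return path
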