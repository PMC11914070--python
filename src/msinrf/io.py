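"""Readers and writers: stimulus stacks, experiment results, filter tables.

Stimuli are stored as ``.npy`` (double) or multi-page ``.tif`` (float32)
stacks with a JSON sidecar carrying the calibration (fps, deg/px) and
the full recipe/seed record.  Experiment results are stored as a CSV
table (grid + mean + dispersion, 17 significant digits so doubles
round-trip exactly) plus a JSON sidecar with the name, config and
extras.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .experiments import ExperimentResult
from .filters import SampledFilter, SpatialKernel
from .stimuli import StimulusSequence

__all__ = [
    "save_stimulus",
    "load_stimulus",
    "write_result",
    "read_result",
    "filter_to_csv",
    "kernel_to_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stimulus(seq: StimulusSequence, path) -> Path:
    """Write a stimulus stack (.npy or .tif) plus its JSON sidecar."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.ascontiguousarray(seq.frames))
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(seq.frames, dtype=np.float32))
    else:
        raise InvalidInputError(f"unsupported stimulus format {path.suffix!r}")
    meta = {"fps": seq.fps, "deg_per_px": seq.deg_per_px, "meta": seq.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=_json_default))
    return path


def load_stimulus(path) -> StimulusSequence:
    """Read a stimulus stack written by :func:`save_stimulus`."""
    path = Path(path)
    if path.suffix == ".npy":
        frames = np.load(path)
    elif path.suffix in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path).astype(float)
    else:
        raise InvalidInputError(f"unsupported stimulus format {path.suffix!r}")
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return StimulusSequence(
        frames,
        fps=meta.get("fps", 120.0),
        deg_per_px=meta.get("deg_per_px", 0.005),
        meta=meta.get("meta", {}),
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.bool_)):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_result(result: ExperimentResult, basepath) -> tuple:
    """Write an ExperimentResult as <base>.csv + <base>.json.

    The CSV holds the long-format grid with mean and dispersion columns
    in a stable order; the JSON sidecar holds the name, config (seeds
    included) and extras.
    """
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    names = list(result.variable_grid)
    if result.responses.ndim == 2 and len(names) == 2:
        g0, g1 = (np.asarray(result.variable_grid[n]) for n in names)
        rows = {
            names[0]: np.repeat(g0, g1.size),
            names[1]: np.tile(g1, g0.size),
            "response_mean": result.responses.ravel(),
            "dispersion": result.dispersion.ravel(),
        }
    else:
        rows = {n: np.asarray(result.variable_grid[n]) for n in names}
        rows["response_mean"] = result.responses
        rows["dispersion"] = result.dispersion
    csv_path = basepath.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "name": result.name,
        "config": result.config,
        "extras": result.extras,
        "grid_shape": list(result.responses.shape),
        "grid_names": names,
    }
    json_path = basepath.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2, default=_json_default))
    return csv_path, json_path


def read_result(basepath) -> ExperimentResult:
    """Read back an ExperimentResult written by :func:`write_result`."""
    basepath = Path(basepath)
    try:
        meta = json.loads(basepath.with_suffix(".json").read_text())
        df = pd.read_csv(basepath.with_suffix(".csv"), float_precision="round_trip")
    except (json.JSONDecodeError, pd.errors.ParserError) as e:
        raise InvalidInputError(f"malformed result files at {basepath}: {e}") from e
    names = meta["grid_names"]
    shape = tuple(meta["grid_shape"])
    if len(shape) == 2 and len(names) == 2:
        grid = {
            names[0]: df[names[0]].to_numpy()[:: shape[1]],
            names[1]: df[names[1]].to_numpy()[: shape[1]],
        }
        responses = df["response_mean"].to_numpy().reshape(shape)
        dispersion = df["dispersion"].to_numpy().reshape(shape)
    else:
        col = df[names[0]]
        grid = {names[0]: col.to_numpy() if col.dtype != object else list(col)}
        responses = df["response_mean"].to_numpy()
        dispersion = df["dispersion"].to_numpy()
    extras = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in meta.get("extras", {}).items()
    }
    return ExperimentResult(
        meta["name"], grid, responses, dispersion, meta["config"], extras
    )


def filter_to_csv(filt: SampledFilter, path) -> Path:
    """Write a temporal filter's tap table (delay_ms, weight)."""
    path = Path(path)
    pd.DataFrame({"delay_ms": filt.delays_ms, "weight": filt.taps}).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def kernel_to_csv(kernel: SpatialKernel, path) -> Path:
    """Write a spatial kernel's weight grid as CSV (rows x cols)."""
    path = Path(path)
    pd.DataFrame(kernel.weights).to_csv(path, index=False, header=False,
                                        float_format="%.17g")
    return path
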