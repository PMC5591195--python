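"""Stack and trace I/O.

Image stacks travel as multi-page TIFF (one page per frame, 16-bit unsigned
or 32-bit float) with a JSON sidecar (``<stem>.json``) carrying acquisition
metadata: frame count, exposure, pixel size, channel layout, sweep
configuration and the simulation seed.  Sidecar JSON rather than TIFF tags
keeps the metadata portable across readers.

Decoded traces are written as CSV (one row per substep) and optionally as
an HDF5 bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import InvalidArgumentError
from .simulate import FrameStack, ChannelLayout
from .sweep import SweepConfig

SATURATION = 65535


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a stack as multi-page TIFF plus a JSON sidecar.

    With ``dtype="uint16"`` pixel values are rounded and clipped to
    [0, 65535] (a warning lands in the sidecar when clipping occurred);
    ``dtype="float32"`` is lossless.
    """
    path = Path(path)
    frames = np.asarray(stack.frames)
    saturated = False
    if dtype == "uint16":
        saturated = bool((frames > SATURATION).any())
        out = np.clip(np.round(frames), 0, SATURATION).astype(np.uint16)
    elif dtype == "float32":
        out = frames.astype(np.float32)
    else:
        raise InvalidArgumentError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out, photometric="minisblack")
    meta = {
        "n_frames": int(stack.n_frames),
        "exposure_ms": stack.exposure_ms,
        "pixel_size_um": stack.pixel_size_um,
        "layout": stack.layout.to_dict() if stack.layout else None,
        "sweep": stack.sweep.to_dict() if stack.sweep else None,
        "meta": _jsonable(stack.meta),
        "dtype": dtype,
        "saturated": saturated,
        "smsweep_version": __version__,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer, np.floating, np.bool_)):
            v = v.item()
        out[k] = v
    return out


def read_stack(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF and its JSON sidecar back into a FrameStack."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise InvalidArgumentError(f"cannot read TIFF stack {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    sc = sidecar_path(path)
    if not sc.exists():
        raise InvalidArgumentError(f"missing sidecar metadata file {sc}")
    meta = json.loads(sc.read_text())
    if meta.get("n_frames") != frames.shape[0]:
        raise InvalidArgumentError(
            f"sidecar {sc} declares n_frames={meta.get('n_frames')} but the TIFF "
            f"holds {frames.shape[0]} pages")
    layout = ChannelLayout.from_dict(meta["layout"]) if meta.get("layout") else None
    sweep = SweepConfig.from_dict(meta["sweep"]) if meta.get("sweep") else None
    return FrameStack(frames=frames, pixel_size_um=meta["pixel_size_um"],
                      exposure_ms=meta["exposure_ms"], layout=layout,
                      sweep=sweep, meta=meta.get("meta", {}))


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def traces_to_frame(traces, n_steps: int) -> pd.DataFrame:
    """Long-format table of decoded traces (one row per substep)."""
    rows = []
    for mol_id, tr in enumerate(traces):
        n = tr.values.size
        frame = np.arange(n) // n_steps
        substep = np.arange(n) % n_steps
        rows.append(pd.DataFrame({
            "molecule_id": mol_id,
            "frame": frame,
            "substep": substep,
            "time_ms": np.arange(n) * tr.substep_ms,
            "intensity": tr.values,
            "raw_intensity": tr.raw_values,
            "i_b": tr.i_b,
            "sigma_b": tr.sigma_b,
        }))
    if not rows:
        return pd.DataFrame(columns=["molecule_id", "frame", "substep", "time_ms",
                                     "intensity", "raw_intensity", "i_b", "sigma_b"])
    return pd.concat(rows, ignore_index=True)


def write_traces_csv(traces, n_steps: int, path: str | Path) -> Path:
    path = Path(path)
    traces_to_frame(traces, n_steps).to_csv(path, index=False)
    return path


def write_traces_h5(traces, path: str | Path) -> Path:
    """HDF5 bundle: one group per molecule with values/raw plus backgrounds."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["smsweep_version"] = __version__
        f.attrs["n_molecules"] = len(traces)
        for i, tr in enumerate(traces):
            g = f.create_group(f"molecule_{i:04d}")
            g.create_dataset("intensity", data=tr.values)
            g.create_dataset("raw_intensity", data=tr.raw_values)
            g.attrs["i_b"] = tr.i_b
            g.attrs["sigma_b"] = tr.sigma_b
            g.attrs["substep_ms"] = tr.substep_ms
            g.attrs["peak_x"] = tr.source_peak.x
            g.attrs["peak_y"] = tr.source_peak.y
    return path


def dwells_to_frame(dwells) -> pd.DataFrame:
    return pd.DataFrame({
        "molecule_id": [d.molecule_id for d in dwells],
        "state": [d.state for d in dwells],
        "start_ms": [d.start_ms for d in dwells],
        "duration_ms": [d.duration_ms for d in dwells],
        "censored": [d.censored for d in dwells],
    })


_RUN_KEYS = {"scenario", "seed", "n_frames", "n_molecules", "height",
             "sweep", "camera", "kinetics", "out"}


def load_run_config(path: str | Path) -> dict:
    """Load and schema-check a simulation run configuration (YAML or JSON).

    Recognized keys: scenario, seed (mandatory), n_frames, n_molecules,
    height, out, plus optional ``sweep``/``camera``/``kinetics`` blocks that
    override the scenario preset.  Unknown keys are rejected so typos fail
    loudly rather than silently falling back to defaults.
    """
    import yaml

    path = Path(path)
    if not path.exists():
        raise InvalidArgumentError(f"config file {path} does not exist")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"config {path} must be a mapping")
    unknown = set(cfg) - _RUN_KEYS
    if unknown:
        raise InvalidArgumentError(f"unknown config keys in {path}: {sorted(unknown)}")
    if "seed" not in cfg:
        raise InvalidArgumentError(f"config {path} must set a seed")
    if "scenario" not in cfg:
        raise InvalidArgumentError(f"config {path} must name a scenario")
    return cfg


def write_provenance(path: str | Path, command: str, config: dict,
                     seed: int | None) -> Path:
    """Machine-readable run record written next to each CLI output."""
    record = {"command": command, "config": _jsonable(config), "seed": seed,
              "smsweep_version": __version__}
    path = Path(path)
    path.write_text(json.dumps(record, indent=1, default=str))
    return path
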