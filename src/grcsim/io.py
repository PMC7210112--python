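"""Plain-text exchange formats: traces as CSV + JSON sidecar, feature
tables as CSV, protocols and model parameter sets as YAML."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell import GrCModel, VoltageTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_features_table",
    "read_features_table",
    "save_protocol",
    "load_protocol",
    "model_overrides_to_yaml",
]


def write_trace(trace: VoltageTrace, basename: str | Path) -> tuple[Path, Path]:
    """Write ``<basename>.csv`` (time + one column per location, plus aux
    series) and ``<basename>.json`` (dt, units, stimulus annotation)."""
    basename = Path(basename)
    csv_path = basename.with_suffix(".csv")
    json_path = basename.with_suffix(".json")
    cols = {"time_ms": trace.time}
    for loc in trace.locations:
        cols[loc] = trace.data[loc]
    for name, series in trace.aux.items():
        cols[f"aux_{name}"] = series
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.6g")
    stim = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in trace.stim.items()
    }
    meta = {
        "dt_ms": trace.dt,
        "unit": trace.unit,
        "locations": list(trace.locations),
        "aux": list(trace.aux),
        "stim": stim,
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def read_trace(basename: str | Path) -> VoltageTrace:
    basename = Path(basename)
    meta = json.loads(basename.with_suffix(".json").read_text())
    df = pd.read_csv(basename.with_suffix(".csv"))
    data = {loc: df[loc].to_numpy() for loc in meta["locations"]}
    aux = {name: df[f"aux_{name}"].to_numpy() for name in meta.get("aux", [])}
    return VoltageTrace(
        dt=float(meta["dt_ms"]),
        data=data,
        stim=meta.get("stim", {}),
        aux=aux,
        unit=meta.get("unit", "mV"),
    )


def write_features_table(df: pd.DataFrame, path: str | Path) -> Path:
    """One row per cell/model per stimulus; plain CSV."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_features_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_protocol(proto, path: str | Path) -> Path:
    """Serialize any protocol dataclass with a ``to_dict`` to YAML."""
    path = Path(path)
    payload = {"type": type(proto).__name__, "params": proto.to_dict()}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path


def load_protocol(path: str | Path):
    from . import protocols

    payload = yaml.safe_load(Path(path).read_text())
    cls = getattr(protocols, payload["type"])
    return cls.from_dict(payload["params"])


def model_overrides_to_yaml(model: GrCModel, path: str | Path) -> Path:
    """Persist a model's subtype tag + conductance overrides (YAML)."""
    path = Path(path)
    gmax: dict[str, dict[str, float]] = {}
    for (chan, comp), val in model.gmax_overrides.items():
        gmax.setdefault(chan, {})[comp] = float(val)
    payload = {
        "tag": model.subtype_tag,
        "trpm4_enabled": model.trpm4_enabled,
        "gmax": gmax,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
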