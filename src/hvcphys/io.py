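"""File formats: trace CSV + JSON sidecar, parameter/protocol YAML, tables.

Traces are stored as plain CSV (columns time_ms, V_mV, I_pA) so they stay
diffable; sweep metadata (parameter identity, protocol, solver settings)
goes to a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import VoltageTrace, StimulusProtocol
from .params import NeuronParams
from .features import FeatureSet


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_trace(trace: VoltageTrace, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_ms": trace.t, "V_mV": trace.v, "I_pA": trace.i_app})
    df.to_csv(path, index=False, float_format="%.6g")
    _sidecar(path).write_text(json.dumps(trace.meta, indent=1, default=str))
    return path


def load_trace(path) -> VoltageTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return VoltageTrace(t=df["time_ms"].to_numpy(),
                        v=df["V_mV"].to_numpy(),
                        i_app=df["I_pA"].to_numpy(), meta=meta)


def save_params(p: NeuronParams, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(p.to_dict(), sort_keys=False))
    return path


def load_params(path) -> NeuronParams:
    return NeuronParams.from_dict(yaml.safe_load(Path(path).read_text()))


def save_protocol(proto: StimulusProtocol, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = {"pre_ms": proto.pre_ms, "pulse_pA": list(proto.pulse_pA),
         "pulse_ms": proto.pulse_ms, "post_ms": proto.post_ms,
         "dt_out": proto.dt_out}
    path.write_text(yaml.safe_dump(d, sort_keys=False))
    return path


def load_protocol(path) -> StimulusProtocol:
    d = yaml.safe_load(Path(path).read_text())
    d["pulse_pA"] = tuple(d["pulse_pA"])
    return StimulusProtocol(**d)


def feature_table(named_features: dict[str, FeatureSet]) -> pd.DataFrame:
    """One row per cell; list-valued fields (ISIs) serialised as strings."""
    rows = []
    for name, fs in named_features.items():
        d = fs.to_dict()
        d["isis_ms"] = ";".join(f"{x:.6g}" for x in d["isis_ms"])
        rows.append({"cell": name, **d})
    return pd.DataFrame(rows)


def save_features(named_features: dict[str, FeatureSet], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    feature_table(named_features).to_csv(path, index=False, float_format="%.6g")
    return path
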