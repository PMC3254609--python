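"""Serialization: network archives, stimulus JSON, trace/matrix CSV.

Networks and traces are stored as NumPy ``.npz`` archives of named 2-D
arrays plus a JSON metadata header kept in a ``_meta`` entry (spec
echo, seed, regime, package version).  Stimuli are plain JSON.
Response matrices and analysis maps export to CSV with labelled bin
times and a JSON sidecar of parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coding import ResponseMatrix
from .network import Network, NetworkSpec
from .simulate import ActivityTrace
from .stimuli import StimulusProgram

__all__ = [
    "save_network",
    "load_network",
    "save_stimulus",
    "load_stimulus",
    "save_trace",
    "load_trace",
    "trace_to_csv",
    "response_matrix_to_csv",
    "map_to_csv",
]

_NET_BLOCKS = ("w_pn_pn", "w_ln_pn", "w_pn_ln", "w_ln_ln", "a_orn_pn", "a_orn_ln")


def _meta_array(meta: dict) -> np.ndarray:
    return np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)


def _meta_from(arr: np.ndarray) -> dict:
    return json.loads(arr.tobytes().decode())


def save_network(net: Network, path: str | Path) -> None:
    meta = {
        "format": "mgc-network",
        "version": __version__,
        "spec": dataclasses.asdict(net.spec),
    }
    np.savez(
        path,
        _meta=_meta_array(meta),
        **{name: getattr(net, name) for name in _NET_BLOCKS},
    )


def load_network(path: str | Path) -> Network:
    with np.load(path) as data:
        meta = _meta_from(data["_meta"])
        spec_d = meta["spec"]
        for key in ("w_pn_pn", "w_ln_pn", "w_pn_ln", "w_ln_ln", "w_orn"):
            spec_d[key] = tuple(spec_d[key])
        spec = NetworkSpec(**spec_d)
        return Network(spec, *(data[name] for name in _NET_BLOCKS))


def save_stimulus(stim: StimulusProgram, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "ratio": stim.ratio,
                "amplitude": stim.amplitude,
                "pulses": [list(p) for p in stim.pulses],
            },
            indent=2,
        )
    )


def load_stimulus(path: str | Path) -> StimulusProgram:
    d = json.loads(Path(path).read_text())
    return StimulusProgram(
        d["ratio"], tuple(tuple(p) for p in d["pulses"]), d["amplitude"]
    )


def save_trace(trace: ActivityTrace, path: str | Path) -> None:
    meta = {
        "format": "mgc-trace",
        "version": __version__,
        "onset": trace.onset,
        "meta": trace.meta,
    }
    np.savez(
        path,
        _meta=_meta_array(meta),
        times=trace.times,
        pn=trace.pn,
        ln=trace.ln,
        stimulus=trace.stimulus,
    )


def load_trace(path: str | Path) -> ActivityTrace:
    with np.load(path) as data:
        meta = _meta_from(data["_meta"])
        return ActivityTrace(
            times=data["times"],
            pn=data["pn"],
            ln=data["ln"],
            stimulus=data["stimulus"],
            onset=meta.get("onset"),
            meta=meta.get("meta", {}),
        )


def trace_to_csv(trace: ActivityTrace, path: str | Path) -> None:
    """One row per time step; columns: time, stimulus, PNs, LNs."""
    cols = {"time_ms": trace.times}
    cols.update({f"g{c + 1}": trace.stimulus[c] for c in range(trace.stimulus.shape[0])})
    cols.update({f"pn{i + 1}": trace.pn[i] for i in range(trace.pn.shape[0])})
    cols.update({f"ln{i + 1}": trace.ln[i] for i in range(trace.ln.shape[0])})
    pd.DataFrame(cols).to_csv(path, index=False)


def _sidecar(path: Path, params: dict) -> None:
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"version": __version__, **params}, indent=2)
    )


def response_matrix_to_csv(rm: ResponseMatrix, path: str | Path) -> None:
    """Rows = PNs, labelled columns = bin centres (ms after onset)."""
    path = Path(path)
    df = pd.DataFrame(
        rm.R,
        index=[f"pn{i + 1}" for i in range(rm.n_pn)],
        columns=[f"{t:g}" for t in rm.bin_times()],
    )
    df.to_csv(path, index_label="neuron")
    _sidecar(path, {"bin_ms": rm.bin_ms, "t_start": rm.t_start, "onset": rm.onset,
                    "meta": rm.meta})


def map_to_csv(
    values: np.ndarray,
    path: str | Path,
    row_times: np.ndarray | None = None,
    col_times: np.ndarray | None = None,
    params: dict | None = None,
) -> None:
    """Export a correlation or classification map with labelled bin times."""
    path = Path(path)
    idx = None if row_times is None else [f"{t:g}" for t in row_times]
    cols = None if col_times is None else [f"{t:g}" for t in col_times]
    pd.DataFrame(values, index=idx, columns=cols).to_csv(path, index_label="ref_bin_ms")
    _sidecar(path, params or {})
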