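"""HDF5 serialization for networks, interval parameters and datasets.

Networks are stored with one group per layer holding ``W`` and ``b`` (plus
``W_lo``, ``W_hi``, ``b_lo``, ``b_hi`` once interval parameters exist) and
attributes recording the layer kind and activation.  Datasets store the
signal/measurement/input arrays and split labels, with the generating
parameters kept both as HDF5 attributes and in an optional JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .intervals import IntervalBox, IntervalNetwork
from .nets import Conv1d, Dense, PredictionNetwork
from .synthetic import SampleSet

__all__ = [
    "save_network", "load_network",
    "save_interval_network", "load_interval_network",
    "save_dataset", "load_dataset",
]

_LAYER_KINDS = {"dense": Dense, "conv1d": Conv1d}


def _write_base(f: h5py.Group, net: PredictionNetwork):
    f.attrs["n_layers"] = net.n_layers
    f.attrs["dropout_sites"] = json.dumps(
        {str(k): v for k, v in net.dropout_sites.items()}
    )
    for i, lay in enumerate(net.layers):
        g = f.require_group(f"layer_{i:02d}")
        g.attrs["kind"] = lay.kind
        g.attrs["activation"] = lay.activation
        for name, arr in (("W", lay.W), ("b", lay.b)):
            if name in g:
                del g[name]
            g.create_dataset(name, data=arr)


def save_network(path, net: PredictionNetwork):
    with h5py.File(path, "w") as f:
        _write_base(f, net)


def _read_base(f: h5py.Group) -> PredictionNetwork:
    n = int(f.attrs["n_layers"])
    layers = []
    for i in range(n):
        g = f[f"layer_{i:02d}"]
        cls = _LAYER_KINDS[g.attrs["kind"]]
        layers.append(cls(g["W"][()], g["b"][()], activation=g.attrs["activation"]))
    sites = {int(k): float(v)
             for k, v in json.loads(f.attrs["dropout_sites"]).items()}
    return PredictionNetwork(layers, dropout_sites=sites)


def load_network(path) -> PredictionNetwork:
    with h5py.File(path, "r") as f:
        return _read_base(f)


def save_interval_network(path, inn: IntervalNetwork):
    """Write base parameters and interval bounds to one container file."""
    with h5py.File(path, "w") as f:
        _write_base(f, inn.base)
        f.attrs["beta"] = inn.beta
        f.attrs["interval_layers"] = list(inn.interval_layers)
        for i in range(inn.base.n_layers):
            g = f[f"layer_{i:02d}"]
            wb, bb = inn.weight_intervals[i], inn.bias_intervals[i]
            for name, arr in (("W_lo", wb.lower), ("W_hi", wb.upper),
                              ("b_lo", bb.lower), ("b_hi", bb.upper)):
                g.create_dataset(name, data=arr)


def load_interval_network(path) -> IntervalNetwork:
    with h5py.File(path, "r") as f:
        base = _read_base(f)
        w_boxes, b_boxes = [], []
        for i in range(base.n_layers):
            g = f[f"layer_{i:02d}"]
            w_boxes.append(IntervalBox(g["W_lo"][()], g["W_hi"][()]))
            b_boxes.append(IntervalBox(g["b_lo"][()], g["b_hi"][()]))
        return IntervalNetwork(
            base, w_boxes, b_boxes,
            interval_layers=[int(i) for i in f.attrs["interval_layers"]],
            beta=float(f.attrs["beta"]),
        )


def save_dataset(path, data: SampleSet, params: dict | None = None,
                 sidecar: bool = True):
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=data.signals)
        f.create_dataset("measurements", data=data.measurements)
        f.create_dataset("inputs", data=data.inputs)
        f.create_dataset("splits", data=np.char.encode(data.splits, "ascii"))
        f.attrs["seed"] = data.seed
        if params:
            f.attrs["params"] = json.dumps(params)
    if sidecar:
        meta = {**(params or {}), "seed": int(data.seed)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_dataset(path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            signals=f["signals"][()],
            measurements=f["measurements"][()],
            inputs=f["inputs"][()],
            splits=np.char.decode(f["splits"][()], "ascii"),
            seed=int(f.attrs["seed"]),
        )
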