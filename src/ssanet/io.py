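"""Reading and writing networks, rasters and spectral reports.

Weight matrices travel as Matrix Market real general sparse files;
neuron types and partitions as a sidecar JSON
(``{"types": [...], "groups": [...], "scope": ..., "levels": [...]}``).
Rasters are two-column CSV ``neuron_id,time_ms`` with 0-based indices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io as sio
import scipy.sparse as sp

from ssanet.lif import SpikeRaster
from ssanet.topology import Partition, WeightMatrix

__all__ = [
    "save_network", "load_network", "save_raster", "load_raster",
    "sidecar_path",
]


def sidecar_path(mtx_path: str | Path) -> Path:
    return Path(mtx_path).with_suffix(".json")


def save_network(path: str | Path, W: WeightMatrix,
                 partition: Partition | None = None) -> None:
    path = Path(path)
    sio.mmwrite(str(path), sp.csr_matrix(W.values))
    meta = {"types": W.neuron_types.tolist()}
    if partition is not None:
        meta["groups"] = partition.group_of.tolist()
        meta["scope"] = partition.scope
        if partition.levels is not None:
            meta["levels"] = [lvl.tolist() for lvl in partition.levels]
    sidecar_path(path).write_text(json.dumps(meta))


def load_network(path: str | Path) -> tuple[WeightMatrix, Partition | None]:
    path = Path(path)
    mat = sio.mmread(str(path))
    values = np.asarray(mat.todense() if sp.issparse(mat) else mat,
                        dtype=float)
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        types = np.array(meta["types"])
        part = None
        if "groups" in meta:
            part = Partition(group_of=np.array(meta["groups"]),
                             scope=meta.get("scope", "E"),
                             levels=[np.array(l) for l in meta["levels"]]
                             if "levels" in meta else None)
    else:
        types = np.array(["E"] * values.shape[0])
        part = None
    return WeightMatrix(values=values, neuron_types=types), part


def save_raster(path: str | Path, raster: SpikeRaster) -> None:
    with open(path, "w") as fh:
        fh.write(f"# N={raster.N} duration_ms={raster.duration_ms}\n")
        fh.write("neuron_id,time_ms\n")
        for n, t in zip(raster.neurons, raster.times):
            fh.write(f"{n},{t:.4f}\n")


def load_raster(path: str | Path, N: int | None = None,
                duration_ms: float | None = None) -> SpikeRaster:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    meta = {}
    if header.startswith("#"):
        for tok in header[1:].split():
            if "=" in tok:
                k, v = tok.split("=")
                meta[k] = float(v)
        skip = 2
    else:
        skip = 1
    data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    if data.size == 0:
        neurons, times = np.empty(0, int), np.empty(0)
    else:
        neurons, times = data[:, 0].astype(int), data[:, 1]
    N = N if N is not None else int(meta.get("N", neurons.max() + 1
                                              if neurons.size else 0))
    duration_ms = duration_ms if duration_ms is not None else float(
        meta.get("duration_ms", times.max() if times.size else 0.0))
    return SpikeRaster(neurons=neurons, times=times, N=N,
                       duration_ms=duration_ms)
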