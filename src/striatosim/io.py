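"""File I/O: CSV/HDF5 writers, JSON reports and run manifests.

Unit policy for files: nM, µm, s throughout; column names carry the unit.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .config import RunConfig, dump_config
from .dopamine_field import ConcentrationTrace
from .innervation import TerminalMap, Void
from .spike_trains import SpikeTrainSet

__all__ = [
    "write_spikes_csv",
    "read_spikes_csv",
    "write_schedule_csv",
    "write_terminals_csv",
    "read_terminals_csv",
    "write_counts_h5",
    "write_trace_csv",
    "write_field_h5",
    "void_report",
    "write_manifest",
]


def write_spikes_csv(trains: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (i, t) for i, spikes in enumerate(trains.spikes) for t in spikes
    ]
    df = pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"])
    df.to_csv(path, index=False)


def read_spikes_csv(path: str | Path, n_neurons: Optional[int] = None, duration: Optional[float] = None) -> SpikeTrainSet:
    """Load user-supplied spike trains (columns neuron_id, spike_time_s)."""
    df = pd.read_csv(path)
    if not {"neuron_id", "spike_time_s"} <= set(df.columns):
        raise ValueError("spike CSV needs columns neuron_id,spike_time_s")
    n = int(df["neuron_id"].max()) + 1 if len(df) else 0
    if n_neurons is not None:
        n = max(n, n_neurons)
    spikes = [
        np.sort(df.loc[df["neuron_id"] == i, "spike_time_s"].to_numpy(float))
        for i in range(n)
    ]
    dur = duration if duration is not None else (float(df["spike_time_s"].max()) if len(df) else 0.0)
    return SpikeTrainSet(n_neurons=n, duration=dur, spikes=spikes)


def write_schedule_csv(trains: SpikeTrainSet, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.start, e.end, e.kind) for e in trains.schedule],
        columns=["epoch_start_s", "epoch_end_s", "epoch_type"],
    )
    df.to_csv(path, index=False)


def write_terminals_csv(tmap: TerminalMap, path: str | Path) -> None:
    df = pd.DataFrame(tmap.positions, columns=["x_um", "y_um", "z_um"])
    df["arbor_id"] = tmap.arbor_id if tmap.arbor_id is not None else -1
    df.to_csv(path, index=False)


def read_terminals_csv(path: str | Path, lattice, intact_density: float = 0.0) -> TerminalMap:
    df = pd.read_csv(path)
    pos = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    arbor = df["arbor_id"].to_numpy(np.int64) if "arbor_id" in df else None
    if arbor is not None and (arbor < 0).all():
        arbor = None
    return TerminalMap(lattice=lattice, positions=pos, arbor_id=arbor, intact_density=intact_density)


def write_counts_h5(tmap: TerminalMap, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("terminal_counts", data=tmap.counts())
        d.attrs["voxel_size_um"] = tmap.lattice.voxel_size
        d.attrs["extent_um"] = tmap.lattice.extent


def write_trace_csv(trace: ConcentrationTrace, path: str | Path) -> None:
    cols = {"time_s": trace.times}
    for i in range(trace.values.shape[1]):
        cols[f"probe_{i}_nM"] = trace.values[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_field_h5(field: np.ndarray, voxel_size: float, t: float, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("concentration_nM", data=field)
        d.attrs["voxel_size_um"] = voxel_size
        d.attrs["time_s"] = t


def void_report(voids: Iterable[Void]) -> List[Dict]:
    return [
        {
            "component_id": v.component_id,
            "n_voxels": v.n_voxels,
            "equivalent_diameter_um": round(v.equivalent_diameter, 3),
        }
        for v in voids
    ]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    cfg: RunConfig,
    seed: int,
    outputs: Iterable[str | Path],
    out_dir: str | Path,
    wall_time_s: float,
) -> Path:
    """Write the run manifest (config hash, seed, output checksums)."""
    from importlib.metadata import PackageNotFoundError, version

    try:
        ver = version("striatosim")
    except PackageNotFoundError:
        ver = "unknown"
    manifest = {
        "config_sha256": hashlib.sha256(dump_config(cfg).encode()).hexdigest(),
        "seed": seed,
        "code_version": ver,
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
        "wall_time_s": round(wall_time_s, 3),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
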