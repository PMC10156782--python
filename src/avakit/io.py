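"""Raster and trial-table I/O: dense CSV/TSV and an HDF5 layout.

CSV layout: one row per cell (index = cell id), one column per bin, header row of bin
times in seconds.  HDF5 layout: ``/raster/values``, ``/raster/dt``,
``/raster/cell_ids`` and optionally ``/raster/cell_type``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .raster import SpikeRaster, TrialTable

__all__ = [
    "read_raster_csv",
    "write_raster_csv",
    "read_raster_h5",
    "write_raster_h5",
    "read_trials_csv",
    "write_trials_csv",
]


def write_raster_csv(raster: SpikeRaster, path: str | Path, sep: str = ",") -> None:
    times = np.arange(raster.n_bins) * raster.dt
    frame = pd.DataFrame(raster.values, index=raster.cell_ids, columns=times)
    frame.index.name = "cell_id"
    frame.to_csv(path, sep=sep)


def read_raster_csv(path: str | Path, sep: str = ",") -> SpikeRaster:
    frame = pd.read_csv(path, sep=sep, index_col=0)
    times = frame.columns.to_numpy(dtype=float)
    if times.size > 1:
        dt = float(np.median(np.diff(times)))
    else:
        dt = float(times[0]) if times[0] > 0 else 1.0
    return SpikeRaster(
        values=frame.to_numpy(dtype=float),
        dt=dt,
        cell_ids=[str(i) for i in frame.index],
    )


def write_raster_h5(raster: SpikeRaster, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("raster")
        grp.create_dataset("values", data=raster.values, compression="gzip")
        grp.create_dataset("dt", data=float(raster.dt))
        ids = np.asarray(raster.cell_ids, dtype=h5py.string_dtype())
        grp.create_dataset("cell_ids", data=ids)
        if raster.cell_type is not None:
            types = np.asarray(raster.cell_type, dtype=h5py.string_dtype())
            grp.create_dataset("cell_type", data=types)


def read_raster_h5(path: str | Path) -> SpikeRaster:
    with h5py.File(path, "r") as f:
        grp = f["raster"]
        values = grp["values"][()]
        dt = float(grp["dt"][()])
        cell_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in grp["cell_ids"][()]]
        cell_type = None
        if "cell_type" in grp:
            cell_type = np.asarray(
                [s.decode() if isinstance(s, bytes) else str(s) for s in grp["cell_type"][()]]
            )
    return SpikeRaster(values=values, dt=dt, cell_ids=cell_ids, cell_type=cell_type)


def write_trials_csv(trials: TrialTable, path: str | Path) -> None:
    trials.to_frame().to_csv(path, index=False)


def read_trials_csv(path: str | Path) -> TrialTable:
    frame = pd.read_csv(path)
    return TrialTable(
        conditions=frame["condition"].to_numpy(),
        starts=frame["start_bin"].to_numpy(),
        ends=frame["end_bin"].to_numpy(),
    )
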