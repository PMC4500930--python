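"""Readers and writers for spike-train recordings and derived tables.

Two on-disk layouts are supported:

* **tabular** — a delimiter-separated spike table with header
  ``network_id,unit_id,electrode_id,time_ms`` plus a side-car metadata table
  (``<stem>.meta.csv``) with columns
  ``network_id,group,div,well,window_start_ms,window_end_ms``.
* **hierarchical** — an HDF5 file with one group per network, one dataset of
  spike times per unit, and window/metadata stored as attributes.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import NetworkRecording, SpikeTrain

__all__ = [
    "read_recording",
    "read_recordings",
    "write_recording",
    "write_recordings",
    "burst_table",
    "write_burst_table",
]

_META_COLS = ["network_id", "group", "div", "well", "window_start_ms", "window_end_ms"]
_SPIKE_COLS = ["network_id", "unit_id", "electrode_id", "time_ms"]


def _meta_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    return p.with_suffix(".meta.csv")


def _build_recording(
    network_id: str,
    unit_rows: dict[str, tuple[str | None, np.ndarray]],
    window: tuple[float, float],
    meta: dict,
) -> NetworkRecording:
    trains = []
    for unit_id, (electrode_id, times) in unit_rows.items():
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError(
                f"network {network_id!r}, unit {unit_id!r}: spike times are not "
                "strictly ascending"
            )
        try:
            trains.append(SpikeTrain(unit_id, times, window, electrode_id=electrode_id))
        except ValueError as exc:
            raise ValueError(f"network {network_id!r}: {exc}") from exc
    return NetworkRecording(network_id, tuple(trains), meta)


def read_recordings(path: str | os.PathLike, format: str = "tabular") -> list[NetworkRecording]:
    """Read every network stored in a file; see module docstring for layouts."""
    if format == "tabular":
        return _read_tabular(path)
    if format == "hierarchical":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def read_recording(
    path: str | os.PathLike, format: str = "tabular", network_id: str | None = None
) -> NetworkRecording:
    """Read a single network (the only one, or the one named)."""
    recs = read_recordings(path, format=format)
    if network_id is not None:
        for r in recs:
            if r.network_id == network_id:
                return r
        raise KeyError(f"network {network_id!r} not found in {path}")
    if len(recs) != 1:
        raise ValueError(
            f"{path} holds {len(recs)} networks; pass network_id to disambiguate"
        )
    return recs[0]


def _read_tabular(path: str | os.PathLike) -> list[NetworkRecording]:
    spikes = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SPIKE_COLS if c not in spikes.columns]
    if missing:
        raise ValueError(f"{path}: missing spike columns {missing}")
    mpath = _meta_path(path)
    if not mpath.exists():
        raise FileNotFoundError(f"side-car metadata file {mpath} not found")
    meta = pd.read_csv(mpath)
    missing = [c for c in _META_COLS if c not in meta.columns]
    if missing:
        raise ValueError(f"{mpath}: missing metadata columns {missing}")
    bad = spikes["time_ms"].isna()
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} rows with missing time_ms")

    recs = []
    meta = meta.set_index("network_id", verify_integrity=True)
    for nid, sub in spikes.groupby("network_id", sort=True):
        if nid not in meta.index:
            raise ValueError(f"{path}: network {nid!r} has no metadata row")
        mrow = meta.loc[nid]
        window = (float(mrow["window_start_ms"]), float(mrow["window_end_ms"]))
        unit_rows: dict[str, tuple[str | None, np.ndarray]] = {}
        for uid, urows in sub.groupby("unit_id", sort=True):
            eid = urows["electrode_id"].iloc[0]
            eid = None if pd.isna(eid) else str(eid)
            unit_rows[str(uid)] = (eid, urows["time_ms"].to_numpy(dtype=float))
        m = {"group": mrow["group"], "div": mrow["div"], "well": mrow["well"]}
        recs.append(_build_recording(str(nid), unit_rows, window, m))
    return recs


def _read_hdf5(path: str | os.PathLike) -> list[NetworkRecording]:
    recs = []
    with h5py.File(path, "r") as f:
        for nid in sorted(f.keys()):
            grp = f[nid]
            window = (float(grp.attrs["window_start_ms"]), float(grp.attrs["window_end_ms"]))
            meta = {
                k: grp.attrs[k]
                for k in ("group", "div", "well")
                if k in grp.attrs
            }
            unit_rows: dict[str, tuple[str | None, np.ndarray]] = {}
            for uid in sorted(grp.keys()):
                ds = grp[uid]
                eid = ds.attrs.get("electrode_id")
                eid = None if eid is None else str(eid)
                unit_rows[str(uid)] = (eid, np.asarray(ds[()], dtype=float))
            recs.append(_build_recording(str(nid), unit_rows, window, meta))
    return recs


def write_recordings(
    recs: Sequence[NetworkRecording], path: str | os.PathLike, format: str = "tabular"
) -> None:
    if format == "tabular":
        _write_tabular(recs, path)
    elif format == "hierarchical":
        _write_hdf5(recs, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_recording(
    rec: NetworkRecording, path: str | os.PathLike, format: str = "tabular"
) -> None:
    write_recordings([rec], path, format=format)


def _write_tabular(recs: Sequence[NetworkRecording], path: str | os.PathLike) -> None:
    rows = []
    meta_rows = []
    for rec in recs:
        for tr in rec.trains:
            for t in tr.spike_times:
                rows.append((rec.network_id, tr.unit_id, tr.electrode_id, t))
        meta_rows.append(
            (
                rec.network_id,
                rec.meta.get("group", ""),
                rec.meta.get("div", ""),
                rec.meta.get("well", ""),
                rec.window[0],
                rec.window[1],
            )
        )
    # %.17g guarantees exact float64 round-trips through text
    pd.DataFrame(rows, columns=_SPIKE_COLS).to_csv(path, index=False, float_format="%.17g")
    pd.DataFrame(meta_rows, columns=_META_COLS).to_csv(_meta_path(path), index=False)


def _write_hdf5(recs: Sequence[NetworkRecording], path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        for rec in recs:
            grp = f.create_group(rec.network_id)
            grp.attrs["window_start_ms"] = rec.window[0]
            grp.attrs["window_end_ms"] = rec.window[1]
            for k in ("group", "div", "well"):
                if k in rec.meta and rec.meta[k] is not None:
                    grp.attrs[k] = rec.meta[k]
            for tr in rec.trains:
                ds = grp.create_dataset(tr.unit_id, data=tr.spike_times)
                if tr.electrode_id is not None:
                    ds.attrs["electrode_id"] = tr.electrode_id


def burst_table(network_id: str, bursts_by_unit: dict[str, list]) -> pd.DataFrame:
    """Flatten detected bursts into the export table layout."""
    rows = []
    for uid, bursts in bursts_by_unit.items():
        for i, b in enumerate(bursts):
            rows.append((network_id, uid, i, b.start, b.end, b.n_spikes))
    return pd.DataFrame(
        rows,
        columns=["network_id", "unit_id", "burst_index", "start_ms", "end_ms", "n_spikes"],
    )


def write_burst_table(
    network_id: str, bursts_by_unit: dict[str, list], path: str | os.PathLike
) -> None:
    burst_table(network_id, bursts_by_unit).to_csv(path, index=False)
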