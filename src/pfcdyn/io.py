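"""HDF5/CSV container format for datasets and results.

Layout of a dataset file:

* ``/lfp/<region>/<electrode>`` — trials x time float array with ``time_ms``
  and ``fs_hz`` attributes plus session/subject ids and trial ids.
* ``/spikes/<region>/<unit>`` — ragged per-trial spike-time lists (variable-
  length float rows) with the raster window in attributes.
* ``/truth/<table>`` — ground-truth latent tables, one dataset per column.

Trial metadata travels as a plain CSV next to the HDF5 file (or any path
the caller picks), with the canonical trial-table columns.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .containers import LFPArray, SpikeRaster


def save_dataset(
    path,
    arrays=None,
    spikes=None,
    truth: pd.DataFrame | None = None,
) -> None:
    """Write LFP arrays, spike rasters and ground-truth tables to HDF5."""
    with h5py.File(path, "w") as f:
        for arr in arrays or []:
            g = f.require_group(f"lfp/{arr.region or 'none'}")
            d = g.create_dataset(str(arr.electrode_id), data=arr.data)
            d.attrs["time_ms"] = arr.time_ms
            d.attrs["fs_hz"] = arr.fs_hz
            d.attrs["session_id"] = arr.session_id
            d.attrs["subject_id"] = -1 if arr.subject_id is None else arr.subject_id
            d.attrs["trial_ids"] = arr.trial_ids
        vlen = h5py.special_dtype(vlen=np.dtype("float64"))
        for ras in spikes or []:
            g = f.require_group(f"spikes/{ras.region or 'none'}")
            d = g.create_dataset(str(ras.unit_id), (ras.n_trials,), dtype=vlen)
            for i, s in enumerate(ras.spikes):
                d[i] = s
            d.attrs["window_ms"] = np.asarray(ras.window_ms, float)
            d.attrs["session_id"] = ras.session_id
            d.attrs["electrode_id"] = ras.electrode_id
            d.attrs["trial_ids"] = ras.trial_ids
        if truth is not None:
            g = f.require_group("truth")
            for col in truth.columns:
                vals = truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)


def load_dataset(path):
    """Read a dataset file back into ``(arrays, spikes, truth)``."""
    arrays, spikes = [], []
    truth = None
    with h5py.File(path, "r") as f:
        for region in f.get("lfp", {}):
            for eid in f[f"lfp/{region}"]:
                d = f[f"lfp/{region}/{eid}"]
                sid = int(d.attrs["subject_id"])
                arrays.append(
                    LFPArray(
                        data=d[()],
                        time_ms=d.attrs["time_ms"],
                        fs_hz=float(d.attrs["fs_hz"]),
                        electrode_id=int(eid),
                        region=region,
                        session_id=int(d.attrs["session_id"]),
                        subject_id=None if sid < 0 else sid,
                        trial_ids=d.attrs["trial_ids"],
                    )
                )
        for region in f.get("spikes", {}):
            for uid in f[f"spikes/{region}"]:
                d = f[f"spikes/{region}/{uid}"]
                spikes.append(
                    SpikeRaster(
                        spikes=[np.asarray(row) for row in d[()]],
                        window_ms=tuple(d.attrs["window_ms"]),
                        unit_id=int(uid),
                        region=region,
                        session_id=int(d.attrs["session_id"]),
                        electrode_id=int(d.attrs["electrode_id"]),
                        trial_ids=d.attrs["trial_ids"],
                    )
                )
        if "truth" in f:
            cols = {}
            for col in f["truth"]:
                vals = f[f"truth/{col}"][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            truth = pd.DataFrame(cols)
    arrays.sort(key=lambda a: (a.session_id, a.electrode_id))
    spikes.sort(key=lambda s: (s.session_id, s.unit_id))
    return arrays, spikes, truth


def save_decomposition(path, d) -> None:
    """Write a PCADecomposition to HDF5 (/pca/*)."""
    with h5py.File(path, "w") as f:
        g = f.require_group("pca")
        g.create_dataset("V", data=d.V)
        g.create_dataset("U", data=d.U)
        g.create_dataset("singular_values", data=d.singular_values)
        g.create_dataset("explained", data=d.explained_variance_fraction)
        g.create_dataset("excluded", data=d.excluded_rows)
        g.create_dataset("mean_timecourse", data=d.mean_timecourse)
        g.create_dataset("time_ms", data=d.time_ms)
        ri = f.require_group("pca/row_index")
        for col in d.row_index.columns:
            vals = d.row_index[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            ri.create_dataset(col, data=vals)


def save_trials_csv(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False)


def load_trials_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
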