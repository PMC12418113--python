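"""File formats: HDF5 epoch containers, BIDS-style events tables, TSV tables.

Array data travel as HDF5 (datasets ``/data`` [trial, channel, time] and
``/time`` with a ``sampling_rate`` attribute); tabular data as UTF-8
tab-separated values with "." decimals; configuration as YAML.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import pandas as pd

from .synthetic import CHANNELS, EpochSet

EVENT_COLUMNS = ["onset", "duration", "trial_id", "subject_id",
                 "condition", "alley", "valence"]


def write_epochs(epochs: EpochSet, h5_path, events_path=None) -> None:
    """Write an epoch set to HDF5 plus a BIDS-style events TSV.

    The events table gets ``onset`` / ``duration`` columns in seconds
    (zero onset: times are epoch-relative) ahead of the trial metadata.
    """
    h5_path = Path(h5_path)
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("time", data=epochs.time_axis)
        fh.attrs["sampling_rate"] = epochs.sampling_rate
        fh.attrs["channel_names"] = list(epochs.channel_names)
        if epochs.ground_truth is not None:
            gt = fh.create_group("ground_truth")
            for col in epochs.ground_truth.columns:
                vals = epochs.ground_truth[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                gt.create_dataset(col, data=vals)
    ev = epochs.events.copy()
    ev.insert(0, "onset", 0.0)
    ev.insert(1, "duration", (epochs.time_axis[-1] - epochs.time_axis[0]) / 1000.0)
    if events_path is None:
        events_path = h5_path.with_name(h5_path.stem + "_events.tsv")
    write_table(ev[[c for c in EVENT_COLUMNS if c in ev.columns]], events_path)


def read_epochs(h5_path, events_path=None) -> EpochSet:
    h5_path = Path(h5_path)
    if events_path is None:
        events_path = h5_path.with_name(h5_path.stem + "_events.tsv")
        if not events_path.exists():
            events_path = h5_path.with_name("events.tsv")
    with h5py.File(h5_path, "r") as fh:
        data = fh["data"][()]
        time_axis = fh["time"][()]
        fs = float(fh.attrs["sampling_rate"])
        channels = tuple(str(c) for c in fh.attrs.get("channel_names", CHANNELS))
        gt = None
        if "ground_truth" in fh:
            cols = {}
            for col in fh["ground_truth"]:
                vals = fh["ground_truth"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
            gt = pd.DataFrame(cols)
    events = read_table(events_path)
    events = events.drop(columns=[c for c in ("onset", "duration")
                                  if c in events.columns])
    return EpochSet(data, time_axis, fs, events, channels, gt)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_spectrogram_powers(spec, path) -> None:
    """Persist trial-average total/evoked/induced power grids to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("freqs", data=spec.freqs)
        fh.create_dataset("time", data=spec.time_axis)
        for name in ("power_total", "power_evoked", "power_induced"):
            arr = getattr(spec, name)
            if arr is not None:
                fh.create_dataset(name, data=arr)
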