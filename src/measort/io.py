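"""File formats: HDF5 signals with ground truth, CSV tables, raw binary.

One HDF5 file per signal:

* dataset ``trace`` (float64 samples), attributes ``fs_hz``, ``seed``,
  ``snr``;
* optional group ``ground_truth`` with ``spike_times`` (int64, 0-based
  sample indices), ``unit_labels`` (int64) and one dataset per template
  (``template_<unit>``).

Raw float32 binary traces are supported with a JSON sidecar carrying the
sampling rate.  Spike tables and assignments are exported as plain CSV.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import pandas as pd

from .core import InputError, Trace
from .simulate import GroundTruth, SpikeTemplate

__all__ = [
    "save_signal",
    "load_signal",
    "load_raw_binary",
    "ground_truth_to_csv",
    "spike_table_to_csv",
    "save_waveforms",
    "load_waveforms",
]


def save_signal(path: str, trace: Trace,
                truth: GroundTruth | None = None) -> None:
    """Write a trace (and optionally its ground truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("trace", data=trace.samples)
        d.attrs["fs_hz"] = trace.fs_hz
        d.attrs["channel_id"] = trace.channel_id
        if truth is not None:
            d.attrs["seed"] = truth.provenance.get("seed", -1)
            d.attrs["snr"] = truth.provenance.get("snr_target", np.nan)
            g = fh.create_group("ground_truth")
            g.create_dataset("spike_times", data=truth.spike_times)
            g.create_dataset("unit_labels", data=truth.unit_labels)
            for t in truth.templates:
                g.create_dataset(f"template_{t.unit_id}", data=t.samples)


def load_signal(path: str) -> tuple[Trace, GroundTruth | None]:
    """Read a signal written by :func:`save_signal`."""
    with h5py.File(path, "r") as fh:
        d = fh["trace"]
        trace = Trace(d[...], float(d.attrs["fs_hz"]),
                      int(d.attrs.get("channel_id", 0)))
        truth = None
        if "ground_truth" in fh:
            g = fh["ground_truth"]
            templates = []
            for name in sorted(k for k in g if k.startswith("template_")):
                uid = int(name.split("_")[1])
                templates.append(SpikeTemplate(g[name][...], unit_id=uid))
            truth = GroundTruth(
                g["spike_times"][...], g["unit_labels"][...], templates,
                provenance={"seed": int(d.attrs.get("seed", -1)),
                            "snr_target": float(d.attrs.get("snr", np.nan))},
            )
    return trace, truth


def load_raw_binary(path: str, sidecar: str | None = None) -> Trace:
    """Read a raw float32 trace with a JSON sidecar holding ``fs_hz``."""
    sidecar = sidecar or path + ".json"
    if not os.path.exists(sidecar):
        raise InputError(f"missing JSON sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    if "fs_hz" not in meta:
        raise InputError("sidecar must define fs_hz")
    samples = np.fromfile(path, dtype=np.float32).astype(np.float64)
    return Trace(samples, float(meta["fs_hz"]),
                 int(meta.get("channel_id", 0)))


def ground_truth_to_csv(path: str, truth: GroundTruth, fs_hz: float) -> None:
    """Export ground truth as CSV (columns: time_s, unit)."""
    pd.DataFrame({
        "time_s": truth.spike_times / fs_hz,
        "unit": truth.unit_labels,
    }).to_csv(path, index=False)


def spike_table_to_csv(path: str, events) -> None:
    """Export detected/classified events (channel, times, label) as CSV."""
    pd.DataFrame([{
        "channel": e.channel_id,
        "t_cross_sample": e.t_cross,
        "t_peak_sample": e.t_peak,
        "label": e.label,
    } for e in events]).to_csv(path, index=False)


def save_waveforms(path: str, waveforms: np.ndarray) -> None:
    """Store a spike waveform matrix (n_spikes × n) in HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("waveforms", data=np.asarray(waveforms))


def load_waveforms(path: str) -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh["waveforms"][...]
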