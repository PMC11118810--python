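"""HDF5 session container and text exports.

Session layout::

    /eeg/data        float32, channels × time × trials (µV)
    /eeg/fs, /eeg/time_ms, /eeg/labels
    /emg/...         (mV)
    /leadfield/gain, /leadfield/positions [, /leadfield/sensor_positions]
    /truth/<column>  per-trial ground-truth vectors
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochedRecording, LeadField
from .synthgen import (ArtifactConfig, CouplingTarget, MEPModelConfig,
                       NoiseConfig, SimConfig, SyntheticSession)


def _write_recording(g: h5py.Group, rec: EpochedRecording) -> None:
    g.create_dataset("data", data=rec.data.astype(np.float32))
    g["fs"] = rec.fs
    g["time_ms"] = rec.time_ms
    g.create_dataset("labels", data=np.array(rec.labels, dtype="S"))
    g.attrs["role"] = rec.role


def _read_recording(g: h5py.Group) -> EpochedRecording:
    return EpochedRecording(
        data=g["data"][()], fs=float(g["fs"][()]), time_ms=g["time_ms"][()],
        labels=[s.decode() for s in g["labels"][()]],
        role=g.attrs.get("role", "eeg"))


def save_session(path: str | Path, session: SyntheticSession) -> None:
    with h5py.File(path, "w") as f:
        _write_recording(f.create_group("eeg"), session.eeg)
        _write_recording(f.create_group("emg"), session.emg)
        lf = f.create_group("leadfield")
        lf["gain"] = session.leadfield.gain
        lf["positions"] = session.leadfield.positions
        if session.leadfield.sensor_positions is not None:
            lf["sensor_positions"] = session.leadfield.sensor_positions
        tg = f.create_group("truth")
        for col in session.truth.columns:
            tg[col] = session.truth[col].to_numpy()
        f.attrs["f_mu"] = session.cfg.f_mu
        f.attrs["seed"] = session.cfg.seed


def load_session(path: str | Path) -> dict:
    """Load a session file into plain containers (no config reconstruction)."""
    with h5py.File(path, "r") as f:
        eeg = _read_recording(f["eeg"])
        emg = _read_recording(f["emg"])
        lf = LeadField(
            gain=f["leadfield/gain"][()],
            positions=f["leadfield/positions"][()],
            sensor_positions=(f["leadfield/sensor_positions"][()]
                              if "sensor_positions" in f["leadfield"] else None))
        truth = pd.DataFrame({k: f["truth"][k][()] for k in f["truth"]})
        meta = {"f_mu": float(f.attrs.get("f_mu", np.nan)),
                "seed": int(f.attrs.get("seed", -1))}
    return {"eeg": eeg, "emg": emg, "leadfield": lf, "truth": truth, **meta}


def load_leadfield(gain_path: str | Path,
                   positions_path: str | Path | None = None) -> LeadField:
    """Lead field from a standalone HDF5 file or a CSV pair (gain, positions)."""
    gain_path = Path(gain_path)
    if gain_path.suffix in (".h5", ".hdf5"):
        with h5py.File(gain_path, "r") as f:
            return LeadField(gain=f["gain"][()], positions=f["positions"][()])
    gain = np.loadtxt(gain_path, delimiter=",")
    pos = np.loadtxt(positions_path, delimiter=",")
    return LeadField(gain=gain, positions=pos)


def config_from_yaml(path: str | Path) -> SimConfig:
    """Build a SimConfig from a structured YAML file (missing keys use defaults)."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    kwargs = dict(raw)
    if "coupling_targets" in kwargs:
        kwargs["coupling_targets"] = [CouplingTarget(**t)
                                      for t in kwargs["coupling_targets"]]
    for key, cls in (("noise", NoiseConfig), ("mep_model", MEPModelConfig),
                     ("artifact", ArtifactConfig)):
        if key in kwargs:
            kwargs[key] = cls(**kwargs[key])
    if "source_positions" in kwargs and kwargs["source_positions"] is not None:
        kwargs["source_positions"] = np.asarray(kwargs["source_positions"], float)
    return SimConfig(**kwargs)


def map_to_csv(cmap, path: str | Path) -> None:
    """Export a connectivity map as CSV (source index, MNI x/y/z, iPLV)."""
    df = pd.DataFrame({
        "source": np.arange(len(cmap.values)),
        "mni_x": cmap.positions[:, 0], "mni_y": cmap.positions[:, 1],
        "mni_z": cmap.positions[:, 2], "iplv": cmap.values})
    df.to_csv(path, index=False)


def mep_table_to_csv(mep_table, path: str | Path) -> None:
    mep_table.table.to_csv(path)
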