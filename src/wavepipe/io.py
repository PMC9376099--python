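"""HDF5 / CSV / JSON persistence for ensembles, laminar data and spikes.

Layout
------
Ensemble HDF5: ``/lfp`` (trials x channels x time), ``/t_axis``,
``/geometry/positions`` with grid attributes, root attributes
``sampling_rate``, ``pre_window``, ``post_window``; ground truth as a JSON
string attribute.  Laminar HDF5: ``/laminar/lfp``, ``/laminar/z_um``.
Spikes: CSV with columns unit_id, depth_um, spike_time_s.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import GridGeometry, LaminarRecording, SpikeTrain, TrialEnsemble

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "save_laminar",
    "load_laminar",
    "save_spikes",
    "load_spikes",
    "save_ground_truth",
    "load_ground_truth",
]


def save_ensemble(path: str | Path, ensemble: TrialEnsemble) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=ensemble.lfp)
        f.create_dataset("t_axis", data=ensemble.t_axis)
        f.attrs["sampling_rate"] = ensemble.sampling_rate
        f.attrs["pre_window"] = ensemble.pre_window
        f.attrs["post_window"] = ensemble.post_window
        if ensemble.geometry is not None:
            g = f.create_group("geometry")
            g.create_dataset("positions", data=ensemble.geometry.positions)
            g.attrs["n_rows"] = ensemble.geometry.n_rows
            g.attrs["n_cols"] = ensemble.geometry.n_cols
            g.attrs["pitch_mm"] = ensemble.geometry.pitch_mm
        if ensemble.ground_truth:
            f.attrs["ground_truth"] = json.dumps(ensemble.ground_truth)


def load_ensemble(path: str | Path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        geometry = None
        if "geometry" in f:
            g = f["geometry"]
            geometry = GridGeometry(
                n_rows=int(g.attrs["n_rows"]),
                n_cols=int(g.attrs["n_cols"]),
                pitch_mm=float(g.attrs["pitch_mm"]),
                positions=g["positions"][()],
            )
        truth = {}
        if "ground_truth" in f.attrs:
            truth = json.loads(f.attrs["ground_truth"])
        return TrialEnsemble(
            lfp=f["lfp"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            t_axis=f["t_axis"][()],
            geometry=geometry,
            pre_window=float(f.attrs["pre_window"]),
            post_window=float(f.attrs["post_window"]),
            ground_truth=truth,
        )


def save_laminar(path: str | Path, rec: LaminarRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("laminar")
        g.create_dataset("lfp", data=rec.phi)
        g.create_dataset("z_um", data=rec.z_um)
        g.attrs["sampling_rate"] = rec.sampling_rate


def load_laminar(path: str | Path) -> LaminarRecording:
    with h5py.File(path, "r") as f:
        g = f["laminar"]
        return LaminarRecording(
            phi=g["lfp"][()],
            z_um=g["z_um"][()],
            sampling_rate=float(g.attrs["sampling_rate"]),
        )


def save_spikes(path: str | Path, trains: list[SpikeTrain]) -> None:
    rows = []
    for tr in trains:
        for t in tr.spike_times:
            rows.append({"unit_id": tr.unit_id, "depth_um": tr.depth_um,
                         "spike_time_s": t})
    pd.DataFrame(rows, columns=["unit_id", "depth_um", "spike_time_s"]).to_csv(
        path, index=False
    )


def load_spikes(path: str | Path, duration: float | None = None) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=False):
        trains.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times=np.sort(grp["spike_time_s"].to_numpy()),
                depth_um=float(grp["depth_um"].iloc[0]),
                duration=duration,
            )
        )
    return trains


def save_ground_truth(path: str | Path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def load_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
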