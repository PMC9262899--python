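"""Tabular I/O: trial/EMG CSV dialects and OpenSim-style .sto/.mot tables.

All package outputs are plain CSV with a header row. Gait trials use
columns ``time, <dof>_angle_rad..., <dof>_moment_Nm..., stance,
interseg_axial_N, grf_vertical_N``; EMG files use ``time`` plus one column
per channel. The .sto/.mot reader understands the OpenSim text-table
dialect (key=value header lines, ``nRows``/``nColumns``, ``endheader``,
tab- or whitespace-separated data) for ingesting exported real data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import DOFS
from .synth import GaitTrial


def write_trial_csv(trial: GaitTrial, path: str | Path) -> None:
    data = {"time": trial.t}
    for dof in DOFS:
        data[f"{dof}_angle_rad"] = trial.q[dof]
    for dof in DOFS:
        data[f"{dof}_moment_Nm"] = trial.m_id[dof]
    data["stance"] = trial.stance_mask.astype(int)
    if trial.interseg_axial is not None:
        data["interseg_axial_N"] = trial.interseg_axial
    if trial.grf_vertical is not None:
        data["grf_vertical_N"] = trial.grf_vertical
    df = pd.DataFrame(data)
    df.attrs["bodyweight_N"] = trial.bodyweight
    with open(path, "w") as fh:
        fh.write(f"# bodyweight_N={trial.bodyweight}\n")
        df.to_csv(fh, index=False)


def read_trial_csv(path: str | Path) -> GaitTrial:
    bodyweight = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split(","):
                k, _, v = tok.strip().partition("=")
                if k == "bodyweight_N":
                    bodyweight = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if bodyweight is None:
        raise ValueError(f"{path}: missing '# bodyweight_N=' header line")
    q = {dof: df[f"{dof}_angle_rad"].to_numpy() for dof in DOFS}
    m_id = {dof: df[f"{dof}_moment_Nm"].to_numpy() for dof in DOFS}
    return GaitTrial(
        t=df["time"].to_numpy(),
        q=q,
        m_id=m_id,
        stance_mask=df["stance"].to_numpy().astype(bool),
        interseg_axial=(
            df["interseg_axial_N"].to_numpy()
            if "interseg_axial_N" in df else None
        ),
        bodyweight=bodyweight,
        grf_vertical=(
            df["grf_vertical_N"].to_numpy() if "grf_vertical_N" in df else None
        ),
    )


def write_emg_csv(channels: dict[str, np.ndarray], fs: float, path: str | Path) -> None:
    n = len(next(iter(channels.values())))
    df = pd.DataFrame({"time": np.arange(n) / fs, **channels})
    with open(path, "w") as fh:
        fh.write(f"# fs_Hz={fs} units=mV\n")
        df.to_csv(fh, index=False)


def read_emg_csv(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    with open(path) as fh:
        first = fh.readline()
        fs = None
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "fs_Hz":
                    fs = float(v)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if fs is None:
        t = df["time"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time"}
    return channels, fs


def read_storage(path: str | Path) -> pd.DataFrame:
    """Read an OpenSim .sto/.mot text table into a DataFrame.

    Handles the ``key=value`` header block terminated by ``endheader`` and
    whitespace- or tab-separated data with a column-name row.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    # some files start with a name line without '='
    while i < len(lines) and lines[i].strip().lower() != "endheader":
        line = lines[i].strip()
        if "=" in line:
            k, _, v = line.partition("=")
            meta[k.strip()] = v.strip()
        i += 1
    if i == len(lines):
        raise ValueError(f"{path}: no 'endheader' line — not a .sto/.mot file")
    i += 1
    header = lines[i].split()
    data = np.array(
        [[float(x) for x in row.split()] for row in lines[i + 1:] if row.strip()]
    )
    if "nColumns" in meta and int(meta["nColumns"]) != data.shape[1]:
        raise ValueError(f"{path}: nColumns header disagrees with data")
    if "nRows" in meta and int(meta["nRows"]) != data.shape[0]:
        raise ValueError(f"{path}: nRows header disagrees with data")
    df = pd.DataFrame(data, columns=header)
    df.attrs.update(meta)
    return df


def write_storage(df: pd.DataFrame, path: str | Path, name: str = "table") -> None:
    """Write a DataFrame as an OpenSim-style .sto text table."""
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={len(df)}\n"
                 f"nColumns={df.shape[1]}\ninDegrees=no\nendheader\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(f"{v:.8f}" for v in row.to_numpy()) + "\n")
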