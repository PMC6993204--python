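"""Trial file format and cohort manifests.

No standard biosignal container covers 6-DOF pose plus wrench, so
trials are stored as plain delimited text: one row per sample with
columns ``t, px, py, pz, qw, qx, qy, qz, grip, fx, fy, fz, tqx, tqy,
tqz`` (SI units, scalar-first quaternions) and a single ``#``-prefixed
JSON header line carrying metadata and, optionally, the tissue
geometry and per-sample segment labels.  Floats are written with
round-trip precision, so write-then-read is lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trial import TissueGeometry, TrialRecording, UniformTrial

__all__ = [
    "TrialSchemaError",
    "write_trial",
    "read_trial",
    "write_cohort",
    "read_cohort",
    "file_hash",
]

_BASE_COLUMNS = [
    "t", "px", "py", "pz", "qw", "qx", "qy", "qz",
    "grip", "fx", "fy", "fz", "tqx", "tqy", "tqz",
]
_DERIV_COLUMNS = ["vx", "vy", "vz", "ax", "ay", "az", "jx", "jy", "jz"]


class TrialSchemaError(ValueError):
    """The file does not conform to the trial schema."""


def _geometry_to_dict(geom: TissueGeometry) -> dict:
    return {
        "contour": geom.contour.tolist(),
        "entrance_point": geom.entrance_point.tolist(),
        "desired_exit": geom.desired_exit.tolist(),
        "actual_exit": None if geom.actual_exit is None else geom.actual_exit.tolist(),
        "frame_origin": geom.frame_origin.tolist(),
        "frame_axes": geom.frame_axes.tolist(),
        "marker_radius": geom.marker_radius,
    }


def _geometry_from_dict(d: dict) -> TissueGeometry:
    return TissueGeometry(
        contour=np.array(d["contour"]),
        entrance_point=np.array(d["entrance_point"]),
        desired_exit=np.array(d["desired_exit"]),
        actual_exit=None if d.get("actual_exit") is None else np.array(d["actual_exit"]),
        frame_origin=np.array(d["frame_origin"]),
        frame_axes=np.array(d["frame_axes"]),
        marker_radius=float(d.get("marker_radius", 0.002)),
    )


def write_trial(
    trial: TrialRecording,
    path,
    geometry: TissueGeometry | None = None,
    labels: np.ndarray | None = None,
) -> Path:
    """Write a trial (raw or preprocessed) to a delimited text file."""
    path = Path(path)
    cols = {
        "t": trial.t,
        "px": trial.position[:, 0], "py": trial.position[:, 1], "pz": trial.position[:, 2],
        "qw": trial.orientation[:, 0], "qx": trial.orientation[:, 1],
        "qy": trial.orientation[:, 2], "qz": trial.orientation[:, 3],
        "grip": trial.gripper,
        "fx": trial.force[:, 0], "fy": trial.force[:, 1], "fz": trial.force[:, 2],
        "tqx": trial.torque[:, 0], "tqy": trial.torque[:, 1], "tqz": trial.torque[:, 2],
    }
    if isinstance(trial, UniformTrial) and trial.velocity is not None:
        for prefix, arr in (("v", trial.velocity), ("a", trial.acceleration), ("j", trial.jerk)):
            for i, axis in enumerate("xyz"):
                cols[f"{prefix}{axis}"] = arr[:, i]
    header = {"meta": trial.meta}
    if isinstance(trial, UniformTrial):
        header["rate"] = trial.rate
    if geometry is not None:
        header["geometry"] = _geometry_to_dict(geometry)
    if labels is not None:
        cols["segment"] = np.asarray(labels, dtype=int)

    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write(",".join(df.columns) + "\n")
        fmt = ["%d" if c == "segment" else "%.17g" for c in df.columns]
        np.savetxt(fh, df.to_numpy(), fmt=",".join(fmt).split(","), delimiter=",")
    return path


def read_trial(path):
    """Read a trial file.

    Returns ``(trial, geometry, labels)`` where geometry/labels are
    None when absent.  The trial is a :class:`UniformTrial` when
    derivative columns are present.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise TrialSchemaError(f"{path}: missing JSON header line (line 1)")
        try:
            header = json.loads(first[1:])
        except json.JSONDecodeError as err:
            raise TrialSchemaError(f"{path}: malformed JSON header: {err}") from err
        df = pd.read_csv(fh)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise TrialSchemaError(f"{path}: missing required columns {missing}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 3  # header + column line offset
        raise TrialSchemaError(f"{path}: non-numeric or missing value near line {bad}")

    meta = header.get("meta", {})
    kwargs = dict(
        t=df["t"].to_numpy(),
        position=df[["px", "py", "pz"]].to_numpy(),
        orientation=df[["qw", "qx", "qy", "qz"]].to_numpy(),
        gripper=df["grip"].to_numpy(),
        force=df[["fx", "fy", "fz"]].to_numpy(),
        torque=df[["tqx", "tqy", "tqz"]].to_numpy(),
        meta=meta,
    )
    if all(c in df.columns for c in _DERIV_COLUMNS):
        trial = UniformTrial(
            **kwargs,
            rate=float(header.get("rate", meta.get("rate", 100.0))),
            velocity=df[["vx", "vy", "vz"]].to_numpy(),
            acceleration=df[["ax", "ay", "az"]].to_numpy(),
            jerk=df[["jx", "jy", "jz"]].to_numpy(),
        )
    else:
        trial = TrialRecording(**kwargs)
    geometry = (
        _geometry_from_dict(header["geometry"]) if header.get("geometry") else None
    )
    labels = df["segment"].to_numpy(dtype=int) if "segment" in df.columns else None
    return trial, geometry, labels


def write_cohort(dataset, directory) -> Path:
    """Write a signal-level cohort: manifest.csv plus one file per trial."""
    directory = Path(directory)
    (directory / "trials").mkdir(parents=True, exist_ok=True)
    manifest = dataset.manifest.copy()
    files = []
    for _, row in manifest.iterrows():
        key = (row["participant"], int(row["trial"]))
        trial, gt = dataset.trials[key]
        fname = f"trials/{row['participant']}_t{int(row['trial']):03d}.csv"
        write_trial(trial, directory / fname, geometry=gt.geometry, labels=gt.labels)
        files.append(fname)
    manifest["file"] = files
    manifest.to_csv(directory / "manifest.csv", index=False)
    cfg = dataset.config
    with open(directory / "cohort.json", "w") as fh:
        json.dump(
            {
                "n_per_group": cfg.n_per_group,
                "conditions": list(cfg.conditions),
                "trials_per_block": cfg.trials_per_block,
                "blocks": cfg.blocks,
                "seed": cfg.seed,
            },
            fh,
        )
    return directory


def read_cohort(directory):
    """Read a cohort directory written by :func:`write_cohort`."""
    from .synthetic import CohortConfig, CohortDataset, TrialGroundTruth

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    trials = {}
    for _, row in manifest.iterrows():
        trial, geometry, labels = read_trial(directory / row["file"])
        if geometry is None:
            raise TrialSchemaError(f"{row['file']}: cohort trials must embed geometry")
        gt = TrialGroundTruth(
            intervals=[], bounds_time=(np.nan, np.nan), labels=labels, geometry=geometry
        )
        trials[(row["participant"], int(row["trial"]))] = (trial, gt)
    with open(directory / "cohort.json") as fh:
        cj = json.load(fh)
    cfg = CohortConfig(
        n_per_group=cj["n_per_group"],
        conditions=tuple(cj["conditions"]),
        trials_per_block=cj["trials_per_block"],
        blocks=cj["blocks"],
        seed=cj["seed"],
    )
    return CohortDataset(manifest=manifest, trials=trials, config=cfg)


def file_hash(path) -> str:
    """Content hash used to skip unchanged pipeline stages."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
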