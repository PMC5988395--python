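"""Readers and writers for the pipeline's file formats.

Connectome matrices travel as dense TSV (header row/column of ROI ids) or as
a compressed NumPy archive (``.npz`` with keys ``sc``, ``fc``, ``roi_ids``).
Cohort tables, degree/descriptor/effect tables, balance scores and sway
trajectories are TSV.  Voxel data (4-D BOLD, integer-labeled parcellations,
spatial maps and t-maps) are NIfTI via nibabel.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ConnectomePair
from .balance import SwayTrajectory

__all__ = [
    "save_connectome_tsv",
    "load_connectome_tsv",
    "save_connectome_pair_npz",
    "save_module_table",
    "load_connectome_pair_npz",
    "load_cohort_table",
    "save_cohort_table",
    "save_trajectories_tsv",
    "load_trajectories_tsv",
    "save_bold_nifti",
    "load_bold_nifti",
    "save_parcellation_nifti",
    "load_parcellation_nifti",
    "save_map_nifti",
    "extract_module_series",
]

COHORT_COLUMNS = ["group", "age", "sex", "fd_mean", "eddy_motion_mean"]


def save_connectome_tsv(matrix: np.ndarray, path, roi_ids=None) -> None:
    m = np.asarray(matrix)
    ids = list(range(m.shape[0])) if roi_ids is None else list(roi_ids)
    pd.DataFrame(m, index=ids, columns=ids).to_csv(path, sep="\t")


def load_connectome_tsv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.columns)


def save_connectome_pair_npz(pair: ConnectomePair, path) -> None:
    np.savez_compressed(
        path, sc=pair.sc, fc=pair.fc, roi_ids=np.asarray(pair.roi_ids)
    )


def load_connectome_pair_npz(path) -> ConnectomePair:
    with np.load(path, allow_pickle=False) as z:
        return ConnectomePair(sc=z["sc"], fc=z["fc"], roi_ids=list(z["roi_ids"]))


def save_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index_label="subject")


def load_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject")
    missing = [c for c in ("group", "age") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    return df


def save_trajectories_tsv(trials: list[SwayTrajectory], path) -> None:
    rows = []
    for t in trials:
        times = np.arange(t.samples.shape[0]) / t.fs
        tx = "" if t.target is None else f"{t.target[0]:.6f},{t.target[1]:.6f}"
        for ti, (x, y) in zip(times, t.samples):
            rows.append(
                {
                    "t": ti,
                    "x": x,
                    "y": y,
                    "trial": t.trial,
                    "protocol": t.protocol,
                    "condition": t.condition,
                    "fall": int(t.fall),
                    "target": tx,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_trajectories_tsv(path) -> list[SwayTrajectory]:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for (proto, cond, trial), grp in df.groupby(["protocol", "condition", "trial"]):
        grp = grp.sort_values("t")
        tgt = None
        tval = grp["target"].iloc[0]
        if isinstance(tval, str) and tval:
            tgt = np.array([float(v) for v in tval.split(",")])
        dt = np.diff(grp["t"].to_numpy())
        fs = 1.0 / float(np.median(dt)) if dt.size else 100.0
        trials.append(
            SwayTrajectory(
                samples=grp[["x", "y"]].to_numpy(),
                fs=fs,
                protocol=proto,
                condition=int(cond),
                trial=int(trial),
                fall=bool(grp["fall"].iloc[0]),
                target=tgt,
            )
        )
    return trials


def save_module_table(partition, path, roi_ids=None, voxel_labels=None) -> None:
    """Module table TSV: module id, member ROI ids, and voxel volume
    (voxel count per module, when a voxel parcellation is supplied)."""
    labels = np.asarray(partition.labels)
    ids = np.asarray(roi_ids if roi_ids is not None else np.arange(labels.size))
    rows = []
    for m in range(1, int(labels.max()) + 1):
        row = {
            "module": m,
            "roi_ids": ",".join(str(r) for r in ids[labels == m]),
        }
        if voxel_labels is not None:
            row["voxel_volume"] = int(np.sum(np.asarray(voxel_labels) == m))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _default_affine() -> np.ndarray:
    return np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic


def save_bold_nifti(bold: np.ndarray, grid: tuple, path, tr: float = 3.0) -> None:
    """T x V array -> 4-D NIfTI on the given grid."""
    t = bold.shape[0]
    vol = np.asarray(bold, dtype=np.float32).T.reshape(*grid, t)
    img = nib.Nifti1Image(vol, _default_affine())
    img.header.set_zooms((3.0, 3.0, 3.0, tr))
    nib.save(img, str(path))


def load_bold_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float32)
    grid = vol.shape[:3]
    return vol.reshape(-1, vol.shape[3]).T, grid


def save_parcellation_nifti(labels: np.ndarray, grid: tuple, path) -> None:
    vol = np.asarray(labels, dtype=np.int32).reshape(grid)
    nib.save(nib.Nifti1Image(vol, _default_affine()), str(path))


def load_parcellation_nifti(path) -> tuple[np.ndarray, tuple]:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj).astype(int)
    return vol.ravel(), vol.shape


def save_map_nifti(map_values: np.ndarray, grid: tuple, path) -> None:
    vol = np.asarray(map_values, dtype=np.float32).reshape(grid)
    nib.save(nib.Nifti1Image(vol, _default_affine()), str(path))


def extract_module_series(bold: np.ndarray, voxel_labels: np.ndarray, module: int) -> np.ndarray:
    """T x V_module block of one module's voxels."""
    voxel_labels = np.asarray(voxel_labels).ravel()
    if voxel_labels.shape[0] != bold.shape[1]:
        raise ValueError("parcellation size does not match BOLD voxel count")
    idx = np.flatnonzero(voxel_labels == module)
    if idx.size == 0:
        raise ValueError(f"module {module} has no voxels in the parcellation")
    return bold[:, idx]
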