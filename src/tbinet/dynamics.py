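"""Per-module BOLD dynamics: representative timecourse and descriptors.

Each module is summarized by the timecourse of the first principal component
of its voxel (or ROI) series.  Four descriptors characterize the dynamics:
sample variance, skewness, kurtosis (raw 4th standardized moment, Gaussian
reference 3), and the point-process count of frames exceeding the mean plus
one standard deviation.  High-motion frames (framewise displacement above a
threshold, default 0.5 mm) can be replaced by natural cubic-spline
interpolation before the component is extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline

from . import stats

__all__ = [
    "ModuleTimeSeries",
    "DynamicsDescriptors",
    "scrub_interpolate",
    "first_principal_timecourse",
    "dynamics_descriptors",
    "cohort_dynamics_descriptors",
    "dynamics_group_comparison",
]


@dataclass
class ModuleTimeSeries:
    timecourse: np.ndarray
    explained_variance: float
    tr: float = 3.0
    module: int | None = None

    def __post_init__(self) -> None:
        self.timecourse = np.asarray(self.timecourse, dtype=float)
        if not 0.0 <= self.explained_variance <= 1.0 + 1e-9:
            raise ValueError("explained_variance must be in [0, 1]")


@dataclass
class DynamicsDescriptors:
    variance: float
    skewness: float
    kurtosis: float
    ppa_count: int

    def as_dict(self) -> dict:
        return {
            "variance": self.variance,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "ppa_count": self.ppa_count,
        }


def scrub_interpolate(
    series: np.ndarray, fd: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Replace high-motion frames by natural cubic-spline interpolation.

    Frames with FD > threshold are recomputed from the unflagged frames; a
    flagged run at either boundary is held at the nearest unflagged value
    (a spline extrapolation there would be unconstrained).
    """
    series = np.asarray(series, dtype=float)
    fd = np.asarray(fd, dtype=float)
    squeeze = series.ndim == 1
    x = series[:, None] if squeeze else series.copy()
    if fd.shape[0] != x.shape[0]:
        raise ValueError("series and motion trace lengths differ")
    if np.any(fd < 0) or not np.all(np.isfinite(fd)):
        raise ValueError("framewise displacement must be nonnegative and finite")
    flagged = fd > threshold
    clean = np.flatnonzero(~flagged)
    if clean.size < 4:
        raise ValueError(
            f"only {clean.size} frames below the motion threshold; need >= 4"
        )
    if flagged.any():
        out = x.copy()
        cs = CubicSpline(clean, x[clean], bc_type="natural")
        interior = np.flatnonzero(flagged & (np.arange(x.shape[0]) > clean[0]) & (np.arange(x.shape[0]) < clean[-1]))
        if interior.size:
            out[interior] = cs(interior)
        out[: clean[0]] = x[clean[0]]
        out[clean[-1] + 1 :] = x[clean[-1]]
        x = out
    return x[:, 0] if squeeze else x


def first_principal_timecourse(
    voxel_series: np.ndarray, tr: float = 3.0, module: int | None = None
) -> ModuleTimeSeries:
    """Leading principal-component timecourse of a T x V module block.

    Columns are centered internally; the component sign is fixed so that its
    correlation with the module-mean timecourse is nonnegative.  The
    explained-variance fraction is the leading eigenvalue share.
    """
    x = np.asarray(voxel_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("voxel series must be T x V")
    t, v = x.shape
    if v < 2:
        raise ValueError("need at least 2 voxels")
    xc = x - x.mean(axis=0)
    if np.allclose(xc, 0):
        raise ValueError("module series is constant; no principal component")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    tc = u[:, 0] * s[0]
    ev = float(s[0] ** 2 / (s**2).sum())
    mean_tc = xc.mean(axis=1)
    if np.dot(tc, mean_tc) < 0:
        tc = -tc
    return ModuleTimeSeries(timecourse=tc, explained_variance=ev, tr=tr, module=module)


def dynamics_descriptors(timecourse: np.ndarray) -> DynamicsDescriptors:
    """Variance, skewness, kurtosis and peak count of one timecourse.

    Variance uses the n-1 denominator; skewness/kurtosis are the plain
    standardized 3rd/4th moments (kurtosis of a Gaussian is 3); the point
    count uses the strict threshold mean + 1 * sample SD.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-D timecourse with at least 8 frames")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("constant timecourse; descriptors undefined")
    return DynamicsDescriptors(
        variance=float(np.var(x, ddof=1)),
        skewness=float(sps.skew(x, bias=True)),
        kurtosis=float(sps.kurtosis(x, fisher=False, bias=True)),
        ppa_count=int(np.sum(x > x.mean() + sd)),
    )


def cohort_dynamics_descriptors(
    bold_by_subject: dict,
    voxel_labels: np.ndarray,
    motion_by_subject: dict | None = None,
    fd_threshold: float = 0.5,
    tr: float = 3.0,
    subjects=None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Descriptor tables (subjects x modules) for a whole cohort.

    ``bold_by_subject`` maps subject -> T x V voxel series; ``voxel_labels``
    assigns each voxel to a module (1..M).  If motion traces are supplied,
    high-FD frames are scrubbed before the principal component is extracted.
    Returns one DataFrame per descriptor plus the explained-variance table.
    """
    voxel_labels = np.asarray(voxel_labels, dtype=int)
    modules = np.unique(voxel_labels[voxel_labels > 0])
    subjects = list(bold_by_subject) if subjects is None else list(subjects)
    names = ["variance", "skewness", "kurtosis", "ppa_count"]
    tables: dict[str, list] = {n: [] for n in names}
    ev_rows = []
    for s in subjects:
        x = np.asarray(bold_by_subject[s], dtype=float)
        if motion_by_subject is not None:
            x = scrub_interpolate(x, motion_by_subject[s], threshold=fd_threshold)
        row = {n: {} for n in names}
        ev_row = {}
        for m in modules:
            block = x[:, voxel_labels == m]
            ts = first_principal_timecourse(block, tr=tr, module=int(m))
            d = dynamics_descriptors(ts.timecourse).as_dict()
            for n in names:
                row[n][f"module_{m}"] = d[n]
            ev_row[f"module_{m}"] = ts.explained_variance
        for n in names:
            tables[n].append(row[n])
        ev_rows.append(ev_row)
    out = {
        n: pd.DataFrame(tables[n], index=subjects).astype(float) for n in names
    }
    return out, pd.DataFrame(ev_rows, index=subjects).astype(float)


def dynamics_group_comparison(
    descriptors: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=("age", "fd_mean"),
    contrast=stats.CONTRAST_CONTROL_MINUS_TBI,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module descriptor comparison (same machinery as the degree test),
    with the functional head-motion covariate (mean FD)."""
    return stats.group_comparison_table(
        descriptors,
        cohort,
        covariates=covariates,
        contrast=contrast,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
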