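"""Posturography scoring: COP path length and directional control.

Three force-platform protocols are supported.  The sensory organization test
(SOT; quiet stance under four sensory conditions, three 20-s trials each at
100 Hz) is scored by the inverse path length (iPL) of the center-of-pressure
trajectory, so higher scores mean less body sway.  The limits-of-stability
(LOS; eight goal-directed lean directions) and rhythmic weight shift (RWS;
two directions x three speeds) protocols are scored by directional control,

    DC = (on-target - off-target movement) / on-target movement * 100%,

where each displacement increment is decomposed into its component along the
target direction (on-target, absolute projection by default) and the residual
orthogonal magnitude (off-target).  Only a perfectly straight path scores
100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "SwayTrajectory",
    "BalanceScores",
    "path_length",
    "inverse_path_length",
    "directional_control",
    "aggregate_scores",
    "behavior_brain_association",
    "SOT_CONDITIONS",
    "LOS_DIRECTIONS",
    "RWS_TRIALS",
]

SOT_CONDITIONS = (1, 2, 3, 4)
LOS_DIRECTIONS = tuple(range(1, 9))
RWS_TRIALS = tuple(range(1, 7))  # 2 directions x 3 speeds


@dataclass
class SwayTrajectory:
    """Timestamped 2-D COP/COG trace for one trial.

    ``protocol`` is 'sot', 'los' or 'rws'; ``condition`` identifies the SOT
    condition (1-4), LOS direction (1-8) or RWS speed x direction (1-6);
    ``target`` is the LOS/RWS unit target direction.
    """

    samples: np.ndarray  # (n, 2) mm
    fs: float = 100.0
    protocol: str = "sot"
    condition: int = 1
    trial: int = 1
    fall: bool = False
    target: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array")
        if self.samples.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs


@dataclass
class BalanceScores:
    """Per-subject protocol scores (one row each in the cohort table)."""

    ipl_sot: float
    dc_los: float
    dc_rws: float

    def as_dict(self) -> dict:
        return {"ipl_sot": self.ipl_sot, "dc_los": self.dc_los, "dc_rws": self.dc_rws}


def path_length(traj: SwayTrajectory | np.ndarray) -> float:
    """Total Euclidean length (mm) of the sampled trajectory."""
    xy = traj.samples if isinstance(traj, SwayTrajectory) else np.asarray(traj, float)
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def inverse_path_length(traj: SwayTrajectory | np.ndarray) -> float:
    """iPL = 1 / path length (mm^-1); undefined for a zero-length path."""
    pl = path_length(traj)
    if pl == 0:
        raise ValueError("zero path length; inverse path length undefined")
    return 1.0 / pl


def directional_control(
    traj: SwayTrajectory | np.ndarray,
    target_direction: np.ndarray | None = None,
    mode: str = "absolute",
) -> float:
    """Directional-control percentage of a goal-directed trajectory.

    ``mode='absolute'`` (default) sums |increment . u| as on-target movement;
    ``mode='net'`` sums the signed projections (net displacement along the
    target).  Off-target movement is the summed orthogonal magnitude either
    way.  Raises when there is no on-target movement.
    """
    if isinstance(traj, SwayTrajectory):
        xy = traj.samples
        if target_direction is None:
            target_direction = traj.target
    else:
        xy = np.asarray(traj, dtype=float)
    if target_direction is None:
        raise ValueError("a target direction is required")
    u = np.asarray(target_direction, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise ValueError("target direction must be nonzero")
    u = u / nu
    if mode not in ("absolute", "net"):
        raise ValueError("mode must be 'absolute' or 'net'")
    inc = np.diff(xy, axis=0)
    proj = inc @ u
    on = float(np.sum(np.abs(proj))) if mode == "absolute" else float(np.sum(proj))
    off = float(np.sum(np.linalg.norm(inc - np.outer(proj, u), axis=1)))
    if on <= 0:
        raise ValueError("no on-target movement; directional control undefined")
    return (on - off) / on * 100.0


def _sot_score(trials: list[SwayTrajectory]) -> float:
    by_cond: dict[int, list[float]] = {c: [] for c in SOT_CONDITIONS}
    for t in trials:
        if t.fall:
            continue
        by_cond.setdefault(t.condition, []).append(inverse_path_length(t))
    missing = [c for c in SOT_CONDITIONS if not by_cond.get(c)]
    if missing:
        raise ValueError(f"SOT conditions with no non-fall trials: {missing}")
    return float(np.mean([np.mean(by_cond[c]) for c in SOT_CONDITIONS]))


def _dc_score(trials: list[SwayTrajectory], required, protocol: str, mode: str) -> float:
    by_cond: dict[int, list[float]] = {}
    for t in trials:
        if t.fall:
            continue
        by_cond.setdefault(t.condition, []).append(
            directional_control(t, mode=mode)
        )
    missing = [c for c in required if not by_cond.get(c)]
    if missing:
        raise ValueError(f"{protocol.upper()} conditions with no usable trials: {missing}")
    return float(np.mean([np.mean(by_cond[c]) for c in required]))


def aggregate_scores(trials: list[SwayTrajectory], dc_mode: str = "absolute") -> BalanceScores:
    """Protocol aggregation of one subject's trials into the three indexes.

    SOT: mean iPL over non-fall trials within each of the 4 conditions, then
    the mean across conditions.  LOS: mean DC across the 8 directions.  RWS:
    mean DC across the 6 speed x direction trials.  A required condition with
    no usable trial raises, naming the condition.
    """
    sot = [t for t in trials if t.protocol == "sot"]
    los = [t for t in trials if t.protocol == "los"]
    rws = [t for t in trials if t.protocol == "rws"]
    return BalanceScores(
        ipl_sot=_sot_score(sot),
        dc_los=_dc_score(los, LOS_DIRECTIONS, "los", dc_mode),
        dc_rws=_dc_score(rws, RWS_TRIALS, "rws", dc_mode),
    )


def cohort_balance_scores(trials_by_subject: dict, dc_mode: str = "absolute") -> pd.DataFrame:
    rows = {s: aggregate_scores(tr, dc_mode).as_dict() for s, tr in trials_by_subject.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def behavior_brain_association(
    descriptor: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    residualize: str = "x_only",
) -> dict:
    """Association between an imaging descriptor and a balance score.

    By default only the imaging descriptor is residualized on the covariates
    (age, mean FD) -- the "corrected" descriptor -- and correlated with the
    raw behavioral score by both Pearson and Spearman.
    """
    return stats.adjusted_association(
        np.asarray(descriptor, float),
        np.asarray(scores, float),
        covariates=covariates,
        residualize=residualize,
    )
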