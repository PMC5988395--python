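"""Synthetic multimodal cohorts with planted, ground-truth-recorded effects.

The generator emulates the study design every pipeline stage is validated
against: a 27-control / 14-TBI cohort with matched age and sex; hierarchically
modular structural and functional connectomes (nested stochastic block model
plus module-coherent latent signals); voxel BOLD on a small 3-D grid whose
fine modules carry one of five latent "family" signals (the five spatial-map
families the MRC clustering must recover); per-frame head-motion traces; and
20-s, 100-Hz center-of-pressure trajectories whose sway magnitude is coupled
to the planted imaging effect.

Planted group effects, all parameterized in an :class:`EffectSpec` and written
to a ground-truth record:

* a TBI degree *deficit* in named coarse-level modules (inter-module edge
  probabilities thinned by the amount that yields the requested Cohen's d on
  module degree),
* a TBI degree *surplus* in one fine-level "prefrontal" module,
* a variance *surplus* of that module's BOLD latent signal in TBI subjects,
* a TBI-only "frontal recruitment" blob: blob voxels additionally load on one
  spatial-map family's latent signal,
* a negative coupling between the planted module variance and the iPL-SOT
  balance score (parameterized as the planted partial correlation).

Everything is a deterministic function of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import ConnectomePair, Partition
from .balance import SwayTrajectory

__all__ = [
    "EffectSpec",
    "GroundTruth",
    "SyntheticCohort",
    "module_hierarchy",
    "simulate_multimodal_connectome",
    "simulate_cohort",
    "simulate_sway",
]

N_FAMILIES = 5
_SQRT_HALF_PI = float(np.sqrt(np.pi / 2.0))


@dataclass
class EffectSpec:
    """Planted group effects, in Cohen's-d units unless noted.

    ``behavior_coupling`` is the planted partial correlation between the
    variance-surplus module's latent variance and the iPL-SOT score
    (negative: more prefrontal dynamics, more sway).
    """

    degree_deficit_modules: tuple = (7, 8)  # coarse-level, control > tbi
    degree_deficit_size: float = 1.0
    degree_surplus_module: int = 11  # fine-level "prefrontal" module, tbi > control
    degree_surplus_size: float = 0.9
    variance_surplus_module: int = 11  # fine-level, tbi > control
    variance_surplus_size: float = 0.9
    frontal_blob_amplitude: float = 1.0  # tbi-only loading on one map family
    behavior_coupling: float = -0.85  # planted partial correlation

    @classmethod
    def default_for(cls, coarse_m: int, fine_m: int) -> "EffectSpec":
        """Default effects re-addressed to a smaller hierarchy: the deficit
        hits the last two coarse modules, the prefrontal module keeps its
        default index when it exists."""
        return cls(
            degree_deficit_modules=(max(1, coarse_m - 1), coarse_m),
            degree_surplus_module=min(11, fine_m),
            variance_surplus_module=min(11, fine_m),
        )

    @classmethod
    def null(cls) -> "EffectSpec":
        """Zero-effect spec: every downstream group test should calibrate."""
        return cls(
            degree_deficit_modules=(),
            degree_deficit_size=0.0,
            degree_surplus_module=1,
            degree_surplus_size=0.0,
            variance_surplus_module=1,
            variance_surplus_size=0.0,
            frontal_blob_amplitude=0.0,
            behavior_coupling=0.0,
        )

    def validate(self, coarse_m: int, fine_m: int) -> None:
        for m in self.degree_deficit_modules:
            if not 1 <= m <= coarse_m:
                raise ValueError(f"deficit module {m} not in coarse hierarchy 1..{coarse_m}")
        for name, m in (
            ("degree_surplus_module", self.degree_surplus_module),
            ("variance_surplus_module", self.variance_surplus_module),
        ):
            if not 1 <= m <= fine_m:
                raise ValueError(f"{name}={m} not in fine hierarchy 1..{fine_m}")
        if not np.isfinite(
            [
                self.degree_deficit_size,
                self.degree_surplus_size,
                self.variance_surplus_size,
                self.frontal_blob_amplitude,
                self.behavior_coupling,
            ]
        ).all():
            raise ValueError("effect sizes must be finite")


@dataclass
class GroundTruth:
    """Every planted quantity a downstream oracle comparison needs."""

    effects: EffectSpec
    coarse_of_fine: np.ndarray
    family_of_fine: np.ndarray
    recruitment_family: int
    blob_voxels: np.ndarray
    latent_amplitude: pd.DataFrame  # subjects x fine modules
    target_ipl: pd.Series
    planted_r: float
    behavior_noise: pd.Series


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame
    connectomes: dict
    bold: dict
    motion: dict
    sway: dict
    voxel_labels: np.ndarray
    grid: tuple
    fine_partition: Partition
    coarse_partition: Partition
    tr: float
    truth: GroundTruth

    @property
    def subjects(self) -> list:
        return list(self.cohort.index)


def module_hierarchy(n_roi: int, coarse_m: int, fine_m: int) -> tuple[np.ndarray, np.ndarray]:
    """Nested two-level assignment: ROI -> fine module -> coarse module."""
    if fine_m < coarse_m:
        raise ValueError("fine level must have at least as many modules as coarse")
    if n_roi < fine_m:
        raise ValueError("need at least one ROI per fine module")
    fine_labels = np.concatenate(
        [np.full(len(c), i + 1) for i, c in enumerate(np.array_split(np.arange(n_roi), fine_m))]
    )
    coarse_of_fine = np.concatenate(
        [np.full(len(c), i + 1) for i, c in enumerate(np.array_split(np.arange(fine_m), coarse_m))]
    )
    return fine_labels, coarse_of_fine


def _pair_prob_matrix(
    fine_labels: np.ndarray,
    coarse_of_fine: np.ndarray,
    p_in: float,
    p_mid: float,
    p_out: float,
) -> np.ndarray:
    coarse_labels = coarse_of_fine[fine_labels - 1]
    same_fine = fine_labels[:, None] == fine_labels[None, :]
    same_coarse = coarse_labels[:, None] == coarse_labels[None, :]
    p = np.where(same_fine, p_in, np.where(same_coarse, p_mid, p_out))
    np.fill_diagonal(p, 0.0)
    return p


def _ar1_laplace(rng: np.random.Generator, t: int, rho: float = 0.3, size: int = 1) -> np.ndarray:
    """Unit-variance supergaussian signals with mild temporal autocorrelation.

    Returns a (size, t) array of AR(1)-filtered Laplace innovations; the
    heavy tails keep the sources identifiable for ICA.
    """
    from scipy.signal import lfilter

    innov = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=(size, t))
    x = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], innov, axis=1)
    x[:, 0] = innov[:, 0]
    return x / x.std(axis=1, keepdims=True)


def simulate_multimodal_connectome(
    n_roi: int = 200,
    coarse_m: int = 8,
    fine_m: int = 20,
    p_in: float = 0.6,
    p_out: float = 0.05,
    p_mid: float | None = None,
    coupling: float = 0.6,
    seed: int = 0,
    t_latent: int = 150,
    prob_adjust: np.ndarray | None = None,
) -> ConnectomePair:
    """One subject's structural + functional pair from a nested block model.

    Structural adjacency: Bernoulli edges with probability ``p_in`` within a
    fine module, ``p_mid`` (default sqrt(p_in * p_out)) within a coarse module
    across fine modules, and ``p_out`` across coarse modules; ``prob_adjust``
    (same shape) lets the cohort generator plant degree effects.  Functional
    matrix: Pearson correlations of module-coherent latent signals whose
    coherence strength is ``coupling``, so FC blocks align with SC blocks.
    """
    if not 0 < p_out < p_in < 1:
        raise ValueError("need 0 < p_out < p_in < 1")
    if not 0 <= coupling < 1:
        raise ValueError("coupling must be in [0, 1)")
    if p_mid is None:
        p_mid = float(np.sqrt(p_in * p_out))
    fine_labels, coarse_of_fine = module_hierarchy(n_roi, coarse_m, fine_m)
    rng = np.random.default_rng(seed)
    p = _pair_prob_matrix(fine_labels, coarse_of_fine, p_in, p_mid, p_out)
    if prob_adjust is not None:
        p = np.clip(p + prob_adjust, 0.0, 1.0)
        np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(n_roi, k=1)
    edges = rng.random(iu[0].size) < p[iu]
    sc = np.zeros((n_roi, n_roi), dtype=int)
    sc[iu[0][edges], iu[1][edges]] = 1
    sc = sc + sc.T

    # module-coherent latent signals -> correlation matrix
    coarse_labels = coarse_of_fine[fine_labels - 1]
    flat = fine_m == coarse_m
    g = rng.standard_normal((coarse_m, t_latent))
    h = rng.standard_normal((fine_m, t_latent))
    noise = rng.standard_normal((n_roi, t_latent))
    if flat:
        w_c, w_f = coupling, 0.0
    else:
        w_c, w_f = 0.6 * coupling, 0.4 * coupling
    series = (
        np.sqrt(w_c) * g[coarse_labels - 1]
        + (np.sqrt(w_f) * h[fine_labels - 1] if w_f > 0 else 0.0)
        + np.sqrt(1.0 - w_c - w_f) * noise
    )
    fc = np.corrcoef(series)
    np.fill_diagonal(fc, 1.0)
    return ConnectomePair(sc=sc, fc=np.clip(fc, -1, 1))


def _degree_deficit_adjust(
    fine_labels: np.ndarray,
    coarse_of_fine: np.ndarray,
    effects: EffectSpec,
    p_mid: float,
    p_out: float,
) -> np.ndarray:
    """Per-pair probability shifts realizing the planted degree effects.

    A module's inter-module degree is a sum of independent Bernoulli links, so
    a mean shift of d standard deviations needs a per-pair probability change
    of d * sqrt(sum p(1-p)) / n_pairs over the module's inter-module pairs.
    """
    n_roi = fine_labels.shape[0]
    coarse_labels = coarse_of_fine[fine_labels - 1]
    adjust = np.zeros((n_roi, n_roi))

    if effects.degree_deficit_size > 0:
        for cmod in effects.degree_deficit_modules:
            inside = coarse_labels == cmod
            pairs = np.outer(inside, ~inside)
            pairs = pairs | pairs.T
            n_pairs = pairs.sum() / 2
            # all coarse-crossing pairs have probability p_out
            sd = np.sqrt(n_pairs * p_out * (1 - p_out))
            delta = effects.degree_deficit_size * sd / n_pairs
            adjust[pairs] -= delta

    if effects.degree_surplus_size > 0:
        fmod = effects.degree_surplus_module
        inside = fine_labels == fmod
        pairs = np.outer(inside, ~inside)
        pairs = pairs | pairs.T
        same_coarse = coarse_labels == coarse_of_fine[fmod - 1]
        base = np.where(np.outer(inside, same_coarse & ~inside), p_mid, p_out)
        mask = np.triu(pairs, k=1)
        var = float(np.sum(base[mask] * (1 - base[mask])))
        n_pairs = mask.sum()
        delta = effects.degree_surplus_size * np.sqrt(var) / n_pairs
        adjust[pairs] += delta

    return adjust


def _grid_parcellation(grid: tuple, fine_m: int) -> np.ndarray:
    """Deterministic contiguous parcels: voxels in lexicographic order split
    into fine_m equal blocks."""
    n_vox = int(np.prod(grid))
    if n_vox < 4 * fine_m:
        raise ValueError("grid too small for the requested number of modules")
    labels = np.concatenate(
        [np.full(len(c), i + 1) for i, c in enumerate(np.array_split(np.arange(n_vox), fine_m))]
    )
    return labels


def _blob_voxels(grid: tuple, voxel_labels: np.ndarray, module: int) -> np.ndarray:
    """Sphere of voxels around the centroid of one module's parcel."""
    coords = np.stack(np.unravel_index(np.arange(voxel_labels.size), grid), axis=1)
    center = coords[voxel_labels == module].mean(axis=0)
    radius = max(2.0, min(grid) / 8.0)
    d = np.linalg.norm(coords - center, axis=1)
    return np.flatnonzero(d <= radius)


def simulate_sway(
    sway_sd: float,
    duration: float = 20.0,
    fs: float = 100.0,
    protocol: str = "sot",
    seed: int = 0,
    condition: int = 1,
    trial: int = 1,
    target: np.ndarray | None = None,
    amplitude: float = 80.0,
    pace: float = 2.0,
    kappa: float = 0.02,
) -> SwayTrajectory:
    """One force-platform trial.

    SOT: a mean-reverting (bounded) random walk with per-step jitter SD
    ``sway_sd`` (mm).  LOS: a ramp of length ``amplitude`` toward ``target``
    plus jitter.  RWS: a sinusoidal weight shift along ``target`` at the
    given pace (seconds per half cycle) plus jitter.  The sample count is
    exactly duration * fs.
    """
    if sway_sd < 0:
        raise ValueError("sway_sd must be nonnegative")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    jitter = rng.standard_normal((n, 2)) * sway_sd
    if protocol == "sot":
        pos = np.zeros((n, 2))
        for i in range(1, n):
            pos[i] = pos[i - 1] * (1 - kappa) + jitter[i]
        xy = pos
    elif protocol in ("los", "rws"):
        if target is None:
            raise ValueError(f"{protocol} trials need a target direction")
        u = np.asarray(target, dtype=float)
        u = u / np.linalg.norm(u)
        t = np.arange(n) / fs
        if protocol == "los":
            ramp = amplitude * np.minimum(t / (0.6 * duration), 1.0)
            xy = np.outer(ramp, u) + np.cumsum(jitter, axis=0) * 0.05
        else:
            wave = amplitude / 2.0 * np.sin(np.pi * t / pace)
            xy = np.outer(wave, u) + np.cumsum(jitter, axis=0) * 0.05
    else:
        raise ValueError("protocol must be 'sot', 'los' or 'rws'")
    return SwayTrajectory(
        samples=xy,
        fs=fs,
        protocol=protocol,
        condition=condition,
        trial=trial,
        fall=False,
        target=None if protocol == "sot" else u,
    )


def _subject_sway_trials(
    rng: np.random.Generator, target_ipl: float, fs: float = 100.0
) -> list[SwayTrajectory]:
    """SOT/LOS/RWS trial set whose aggregate iPL-SOT lands near target_ipl."""
    trials: list[SwayTrajectory] = []
    n_steps = int(round(20.0 * fs))
    factors = np.array([0.85, 0.95, 1.05, 1.15])  # condition difficulty
    sigma0 = float(np.mean(1.0 / factors)) / (target_ipl * n_steps * _SQRT_HALF_PI)
    for cond, f in zip((1, 2, 3, 4), factors):
        for tr in (1, 2, 3):
            trials.append(
                simulate_sway(
                    sigma0 * f,
                    protocol="sot",
                    condition=cond,
                    trial=tr,
                    seed=int(rng.integers(2**31)),
                    fs=fs,
                )
            )
    for d in range(8):
        ang = 2 * np.pi * d / 8
        trials.append(
            simulate_sway(
                0.4,
                duration=8.0,
                protocol="los",
                condition=d + 1,
                seed=int(rng.integers(2**31)),
                target=np.array([np.cos(ang), np.sin(ang)]),
                fs=fs,
            )
        )
    for i, (pace, ang) in enumerate(
        [(3.0, 0.0), (2.0, 0.0), (1.0, 0.0), (3.0, np.pi / 2), (2.0, np.pi / 2), (1.0, np.pi / 2)]
    ):
        trials.append(
            simulate_sway(
                0.4,
                duration=6 * pace,
                protocol="rws",
                condition=i + 1,
                pace=pace,
                seed=int(rng.integers(2**31)),
                target=np.array([np.cos(ang), np.sin(ang)]),
                fs=fs,
            )
        )
    return trials


def simulate_cohort(
    effects: EffectSpec | None = None,
    n_control: int = 27,
    n_tbi: int = 14,
    n_roi: int = 200,
    coarse_m: int = 8,
    fine_m: int = 20,
    grid: tuple = (24, 24, 24),
    n_frames: int = 200,
    tr: float = 3.0,
    p_in: float = 0.6,
    p_out: float = 0.05,
    coupling: float = 0.6,
    seed: int = 0,
    with_sway: bool = True,
) -> SyntheticCohort:
    """Complete synthetic cohort with every planted effect recorded.

    Defaults reproduce the emulated study conditions: 27 controls + 14 TBI,
    a 24^3 voxel grid with 200 BOLD frames at TR = 3 s, 200 ROIs in an
    8-coarse / 20-fine nested hierarchy, and ages drawn uniformly on 8-19 y
    with identically distributed head motion in both groups (matched design).
    """
    effects = EffectSpec() if effects is None else effects
    effects.validate(coarse_m, fine_m)
    ss = np.random.SeedSequence(seed)
    rng_cohort, rng_signals, rng_sway, rng_behavior = [
        np.random.default_rng(c) for c in ss.spawn(4)
    ]

    subjects = [f"C{i + 1:02d}" for i in range(n_control)] + [
        f"T{i + 1:02d}" for i in range(n_tbi)
    ]
    groups = ["control"] * n_control + ["tbi"] * n_tbi
    n_sub = len(subjects)
    cohort = pd.DataFrame(
        {
            "group": groups,
            "age": rng_cohort.uniform(8.0, 19.0, size=n_sub),
            "sex": rng_cohort.choice(["M", "F"], size=n_sub),
        },
        index=pd.Index(subjects, name="subject"),
    )

    fine_labels, coarse_of_fine = module_hierarchy(n_roi, coarse_m, fine_m)
    fine_part = Partition(labels=fine_labels)
    coarse_part = Partition(labels=coarse_of_fine[fine_labels - 1])
    p_mid = float(np.sqrt(p_in * p_out))
    adjust = _degree_deficit_adjust(fine_labels, coarse_of_fine, effects, p_mid, p_out)

    voxel_labels = _grid_parcellation(grid, fine_m)
    family_of_fine = (np.arange(fine_m) % N_FAMILIES) + 1
    pf = effects.variance_surplus_module
    recruitment_family = int(family_of_fine[pf - 1] % N_FAMILIES + 1)
    blob = _blob_voxels(grid, voxel_labels, pf)

    # per-frame framewise displacement and eddy-correction displacement
    fd_traces = {
        s: rng_cohort.lognormal(np.log(0.2), 0.4, size=n_frames) for s in subjects
    }
    cohort["fd_mean"] = [fd_traces[s].mean() for s in subjects]
    cohort["eddy_motion_mean"] = rng_cohort.lognormal(np.log(0.5), 0.3, size=n_sub)

    # subject-level latent amplitude per fine module (lognormal heterogeneity);
    # the TBI variance surplus shifts the log-amplitude of the planted module
    # by half the requested d times the total log-variance spread (amplitude
    # enters the variance descriptor squared).
    s_amp = 0.15
    rho = 0.3
    t_eff = n_frames * (1 - rho) / (1 + rho)
    log_var_sd = float(np.sqrt(s_amp**2 + 2.0 / t_eff))
    amp_shift = effects.variance_surplus_size * log_var_sd / 2.0
    log_amp = rng_signals.normal(0.0, s_amp, size=(n_sub, fine_m))
    for i, g in enumerate(groups):
        if g == "tbi" and effects.variance_surplus_size > 0:
            log_amp[i, pf - 1] += amp_shift
    amplitude = pd.DataFrame(np.exp(log_amp), index=cohort.index,
                             columns=[f"module_{m}" for m in range(1, fine_m + 1)])

    w_sig = 0.75  # voxel loading; shared-signal fraction ~ w^2/(w^2+1) ~ 0.36
    alpha, beta = np.sqrt(0.6), np.sqrt(0.4)

    connectomes: dict = {}
    bold: dict = {}
    for i, s in enumerate(subjects):
        is_tbi = groups[i] == "tbi"
        connectomes[s] = simulate_multimodal_connectome(
            n_roi=n_roi,
            coarse_m=coarse_m,
            fine_m=fine_m,
            p_in=p_in,
            p_out=p_out,
            coupling=coupling,
            seed=int(rng_signals.integers(2**31)),
            prob_adjust=adjust if is_tbi else None,
        )
        fam_sig = _ar1_laplace(rng_signals, n_frames, rho, size=N_FAMILIES)
        mod_sig = _ar1_laplace(rng_signals, n_frames, rho, size=fine_m)
        lam = rng_signals.uniform(0.8, 1.2, size=voxel_labels.size)
        amp = amplitude.loc[s].to_numpy()
        shared = (
            alpha * fam_sig[family_of_fine[voxel_labels - 1] - 1]
            + beta * mod_sig[voxel_labels - 1]
        )  # V x T
        x = (
            w_sig * (lam * amp[voxel_labels - 1])[:, None] * shared
            + rng_signals.standard_normal((voxel_labels.size, n_frames))
        )
        if is_tbi and effects.frontal_blob_amplitude > 0:
            x[blob] += effects.frontal_blob_amplitude * fam_sig[recruitment_family - 1]
        bold[s] = np.ascontiguousarray(x.T, dtype=np.float32)  # T x V

    # behavior: iPL-SOT coupled to the planted module's realized variance --
    # the PC1 variance each subject's BOLD actually carries, so the planted
    # correlation is the quantity the association stage estimates
    from .dynamics import dynamics_descriptors, first_principal_timecourse

    r = float(np.clip(effects.behavior_coupling, -0.999, 0.999))
    v = np.array(
        [
            dynamics_descriptors(
                first_principal_timecourse(
                    bold[s][:, voxel_labels == pf].astype(float)
                ).timecourse
            ).variance
            for s in subjects
        ]
    )
    z_v = (v - v.mean()) / v.std() if v.std() > 0 else np.zeros(n_sub)
    z_noise = rng_behavior.standard_normal(n_sub)
    mix = r * z_v + np.sqrt(1 - r**2) * z_noise
    mu_ipl, cv = 0.004, 0.15
    target_ipl = pd.Series(
        np.maximum(mu_ipl * (1 + cv * mix), 0.3 * mu_ipl), index=cohort.index
    )

    sway: dict = {}
    if with_sway:
        for s in subjects:
            sway[s] = _subject_sway_trials(rng_sway, float(target_ipl[s]))

    truth = GroundTruth(
        effects=effects,
        coarse_of_fine=coarse_of_fine,
        family_of_fine=family_of_fine,
        recruitment_family=recruitment_family,
        blob_voxels=blob,
        latent_amplitude=amplitude,
        target_ipl=target_ipl,
        planted_r=r,
        behavior_noise=pd.Series(z_noise, index=cohort.index),
    )
    return SyntheticCohort(
        cohort=cohort,
        connectomes=connectomes,
        bold=bold,
        motion=fd_traces,
        sway=sway,
        voxel_labels=voxel_labels,
        grid=tuple(grid),
        fine_partition=fine_part,
        coarse_partition=coarse_part,
        tr=tr,
        truth=truth,
    )
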