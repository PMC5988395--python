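"""Functional-network mapping by module ICA, spatial-map clustering and
cluster-extent familywise-error control.

For each module, the voxel series are reduced by PCA and unmixed by a
fixed-point (logcosh) ICA into ``C`` unit-variance timecourses.  Each
component's whole-brain spatial map is the voxel-wise multiple-regression
coefficient of that component when all ``C`` components are fit jointly.
The maps of all subjects and modules are pooled and k-means-clustered with a
1 - Pearson-spatial-correlation distance into k "most representative
clusters" (MRCs).  Group contrasts over one MRC's maps yield voxel-wise
t-maps; multiple comparisons are controlled with a Monte-Carlo cluster-extent
threshold (smooth Gaussian noise fields, max-cluster-size null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import stats

__all__ = [
    "ComponentSet",
    "SpatialMapSet",
    "MrcAssignment",
    "ClusterExtentNull",
    "Cluster",
    "module_ica_components",
    "component_spatial_map",
    "cluster_spatial_maps",
    "mrc_group_contrast",
    "cluster_extent_threshold",
    "apply_cluster_correction",
    "DEFAULT_CONTRASTS",
]

DEFAULT_CONTRASTS = {
    "control": stats.CONTRAST_CONTROL,
    "tbi": stats.CONTRAST_TBI,
    "control_gt_tbi": stats.CONTRAST_CONTROL_MINUS_TBI,
    "tbi_gt_control": stats.CONTRAST_TBI_MINUS_CONTROL,
}

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ComponentSet:
    """Unit-variance independent timecourses for one module of one subject."""

    components: np.ndarray  # T x C
    module: int | None = None
    subject: str | None = None
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class SpatialMapSet:
    """Voxel-wise coefficient maps, one per component, on a common grid."""

    maps: np.ndarray  # C x V
    shape: tuple | None = None
    module: int | None = None
    subject: str | None = None


@dataclass
class MrcAssignment:
    labels: np.ndarray  # 1..k per pooled map
    centroids: np.ndarray  # k x V, unit L2 norm
    provenance: pd.DataFrame  # columns module, subject, component
    inertia: float


@dataclass
class ClusterExtentNull:
    shape: tuple
    fwhm: float
    voxel_p: float
    alpha: float
    n_iter: int
    connectivity: int
    two_sided: bool
    min_cluster_size: int
    max_sizes: np.ndarray = field(repr=False, default=None)


@dataclass
class Cluster:
    size: int
    indices: np.ndarray
    peak_value: float
    peak_index: tuple


def module_ica_components(
    voxel_series: np.ndarray,
    n_pca: int = 20,
    n_ica: int = 20,
    seed: int = 0,
    module: int | None = None,
    subject: str | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> ComponentSet:
    """PCA to ``n_pca`` dimensions, then fixed-point ICA to ``n_ica``
    unit-variance timecourses.

    Components are ordered by descending back-projection energy (the variance
    of the module data each component's map carries), which makes the order a
    deterministic function of the input and seed.
    """
    x = np.asarray(voxel_series, dtype=float)
    t, v = x.shape
    if n_ica > n_pca:
        raise ValueError("n_ica cannot exceed n_pca")
    if v <= n_pca or t <= n_pca:
        raise ValueError(f"need more than n_pca={n_pca} voxels and frames")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    if np.sum(s > s[0] * 1e-10) < n_pca:
        raise ValueError(
            f"data rank below n_pca={n_pca}; request fewer principal components"
        )
    scores = u[:, :n_pca] * s[:n_pca]
    ica = FastICA(
        n_components=n_ica,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    # the contract is determinism given the seed, not fixed-point convergence
    # on noisy data; a non-converged unmixing is still a valid rotation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(scores)  # T x C
    sources = (sources - sources.mean(axis=0)) / sources.std(axis=0, ddof=1)
    # back-projection energy of each component in the module data
    energy = np.sum((xc.T @ sources) ** 2, axis=0)
    order = np.argsort(-energy, kind="stable")
    return ComponentSet(
        components=sources[:, order], module=module, subject=subject, seed=seed
    )


def component_spatial_map(
    brain_series: np.ndarray,
    components: ComponentSet,
    shape: tuple | None = None,
) -> SpatialMapSet:
    """Joint multiple regression of every voxel on all components.

    Map value = the voxel's regression coefficient for that component when all
    C component timecourses are fit together (so shared variance is split by
    the least-squares solution, not double-counted).
    """
    y = np.asarray(brain_series, dtype=float)
    c = components.components
    if y.shape[0] != c.shape[0]:
        raise ValueError("brain series and components must share T")
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("collinear components; spatial regression undefined")
    yc = y - y.mean(axis=0)
    cc = c - c.mean(axis=0)
    beta = np.linalg.solve(cc.T @ cc, cc.T @ yc)  # C x V
    return SpatialMapSet(
        maps=beta,
        shape=shape,
        module=components.module,
        subject=components.subject,
    )


def _zscore_rows(maps: np.ndarray) -> np.ndarray:
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"degenerate (constant) spatial map at pooled index {bad[0]}")
    return (maps - mu) / sd


def cluster_spatial_maps(
    pooled_maps: np.ndarray,
    provenance: pd.DataFrame | None = None,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> MrcAssignment:
    """k-means over pooled spatial maps with 1 - Pearson-correlation distance.

    Implemented as Euclidean k-means on row-standardized maps, which is
    monotonically equivalent (1 - corr(a, b) = ||z_a - z_b||^2 / 2V), the
    standard realization of correlation-distance k-means.  Best of
    ``n_restarts`` initializations by within-cluster dissimilarity;
    deterministic given the seed.
    """
    maps = np.asarray(pooled_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < k:
        raise ValueError(f"need at least k={k} maps of equal geometry")
    z = _zscore_rows(maps)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z) + 1
    cent = km.cluster_centers_
    norms = np.linalg.norm(cent, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    cent = cent / norms
    if provenance is None:
        provenance = pd.DataFrame(
            {"module": -1, "subject": "", "component": np.arange(maps.shape[0])}
        )
    provenance = provenance.copy().reset_index(drop=True)
    provenance["mrc"] = labels
    return MrcAssignment(
        labels=labels, centroids=cent, provenance=provenance, inertia=float(km.inertia_)
    )


def mrc_group_contrast(
    maps_by_subject: dict,
    cohort: pd.DataFrame,
    covariates=("age", "fd_mean"),
    contrasts: dict | None = None,
) -> tuple[dict[str, np.ndarray], int, pd.DataFrame]:
    """Voxel-wise GLM t-maps for one MRC of one module.

    ``maps_by_subject`` maps subject id -> (n_i x V) array of that subject's
    maps assigned to the MRC; a subject's maps are averaged first so each
    subject contributes one observation.  Subjects without maps are dropped
    from the design; an entire group without maps is an error.  Returns
    (t-maps keyed by contrast name, residual df, the cohort rows used).
    """
    contrasts = DEFAULT_CONTRASTS if contrasts is None else contrasts
    present = [s for s in cohort.index if s in maps_by_subject and len(maps_by_subject[s])]
    sub_cohort = cohort.loc[present]
    groups = set(sub_cohort["group"])
    if groups != {"control", "tbi"}:
        missing = {"control", "tbi"} - groups
        raise ValueError(f"no maps in this MRC for group(s): {sorted(missing)}")
    y = np.vstack(
        [np.asarray(maps_by_subject[s], dtype=float).mean(axis=0) for s in present]
    )
    design = stats.design_from_cohort(sub_cohort, covariates)
    out: dict[str, np.ndarray] = {}
    df = None
    for name, c in contrasts.items():
        t, _, df = stats.glm_contrast_ttest(y, design, c)
        out[name] = t
    return out, int(df), sub_cohort


def _max_cluster_size(mask: np.ndarray, structure: np.ndarray) -> int:
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))))


def cluster_extent_threshold(
    shape: tuple,
    fwhm: float,
    voxel_p: float,
    alpha: float = 0.05,
    n_iter: int = 10000,
    connectivity: int = 6,
    seed: int = 0,
    two_sided: bool = True,
) -> ClusterExtentNull:
    """Monte-Carlo cluster-size threshold on smooth Gaussian noise fields.

    Each iteration draws an i.i.d. Gaussian field on ``shape``, smooths it to
    the requested FWHM (voxels), restandardizes, thresholds at the voxel-wise
    p (two-sided by default), and records the largest connected cluster under
    the chosen neighbor rule.  The returned minimum cluster size is the
    smallest s with P(max cluster >= s) <= alpha.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = _STRUCTURES[connectivity]
    rng = np.random.default_rng(seed)
    zthr = sps.norm.isf(voxel_p / 2) if two_sided else sps.norm.isf(voxel_p)
    sigma = fwhm * _FWHM_TO_SIGMA
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        field_ = rng.standard_normal(shape)
        if sigma > 0:
            field_ = ndimage.gaussian_filter(field_, sigma=sigma, mode="wrap")
            field_ = field_ / field_.std()
        mask = np.abs(field_) > zthr if two_sided else field_ > zthr
        max_sizes[i] = _max_cluster_size(mask, structure)
    # smallest s with empirical P(max >= s) <= alpha
    s = 1
    while np.mean(max_sizes >= s) > alpha:
        s += 1
    return ClusterExtentNull(
        shape=tuple(shape),
        fwhm=float(fwhm),
        voxel_p=float(voxel_p),
        alpha=float(alpha),
        n_iter=int(n_iter),
        connectivity=int(connectivity),
        two_sided=bool(two_sided),
        min_cluster_size=int(s),
        max_sizes=max_sizes,
    )


def apply_cluster_correction(
    t_map: np.ndarray,
    df: int,
    voxel_p: float,
    null: ClusterExtentNull,
    sided: str = "two",
) -> list[Cluster]:
    """Threshold a t-map at the voxel-forming p and keep clusters that reach
    the Monte-Carlo minimum extent.

    ``sided='two'`` masks |t|; ``'pos'``/``'neg'`` keep one tail only (used
    for directional group-difference contrasts).
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.shape != null.shape:
        raise ValueError(
            f"t-map geometry {t_map.shape} does not match null {null.shape}"
        )
    if sided == "two":
        thr = sps.t.isf(voxel_p / 2, df)
        mask = np.abs(t_map) > thr
    elif sided == "pos":
        thr = sps.t.isf(voxel_p, df)
        mask = t_map > thr
    elif sided == "neg":
        thr = sps.t.isf(voxel_p, df)
        mask = -t_map > thr
    else:
        raise ValueError("sided must be 'two', 'pos' or 'neg'")
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[null.connectivity])
    clusters = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labeled == lab)
        if idx.shape[0] < null.min_cluster_size:
            continue
        vals = t_map[tuple(idx.T)]
        peak = int(np.argmax(np.abs(vals)))
        clusters.append(
            Cluster(
                size=idx.shape[0],
                indices=idx,
                peak_value=float(vals[peak]),
                peak_index=tuple(idx[peak]),
            )
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters
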