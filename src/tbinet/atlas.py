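"""Hierarchical multimodal parcellation of a brain connectome.

A cohort's structural (streamline-count) and functional (BOLD correlation)
ROI x ROI matrices are clustered into nested dendrograms; cutting a tree at a
level ``M`` pools the ROIs into ``M`` modules.  A good level is one whose
modules are simultaneously well separated in the structural graph, well
separated in the functional graph, and similar across the two modalities.
That trade-off is scored by the *cross-modularity* index

    X(M) = (Q_s * Q_f * <S>) ** (1/3)

where ``Q_s``/``Q_f`` are Newman modularities of the structural/functional
cuts and ``<S>`` is the mean best-match Sorensen similarity between the
intramodule edge sets of the two partitions.  ``select_optimal_level``
maximizes X over a range of candidate module counts.

Agglomeration is average-linkage (UPGMA) on dissimilarity: ``1 - fc`` for the
functional tree and ``1 - binarized sc`` (optionally ``1 -`` log-scaled,
min-max-normalized counts) for the structural tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


__all__ = [
    "ConnectomePair",
    "Dendrogram",
    "Partition",
    "ModularityReport",
    "build_dendrogram",
    "cut_dendrogram",
    "newman_modularity",
    "sorensen_similarity",
    "cross_modularity",
    "select_optimal_level",
    "structural_similarity",
    "density_matched_functional_graph",
    "intramodule_edge_sets",
]


def _check_symmetric(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return a


@dataclass
class ConnectomePair:
    """A subject's structural and functional ROI x ROI matrices.

    ``sc`` holds nonnegative integer streamline counts with a zero diagonal;
    ``fc`` holds Pearson correlations (unit diagonal, entries in [-1, 1]).
    Both share the ROI order given by ``roi_ids``.
    """

    sc: np.ndarray
    fc: np.ndarray
    roi_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        sc = _check_symmetric(self.sc, "sc")
        fc = _check_symmetric(self.fc, "fc")
        if sc.shape != fc.shape:
            raise ValueError("sc and fc must have the same shape")
        if np.any(sc < 0):
            raise ValueError("sc must be nonnegative")
        if np.any(np.diag(sc) != 0):
            raise ValueError("sc diagonal must be zero")
        if not np.allclose(np.diag(fc), 1.0, atol=1e-8):
            raise ValueError("fc diagonal must be 1")
        if np.any(np.abs(fc) > 1 + 1e-8):
            raise ValueError("fc entries must lie in [-1, 1]")
        self.sc = sc
        self.fc = np.clip(fc, -1.0, 1.0)
        if not self.roi_ids:
            self.roi_ids = list(range(sc.shape[0]))
        if len(self.roi_ids) != sc.shape[0]:
            raise ValueError("roi_ids length must match matrix size")

    @property
    def n_roi(self) -> int:
        return self.sc.shape[0]


@dataclass
class Dendrogram:
    """Complete agglomerative tree over ROIs (scipy linkage encoding)."""

    linkage: np.ndarray  # (N-1, 4) scipy linkage matrix
    leaves: list
    modality: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class Partition:
    """A cut of the tree into ``n_modules`` modules, labels in 1..M."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("module labels must be contiguous 1..M with no gaps")
        self._n_modules = len(uniq)

    @property
    def n_modules(self) -> int:
        return self._n_modules

    def members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.labels == m)


@dataclass
class ModularityReport:
    m: int
    q_structural: float
    q_functional: float
    mean_sorensen: float
    cross_modularity: float


def build_dendrogram(matrix: np.ndarray, modality: str = "functional") -> Dendrogram:
    """UPGMA tree from a symmetric similarity matrix (entries <= 1).

    Dissimilarity is ``1 - similarity``.  Ties are resolved by scipy's
    deterministic nearest-neighbor-chain ordering, so the tree is a pure
    function of its input.
    """
    sim = _check_symmetric(matrix, "similarity matrix")
    n = sim.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ROIs to build a dendrogram")
    if sim.max() > 1 + 1e-8:
        raise ValueError(
            "similarity entries must be <= 1; rescale raw counts first "
            "(see structural_similarity)"
        )
    diss = 1.0 - sim
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=z, leaves=list(range(n)), modality=modality)


def cut_dendrogram(dend: Dendrogram, n_modules: int) -> Partition:
    """Cut the tree into exactly ``n_modules`` modules (nested across levels)."""
    n = dend.n_leaves
    if not 1 <= n_modules <= n:
        raise ValueError(f"module count must be in [1, {n}], got {n_modules}")
    raw = hierarchy.cut_tree(dend.linkage, n_clusters=n_modules).ravel()
    # relabel 1..M in order of first appearance for determinism
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return Partition(labels=labels)


def newman_modularity(adjacency: np.ndarray, partition: Partition) -> float:
    """Newman's modularity Q = sum_i (e_ii - a_i^2) of a given partition.

    ``e`` is the matrix of edge-weight fractions between modules and ``a_i``
    the marginal fraction attached to module ``i``.  Works for binary or
    weighted symmetric adjacencies; raises on an edgeless graph (Q undefined).
    """
    adj = _check_symmetric(adjacency, "adjacency")
    if np.any(adj < 0):
        raise ValueError("adjacency must be nonnegative")
    adj = adj.copy()
    np.fill_diagonal(adj, 0.0)
    total = adj.sum()  # = 2m for undirected graphs
    if total <= 0:
        raise ValueError("modularity undefined for an edgeless graph")
    labels = partition.labels
    if labels.shape[0] != adj.shape[0]:
        raise ValueError("partition size does not match adjacency")
    q = 0.0
    for m in np.unique(labels):
        idx = labels == m
        e_mm = adj[np.ix_(idx, idx)].sum() / total
        a_m = adj[idx, :].sum() / total
        q += e_mm - a_m**2
    return float(q)


def _canonical_edges(edges) -> frozenset:
    return frozenset(tuple(sorted((int(i), int(j)))) for i, j in edges)


def sorensen_similarity(edges_a, edges_b) -> float:
    """Sorensen index 2|A^B| / (|A|+|B|) between two undirected edge sets."""
    a = _canonical_edges(edges_a)
    b = _canonical_edges(edges_b)
    if not a and not b:
        raise ValueError("Sorensen similarity undefined for two empty edge sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def structural_similarity(sc: np.ndarray, weighted: bool = False) -> np.ndarray:
    """Similarity in [0, 1] from raw streamline counts.

    Binary by default (1 where any streamline exists); the weighted variant
    log1p-scales the counts and min-max normalizes them.
    """
    sc = _check_symmetric(sc, "sc")
    if np.any(sc < 0):
        raise ValueError("sc must be nonnegative")
    if not weighted:
        sim = (sc > 0).astype(float)
    else:
        logd = np.log1p(sc)
        rng = logd.max() - logd.min()
        sim = (logd - logd.min()) / rng if rng > 0 else np.zeros_like(logd)
    np.fill_diagonal(sim, 1.0)
    return sim


def density_matched_functional_graph(fc: np.ndarray, n_edges: int) -> np.ndarray:
    """Binary graph keeping the ``n_edges`` strongest correlations.

    Matching the structural edge density puts the two modalities' graphs on a
    common footing for modularity and edge-set comparison.  Ties are broken by
    ROI-pair index order (deterministic).
    """
    fc = _check_symmetric(fc, "fc")
    n = fc.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = fc[iu]
    if n_edges <= 0 or n_edges > vals.size:
        raise ValueError("n_edges must be in [1, number of ROI pairs]")
    order = np.lexsort((iu[1], iu[0], -vals))  # strongest first, index tie-break
    keep = order[:n_edges]
    g = np.zeros_like(fc)
    g[iu[0][keep], iu[1][keep]] = 1.0
    return g + g.T


def intramodule_edge_sets(adjacency: np.ndarray, partition: Partition) -> dict[int, frozenset]:
    """Per-module set of (i, j) edges with both endpoints inside the module."""
    adj = np.asarray(adjacency)
    out: dict[int, frozenset] = {}
    for m in range(1, partition.n_modules + 1):
        idx = partition.members(m)
        sub = adj[np.ix_(idx, idx)]
        ii, jj = np.nonzero(np.triu(sub, k=1))
        out[m] = frozenset((int(idx[i]), int(idx[j])) for i, j in zip(ii, jj))
    return out


def _mean_best_match_sorensen(sets_a: dict, sets_b: dict) -> float:
    """Symmetrized mean of best-match Sorensen similarity across partitions.

    Modules with empty intramodule edge sets contribute 0 (a module wired to
    nothing shares no connections with any module of the other modality).
    """

    def directed(src: dict, dst: dict) -> float:
        scores = []
        for ea in src.values():
            best = 0.0
            for eb in dst.values():
                if not ea and not eb:
                    continue
                s = 2.0 * len(ea & eb) / (len(ea) + len(eb)) if (ea or eb) else 0.0
                best = max(best, s)
            scores.append(best)
        return float(np.mean(scores)) if scores else 0.0

    return 0.5 * (directed(sets_a, sets_b) + directed(sets_b, sets_a))


def cross_modularity(
    pair: ConnectomePair,
    n_modules: int,
    weighted_structural_tree: bool = False,
) -> ModularityReport:
    """Score one hierarchy level M of a structural-functional pair.

    Builds both dendrograms, cuts them at M, evaluates Q on each modality's
    binary graph (functional graph density-matched to the structural one) and
    the symmetrized best-match Sorensen similarity <S> between intramodule
    edge sets, and combines them as X = (Q_s * Q_f * <S>)^(1/3), clipped to 0
    whenever any factor is negative.
    """
    n = pair.n_roi
    if not 2 <= n_modules <= n:
        raise ValueError(f"n_modules must be in [2, {n}]")
    sc_bin = (pair.sc > 0).astype(float)
    np.fill_diagonal(sc_bin, 0.0)
    n_edges = int(np.triu(sc_bin, k=1).sum())
    if n_edges == 0:
        raise ValueError("structural matrix has no edges")
    f_graph = density_matched_functional_graph(pair.fc, n_edges)

    dend_s = build_dendrogram(
        structural_similarity(pair.sc, weighted=weighted_structural_tree), "structural"
    )
    dend_f = build_dendrogram(np.clip(pair.fc, -1, 1), "functional")
    part_s = cut_dendrogram(dend_s, n_modules)
    part_f = cut_dendrogram(dend_f, n_modules)

    q_s = newman_modularity(sc_bin, part_s)
    q_f = newman_modularity(f_graph, part_f)
    mean_s = _mean_best_match_sorensen(
        intramodule_edge_sets(sc_bin, part_s),
        intramodule_edge_sets(f_graph, part_f),
    )
    if q_s <= 0 or q_f <= 0 or mean_s <= 0:
        x = 0.0
    else:
        x = float((q_s * q_f * mean_s) ** (1.0 / 3.0))
    return ModularityReport(
        m=n_modules,
        q_structural=q_s,
        q_functional=q_f,
        mean_sorensen=mean_s,
        cross_modularity=x,
    )


def select_optimal_level(
    pair: ConnectomePair,
    m_range,
    weighted_structural_tree: bool = False,
) -> tuple[int, list[ModularityReport]]:
    """Cross-modularity argmax over candidate module counts.

    Returns the optimal M (ties broken toward the smallest M) together with
    the full report list.
    """
    m_range = list(m_range)
    if not m_range:
        raise ValueError("m_range must be nonempty")
    reports = [
        cross_modularity(pair, m, weighted_structural_tree=weighted_structural_tree)
        for m in sorted(m_range)
    ]
    best = max(reports, key=lambda r: (r.cross_modularity, -r.m))
    return best.m, reports
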