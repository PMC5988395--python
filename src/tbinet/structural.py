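"""Structural connectome aggregation and group comparison.

Binary ROI-level streamline graphs are aggregated to inter-module connection
counts at any hierarchy level; a module's degree is the total number of
binary links reaching it from other modules (intra-module links are kept
separately and excluded from degree).  Group differences in module degree are
tested with a covariate-adjusted GLM contrast whose significance is assessed
by subject-label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Partition
from . import stats

__all__ = [
    "ModuleGraph",
    "binarize_connectome",
    "intermodule_connectivity",
    "module_degree",
    "cohort_module_degrees",
    "structural_group_comparison",
]


@dataclass
class ModuleGraph:
    """Inter-module link counts (symmetric, zero diagonal) plus intra counts."""

    weights: np.ndarray  # M x M inter-module link counts
    intra: np.ndarray  # per-module within-module link counts

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.intra = np.asarray(self.intra, dtype=float)
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weights diagonal must be zero")
        if self.intra.shape[0] != self.weights.shape[0]:
            raise ValueError("intra length must match module count")

    @property
    def n_modules(self) -> int:
        return self.weights.shape[0]


def binarize_connectome(sc: np.ndarray) -> np.ndarray:
    """1 where any streamline exists, 0 elsewhere; diagonal forced to 0."""
    sc = np.asarray(sc)
    if sc.ndim != 2 or sc.shape[0] != sc.shape[1]:
        raise ValueError("sc must be square")
    if np.any(sc < 0):
        raise ValueError("sc must be nonnegative")
    b = (sc > 0).astype(np.int8)
    np.fill_diagonal(b, 0)
    return b


def intermodule_connectivity(binary_sc: np.ndarray, partition: Partition) -> ModuleGraph:
    """Count binary ROI links crossing (and staying within) modules."""
    b = np.asarray(binary_sc)
    labels = partition.labels
    if labels.shape[0] != b.shape[0]:
        raise ValueError(
            f"partition covers {labels.shape[0]} ROIs but matrix has {b.shape[0]}"
        )
    m = partition.n_modules
    # one-hot aggregation: counts[a, b] = sum of links between modules a and b
    onehot = np.zeros((labels.shape[0], m))
    onehot[np.arange(labels.shape[0]), labels - 1] = 1.0
    block = onehot.T @ np.triu(b, k=1) @ onehot
    full = block + block.T
    intra = np.diag(block).copy()
    np.fill_diagonal(full, 0.0)
    return ModuleGraph(weights=full, intra=intra)


def module_degree(mg: ModuleGraph) -> np.ndarray:
    """Total inter-module links reaching each module (row sums off-diagonal)."""
    return mg.weights.sum(axis=1)


def cohort_module_degrees(
    connectomes: dict, partition: Partition, subjects=None
) -> pd.DataFrame:
    """Subjects x modules degree table from per-subject streamline matrices."""
    subjects = list(connectomes) if subjects is None else list(subjects)
    rows = []
    for s in subjects:
        sc = connectomes[s].sc if hasattr(connectomes[s], "sc") else connectomes[s]
        mg = intermodule_connectivity(binarize_connectome(sc), partition)
        rows.append(module_degree(mg))
    cols = [f"module_{m}" for m in range(1, partition.n_modules + 1)]
    return pd.DataFrame(rows, index=subjects, columns=cols)


def structural_group_comparison(
    degrees: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates=("age", "eddy_motion_mean"),
    contrast=stats.CONTRAST_CONTROL_MINUS_TBI,
    n_perm: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module degree comparison: GLM t, permutation p, Hedges g.

    Head motion enters through the structural (eddy-correction) displacement
    covariate.  Modules with permutation p >= alpha are flagged discarded.
    """
    return stats.group_comparison_table(
        degrees,
        cohort,
        covariates=covariates,
        contrast=contrast,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
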