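"""Unsupervised statistics for feature tables: normalization, scaling,
Manhattan distances, principal coordinate analysis, hierarchical clustering
and PERMANOVA.

The canonical preprocessing chain is median normalization (per-sample) then
Pareto scaling (per-feature); the state machine on
:class:`AbundanceMatrix` enforces that order.  Ordination and tests run on
Manhattan distances, which are robust to the heavy-tailed intensity
distributions of metabolomics feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .design import SampleDesign
from .tables import FeatureTable

STATES = ("raw", "median_normalized", "pareto_scaled")


@dataclass
class AbundanceMatrix:
    """Features x samples abundance matrix with design and scaling state."""

    values: pd.DataFrame                       # features x samples
    design: list[SampleDesign] | None = None
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw abundance matrix contains negatives")
        if self.design is not None:
            ids = [s.sample_id for s in self.design]
            if list(self.values.columns) != ids:
                self.values = self.values[ids]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_feature_table(
        cls, table: FeatureTable, design: list[SampleDesign] | None = None
    ) -> "AbundanceMatrix":
        return cls(values=table.intensities, design=design)


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample by its median of nonzero values, then rescale by
    the grand median of those medians so intensities keep their scale.

    Zeros stay zero (absence below detection is not imputed).
    """
    if matrix.state != "raw":
        raise ValueError(f"median_normalize expects raw state, got {matrix.state}")
    X = matrix.values.to_numpy(dtype=float)
    medians = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        nz = X[:, j][X[:, j] > 0]
        if nz.size == 0:
            raise ValueError(
                f"sample {matrix.values.columns[j]!r} is all zeros: degenerate"
            )
        medians[j] = np.median(nz)
    grand = np.median(medians)
    out = X / medians[None, :] * grand
    return AbundanceMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        design=matrix.design,
        state="median_normalized",
    )


def pareto_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Center each feature and divide by the square root of its sample SD
    (n-1).  Constant features are left centered at zero."""
    if matrix.state != "median_normalized":
        raise ValueError(
            f"pareto_scale expects median_normalized state, got {matrix.state}"
        )
    X = matrix.values.to_numpy(dtype=float)
    centered = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    scale = np.sqrt(sd)
    scale[scale == 0] = 1.0  # constant feature -> stays at 0
    out = centered / scale
    obj = AbundanceMatrix.__new__(AbundanceMatrix)
    obj.values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    obj.design = matrix.design
    obj.state = "pareto_scaled"
    return obj


def manhattan_distance(matrix: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Manhattan (city-block) distances between samples."""
    values = matrix.values if isinstance(matrix, AbundanceMatrix) else matrix
    X = values.to_numpy(dtype=float).T  # samples x features
    D = cdist(X, X, metric="cityblock")
    return pd.DataFrame(D, index=values.columns, columns=values.columns)


def _check_distance(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = D.to_numpy(dtype=float) if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    return arr


# ----------------------------------------------------------------------
# PCoA
# ----------------------------------------------------------------------
@dataclass
class OrdinationResult:
    """Sample coordinates on ordination axes, with eigenvalue bookkeeping.

    ``proportion_explained`` is computed over positive eigenvalues only;
    negative eigenvalues (possible for non-Euclidean distances such as
    Manhattan) are reported in ``eigenvalues`` but excluded from the
    variance denominator and carry no coordinates.
    """

    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per retained (positive) axis
    method: str = "pcoa"


def pcoa(distance: pd.DataFrame | np.ndarray, eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis (classical metric MDS).

    Gower-centers ``-D**2 / 2`` and eigendecomposes; coordinates are
    eigenvectors scaled by the square roots of the positive eigenvalues.
    """
    D = _check_distance(distance)
    n = D.shape[0]
    ids = (
        list(distance.index)
        if isinstance(distance, pd.DataFrame)
        else [str(i) for i in range(n)]
    )
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > eig_tol * max(1.0, abs(eigvals).max())
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])[None, :]
    props = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=props,
    )


# ----------------------------------------------------------------------
# Hierarchical clustering
# ----------------------------------------------------------------------
def hierarchical_cluster(
    distance: pd.DataFrame | np.ndarray, linkage: str = "average"
) -> np.ndarray:
    """Agglomerative clustering; returns a scipy-style linkage matrix Z.

    Each of the n-1 rows is ``(left, right, height, size)`` with original
    samples numbered 0..n-1 and merged clusters n, n+1, ...  Supported
    linkages: average (UPGMA), single, complete.  Ties in merge height are
    broken toward the lowest cluster-index pair, deterministically.
    """
    D = _check_distance(distance).copy()
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        # lowest-index tie-break: scan pairs in lexicographic order
        best = None
        ids = sorted(active)
        for ii, a in enumerate(ids):
            for b in ids[ii + 1 :]:
                d = dist[(a, b)]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        size = active[a] + active[b]
        Z[step] = (a, b, d, size)
        for c in ids:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            if linkage == "average":
                dn = (active[a] * da + active[b] * db) / size
            elif linkage == "single":
                dn = min(da, db)
            else:
                dn = max(da, db)
            dist[(c, next_id)] = dn
        del active[a], active[b]
        active[next_id] = size
        next_id += 1
    return Z


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------
@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None
    grouping: str = "group"
    permuted_f: np.ndarray | None = field(default=None, repr=False)


def _pseudo_f(D2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.nonzero(codes == g)[0]
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise ValueError("no residual degrees of freedom")
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    distance: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
    grouping_name: str = "group",
    return_null: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA by random label permutation.

    The pseudo-F statistic partitions among/within sums of squared
    distances directly from the distance matrix; the p-value uses the
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` estimator, so it is
    never exactly zero.  Reproducible given ``seed``.
    """
    D = _check_distance(distance)
    labels = np.asarray(list(groups))
    if labels.shape[0] != D.shape[0]:
        raise ValueError("groups length must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    D2 = D**2
    f_obs = _pseudo_f(D2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    exceed = 0
    null = np.empty(n_permutations) if return_null else None
    for b in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm = _pseudo_f(D2, perm, len(uniq))
        if f_perm >= f_obs:
            exceed += 1
        if return_null:
            null[b] = f_perm
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        grouping=grouping_name,
        permuted_f=null,
    )
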