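"""Multiblock sparse PLS discriminant analysis and fold-change trajectories.

The supervised question is which features discriminate amended (PL) from
unamended (PO) peat.  Several data blocks (LC-MS intensities, NMR
concentrations) measured on the same samples are coupled to a shared
dummy-coded class outcome: per component, each block's loading vector is
updated to maximize covariance of its scores with the outcome scores plus a
``design_weight``-weighted covariance with the other blocks' scores, with
soft-thresholding retaining only the ``keep_per_block`` largest loadings.
This is the N-integration scheme of multiblock (s)PLS-DA with regression
deflation of each data block against its own scores; the outcome block is
never deflated.

The module follows the model/results convention: build a
:class:`MultiblockSPLSDA` from data, call :meth:`~MultiblockSPLSDA.fit`,
inspect the returned :class:`DiscriminantResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import SampleDesign
from .multivariate import AbundanceMatrix


def _as_frame(block) -> pd.DataFrame:
    if isinstance(block, AbundanceMatrix):
        return block.values
    if isinstance(block, pd.DataFrame):
        return block
    raise TypeError("blocks must be AbundanceMatrix or DataFrame (features x samples)")


def _soft_threshold_keep(g: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold g so at most ``keep`` entries stay nonzero."""
    a = np.abs(g)
    if keep >= len(g):
        lam = 0.0
    else:
        lam = np.partition(a, len(g) - keep - 1)[len(g) - keep - 1]
    out = np.sign(g) * np.maximum(a - lam, 0.0)
    return out


class MultiblockSPLSDA:
    """Multiblock sparse PLS-DA model for a binary class outcome.

    Parameters
    ----------
    blocks : dict of name -> (features x samples) DataFrame or AbundanceMatrix
        Data blocks sharing an identical sample set (same column order).
    classes : sequence of str
        Binary class label per sample (e.g. "PO" / "PL").
    keep_per_block : dict or sequence of int
        Number of features to retain per block per component.
    n_components : int
        Number of latent variates.
    design_weight : float
        Coupling weight between pairs of data blocks; the coupling of every
        block to the outcome is fixed at 1.
    """

    def __init__(
        self,
        blocks: dict[str, pd.DataFrame | AbundanceMatrix],
        classes,
        keep_per_block=None,
        n_components: int = 2,
        design_weight: float = 0.1,
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        self.block_names = list(blocks)
        frames = {name: _as_frame(b) for name, b in blocks.items()}
        sample_sets = [tuple(f.columns) for f in frames.values()]
        if len(set(sample_sets)) != 1:
            raise ValueError("all blocks must share an identical sample set")
        self.sample_ids = list(sample_sets[0])
        self.classes = pd.Series(list(classes), index=self.sample_ids)
        levels = sorted(self.classes.unique())
        if len(levels) != 2:
            raise ValueError("classes must be binary")
        counts = self.classes.value_counts()
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples: degenerate design")
        self.class_levels = levels
        self.frames = frames
        if keep_per_block is None:
            keep = {n: frames[n].shape[0] for n in self.block_names}
        elif isinstance(keep_per_block, dict):
            keep = dict(keep_per_block)
        else:
            keep = dict(zip(self.block_names, keep_per_block))
        for name, k in keep.items():
            if k < 1:
                raise ValueError(f"keep_per_block[{name!r}] must be >= 1")
        self.keep_per_block = keep
        self.n_components = n_components
        self.design_weight = design_weight
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None) -> "DiscriminantResults":
        """Fit the model.  Initialization is deterministic (leading singular
        vector of each block's cross-covariance with the outcome); ``seed``
        is recorded for downstream resampling utilities only."""
        names = self.block_names
        n = len(self.sample_ids)
        # samples x features, column-centered
        X = {}
        means = {}
        for name in names:
            M = self.frames[name].to_numpy(dtype=float).T
            means[name] = M.mean(axis=0)
            X[name] = M - means[name]
        Y = pd.get_dummies(self.classes).reindex(columns=self.class_levels).to_numpy(float)
        Y = Y - Y.mean(axis=0)

        total_var = {name: float((X[name] ** 2).sum()) for name in names}
        loadings = {name: [] for name in names}
        x_loadings = {name: [] for name in names}
        scores = {name: [] for name in names}
        expl = {name: [] for name in names}
        converged, n_iter = [], []

        for _comp in range(self.n_components):
            a = {}
            for name in names:
                M = X[name].T @ Y
                u_svd, _, _ = np.linalg.svd(M, full_matrices=False)
                v = u_svd[:, 0]
                # deterministic sign: largest-magnitude entry positive
                i = int(np.argmax(np.abs(v)))
                a[name] = v * np.sign(v[i]) if v[i] != 0 else v
            t = {name: X[name] @ a[name] for name in names}
            it = 0
            ok = False
            for it in range(1, self.max_iter + 1):
                t_sum = sum(t[name] for name in names)
                c = Y.T @ t_sum
                nc = np.linalg.norm(c)
                if nc > 0:
                    c = c / nc
                u = Y @ c
                delta = 0.0
                for name in names:
                    target = u.copy()
                    for other in names:
                        if other != name:
                            target += self.design_weight * t[other]
                    g = X[name].T @ target
                    g = _soft_threshold_keep(g, self.keep_per_block[name])
                    norm = np.linalg.norm(g)
                    if norm == 0:
                        g = a[name]
                        norm = 1.0
                    g = g / norm
                    delta = max(delta, float(np.max(np.abs(g - a[name]))))
                    a[name] = g
                    t[name] = X[name] @ g
                if delta < self.tol:
                    ok = True
                    break
            if not ok:
                warnings.warn(
                    f"sPLS-DA component {_comp + 1} did not converge in "
                    f"{self.max_iter} iterations",
                    RuntimeWarning,
                )
            converged.append(ok)
            n_iter.append(it)
            for name in names:
                tt = float(t[name] @ t[name])
                p = X[name].T @ t[name] / tt if tt > 0 else np.zeros(X[name].shape[1])
                loadings[name].append(a[name])
                x_loadings[name].append(p)
                scores[name].append(t[name])
                expl[name].append(tt * float(p @ p) / total_var[name] if total_var[name] > 0 else 0.0)
                X[name] = X[name] - np.outer(t[name], p)  # regression deflation

        res_loadings = {
            name: pd.DataFrame(
                np.column_stack(loadings[name]),
                index=self.frames[name].index,
                columns=[f"comp{i + 1}" for i in range(self.n_components)],
            )
            for name in names
        }
        res_scores = {
            name: pd.DataFrame(
                np.column_stack(scores[name]),
                index=self.sample_ids,
                columns=[f"comp{i + 1}" for i in range(self.n_components)],
            )
            for name in names
        }
        return DiscriminantResults(
            model=self,
            loadings=res_loadings,
            x_loadings={
                name: np.column_stack(x_loadings[name]) for name in names
            },
            scores=res_scores,
            explained_variance={name: list(expl[name]) for name in names},
            block_means=means,
            converged=converged,
            n_iter=n_iter,
            seed=seed,
        )


@dataclass
class DiscriminantResults:
    """Fitted multiblock sPLS-DA: sparse loadings, variate scores,
    per-block explained variance (redundancy) and prediction utilities."""

    model: MultiblockSPLSDA
    loadings: dict[str, pd.DataFrame]
    x_loadings: dict[str, np.ndarray]
    scores: dict[str, pd.DataFrame]
    explained_variance: dict[str, list[float]]
    block_means: dict[str, np.ndarray]
    converged: list[bool]
    n_iter: list[int]
    seed: int | None = None

    # ------------------------------------------------------------------
    def selected_features(self, block: str, component: int = 1) -> list[str]:
        """Feature ids with nonzero loading on a component (1-based)."""
        col = self._col(component)
        lv = self.loadings[block][col]
        return sorted(lv.index[lv != 0.0])

    def _col(self, component: int) -> str:
        if not 1 <= component <= self.model.n_components:
            raise ValueError(
                f"component must be in 1..{self.model.n_components}"
            )
        return f"comp{component}"

    def rank_discriminants(self, component: int = 1) -> pd.DataFrame:
        """Nonzero loadings across blocks, sorted by |loading| descending.

        Ties break on feature id, so the ranking is deterministic and
        invariant to the block input order.
        """
        col = self._col(component)
        rows = []
        for name in self.model.block_names:
            lv = self.loadings[name][col]
            for fid, val in lv.items():
                if val != 0.0:
                    rows.append({"feature_id": fid, "block": name, "loading": float(val)})
        df = pd.DataFrame(rows)
        if len(df) == 0:
            return df
        df["abs_loading"] = df["loading"].abs()
        df = df.sort_values(
            ["abs_loading", "feature_id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return df

    # ------------------------------------------------------------------
    def _project(self, blocks: dict[str, pd.DataFrame]) -> dict[str, np.ndarray]:
        """Per-block component scores for new samples (training centering
        and deflation sequence applied)."""
        out = {}
        for name in self.model.block_names:
            M = _as_frame(blocks[name]).to_numpy(dtype=float).T - self.block_means[name]
            H = self.model.n_components
            T = np.zeros((M.shape[0], H))
            for h in range(H):
                a = self.loadings[name].iloc[:, h].to_numpy()
                t = M @ a
                T[:, h] = t
                M = M - np.outer(t, self.x_loadings[name][:, h])
            out[name] = T
        return out

    def predict(self, blocks: dict[str, pd.DataFrame]) -> pd.Series:
        """Classify new samples by nearest class centroid in the averaged
        block score space."""
        proj = self._project(blocks)
        avg = sum(proj.values()) / len(proj)
        train_avg = sum(
            self.scores[n].to_numpy() for n in self.model.block_names
        ) / len(self.scores)
        labels = self.model.classes.to_numpy()
        centroids = {
            lvl: train_avg[labels == lvl].mean(axis=0)
            for lvl in self.model.class_levels
        }
        sample_ids = list(_as_frame(blocks[self.model.block_names[0]]).columns)
        calls = []
        for i in range(avg.shape[0]):
            dists = {
                lvl: float(np.linalg.norm(avg[i] - cent))
                for lvl, cent in centroids.items()
            }
            calls.append(min(sorted(dists), key=dists.get))
        return pd.Series(calls, index=sample_ids, name="predicted_class")

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Multiblock sPLS-DA results", "=" * 27]
        lines.append(
            f"classes: {' vs '.join(self.model.class_levels)}  "
            f"(n = {len(self.model.sample_ids)})"
        )
        lines.append(f"components: {self.model.n_components}; "
                     f"design weight: {self.model.design_weight}")
        for name in self.model.block_names:
            n_feat = self.loadings[name].shape[0]
            keep = self.model.keep_per_block[name]
            ev = ", ".join(f"{v:.3f}" for v in self.explained_variance[name])
            lines.append(
                f"block {name!r}: {n_feat} features, keep {keep}/component, "
                f"explained variance per component: {ev}"
            )
        lines.append(
            "converged: "
            + ", ".join(
                f"comp{i + 1}={'yes' if c else 'NO'}({k} it)"
                for i, (c, k) in enumerate(zip(self.converged, self.n_iter))
            )
        )
        return "\n".join(lines)


def fit_multiblock_splsda(
    blocks,
    classes,
    keep_per_block=None,
    n_components: int = 2,
    design_weight: float = 0.1,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
) -> DiscriminantResults:
    """Functional wrapper: construct the model and fit it."""
    return MultiblockSPLSDA(
        blocks,
        classes,
        keep_per_block=keep_per_block,
        n_components=n_components,
        design_weight=design_weight,
        max_iter=max_iter,
        tol=tol,
    ).fit(seed=seed)


def rank_discriminants(results: DiscriminantResults, component: int = 1) -> pd.DataFrame:
    """Module-level alias for :meth:`DiscriminantResults.rank_discriminants`."""
    return results.rank_discriminants(component)


# ----------------------------------------------------------------------
# Fold-change trajectories
# ----------------------------------------------------------------------
def log2_fold_change(
    matrix: AbundanceMatrix | pd.DataFrame,
    design: list[SampleDesign] | None = None,
    reference: tuple[str, str] = ("PO", "T0"),
    pseudocount: float | str = "half_min_nonzero",
) -> pd.DataFrame:
    """Per-feature log2 fold change of group means relative to a reference.

    For every (treatment, timepoint) group the change is
    ``log2((mean + eps) / (ref_mean + eps))`` with the reference group mean
    taken at ``reference`` (unamended peat at T0 by default).  ``eps`` is
    half the smallest nonzero value in the matrix, or a number, or 0 — in
    which case a zero/zero ratio raises.
    Returns a tidy frame: feature_id, treatment, timepoint, log2_fc.
    """
    if isinstance(matrix, AbundanceMatrix):
        values = matrix.values
        design = design if design is not None else matrix.design
    else:
        values = matrix
    if design is None:
        raise ValueError("a sample design is required")
    ids = [s.sample_id for s in design]
    values = values[ids]

    if pseudocount == "half_min_nonzero":
        arr = values.to_numpy()
        nz = arr[arr > 0]
        eps = float(nz.min()) / 2.0 if nz.size else 0.0
    else:
        eps = float(pseudocount)

    ref_tr, ref_tp = reference
    ref_samples = [s.sample_id for s in design if s.treatment == ref_tr and s.timepoint == ref_tp]
    if not ref_samples:
        raise ValueError(f"reference group {reference} is empty")
    ref_mean = values[ref_samples].mean(axis=1)

    groups: dict[tuple[str, str], list[str]] = {}
    for s in design:
        groups.setdefault((s.treatment, s.timepoint), []).append(s.sample_id)

    rows = []
    for (tr, tp), samples in sorted(groups.items()):
        gmean = values[samples].mean(axis=1)
        num = gmean + eps
        den = ref_mean + eps
        if eps == 0.0 and ((num == 0) & (den == 0)).any():
            raise ValueError("zero/zero ratio with zero pseudocount: undefined")
        fc = np.log2(num / den)
        for fid, val in fc.items():
            rows.append(
                {
                    "feature_id": fid,
                    "treatment": tr,
                    "timepoint": tp,
                    "log2_fc": float(val),
                }
            )
    return pd.DataFrame(rows)
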