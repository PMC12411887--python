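"""Isotopologue detection core: filtering, clustering, natural-abundance
correction, enrichment estimation and label classification.

In a stable-isotope-assisted experiment, labeled metabolites co-elute with
their natural-abundance counterparts: members of one compound's isotopologue
family share a retention time and are spaced by integer multiples of the
13C-12C mass difference (1.0033548 Da).  This module groups filtered
features into such clusters, deconvolves the natural-abundance contribution
from the observed envelope, and estimates each compound's fractional 13C
label incorporation.

Scale conventions
-----------------
``estimate_enrichment`` returns the *excess* (tracer) atom percent — the
mean of the natural-abundance-corrected envelope.  ``total_atom_percent``
converts that to the total 13C atom percent (tracer plus natural), the scale
on which bulk IRMS enrichment measurements are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .constants import C13_MASS_DIFF, P_NATURAL_13C
from .tables import FeatureRecord, FeatureTable

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------
def filter_features(
    table: FeatureTable,
    min_mass: float = 100.0,
    max_mass: float = 1200.0,
    min_intensity: float = 2e6,
    min_snr: float = 3.0,
) -> FeatureTable:
    """Apply the detection filters: mass window, intensity floor, S/N.

    Retains features with ``min_mass <= mass <= max_mass`` (inclusive
    bounds), maximum per-sample intensity at least ``min_intensity``, and
    signal-to-noise strictly greater than ``min_snr``.  Row order is
    preserved; an empty table passes through empty.
    """
    if min(min_mass, max_mass, min_intensity, min_snr) < 0:
        raise ValueError("filter thresholds must be non-negative")
    df = table.df
    if len(df) == 0:
        return table.copy()
    mass = df["neutral_mass"].to_numpy()
    snr = df["snr"].to_numpy()
    peak = df[table.sample_ids].to_numpy(dtype=float).max(axis=1)
    mask = (mass >= min_mass) & (mass <= max_mass) & (peak >= min_intensity) & (snr > min_snr)
    return FeatureTable(df.loc[mask].reset_index(drop=True))


# ----------------------------------------------------------------------
# Clustering
# ----------------------------------------------------------------------
@dataclass
class IsotopologueCluster:
    """An RT-coherent family of mass-shifted features for one compound.

    ``members`` maps heavy-atom count k to the member feature; k = 0 is the
    monoisotopic (all-12C) base candidate.  Envelopes are proportion vectors
    over k = 0..max(k); ``f_corr`` has the natural-abundance contribution
    removed.  ``enrichment_at_pct`` is excess (tracer) atom percent.
    """

    cluster_id: str
    base_feature: FeatureRecord
    members: list[tuple[int, FeatureRecord]]
    n_carbon_est: int | None = None
    f_obs: np.ndarray | None = None
    f_corr: np.ndarray | None = None
    enrichment_at_pct: float | None = None
    label_call: bool | None = None
    diagnostic_ratio: float | None = None

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.members]
        if len(set(ks)) != len(ks):
            raise ValueError("duplicate k values in cluster")
        if any(k < 0 for k in ks):
            raise ValueError("negative k in cluster")

    @property
    def max_k(self) -> int:
        return max(k for k, _ in self.members)

    def observed_envelope(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """Summed-intensity envelope over k, optionally restricted to samples."""
        env = np.zeros(self.max_k + 1)
        for k, rec in self.members:
            if sample_ids is None:
                env[k] = sum(rec.intensities.values())
            else:
                env[k] = sum(rec.intensities.get(s, 0.0) for s in sample_ids)
        total = env.sum()
        return env / total if total > 0 else env

    def paired_ratio_envelope(
        self, sample_ids: list[str] | None = None, min_pairs: int = 3
    ) -> np.ndarray:
        """Envelope estimated from within-sample member ratios.

        Compound abundance varies between samples (prep, biology) but scales
        all isotopologues of a compound together, so the ratio of two
        members *within* one sample cancels it.  Each member's proportion is
        taken as the geometric mean of its per-sample ratio to the most
        intense member, over samples where both are detected; members with
        fewer than ``min_pairs`` such samples fall back to the summed-
        intensity ratio.  Reduces to the summed envelope on noiseless data.
        """
        ids = sample_ids if sample_ids is not None else sorted(
            self.base_feature.intensities
        )
        M = np.array(
            [[rec.intensities.get(s, 0.0) for s in ids] for _, rec in self.members]
        )
        ks = [k for k, _ in self.members]
        sums = M.sum(axis=1)
        if sums.sum() <= 0:
            return np.zeros(self.max_k + 1)
        ref = int(np.argmax(sums))
        log_r = np.full(len(ks), -np.inf)
        log_r[ref] = 0.0
        for j in range(len(ks)):
            if j == ref:
                continue
            valid = (M[j] > 0) & (M[ref] > 0)
            if valid.sum() >= min_pairs:
                log_r[j] = float(np.mean(np.log(M[j, valid] / M[ref, valid])))
            elif sums[j] > 0 and sums[ref] > 0:
                log_r[j] = float(np.log(sums[j] / sums[ref]))
        env = np.zeros(self.max_k + 1)
        with np.errstate(over="ignore"):
            vals = np.exp(log_r)
        vals[~np.isfinite(vals)] = 0.0
        for j, k in enumerate(ks):
            env[k] = vals[j]
        total = env.sum()
        return env / total if total > 0 else env


def cluster_isotopologues(
    table: FeatureTable,
    rt_tol: float = 0.2,
    mass_tol_ppm: float = 5.0,
    max_k: int = 100,
) -> list[IsotopologueCluster]:
    """Greedy agglomeration of features into isotopologue clusters.

    Seeds with the lowest-mass unassigned feature and attaches any
    unassigned feature whose RT lies within ``rt_tol`` and whose mass
    difference is within ``mass_tol_ppm`` of ``k * 1.0033548`` for integer
    ``1 <= k <= max_k``.  A candidate that would match a different
    lower-mass unassigned feature with a strictly better combined score
    (ppm error + RT error / rt_tol) is deferred to that future seed.
    Features matching nothing become singleton (k = 0 only) clusters.
    Deterministic given the table contents.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    records = table.records()
    n = len(records)
    order = np.lexsort(
        (np.array([r.rt for r in records]), np.array([r.neutral_mass for r in records]))
    )
    records = [records[i] for i in order]
    mass = np.array([r.neutral_mass for r in records])
    rt = np.array([r.rt for r in records])

    def match(base_i: int, cand_j: int) -> tuple[int, float] | None:
        """Best (k, score) pairing of candidate j onto base i, or None."""
        dm = mass[cand_j] - mass[base_i]
        if dm <= 0:
            return None
        k = int(round(dm / C13_MASS_DIFF))
        if not 1 <= k <= max_k:
            return None
        expected = mass[base_i] + k * C13_MASS_DIFF
        ppm = abs(mass[cand_j] - expected) / mass[cand_j] * 1e6
        drt = abs(rt[cand_j] - rt[base_i])
        if ppm > mass_tol_ppm or drt > rt_tol:
            return None
        return k, ppm + drt / rt_tol

    # pass 1: identify seeds by greedy agglomeration in mass order
    unassigned = list(range(n))
    seeds: list[int] = []
    while unassigned:
        seed = unassigned[0]
        seeds.append(seed)
        taken = {seed}
        for j in unassigned[1:]:
            if match(seed, j) is not None:
                taken.add(j)
        unassigned = [i for i in unassigned if i not in taken]

    # pass 2: every non-seed feature joins the seed it matches with the
    # smallest combined (ppm error + RT error / rt_tol) score
    assignment: dict[int, tuple[int, int, float]] = {}  # j -> (seed, k, score)
    seed_set = set(seeds)
    for j in range(n):
        if j in seed_set:
            continue
        best = None
        for s in seeds:
            m = match(s, j)
            if m is not None and (best is None or m[1] < best[2]):
                best = (s, m[0], m[1])
        if best is not None:
            assignment[j] = best

    members_by_seed: dict[int, dict[int, tuple[int, float]]] = {s: {} for s in seeds}
    orphans: list[int] = []
    for j, (s, k, score) in sorted(assignment.items()):
        slot = members_by_seed[s].get(k)
        if slot is None or score < slot[1]:
            if slot is not None:
                orphans.append(slot[0])  # displaced by a better-scoring feature
            members_by_seed[s][k] = (j, score)
        else:
            orphans.append(j)
    for j in range(n):
        if j not in seed_set and j not in assignment:
            orphans.append(j)

    clusters: list[IsotopologueCluster] = []
    for s in seeds:
        members = [(0, records[s])] + [
            (k, records[j]) for k, (j, _) in sorted(members_by_seed[s].items())
        ]
        clusters.append(
            IsotopologueCluster(
                cluster_id=f"clu_{len(clusters):04d}",
                base_feature=records[s],
                members=members,
            )
        )
    for j in sorted(orphans):
        clusters.append(
            IsotopologueCluster(
                cluster_id=f"clu_{len(clusters):04d}",
                base_feature=records[j],
                members=[(0, records[j])],
            )
        )
    return clusters


# ----------------------------------------------------------------------
# Natural-abundance correction
# ----------------------------------------------------------------------
@lru_cache(maxsize=512)
def _correction_matrix_cached(n_carbon: int, p_nat: float) -> np.ndarray:
    size = n_carbon + 1
    C = np.zeros((size, size))
    for j in range(size):
        rem = n_carbon - j
        C[j : j + rem + 1, j] = stats.binom.pmf(np.arange(rem + 1), rem, p_nat)
    C.setflags(write=False)
    return C


def correction_matrix(n_carbon: int, p_nat: float = P_NATURAL_13C) -> np.ndarray:
    """Column-stochastic convolution matrix C with C[i, j] =
    P(Binomial(n_carbon - j, p_nat) = i - j): the probability that a
    molecule carrying j tracer atoms shows i heavy atoms in total."""
    return _correction_matrix_cached(int(n_carbon), float(p_nat)).copy()


def natural_abundance_correct(
    f_obs: np.ndarray, n_carbon: int, p_nat: float = P_NATURAL_13C
) -> np.ndarray:
    """Remove the natural-abundance contribution from an observed envelope.

    Solves ``f_obs = C @ f_corr`` by non-negative least squares, where
    column j of C is the natural envelope of the ``n_carbon - j`` carbons
    not carrying tracer.  The solution is renormalized to sum to 1.
    Envelopes shorter than ``n_carbon + 1`` are zero-padded (missing k).
    """
    f_obs = np.asarray(f_obs, dtype=float)
    if f_obs.ndim != 1:
        raise ValueError("f_obs must be a vector")
    if n_carbon < 0:
        raise ValueError("n_carbon must be >= 0")
    if len(f_obs) > n_carbon + 1:
        raise ValueError(
            f"envelope has {len(f_obs) - 1} heavy isotopologues but only "
            f"{n_carbon} carbons: inconsistent carbon count"
        )
    total = f_obs.sum()
    if total <= 0:
        raise ValueError("f_obs must have positive mass")
    f = np.zeros(n_carbon + 1)
    f[: len(f_obs)] = f_obs / total
    if p_nat == 0.0:
        return f
    C = correction_matrix(n_carbon, p_nat)
    sol, _ = nnls(C, f)
    s = sol.sum()
    if s <= 0:
        raise ValueError("degenerate envelope: NNLS returned all zeros")
    return sol / s


def _nnls_residual(f_obs: np.ndarray, n_carbon: int, p_nat: float) -> float:
    f = np.zeros(n_carbon + 1)
    f[: len(f_obs)] = f_obs
    C = correction_matrix(n_carbon, p_nat)
    _, resid = nnls(C, f)
    return float(resid)


def estimate_n_carbon(
    cluster: IsotopologueCluster,
    mass: float,
    p_nat: float = P_NATURAL_13C,
    sample_ids: list[str] | None = None,
    residual_tol: float = 1e-9,
) -> int:
    """Grid-search the carbon count consistent with mass and envelope.

    Candidates run from ``ceil(mass / 30)`` to ``floor(mass / 12)``; the
    observed maximum heavy-atom count imposes a lower bound.  For each
    candidate the natural-abundance-corrected fit residual is computed and
    the smallest candidate within ``residual_tol`` of the minimum wins
    (the correction matrix is nearly the identity at natural 13C levels, so
    the envelope bounds nC mostly through its support).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    # lower bound uses the rounded carbon ratio: compounds like glucose sit
    # marginally above 30 Da per carbon
    lo = max(1, int(round(mass / 30.0)))
    hi = int(np.floor(mass / 12.0))
    if hi < 1:
        raise ValueError(f"mass {mass} Da is below one carbon: non-organic")
    lo = max(lo, cluster.max_k)
    hi = max(hi, cluster.max_k)
    f_obs = cluster.observed_envelope(sample_ids)
    residuals = {nc: _nnls_residual(f_obs, nc, p_nat) for nc in range(lo, hi + 1)}
    rmin = min(residuals.values())
    for nc in range(lo, hi + 1):
        if residuals[nc] <= rmin + residual_tol:
            return nc
    return hi  # unreachable


def estimate_n_carbon_natural(
    cluster: IsotopologueCluster,
    mass: float,
    sample_ids: list[str],
    p_nat: float = P_NATURAL_13C,
) -> int | None:
    """Carbon count from the natural-abundance envelope of control samples.

    In a paired labeled/unlabeled design the unlabeled samples show every
    compound's *natural* envelope, whose shape (k1/k0 ~ nC * p_nat, ...)
    identifies the carbon count far better than the labeled envelope can.
    Fits log-proportions of the observed members against truncated natural
    envelopes over the mass-bounded candidate grid; returns None when fewer
    than two members are detected in the given samples (no shape
    information), in which case callers fall back to
    :func:`estimate_n_carbon`.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    lo = max(1, int(round(mass / 30.0)), cluster.max_k)
    hi = max(int(np.floor(mass / 12.0)), lo)
    f = cluster.paired_ratio_envelope(sample_ids)
    ks = np.nonzero(f > 0)[0]
    if len(ks) < 2:
        return None
    fo = np.log(f[ks] / f[ks].sum())
    best, best_sse = None, np.inf
    for nc in range(lo, hi + 1):
        t = stats.binom.pmf(ks, nc, p_nat)
        if np.any(t <= 0):
            continue
        sse = float(np.sum((fo - np.log(t / t.sum())) ** 2))
        if sse < best_sse - 1e-12:
            best, best_sse = nc, sse
    return best


# ----------------------------------------------------------------------
# Enrichment and classification
# ----------------------------------------------------------------------
def estimate_enrichment(f_corr: np.ndarray, n_carbon: int) -> float:
    """Fractional label incorporation in excess atom percent:
    ``100 * sum(k * f_corr[k]) / n_carbon``."""
    if n_carbon <= 0:
        raise ValueError("n_carbon must be >= 1")
    f = np.asarray(f_corr, dtype=float)
    total = f.sum()
    if total <= 0:
        raise ValueError("f_corr must have positive mass")
    f = f / total
    return float(100.0 * np.dot(np.arange(len(f)), f) / n_carbon)


def total_atom_percent(excess_at_pct: float, p_nat: float = P_NATURAL_13C) -> float:
    """Convert excess (tracer) atom percent to total 13C atom percent.

    Carbons not carrying tracer remain at natural abundance, so
    ``p_total = p_tracer + (1 - p_tracer) * p_nat``; this inverts the
    natural-abundance correction exactly.
    """
    pt = excess_at_pct / 100.0
    return float(100.0 * (pt + (1.0 - pt) * p_nat))


def classify_labeled(
    cluster: IsotopologueCluster, min_incorporation: float = 0.02
) -> tuple[bool, float]:
    """Call a cluster labeled from its corrected envelope.

    The diagnostic ratio is the excess heavy fraction ``sum_{k>=1}
    f_corr[k]``; the call is positive iff the ratio reaches
    ``min_incorporation`` and the cluster has at least two members (a lone
    feature carries no isotopologue evidence).
    """
    if cluster.f_corr is None:
        raise ValueError("cluster has no corrected envelope")
    ratio = float(np.sum(cluster.f_corr[1:]))
    call = ratio >= min_incorporation and len(cluster.members) >= 2
    return call, ratio


def annotate_clusters(
    clusters: list[IsotopologueCluster],
    p_nat: float = P_NATURAL_13C,
    min_incorporation: float = 0.02,
    sample_ids: list[str] | None = None,
    control_sample_ids: list[str] | None = None,
) -> list[IsotopologueCluster]:
    """Run the estimation chain on every cluster, in place.

    ``sample_ids`` selects the samples whose envelope carries the label
    signal (typically the labeled samples); ``control_sample_ids`` selects
    natural-abundance controls (unlabeled samples) used to pin the carbon
    count via :func:`estimate_n_carbon_natural`, falling back to the
    mass-bounded residual grid when controls carry no signal.  Fills
    ``n_carbon_est``, ``f_obs``, ``f_corr``, ``enrichment_at_pct``,
    ``label_call`` and ``diagnostic_ratio``.
    """
    for c in clusters:
        c.f_obs = c.paired_ratio_envelope(sample_ids)
        if c.f_obs.sum() <= 0:  # all-zero in the selected samples
            c.f_obs = c.paired_ratio_envelope(None)
        nc = None
        if control_sample_ids is not None:
            nc = estimate_n_carbon_natural(
                c, c.base_feature.neutral_mass, control_sample_ids, p_nat=p_nat
            )
        if nc is None:
            nc = estimate_n_carbon(
                c, c.base_feature.neutral_mass, p_nat=p_nat, sample_ids=sample_ids
            )
        c.n_carbon_est = nc
        c.f_corr = natural_abundance_correct(c.f_obs, c.n_carbon_est, p_nat=p_nat)
        c.enrichment_at_pct = estimate_enrichment(c.f_corr, c.n_carbon_est)
        c.label_call, c.diagnostic_ratio = classify_labeled(c, min_incorporation)
    return clusters


# ----------------------------------------------------------------------
# Detection summary
# ----------------------------------------------------------------------
def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (printed style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DetectionSummary:
    """Counts and printed-style percentages of labeled/annotated features."""

    n_features_total: int
    n_labeled: int
    pct_labeled: float
    categories: dict[str, tuple[int, float]] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, total: int, labeled: int, categories: dict[str, int] | None = None
    ) -> "DetectionSummary":
        if total <= 0:
            raise ValueError("total feature count must be positive")
        cats = categories or {}
        bad = {k: v for k, v in cats.items() if v > total or v < 0}
        if labeled > total or labeled < 0 or bad:
            raise ValueError("category counts must lie in [0, total]")
        pct = lambda c: round_half_up(100.0 * c / total, 2)
        return cls(
            n_features_total=total,
            n_labeled=labeled,
            pct_labeled=pct(labeled),
            categories={k: (v, pct(v)) for k, v in cats.items()},
        )

    def to_dict(self) -> dict:
        return {
            "n_features_total": self.n_features_total,
            "n_labeled": self.n_labeled,
            "pct_labeled": self.pct_labeled,
            "categories": {
                k: {"count": c, "pct": p} for k, (c, p) in self.categories.items()
            },
        }


def cluster_abundance_matrix(
    clusters: list[IsotopologueCluster], sample_ids: list[str]
) -> pd.DataFrame:
    """Compound-level abundance matrix: summed member intensities per sample.

    Summing an isotopologue family collapses the mass-shift pattern, so
    labeled and unlabeled samples of the same material become replicates at
    the compound level — the representation on which the multivariate
    statistics operate.  Rows are indexed by the base feature id.
    """
    rows = np.zeros((len(clusters), len(sample_ids)))
    ids = []
    for i, c in enumerate(clusters):
        ids.append(c.base_feature.feature_id)
        for _, rec in c.members:
            rows[i] += np.array([rec.intensities.get(s, 0.0) for s in sample_ids])
    return pd.DataFrame(rows, index=ids, columns=sample_ids)


def summarize_detection(
    clusters: list[IsotopologueCluster],
    annotation_counts: dict[str, int] | None = None,
) -> DetectionSummary:
    """Summarize label calls over clusters, with pass-through annotation
    category counts; percentages are of the total cluster count, rounded
    half-up to two decimals."""
    total = len(clusters)
    labeled = sum(1 for c in clusters if c.label_call)
    return DetectionSummary.from_counts(total, labeled, annotation_counts)
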