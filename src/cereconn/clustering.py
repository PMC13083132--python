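"""Clinical-cognitive subtype discovery by PAM consensus clustering.

Features are min-max normalized to [0, 1] (theoretical bounds for the 0-5
symptom scales, observed complete-case range for raw cognitive scores) after
listwise deletion.  Partitioning Around Medoids (BUILD + SWAP, Euclidean
dissimilarity) is run on repeated 80% subsamples; the co-assignment
frequencies form a consensus matrix whose ambiguity (PAC), together with
silhouette width, Calinski-Harabasz, pairwise adjusted Rand / Jaccard across
subsamples, and a column-permutation test, quantifies partition stability.
The number of subtypes is chosen as the k with minimum PAC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    silhouette_score,
)

from .types import ClinicalTable, SYMPTOM_COLUMNS, SYMPTOM_SCALE, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedClinicalTable:
    """Complete-case clinical features scaled to [0, 1]."""

    data: pd.DataFrame
    groups: pd.Series
    bounds_used: dict[str, tuple[float, float]]
    dropped: list[str]


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    medoids: np.ndarray
    consensus: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    iteration_labels: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    permutation_p: float | None = None


def minmax_normalize(
    table: ClinicalTable, bounds: dict[str, tuple[float, float]] | None = None
) -> NormalizedClinicalTable:
    """Listwise-delete incomplete rows, then min-max scale each feature.

    Bounds resolution order: explicit ``bounds`` argument, the table's
    declared ``column_bounds``, the theoretical 0-5 scale for symptom
    columns, and finally the observed complete-case range.
    """
    feats = table.feature_columns
    if not feats:
        raise ValidationError("clinical table has no recognized feature columns")
    df = table.data
    complete = df[feats].notna().all(axis=1)
    dropped = list(df.index[~complete])
    sub = df.loc[complete, feats].astype(float)
    if sub.empty:
        raise ValidationError("no complete cases after listwise deletion")

    used: dict[str, tuple[float, float]] = {}
    out = pd.DataFrame(index=sub.index, columns=feats, dtype=float)
    for col in feats:
        if bounds and col in bounds:
            lo, hi = bounds[col]
        elif col in table.column_bounds:
            lo, hi = table.column_bounds[col]
        elif col in SYMPTOM_COLUMNS:
            lo, hi = SYMPTOM_SCALE
        else:
            lo, hi = float(sub[col].min()), float(sub[col].max())
        if hi <= lo:
            raise ValidationError(f"constant column {col!r}: cannot min-max normalize")
        used[col] = (lo, hi)
        out[col] = (sub[col] - lo) / (hi - lo)
    groups = (
        df.loc[complete, "group"] if "group" in df.columns
        else pd.Series(index=sub.index, dtype=object)
    )
    return NormalizedClinicalTable(data=out, groups=groups, bounds_used=used,
                                   dropped=dropped)


# ---------------------------------------------------------------------------
# PAM (k-medoids, BUILD + SWAP)
# ---------------------------------------------------------------------------


def _build_init(d: np.ndarray, k: int) -> np.ndarray:
    """Classic BUILD: first medoid minimizes total dissimilarity, then
    greedy additions maximizing the cost reduction."""
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        new = int(np.argmax(gain))
        medoids.append(new)
        nearest = np.minimum(nearest, d[new])
    return np.array(sorted(medoids), dtype=int)


def _swap_descent(d: np.ndarray, init: np.ndarray) -> tuple[np.ndarray, float]:
    """Best-improvement SWAP from an initial medoid set.

    Equal-cost (sideways) moves to unvisited medoid sets are accepted so
    the descent can cross cost plateaus between swap-local optima.
    Deterministic: candidates are ordered by (cost, medoid set).
    """
    n = d.shape[0]
    k = init.size
    eps = 1e-12
    medoid_arr = init.copy()
    cost = float(d[medoid_arr].min(axis=0).sum())
    best_arr, best_cost = medoid_arr.copy(), cost
    visited = {tuple(medoid_arr)}
    for _ in range(100):
        others = np.setdiff1d(np.arange(n), medoid_arr, assume_unique=False)
        all_costs = np.empty((k, others.size))
        for mi in range(k):
            rest = np.delete(medoid_arr, mi)
            base = d[rest].min(axis=0) if rest.size else np.full(n, np.inf)
            all_costs[mi] = np.minimum(base[None, :], d[others]).sum(axis=1)
        cmin = float(all_costs.min())
        if cmin < cost - eps:
            mi, j = np.unravel_index(int(np.argmin(all_costs)), all_costs.shape)
            new_set = tuple(sorted([*np.delete(medoid_arr, mi), int(others[j])]))
        else:
            # no strict improvement: try a sideways move to an unvisited set
            plateau = [
                tuple(sorted([*np.delete(medoid_arr, mi), int(others[j])]))
                for mi, j in zip(*np.nonzero(all_costs <= cost + eps))
            ]
            fresh = sorted(s for s in plateau if s not in visited)
            if not fresh:
                break
            new_set, cmin = fresh[0], cost
        cost, medoid_arr = cmin, np.array(new_set, dtype=int)
        visited.add(new_set)
        if cost < best_cost - eps:
            best_cost, best_arr = cost, medoid_arr.copy()
    return best_arr, float(best_cost)


def _pam_on_dissimilarity(
    d: np.ndarray, k: int, seed: int = 0, restarts: int = 4
) -> tuple[np.ndarray, np.ndarray, float]:
    """Multi-start PAM: BUILD plus seeded random initial medoid sets.

    SWAP descent is a local search, so a few extra deterministic random
    starts guard against swap-local optima; the lowest-cost final set wins
    (ties toward the lexicographically smallest medoid set).
    Returns (labels 1..k, medoid indices, total cost).
    """
    n = d.shape[0]
    starts = [_build_init(d, k)]
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        starts.append(np.sort(rng.choice(n, size=k, replace=False)))
    best_arr, best_cost = None, np.inf
    for init in starts:
        arr, cost = _swap_descent(d, init)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and best_arr is not None
            and tuple(arr) < tuple(best_arr)
        ):
            best_arr, best_cost = arr, cost
    labels = np.argmin(d[best_arr], axis=0) + 1
    return labels, best_arr, float(best_cost)


@dataclass
class PamResult:
    labels: np.ndarray
    medoids: np.ndarray
    cost: float


def pam(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    dissimilarity: np.ndarray | None = None,
) -> PamResult:
    """Partitioning Around Medoids on Euclidean dissimilarity.

    Multi-start BUILD+SWAP; deterministic given the data and ``seed``
    (which drives only the extra random initial medoid sets).
    """
    if dissimilarity is not None:
        d = np.asarray(dissimilarity, dtype=float)
        n = d.shape[0]
    else:
        points = np.asarray(points, dtype=float)
        d = cdist(points, points)
        n = points.shape[0]
    if not 1 <= k < n or (k == n):
        if k == n:
            # degenerate but well-defined: every point its own medoid
            return PamResult(np.arange(1, n + 1), np.arange(n), 0.0)
        raise ValidationError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
    labels, medoids, cost = _pam_on_dissimilarity(d, k, seed=seed)
    return PamResult(labels=labels, medoids=medoids, cost=cost)


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


def consensus_cluster(
    points: np.ndarray,
    k: int,
    iterations: int = 100,
    subsample: float = 0.8,
    embedding: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    pairwise_stats: bool = True,
) -> ClusterSolution:
    """Subsampled-PAM consensus clustering.

    Each iteration subsamples ``subsample`` of the rows without replacement,
    optionally embeds them (identity by default; a UMAP-style reducer can be
    plugged in), and clusters with PAM.  consensus[i, j] is the fraction of
    co-sampled iterations in which i and j share a cluster; final labels
    come from PAM on (1 - consensus).  Pairs never co-sampled are undefined
    (excluded from PAC) and logged.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    m = int(round(subsample * n))
    if m <= k:
        raise ValidationError("subsample * n must exceed k")
    rng = np.random.default_rng(seed)
    co_sampled = np.zeros((n, n))
    co_assigned = np.zeros((n, n))
    iteration_labels: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = points[idx]
        if embedding is not None:
            sub = np.asarray(embedding(sub), dtype=float)
        labels = pam(sub, k).labels
        iteration_labels.append((idx, labels))
        co_sampled[np.ix_(idx, idx)] += 1
        same = labels[:, None] == labels[None, :]
        co_assigned[np.ix_(idx, idx)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_assigned / np.maximum(co_sampled, 1), np.nan)
    never = int(np.isnan(consensus[np.triu_indices(n, k=1)]).sum())
    if never:
        logger.warning("%d subject pairs were never co-sampled; consensus undefined", never)
    np.fill_diagonal(consensus, 1.0)

    dissim = 1.0 - np.nan_to_num(consensus, nan=0.5)
    np.fill_diagonal(dissim, 0.0)
    final = pam(points, k, dissimilarity=dissim)

    solution = ClusterSolution(
        k=k,
        labels=final.labels,
        medoids=final.medoids,
        consensus=consensus,
        iteration_labels=iteration_labels,
    )
    solution.metrics["PAC"] = pac(consensus)
    if k >= 2 and len(np.unique(final.labels)) >= 2:
        solution.metrics["silhouette"] = float(silhouette_score(points, final.labels))
        solution.metrics["calinski_harabasz"] = float(
            calinski_harabasz_score(points, final.labels)
        )
    if pairwise_stats:
        ari, jac = _pairwise_partition_stats(iteration_labels)
        solution.metrics["mean_pairwise_ari"] = ari
        solution.metrics["mean_pairwise_jaccard"] = jac
    return solution


def pac(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering.

    Fraction of defined off-diagonal consensus entries strictly inside
    (lower, upper); lower PAC means a more stable partition.
    """
    c = np.asarray(consensus, dtype=float)
    vals = c[np.triu_indices(c.shape[0], k=1)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


def _jaccard_partitions(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard similarity between two partitions via co-clustered pair counts."""
    ct = pd.crosstab(a, b).to_numpy()
    both = (ct * (ct - 1) // 2).sum()
    in_a = (ct.sum(axis=1) * (ct.sum(axis=1) - 1) // 2).sum()
    in_b = (ct.sum(axis=0) * (ct.sum(axis=0) - 1) // 2).sum()
    union = in_a + in_b - both
    return float(both / union) if union else 1.0


def _pairwise_partition_stats(
    iteration_labels: list[tuple[np.ndarray, np.ndarray]],
    max_pairs: int | None = None,
) -> tuple[float, float]:
    """Mean pairwise ARI / Jaccard across subsample partitions (shared subjects)."""
    pairs = [
        (i, j)
        for i in range(len(iteration_labels))
        for j in range(i + 1, len(iteration_labels))
    ]
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = pairs[:max_pairs]
    aris, jacs = [], []
    for i, j in pairs:
        idx_i, lab_i = iteration_labels[i]
        idx_j, lab_j = iteration_labels[j]
        shared, ii, jj = np.intersect1d(idx_i, idx_j, return_indices=True)
        if shared.size < 2:
            continue
        aris.append(adjusted_rand_score(lab_i[ii], lab_j[jj]))
        jacs.append(_jaccard_partitions(lab_i[ii], lab_j[jj]))
    if not aris:
        return np.nan, np.nan
    return float(np.mean(aris)), float(np.mean(jacs))


def stability_metrics(solution: ClusterSolution, points: np.ndarray) -> dict[str, float]:
    """PAC, silhouette, Calinski-Harabasz and mean pairwise ARI / Jaccard."""
    points = np.asarray(points, dtype=float)
    if solution.k < 2:
        raise ValidationError("silhouette undefined for k = 1")
    ari, jac = _pairwise_partition_stats(solution.iteration_labels)
    return {
        "PAC": pac(solution.consensus),
        "silhouette": float(silhouette_score(points, solution.labels)),
        "calinski_harabasz": float(calinski_harabasz_score(points, solution.labels)),
        "mean_pairwise_ari": ari,
        "mean_pairwise_jaccard": jac,
    }


def permutation_test(
    points: np.ndarray, k: int, B: int = 10000, seed: int = 0
) -> float:
    """Column-permutation test of partition non-randomness.

    The null destroys inter-feature structure while preserving marginals;
    the statistic is the Calinski-Harabasz index of PAM at k.  The p-value
    uses the add-one convention: (1 + #{null >= observed}) / (1 + B).
    """
    points = np.asarray(points, dtype=float)
    if B < 1:
        raise ValidationError("B must be >= 1")
    observed = calinski_harabasz_score(points, pam(points, k).labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = points.copy()
    for _ in range(B):
        for col in range(perm.shape[1]):
            perm[:, col] = rng.permutation(points[:, col])
        stat = calinski_harabasz_score(perm, pam(perm, k).labels)
        if stat >= observed:
            exceed += 1
    return float((1 + exceed) / (1 + B))


@dataclass
class SelectKResult:
    chosen_k: int
    table: pd.DataFrame
    stable: bool
    solutions: dict[int, ClusterSolution]


def select_k(
    points: np.ndarray,
    k_range: range | list[int] = range(2, 7),
    iterations: int = 100,
    subsample: float = 0.8,
    embedding: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    pairwise_stats: bool = False,
) -> SelectKResult:
    """Choose k minimizing PAC; ties broken by higher Calinski-Harabasz.

    Several k can reach identical (often zero) PAC when the data are well
    separated; among such equally stable candidates the silhouette is
    biased toward merging an intermediate cluster into a neighbour, so the
    Calinski-Harabasz index breaks the tie instead (then smaller k).  When
    even the best PAC exceeds 0.5 the result is flagged unstable
    ("no stable k" heuristic).
    """
    solutions: dict[int, ClusterSolution] = {}
    rows = []
    ks = list(k_range)
    seeds = np.random.SeedSequence(seed).spawn(len(ks))
    for k, ss in zip(ks, seeds):
        sol = consensus_cluster(
            points, k, iterations=iterations, subsample=subsample,
            embedding=embedding, seed=int(ss.generate_state(1)[0] % (2**31)),
            pairwise_stats=pairwise_stats,
        )
        solutions[k] = sol
        rows.append({"k": k, **sol.metrics})
    table = pd.DataFrame(rows).set_index("k")
    candidates = [k for k in ks if table.loc[k, "PAC"] == table["PAC"].min()]
    ch = table.get("calinski_harabasz", pd.Series(0.0, index=ks))
    chosen = sorted(candidates, key=lambda k: (-ch.get(k, 0.0), k))[0]
    stable = bool(table["PAC"].min() <= 0.5)
    return SelectKResult(chosen_k=chosen, table=table, stable=stable, solutions=solutions)


def profile_subtypes(
    labels: np.ndarray,
    normalized: NormalizedClinicalTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean normalized feature profile and diagnostic composition per subtype.

    Composition percentages sum to 100 within each subtype.
    """
    labels = np.asarray(labels)
    df = normalized.data.copy()
    df["subtype"] = labels
    profile = df.groupby("subtype").mean()
    comp = pd.crosstab(
        pd.Series(labels, name="subtype"),
        pd.Series(normalized.groups.to_numpy(), name="group"),
        normalize="index",
    ) * 100
    return profile, comp
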