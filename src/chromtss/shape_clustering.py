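"""Two-level clustering of chromatin-profile shapes.

Level 1 clusters the smoothed (48-bin) profiles of expressed RTSSs for one
chromatin mark into k=5 shape classes ("subprofiles") with k-means under
Pearson-correlation distance d = 1 - r, which compares shape rather than
intensity. Level 2 ("meta-clustering") represents every expressed RTSS by
its vector of Pearson correlations to all subprofiles across marks
(12 marks x 5 = 60 features; 55 when a mark is dropped) and k-means-clusters
those feature rows into k=10 combinatorial chromatin states.

The k-means variant matches the semantics of the classical kcluster
routine: each pass starts from a uniformly random assignment, iterates
(arithmetic-mean centroids, minimum-distance reassignment) to convergence,
and the best of `npass` passes by total within-cluster distance wins.
Centroids are plain means of member profiles and are not re-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

K_SUBPROFILES = 5
K_METACLUSTERS = 10
NPASS_LEVEL1 = 200
NPASS_LEVEL2 = 1000
MIN_SIGNAL = 100
_MAX_ITER = 300


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    """Rows standardized to zero mean / unit variance; constant rows -> 0.

    With both arguments standardized this way, mean(za * zb) is the Pearson
    r, and a constant vector correlates 0 with everything by convention.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / safe
    z[(sd == 0).ravel()] = 0.0
    return z


def pearson_correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between rows of a and rows of b (constants -> 0)."""
    a2, b2 = np.atleast_2d(a), np.atleast_2d(b)
    if a2.shape[1] != b2.shape[1]:
        raise ValueError("length mismatch")
    return _zscore_rows(a2) @ _zscore_rows(b2).T / a2.shape[1]


def pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """d = 1 - r(a, b) in [0, 2]; r of a constant vector is defined as 0."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must share length")
    if len(a) < 2:
        raise ValueError("need length >= 2")
    return float(1.0 - pearson_correlation_matrix(a, b)[0, 0])


def _one_pass(x: np.ndarray, k: int, rng: np.random.Generator):
    n = x.shape[0]
    assign = rng.integers(0, k, size=n)
    dist = np.zeros((n, k))
    for _ in range(_MAX_ITER):
        centroids = np.zeros((k, x.shape[1]))
        for c in range(k):
            members = assign == c
            if members.any():
                centroids[c] = x[members].mean(axis=0)
        dist = 1.0 - pearson_correlation_matrix(x, centroids)
        new_assign = dist.argmin(axis=1)
        # repair empty clusters: seize the point farthest from its centroid
        for c in range(k):
            if not (new_assign == c).any():
                worst = int(dist[np.arange(n), new_assign].argmax())
                new_assign[worst] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    objective = float(dist[np.arange(n), assign].sum())
    return assign, objective


def kmeans_pearson(
    x: np.ndarray, k: int, npass: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-npass k-means with Pearson distance.

    Returns (assignments, centroids, objective). Deterministic for a fixed
    seed; fewer rows than k is an error.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < k:
        raise ValueError(f"need >= {k} rows, got {x.shape[0]}")
    if npass < 1:
        raise ValueError("npass must be >= 1")
    rng = np.random.default_rng(seed)
    best_assign, best_obj = None, np.inf
    for _ in range(npass):
        assign, obj = _one_pass(x, k, rng)
        if obj < best_obj - 1e-12:
            best_assign, best_obj = assign, obj
    centroids = np.array([x[best_assign == c].mean(axis=0) for c in range(k)])
    return best_assign, centroids, best_obj


@dataclass
class SubprofileSet:
    """k mean shape templates for one chromatin mark plus the assignment."""

    mark: str
    k: int
    subprofiles: np.ndarray  # (k, n_bins) mean member profiles
    assignments: pd.Series  # rtss_id -> cluster index
    objective: float


def kmeans_shapes(
    profiles: pd.DataFrame,
    mark: str = "",
    k: int = K_SUBPROFILES,
    npass: int = NPASS_LEVEL1,
    seed: int | None = None,
) -> SubprofileSet:
    """Level-1 clustering of one mark's smoothed profiles into k subprofiles."""
    assign, centroids, obj = kmeans_pearson(profiles.values, k, npass, seed)
    return SubprofileSet(
        mark, k, centroids, pd.Series(assign, index=profiles.index), obj
    )


def subprofile_correlations(
    profile: np.ndarray,
    subprofiles: np.ndarray,
    raw_total: float,
    min_signal: float = MIN_SIGNAL,
) -> np.ndarray:
    """Pearson r of a profile against each subprofile; masked to zeros when
    the raw (pre-smoothing) total signal is below min_signal."""
    k = np.atleast_2d(subprofiles).shape[0]
    if raw_total < min_signal:
        return np.zeros(k)
    return pearson_correlation_matrix(profile, subprofiles)[0]


def build_meta_matrix(
    per_mark: dict[str, tuple[pd.DataFrame, pd.Series, SubprofileSet]],
    expressed_ids: list[str],
    mark_order: list[str] | None = None,
    min_signal: float = MIN_SIGNAL,
) -> pd.DataFrame:
    """Meta-feature matrix: rows expressed RTSSs, columns (mark, subprofile).

    per_mark maps mark -> (smoothed profiles, raw totals, SubprofileSet).
    An RTSS with no profile for a mark, or with raw total below min_signal,
    gets zeros for that mark's k columns.
    """
    if not per_mark:
        raise ValueError("need at least one mark")
    marks = mark_order if mark_order is not None else sorted(per_mark)
    blocks = []
    columns = []
    for mark in marks:
        smoothed, totals, subset = per_mark[mark]
        k = subset.subprofiles.shape[0]
        columns.extend([f"{mark}:{c}" for c in range(k)])
        block = np.zeros((len(expressed_ids), k))
        present = smoothed.index.intersection(expressed_ids)
        if len(present):
            r = pearson_correlation_matrix(
                smoothed.loc[present].values, subset.subprofiles
            )
            mask = totals.reindex(present).to_numpy() >= min_signal
            r[~mask] = 0.0
            pos = {rid: i for i, rid in enumerate(expressed_ids)}
            rows = [pos[rid] for rid in present]
            block[rows] = r
        blocks.append(block)
    return pd.DataFrame(
        np.hstack(blocks), index=pd.Index(expressed_ids, name="rtss_id"), columns=columns
    )


@dataclass
class MetaclusterResult:
    k: int
    assignments: pd.Series  # rtss_id -> metacluster index
    sizes: np.ndarray
    centroids: np.ndarray  # (k, n_features) mean feature rows
    objective: float


def metacluster(
    matrix: pd.DataFrame,
    k: int = K_METACLUSTERS,
    npass: int = NPASS_LEVEL2,
    seed: int | None = None,
) -> MetaclusterResult:
    """Level-2 k-means on correlation-feature rows (same engine as level 1)."""
    assign, centroids, obj = kmeans_pearson(matrix.values, k, npass, seed)
    sizes = np.bincount(assign, minlength=k)
    return MetaclusterResult(
        k, pd.Series(assign, index=matrix.index), sizes, centroids, obj
    )


def metacluster_mark_averages(
    result: MetaclusterResult,
    per_mark_smoothed: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Per-metacluster, per-mark average smoothed profiles (heatmap export).

    Long format: metacluster, mark, bin, mean_value.
    """
    rows = []
    for mark in sorted(per_mark_smoothed):
        prof = per_mark_smoothed[mark]
        for c in range(result.k):
            ids = result.assignments.index[result.assignments == c]
            member = prof.index.intersection(ids)
            mean = (
                prof.loc[member].values.mean(axis=0)
                if len(member)
                else np.zeros(prof.shape[1])
            )
            for b, v in enumerate(mean):
                rows.append((c, mark, b, v))
    return pd.DataFrame(rows, columns=["metacluster", "mark", "bin", "mean_value"])


def pca_cluster_diagnostic(matrix: pd.DataFrame, n_components: int = 5) -> pd.DataFrame:
    """PCA of the meta-feature matrix as a pre-clustering diagnostic.

    Reports explained-variance ratios; a guide for eyeballing how much
    combinatorial structure the features carry, not a model selector (k is
    fixed by design).
    """
    x = matrix.values - matrix.values.mean(axis=0)
    _, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    ratios = var[:n_components] / total if total > 0 else np.zeros(n_components)
    return pd.DataFrame(
        {"component": np.arange(1, len(ratios) + 1), "explained_variance_ratio": ratios}
    )
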