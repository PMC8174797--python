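"""Cluster-number selection, k-means state estimation, and centroid matching.

The number of recurrent connectivity states is chosen by a majority rule: a
set of cluster-validity indices is evaluated over a range of candidate k
(default 2..8) on k-means solutions, each index votes for one k, and the k
with the most votes wins (ties broken toward the smallest k).  Thirteen
documented indices are implemented: silhouette, Calinski-Harabasz,
Davies-Bouldin, Dunn, Ball-Hall successive difference, within-SS elbow
curvature, the gap statistic (PCA-aligned uniform reference), Hartigan,
Krzanowski-Lai, C-index, point-biserial, McClain-Rao, and PBM.

States are estimated by Euclidean k-means on the length-45 Fisher-z feature
vectors (no per-feature standardization; z-values share a scale).  The
returned solution is the best-inertia restart; final labels are an exact
nearest-centroid assignment and states are renumbered 1..k by descending
mean absolute off-diagonal centroid z, so the low-connectivity state always
receives the highest label, deterministically across seeds.

Two state solutions are matched by maximizing the total Pearson correlation
between centroid z-vectors over all state bijections (Hungarian assignment),
with per-pair r, two-sided p and 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .io import devectorize_upper_triangle

DEFAULT_SEED = 20210528
DEFAULT_K_RANGE = tuple(range(2, 9))
#: cluster-validity census: a subset of the classical index catalogue, each
#: with its documented decision rule (see select_k_majority)
DEFAULT_INDEX_SET = (
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "dunn",
    "ball_hall",
    "elbow_curvature",
    "gap_statistic",
    "hartigan",
    "kl",
    "c_index",
    "point_biserial",
    "mcclain_rao",
    "pbm",
)


@dataclass
class StateSolution:
    """A k-means state solution: centroids, assignments and fit diagnostics."""

    k: int
    centroids: np.ndarray  # k x 45 feature-space centroids
    labels: np.ndarray  # window index -> state label in 1..k
    inertia: float
    seed: int
    n_init: int
    max_iter: int

    def centroid_matrices(self) -> list[np.ndarray]:
        """Centroids as symmetric 10x10 z-matrices (diagonal 0)."""
        return [devectorize_upper_triangle(c) for c in self.centroids]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")


@dataclass
class KSelectionReport:
    """Majority-rule vote tally over candidate cluster counts."""

    k_range: tuple[int, ...]
    votes: dict[int, int]
    chosen_k: int
    per_index_choice: dict[str, int]


@dataclass
class StateMatching:
    """Optimal bijection between two solutions' states with per-pair statistics."""

    permutation: dict[int, int]  # state label in A -> state label in B
    per_pair_r: dict[int, float]
    per_pair_p: dict[int, float]
    per_pair_ci: dict[int, tuple[float, float]]

    @property
    def total_r(self) -> float:
        return float(sum(self.per_pair_r.values()))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _order_states(centroids: np.ndarray, labels0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber states 1..k by descending mean |off-diagonal z| of the centroid."""
    strength = np.abs(centroids).mean(axis=1)
    order = np.argsort(-strength, kind="stable")  # order[new-1] = old
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(1, len(order) + 1)
    return centroids[order], relabel[labels0]


def kmeans_states(
    features: np.ndarray,
    k: int,
    seed: int = DEFAULT_SEED,
    n_init: int = 25,
    max_iter: int = 25,
) -> StateSolution:
    """Euclidean k-means over feature vectors; best of ``n_init`` restarts.

    Restarts that converge with an empty cluster are handled by scikit-learn's
    re-initialization of empty clusters to the farthest points.  After
    fitting, labels are recomputed as exact nearest-centroid assignments so
    the stated invariant holds even for non-converged runs.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] <= k:
        raise ValueError(f"need more than k={k} points, got {features.shape[0]}")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed % (2**32),
        init="k-means++",
    ).fit(features)
    centroids = km.cluster_centers_
    d = cdist(features, centroids)
    labels0 = d.argmin(axis=1)
    # a centroid can lose all points in the final reassignment; fall back to
    # sklearn's own labels for that restart
    if len(np.unique(labels0)) < k:
        labels0 = km.labels_
    inertia = float(np.sum(d[np.arange(len(labels0)), labels0] ** 2))
    centroids, labels = _order_states(centroids, labels0)
    return StateSolution(k, centroids, labels, inertia, seed, n_init, max_iter)


def assign_windows(centroids: np.ndarray, features: np.ndarray) -> np.ndarray:
    """Label each feature vector by its Euclidean nearest centroid (1-based).

    Ties are broken toward the lowest state label.
    """
    centroids = np.asarray(centroids, dtype=float)
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != centroids.shape[1]:
        raise ValueError(
            f"feature dimension {features.shape[1]} != centroid dimension {centroids.shape[1]}"
        )
    d = cdist(features, centroids)
    return d.argmin(axis=1) + 1  # argmin takes the first minimum -> lowest label


# ---------------------------------------------------------------------------
# validity indices
# ---------------------------------------------------------------------------

def _wss(features: np.ndarray, sol: StateSolution) -> float:
    return sol.inertia


def _dunn_index(d: np.ndarray, labels: np.ndarray) -> float:
    """Min inter-cluster distance / max intra-cluster diameter (pointwise)."""
    ks = np.unique(labels)
    min_between = np.inf
    max_within = 0.0
    for i, a in enumerate(ks):
        ia = labels == a
        da = d[ia][:, ia]
        if da.size:
            max_within = max(max_within, float(da.max()))
        for b in ks[i + 1 :]:
            ib = labels == b
            min_between = min(min_between, float(d[ia][:, ib].min()))
    return min_between / max_within if max_within > 0 else np.inf


def _gap_statistic(
    features: np.ndarray,
    log_w: dict[int, float],
    k_range: tuple[int, ...],
    rng: np.random.Generator,
    n_refs: int = 8,
) -> int:
    """Gap statistic with the one-standard-error rule: smallest k with
    gap(k) >= gap(k+1) - s(k+1); the largest candidate if none qualifies.

    Reference datasets are uniform over the principal-component-aligned
    bounding box of the features (the rotation-respecting reference of the
    original method).
    """
    center = features.mean(axis=0)
    xc = features - center
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    xp = xc @ vt.T
    lo, hi = xp.min(axis=0), xp.max(axis=0)
    ref_log_w = {k: [] for k in k_range}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=xp.shape) @ vt
        for k in k_range:
            km = KMeans(
                n_clusters=k, n_init=2, max_iter=50,
                random_state=int(rng.integers(2**31)),
            ).fit(ref)
            ref_log_w[k].append(np.log(km.inertia_))
    gap = {k: float(np.mean(ref_log_w[k])) - log_w[k] for k in k_range}
    s = {k: float(np.std(ref_log_w[k])) * np.sqrt(1 + 1 / n_refs) for k in k_range}
    for k, k_next in zip(k_range, k_range[1:]):
        if gap[k] >= gap[k_next] - s[k_next]:
            return k
    return k_range[-1]


def _pair_stats(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All pairwise distances with their (i, j) index arrays (i < j)."""
    d = pdist(features)
    n = features.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    return d, ii.astype(np.int32), jj.astype(np.int32)


def select_k_majority(
    features: np.ndarray,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    index_set: tuple[str, ...] = DEFAULT_INDEX_SET,
    seed: int = DEFAULT_SEED,
    n_init: int = 25,
    max_iter: int = 50,
) -> KSelectionReport:
    """Choose the number of states by a majority vote of validity indices.

    Every index is evaluated on the same family of k-means solutions over
    ``k_range``; each casts one vote by its documented decision rule
    (maximum, minimum, maximum successive difference, maximum curvature, or
    the gap one-standard-error rule); the k with the most votes wins, ties
    broken toward the smallest k.  No index is pruned adaptively: members
    that plateau or saturate on a given dataset simply contribute their vote
    like the rest of the census.
    """
    features = np.asarray(features, dtype=float)
    k_range = tuple(sorted(k_range))
    n, p = features.shape
    if n <= max(k_range):
        raise ValueError("fewer points than the largest candidate k")
    unknown = set(index_set) - set(DEFAULT_INDEX_SET)
    if unknown:
        raise ValueError(f"unknown validity indices: {sorted(unknown)}")

    solutions = {k: kmeans_states(features, k, seed, n_init, max_iter) for k in k_range}
    labels = {k: solutions[k].labels for k in k_range}
    w = {k: solutions[k].inertia for k in k_range}
    # flanking solutions for difference/ratio rules (Hartigan, KL, Ball-Hall)
    w[1] = float(((features - features.mean(axis=0)) ** 2).sum())
    k_above = max(k_range) + 1
    w[k_above] = kmeans_states(
        features, k_above, seed, max(n_init // 2, 2), max_iter
    ).inertia
    rng = np.random.default_rng(seed)

    need_pairs = {"dunn", "c_index", "point_biserial", "mcclain_rao"} & set(index_set)
    if need_pairs:
        dvec, ii, jj = _pair_stats(features)
        same = {k: labels[k][ii] == labels[k][jj] for k in k_range}
    if "dunn" in index_set:
        dsq = squareform(dvec)
    if "c_index" in index_set:
        dsorted = np.sort(dvec)
        dcum = np.concatenate([[0.0], np.cumsum(dsorted)])

    def argbest(scores: dict[int, float], sign: int) -> int:
        # sign=+1 maximize, -1 minimize; ties toward smallest k
        return min(scores, key=lambda k: (-sign * scores[k], k))

    def successive_diff(curve: dict[int, float]) -> dict[int, float]:
        ks = sorted(curve)
        return {k2: curve[k1] - curve[k2] for k1, k2 in zip(ks, ks[1:]) if k2 in k_range}

    per_index: dict[str, int] = {}
    for name in index_set:
        if name == "silhouette":
            per_index[name] = argbest(
                {k: silhouette_score(features, labels[k]) for k in k_range}, +1
            )
        elif name == "calinski_harabasz":
            per_index[name] = argbest(
                {k: calinski_harabasz_score(features, labels[k]) for k in k_range}, +1
            )
        elif name == "davies_bouldin":
            per_index[name] = argbest(
                {k: davies_bouldin_score(features, labels[k]) for k in k_range}, -1
            )
        elif name == "dunn":
            per_index[name] = argbest(
                {k: _dunn_index(dsq, labels[k]) for k in k_range}, +1
            )
        elif name == "ball_hall":
            # mean within-cluster dispersion W/k; vote at the largest drop
            # between consecutive candidate levels
            bh = {k: w[k] / k for k in k_range}
            per_index[name] = argbest(successive_diff(bh), +1)
        elif name == "elbow_curvature":
            # maximal positive curvature of the within-SS curve (interior k)
            ks = list(k_range)
            curv = {
                ks[i]: w[ks[i - 1]] - 2 * w[ks[i]] + w[ks[i + 1]]
                for i in range(1, len(ks) - 1)
            }
            per_index[name] = argbest(curv, +1)
        elif name == "gap_statistic":
            log_w = {k: float(np.log(w[k])) for k in k_range}
            per_index[name] = _gap_statistic(features, log_w, k_range, rng)
        elif name == "hartigan":
            # H(k) = (W(k)/W(k+1) - 1)(n - k - 1); vote at the largest drop
            # between consecutive candidate levels
            h = {k: (w[k] / w[k + 1] - 1.0) * (n - k - 1) for k in k_range}
            per_index[name] = argbest(successive_diff(h), +1)
        elif name == "kl":
            # Krzanowski-Lai: |DIFF(k)| / |DIFF(k+1)|,
            # DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k); maximize
            def _diff(k: int) -> float:
                return (k - 1) ** (2 / p) * w[k - 1] - k ** (2 / p) * w[k]

            kl = {
                k: abs(_diff(k)) / max(abs(_diff(k + 1)), 1e-300)
                for k in k_range
                if k - 1 in w and k + 1 in w
            }
            per_index[name] = argbest(kl, +1)
        elif name == "c_index":
            # (S - S_min) / (S_max - S_min) over within-cluster pairs; minimize
            scores = {}
            for k in k_range:
                nw = int(same[k].sum())
                s_within = float(dvec[same[k]].sum())
                s_min = dcum[nw]
                s_max = dcum[-1] - dcum[len(dvec) - nw]
                scores[k] = (s_within - s_min) / (s_max - s_min)
            per_index[name] = argbest(scores, -1)
        elif name == "point_biserial":
            # correlation of pairwise distance with the different-cluster
            # indicator; maximize
            scores = {}
            for k in k_range:
                diff_ind = (~same[k]).astype(float)
                scores[k] = float(np.corrcoef(dvec, diff_ind)[0, 1])
            per_index[name] = argbest(scores, +1)
        elif name == "mcclain_rao":
            # mean within-cluster / mean between-cluster distance; minimize
            scores = {}
            for k in k_range:
                scores[k] = float(dvec[same[k]].mean() / dvec[~same[k]].mean())
            per_index[name] = argbest(scores, -1)
        elif name == "pbm":
            # ((1/k) (E_1/E_k) D_k)^2 with L2 point-to-centroid deviations
            gmean = features.mean(axis=0)
            e1 = float(np.linalg.norm(features - gmean, axis=1).sum())
            scores = {}
            for k in k_range:
                sol = solutions[k]
                ek = sum(
                    float(
                        np.linalg.norm(
                            features[labels[k] == c + 1] - sol.centroids[c], axis=1
                        ).sum()
                    )
                    for c in range(k)
                )
                dk = float(cdist(sol.centroids, sol.centroids).max())
                scores[k] = ((1.0 / k) * (e1 / ek) * dk) ** 2
            per_index[name] = argbest(scores, +1)

    votes: dict[int, int] = {k: 0 for k in k_range}
    for k in per_index.values():
        votes[k] += 1
    chosen = min(votes, key=lambda k: (-votes[k], k))
    return KSelectionReport(k_range, votes, chosen, per_index)


# ---------------------------------------------------------------------------
# centroid matching
# ---------------------------------------------------------------------------

def match_states(a: StateSolution, b: StateSolution, ci_level: float = 0.95) -> StateMatching:
    """Optimal bijection between the states of two equal-k solutions.

    Maximizes the total Pearson correlation between matched centroid
    z-vectors over all k! bijections via the Hungarian algorithm; the k <= 6
    optimum is verified against brute force in the test suite.
    """
    if a.k != b.k:
        raise ValueError(f"solutions have different k: {a.k} != {b.k}")
    k = a.k
    r = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            r[i, j] = stats.pearsonr(a.centroids[i], b.centroids[j]).statistic
    rows, cols = linear_sum_assignment(-r)
    perm, per_r, per_p, per_ci = {}, {}, {}, {}
    for i, j in zip(rows, cols):
        res = stats.pearsonr(a.centroids[i], b.centroids[j])
        ci = res.confidence_interval(confidence_level=ci_level)
        perm[i + 1] = j + 1
        per_r[i + 1] = float(res.statistic)
        per_p[i + 1] = float(res.pvalue)
        per_ci[i + 1] = (float(ci.low), float(ci.high))
    return StateMatching(perm, per_r, per_p, per_ci)
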