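"""Fuzzy c-means clustering of z-scored mean metabolite trajectories.

Metabolite time-course archetypes (sustained decline, rise with plateau,
V-shape, rise-then-fall) are recovered by soft clustering of each
metabolite's z-scored across-subject mean trajectory. The fuzzifier m is
estimated from the data dimensions with the Schwammle-Jensen rule used by
standard fuzzy-clustering packages for omics time courses; each metabolite
is hard-assigned to its maximum-membership cluster for reporting.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus


def estimate_fuzzifier(n_features: int, n_dims: int) -> float:
    """Dimension/size-based fuzzifier estimate (Schwammle-Jensen rule).

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    with N the number of clustered features and D the dimensionality of each
    feature vector. Always > 1; decreases as D grows.
    """
    if n_features < 2 or n_dims < 2:
        raise ValueError("fuzzifier estimate needs n_features >= 2 and n_dims >= 2")
    N, D = float(n_features), float(n_dims)
    return float(
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * np.log(N) - 0.1134)
    )


@dataclasses.dataclass
class FuzzyClusterResult:
    """Soft clustering output.

    ``membership`` rows sum to 1; ``assignment`` is the argmax cluster per
    metabolite; ``objective_trace`` is the (non-increasing) value of
    J(U, V) = sum_i sum_c u_ic^m d_ic^2 per iteration.
    """

    centroids: pd.DataFrame
    membership: pd.DataFrame
    fuzzifier: float
    assignment: pd.Series
    objective_trace: list[float]
    n_iter: int
    converged: bool


def fuzzy_cmeans(
    Z: pd.DataFrame,
    c: int,
    m: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> FuzzyClusterResult:
    """Euclidean fuzzy c-means with k-means++ seeding.

    Alternates the standard updates u_ic = 1 / sum_k (d_ic/d_ik)^(2/(m-1))
    and v_c = sum_i u_ic^m z_i / sum_i u_ic^m until the maximum centroid
    displacement falls below ``tol``. A feature coinciding with a centroid
    receives membership 1 there (the distance-zero limit).
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    X = Z.to_numpy(dtype=float)
    n, d = X.shape
    if c > n:
        raise ValueError("more clusters than features")
    V, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    # pull seeds off the exact data points: a centroid coinciding with a
    # feature would pin its membership at 1 and freeze the iteration
    V = X.mean(axis=0) + 0.99 * (V - X.mean(axis=0))
    power = 2.0 / (m - 1.0)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = cdist(X, V, metric="sqeuclidean")
        U = _memberships(d2, power)
        Um = U**m
        colsum = Um.sum(axis=0)
        if (colsum == 0).any():  # u^m underflow at very large m -> grand mean
            V_new = np.where(
                colsum[:, None] > 0,
                (Um.T @ X) / np.where(colsum[:, None] > 0, colsum[:, None], 1.0),
                X.mean(axis=0),
            )
        else:
            V_new = (Um.T @ X) / colsum[:, None]
        d2_new = cdist(X, V_new, metric="sqeuclidean")
        trace.append(float(np.sum(_memberships(d2_new, power) ** m * d2_new)))
        shift = np.abs(V_new - V).max()
        V = V_new
        if shift < tol:
            converged = True
            break
    d2 = cdist(X, V, metric="sqeuclidean")
    U = _memberships(d2, power)
    idx = Z.index
    cols = [f"cluster_{k+1}" for k in range(c)]
    membership = pd.DataFrame(U, index=idx, columns=cols)
    centroids = pd.DataFrame(V, index=cols, columns=Z.columns)
    assignment = pd.Series(
        [cols[k] for k in np.argmax(U, axis=1)], index=idx, name="cluster"
    )
    return FuzzyClusterResult(
        centroids=centroids,
        membership=membership,
        fuzzifier=m,
        assignment=assignment,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def _memberships(d2: np.ndarray, power: float) -> np.ndarray:
    """Membership matrix from squared distances, with the zero-distance limit."""
    U = np.empty_like(d2)
    zero_rows = (d2 < 1e-300).any(axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-power / 2.0)  # d^{-2/(m-1)}
    U[~zero_rows] = inv[~zero_rows] / inv[~zero_rows].sum(axis=1, keepdims=True)
    for i in np.where(zero_rows)[0]:
        U[i] = 0.0
        U[i, int(np.argmin(d2[i]))] = 1.0
    return U


def cluster_composition(
    result: FuzzyClusterResult, categories: dict[str, str]
) -> pd.DataFrame:
    """Per-cluster proportions of metabolite categories (rows sum to 1)."""
    missing = [m for m in result.assignment.index if m not in categories]
    if missing:
        raise ValueError(f"metabolite without category: {missing[0]!r}")
    df = pd.DataFrame(
        {
            "cluster": result.assignment,
            "category": [categories[m] for m in result.assignment.index],
        }
    )
    counts = df.groupby(["cluster", "category"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)
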