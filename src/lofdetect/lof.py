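"""Local Outlier Factor (LOF) scoring of EEG channels.

Each channel's time series is one point in sample space.  The LOF of a point
is the ratio of the average local reachability density (LRD) of its *k*
nearest neighbours to its own LRD:

    reach-dist_k(p, o) = max{ k-distance(o), d(p, o) }
    LRD_k(p)           = 1 / mean_{o in N_k(p)} reach-dist_k(p, o)
    LOF_k(p)           = mean_{o in N_k(p)} LRD_k(o) / LRD_k(p)

Inliers sitting in a homogeneous cluster score ~1; isolated channels score
substantially above 1.  Distances are either plain Euclidean or standardized
Euclidean (each sample dimension scaled by its standard deviation across
channels); *k* can be fixed or chosen data-driven by the natural-neighbor
search.

Everything here is deterministic and double precision; the O(n_channels^2)
dense distance matrix is fine for EEG montages (tens to a few hundred
channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import ChannelMatrix
from .errors import (
    DegenerateDimensionError,
    DegenerateGeometryWarning,
    InsufficientChannelsError,
    ParameterError,
)

__all__ = [
    "DistanceSpec",
    "NeighborIndex",
    "LOFScores",
    "pairwise_distance",
    "knn",
    "natural_neighbor_k",
    "reachability_distance",
    "local_reachability_density",
    "lof_scores",
    "lof_from_distances",
]

#: LRD cap for exact-duplicate channels (zero mean reachability distance).
DUPLICATE_EPS = 1e-12

_METRIC_ALIASES = {
    "euclidean": "euclidean",
    "euc": "euclidean",
    "seuclidean": "seuclidean",
    "seuc": "seuclidean",
    "standardized_euclidean": "seuclidean",
}


@dataclass
class DistanceSpec:
    """Distance metric for channel activity vectors.

    metric : {"euclidean", "seuclidean"}
        ``"seuclidean"`` scales each sample dimension by its standard
        deviation computed across all channels (ddof=1, the convention of
        MATLAB's and scipy's ``seuclidean``).  Aliases ``euc``/``seuc``/
        ``standardized_euclidean`` are accepted.
    scale : ndarray, optional
        Explicit per-dimension scale (length n_samples, strictly positive);
        only used by ``seuclidean``.  When absent it is computed from the
        data.
    """

    metric: str = "seuclidean"
    scale: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        key = str(self.metric).lower()
        if key not in _METRIC_ALIASES:
            raise ParameterError(f"unknown metric {self.metric!r}")
        self.metric = _METRIC_ALIASES[key]
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=np.float64)
            if np.any(self.scale <= 0):
                bad = np.flatnonzero(self.scale <= 0)
                raise DegenerateDimensionError(bad)


@dataclass
class NeighborIndex:
    """k-nearest-neighbor structure over channels.

    ``neighbor_ids[c]`` lists the ``k`` nearest *other* channels of ``c`` in
    nondecreasing distance order (ties broken by lower channel index);
    ``k_distance[c]`` is the distance to the k-th nearest neighbor.
    """

    k: int
    neighbor_ids: np.ndarray  # (n, k) int
    neighbor_dists: np.ndarray  # (n, k) float
    k_distance: np.ndarray  # (n,) float


@dataclass
class LOFScores:
    """Per-channel LRD and LOF values with the parameters used."""

    lrd: np.ndarray
    lof: np.ndarray
    k_used: int
    metric_used: DistanceSpec


def pairwise_distance(X: ChannelMatrix, spec: DistanceSpec) -> np.ndarray:
    """Symmetric channel-by-channel distance matrix (zero diagonal)."""
    data = X.data
    if spec.metric == "euclidean":
        return squareform(pdist(data, metric="euclidean"))
    scale = spec.scale
    if scale is None:
        scale = np.std(data, axis=0, ddof=1)
        zero = np.flatnonzero(scale == 0)
        if zero.size:
            raise DegenerateDimensionError(zero)
    else:
        if scale.shape != (X.n_samples,):
            raise ParameterError(
                f"scale must have length n_samples={X.n_samples}, got {scale.shape}"
            )
    return squareform(pdist(data, metric="seuclidean", V=scale**2))


def knn(D: np.ndarray, k: int) -> NeighborIndex:
    """k nearest neighbors of every channel from a dense distance matrix.

    Ties at equal distance are broken toward the lower channel index; the
    neighborhood has fixed cardinality ``k`` (ties at the k-th distance do
    not expand it).  A channel is never its own neighbor.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ParameterError("D must be square")
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must be in [1, {n - 1}], got {k}")
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    # stable argsort => ties resolved toward the lower index
    order = np.argsort(masked, axis=1, kind="stable")[:, :k]
    dists = np.take_along_axis(masked, order, axis=1)
    return NeighborIndex(
        k=k,
        neighbor_ids=order,
        neighbor_dists=dists,
        k_distance=dists[:, -1].copy(),
    )


def natural_neighbor_k(D: np.ndarray, *, identical_tol: float = 0.0) -> int:
    """Data-driven neighborhood size via the natural-neighbor (NaN) search.

    Grow the search round r = 1, 2, ...; in round r every channel nominates
    its r-th nearest neighbor, which thereby acquires a reverse neighbor.
    Stop at the first r where every channel has at least one reverse
    neighbor, or where the count of channels still lacking one is unchanged
    from the previous round; return that r (capped at n_channels - 1).

    All-identical channels have no meaningful neighborhood structure: k = 1
    is returned with a :class:`DegenerateGeometryWarning`.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if n < 3:
        raise InsufficientChannelsError("natural_neighbor_k needs >= 3 channels")
    off = D[~np.eye(n, dtype=bool)]
    if np.all(off <= identical_tol):
        warnings.warn(
            "all channels are identical; returning k=1", DegenerateGeometryWarning
        )
        return 1
    masked = D.copy()
    np.fill_diagonal(masked, np.inf)
    order = np.argsort(masked, axis=1, kind="stable")
    has_reverse = np.zeros(n, dtype=bool)
    prev_missing = None
    for r in range(1, n):
        has_reverse[order[:, r - 1]] = True
        missing = int(n - np.count_nonzero(has_reverse))
        if missing == 0 or missing == prev_missing:
            return r
        prev_missing = missing
    return n - 1


def reachability_distance(p: int, o: int, nn: NeighborIndex, D: np.ndarray) -> float:
    """reach-dist_k(p, o) = max{k-distance(o), d(p, o)}."""
    if p == o:
        raise ParameterError("reachability distance requires p != o")
    return float(max(nn.k_distance[o], D[p, o]))


def local_reachability_density(p: int, nn: NeighborIndex, D: np.ndarray) -> float:
    """Inverse mean reachability distance from channel p to its k neighbors.

    Exact-duplicate neighborhoods (mean reachability distance 0) are capped
    at ``1 / DUPLICATE_EPS`` so downstream LOF ratios stay finite.
    """
    nbr = nn.neighbor_ids[p]
    reach = np.maximum(nn.k_distance[nbr], D[p, nbr])
    mean_reach = float(np.mean(reach))
    if mean_reach < DUPLICATE_EPS:
        return 1.0 / DUPLICATE_EPS
    return 1.0 / mean_reach


def lof_from_distances(D: np.ndarray, k: Union[int, str] = "auto") -> tuple[np.ndarray, np.ndarray, int]:
    """LRD and LOF for every channel from a precomputed distance matrix.

    Returns ``(lrd, lof, k_used)``.  Vectorized equivalent of evaluating the
    three defining equations channel by channel.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if n < 3:
        raise InsufficientChannelsError(f"LOF needs >= 3 channels, got {n}")
    if k == "auto":
        k_used = natural_neighbor_k(D)
    else:
        k_used = int(k)
    nn = knn(D, k_used)
    # reach[p, j] = reach-dist(p, j-th neighbor of p)
    reach = np.maximum(nn.k_distance[nn.neighbor_ids], nn.neighbor_dists)
    mean_reach = reach.mean(axis=1)
    lrd = np.where(mean_reach < DUPLICATE_EPS, 1.0 / DUPLICATE_EPS, 1.0 / np.maximum(mean_reach, DUPLICATE_EPS))
    lof = lrd[nn.neighbor_ids].mean(axis=1) / lrd
    return lrd, lof, k_used


def lof_scores(
    X: ChannelMatrix,
    spec: Optional[DistanceSpec] = None,
    k: Union[int, str] = "auto",
) -> LOFScores:
    """LOF outlier scores for every channel of a recording.

    Parameters
    ----------
    X : ChannelMatrix
    spec : DistanceSpec, optional
        Defaults to standardized Euclidean.
    k : int or "auto"
        Neighborhood size; ``"auto"`` selects it with the natural-neighbor
        search.
    """
    if spec is None:
        spec = DistanceSpec()
    if X.n_channels < 3:
        raise InsufficientChannelsError(
            f"LOF needs >= 3 channels, got {X.n_channels}"
        )
    D = pairwise_distance(X, spec)
    lrd, lof, k_used = lof_from_distances(D, k)
    return LOFScores(lrd=lrd, lof=lof, k_used=k_used, metric_used=spec)
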