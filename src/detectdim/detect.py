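"""DETECT index, partition maximization and dimensionality classification.

Given the matrix of pairwise conditional covariances ``C`` and a partition
``P`` of the items into mutually exclusive clusters, the DETECT index is

    D(P) = 100 * [2 / (n (n-1))] * sum_{i<j} delta_ij(P) * C_ij,

with ``delta_ij = +1`` if items i and j share a cluster and ``-1`` otherwise.
The maximizing partition ``P*`` yields the reported value ``D*`` (the usual
x100 reporting convention: raw conditional covariances are of order 1e-3).
``D* < 0.1`` indicates essential unidimensionality; ``D* > 1.0`` sizable
multidimensionality.  The companion ratio index

    r(P) = sum_{i<j} delta_ij C_ij / sum_{i<j} |C_ij|

equals 1 exactly when the partition's cluster structure matches the sign of
every pairwise conditional covariance; ``r > 0.8`` indicates an
approximately simple structure.

Partition search is exhaustive over all set partitions for small item sets
and otherwise uses agglomerative average-linkage clustering of the items
(dissimilarity ``max(C) - C``) cut at every cluster count up to ``max_k``,
with each cut polished by greedy single-item reassignment; ties in the index
are broken toward fewer clusters.

The scikit-learn style estimator :class:`Detect` wraps the full pipeline
(screen items -> conditional covariances -> maximize -> classify) and is the
recommended entry point; :func:`run_detect` is a functional shortcut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .conditional_covariance import (
    CONDITIONING_MODES,
    ccov_matrix,
    degenerate_items,
    _as_score_array,
)

__all__ = [
    "LABEL_UNIDIMENSIONAL",
    "LABEL_MODERATE",
    "LABEL_SIZABLE",
    "UndefinedRatioError",
    "DetectResult",
    "detect_index",
    "ratio_index",
    "classify",
    "all_partitions",
    "maximize_partition",
    "run_detect",
    "Detect",
]

LABEL_UNIDIMENSIONAL = "essentially unidimensional"
LABEL_MODERATE = "moderate multidimensionality"
LABEL_SIZABLE = "sizable multidimensionality"

EXHAUSTIVE_MAX_ITEMS = 12
_TIE_TOL = 1e-12


class UndefinedRatioError(ValueError):
    """Ratio index requested on an all-zero conditional-covariance matrix."""


def _pair_values(ccov: np.ndarray):
    ccov = np.asarray(ccov, dtype=float)
    if ccov.ndim != 2 or ccov.shape[0] != ccov.shape[1]:
        raise ValueError("conditional-covariance matrix must be square")
    iu, ju = np.triu_indices(ccov.shape[0], k=1)
    return ccov.shape[0], iu, ju, ccov[iu, ju]


def _check_labels(labels, n: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ValueError(
            f"partition covers {labels.shape} items but matrix has {n}"
        )
    return labels


def canonical_labels(labels) -> np.ndarray:
    """Relabel clusters contiguously (0..k-1) in order of first appearance."""
    labels = np.asarray(labels)
    _, canon = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty(labels.shape[0], dtype=np.int64)
    for idx, lab in enumerate(canon):
        if lab not in order:
            order[lab] = len(order)
        out[idx] = order[lab]
    return out


def detect_index(ccov: np.ndarray, labels) -> float:
    """DETECT index of a partition: signed average conditional covariance, x100."""
    n, iu, ju, vals = _pair_values(ccov)
    labels = _check_labels(labels, n)
    delta = np.where(labels[iu] == labels[ju], 1.0, -1.0)
    return float(100.0 * (2.0 / (n * (n - 1))) * np.sum(delta * vals))


def ratio_index(ccov: np.ndarray, labels) -> float:
    """Signed-over-absolute sum of conditional covariances under a partition."""
    n, iu, ju, vals = _pair_values(ccov)
    labels = _check_labels(labels, n)
    denom = np.sum(np.abs(vals))
    if denom == 0.0:
        raise UndefinedRatioError("all pairwise conditional covariances are zero")
    delta = np.where(labels[iu] == labels[ju], 1.0, -1.0)
    return float(np.sum(delta * vals) / denom)


def classify(dstar: float) -> str:
    """Map a maximized DETECT value to the conventional dimensionality band.

    Below 0.1: essentially unidimensional; 0.1 to 1.0 (boundaries included):
    moderate multidimensionality; above 1.0: sizable multidimensionality.
    """
    if not np.isfinite(dstar):
        raise ValueError("DETECT value must be finite")
    if dstar < 0.1:
        return LABEL_UNIDIMENSIONAL
    if dstar <= 1.0:
        return LABEL_MODERATE
    return LABEL_SIZABLE


def all_partitions(n: int) -> Iterator[np.ndarray]:
    """Yield every set partition of ``n`` items as a canonical label array.

    Enumerates restricted growth strings, so the single-cluster partition
    comes first and labels are always contiguous in first-appearance order.
    """
    labels = np.zeros(n, dtype=np.int64)
    maxes = np.zeros(n, dtype=np.int64)
    while True:
        yield labels.copy()
        # increment the rightmost position that can still grow
        for pos in range(n - 1, 0, -1):
            if labels[pos] <= maxes[pos - 1]:
                labels[pos] += 1
                maxes[pos] = max(maxes[pos - 1], labels[pos])
                labels[pos + 1 :] = 0
                maxes[pos + 1 :] = maxes[pos]
                break
        else:
            return


def _cluster_sums(ccov0: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """M[i, c] = sum of ccov[i, j] over items j in cluster c (j != i)."""
    n = ccov0.shape[0]
    member = np.zeros((n, k))
    member[np.arange(n), labels] = 1.0
    return ccov0 @ member


def _greedy_refine(
    ccov0: np.ndarray, labels: np.ndarray, max_k: int
) -> np.ndarray:
    """Best-improvement single-item reassignment until no move raises the index.

    Moves an item to another cluster (or, below ``max_k`` clusters, to a new
    singleton) whenever that strictly increases the within-cluster sum of
    conditional covariances, which is equivalent to increasing the DETECT
    index.  Deterministic: the single best move is applied each round.
    """
    labels = canonical_labels(labels)
    n = ccov0.shape[0]
    for _ in range(50 * n):  # safety cap; the index strictly increases
        k = labels.max() + 1
        M = _cluster_sums(ccov0, labels, k)
        own = M[np.arange(n), labels]
        gains = M - own[:, None]
        gains[np.arange(n), labels] = -np.inf
        # a new singleton cluster contributes 0 within-cluster covariance
        allow_new = k < max_k
        new_gain = -own if allow_new else np.full(n, -np.inf)
        best_existing = gains.max(axis=1)
        best_per_item = np.maximum(best_existing, new_gain)
        item = int(np.argmax(best_per_item))
        if best_per_item[item] <= _TIE_TOL:
            break
        if new_gain[item] > best_existing[item]:
            labels[item] = k
        else:
            labels[item] = int(np.argmax(gains[item]))
        labels = canonical_labels(labels)
    return labels


_PARTITION_CACHE: dict = {}


def _partition_table(n: int):
    """All set partitions of n items as a label matrix plus pair co-membership."""
    if n not in _PARTITION_CACHE:
        labels = np.array(list(all_partitions(n)), dtype=np.int8)
        iu, ju = np.triu_indices(n, k=1)
        delta = np.where(labels[:, iu] == labels[:, ju], 1.0, -1.0)
        ks = labels.max(axis=1).astype(np.int64) + 1
        _PARTITION_CACHE[n] = (labels, delta, ks)
    return _PARTITION_CACHE[n]


def _exhaustive_batched(ccov: np.ndarray, max_k: int) -> np.ndarray:
    """Evaluate every set partition at once via the cached co-membership table."""
    n = ccov.shape[0]
    labels, delta, ks = _partition_table(n)
    iu, ju = np.triu_indices(n, k=1)
    d = (200.0 / (n * (n - 1))) * (delta @ ccov[iu, ju])
    d = np.where(ks <= max_k, d, -np.inf)
    top = d.max()
    tied = np.flatnonzero(d >= top - _TIE_TOL)
    best = tied[np.argmin(ks[tied])]
    return labels[best].astype(np.int64)


def _evaluate(ccov, labels):
    labels = canonical_labels(labels)
    return detect_index(ccov, labels), labels


def maximize_partition(
    ccov: np.ndarray,
    max_k: int = 12,
    method: str = "auto",
    refine: bool = True,
) -> np.ndarray:
    """Partition of the items maximizing the DETECT index.

    ``method='exhaustive'`` scans all set partitions (only for up to 12
    items); ``'cluster-heuristic'`` evaluates average-linkage cuts at 1 to
    ``max_k`` clusters, each polished by greedy reassignment; ``'auto'``
    picks exhaustive for up to 8 items.  Ties are resolved toward fewer
    clusters.  Returns canonical 0-based cluster labels.
    """
    ccov = np.asarray(ccov, dtype=float)
    n = ccov.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to partition")
    if method == "auto":
        method = "exhaustive" if n <= 8 else "cluster-heuristic"
    if method not in ("exhaustive", "cluster-heuristic"):
        raise ValueError(f"unknown search method {method!r}")

    if method == "exhaustive":
        if n > EXHAUSTIVE_MAX_ITEMS:
            raise ValueError(
                f"exhaustive search supports at most {EXHAUSTIVE_MAX_ITEMS} items, got {n}"
            )
        if n <= 10:
            return _exhaustive_batched(ccov, max_k)
        best_labels = None
        best = (-np.inf, n + 1)
        for labels in all_partitions(n):
            k = labels.max() + 1
            if k > max_k:
                continue
            d = detect_index(ccov, labels)
            if d > best[0] + _TIE_TOL or (abs(d - best[0]) <= _TIE_TOL and k < best[1]):
                best = (d, k)
                best_labels = labels
        return best_labels

    ccov0 = np.nan_to_num(ccov, nan=0.0)
    np.fill_diagonal(ccov0, 0.0)
    off = ccov0[np.triu_indices(n, k=1)]
    dissim = off.max() - off
    Z = linkage(dissim, method="average")
    best_labels = None
    best = (-np.inf, n + 1)
    for k in range(1, min(n, max_k) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        if refine:
            labels = _greedy_refine(ccov0, labels, max_k)
        d, labels = _evaluate(ccov, labels)
        k_eff = labels.max() + 1
        if d > best[0] + _TIE_TOL or (abs(d - best[0]) <= _TIE_TOL and k_eff < best[1]):
            best = (d, k_eff)
            best_labels = labels
    return best_labels


@dataclass(frozen=True)
class DetectResult:
    """Outcome of a DETECT analysis.

    ``labels`` covers every input item; dropped (zero-variance) items carry
    label -1 and are excluded from the index.
    """

    dstar: float
    r: float
    k: int
    labels: np.ndarray
    classification: str
    cluster_sizes: tuple
    dropped_items: tuple
    ccov: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "dstar": self.dstar,
            "r": self.r,
            "n_clusters": self.k,
            "classification": self.classification,
            "cluster_sizes": list(self.cluster_sizes),
            "clusters": {
                str(c + 1): np.flatnonzero(self.labels == c).tolist()
                for c in range(self.k)
            },
            "dropped_items": list(self.dropped_items),
        }


class Detect(BaseEstimator):
    """Nonparametric dimensionality analysis of a dichotomous test.

    Clusters the *items* (columns) of an examinees-by-items 0/1 response
    matrix by maximizing the DETECT index over partitions of the items, and
    reports the maximized index ``detect_value_``, the simple-structure
    ratio ``ratio_``, and a conventional classification.

    Parameters
    ----------
    min_group : int, default 20
        Minimum examinee count per conditioning-score group; sparse adjacent
        groups are merged until every group reaches this size.
    conditioning : {'both', 'rest', 'total'}, default 'both'
        Composite-ability proxy: pairwise rest score, total score, or the
        average of the two estimators (bias reduction).
    max_clusters : int, default 12
        Largest cluster count considered by the partition search.
    method : {'auto', 'exhaustive', 'cluster-heuristic'}, default 'auto'
        Partition search strategy; 'auto' is exhaustive for up to 8 items.
    refine : bool, default True
        Polish heuristic cuts by greedy single-item reassignment.
    on_degenerate : {'drop', 'raise'}, default 'drop'
        Zero-variance items are either dropped with a warning or raise.

    Attributes
    ----------
    labels_ : ndarray of shape (n_items,)
        Cluster label per item (0-based); -1 marks dropped items.
    n_clusters_ : int
    detect_value_ : float
        Maximized DETECT index D* (x100 convention).
    ratio_ : float
    classification_ : str
    cluster_sizes_ : tuple of int
    dropped_items_ : tuple of int
    ccov_ : ndarray
        Conditional-covariance matrix of the retained items (NaN diagonal).

    Examples
    --------
    >>> import numpy as np
    >>> from detectdim import Detect
    >>> rng = np.random.default_rng(0)
    >>> X = (rng.random((200, 6)) < 0.5).astype(int)
    >>> est = Detect().fit(X)
    >>> est.labels_.shape
    (6,)
    """

    def __init__(
        self,
        min_group: int = 20,
        conditioning: str = "both",
        max_clusters: int = 12,
        method: str = "auto",
        refine: bool = True,
        on_degenerate: str = "drop",
    ):
        self.min_group = min_group
        self.conditioning = conditioning
        self.max_clusters = max_clusters
        self.method = method
        self.refine = refine
        self.on_degenerate = on_degenerate

    def fit(self, X, y=None):
        """Run the full DETECT analysis on a 0/1 response matrix."""
        if self.conditioning not in CONDITIONING_MODES:
            raise ValueError(f"conditioning must be one of {CONDITIONING_MODES}")
        if self.on_degenerate not in ("drop", "raise"):
            raise ValueError("on_degenerate must be 'drop' or 'raise'")
        scores = _as_score_array(X)
        if not np.isin(scores, (0, 1)).all():
            raise ValueError("response matrix entries must be 0/1")
        n_items = scores.shape[1]

        deg = degenerate_items(scores)
        if deg.size and self.on_degenerate == "raise":
            from .conditional_covariance import DegenerateItemError

            raise DegenerateItemError(deg)
        if deg.size:
            warnings.warn(
                f"dropping {deg.size} zero-variance item(s) at column(s) "
                f"{deg.tolist()}",
                UserWarning,
                stacklevel=2,
            )
        keep = np.setdiff1d(np.arange(n_items), deg)
        if keep.size < 3:
            raise ValueError("fewer than 3 non-degenerate items remain")

        ccov = ccov_matrix(
            scores[:, keep], min_group=self.min_group, conditioning=self.conditioning
        )
        kept_labels = maximize_partition(
            ccov, max_k=self.max_clusters, method=self.method, refine=self.refine
        )
        labels = np.full(n_items, -1, dtype=np.int64)
        labels[keep] = kept_labels

        self.dropped_items_ = tuple(int(d) for d in deg)
        self.item_indices_ = keep
        self.ccov_ = ccov
        self.labels_ = labels
        self.n_clusters_ = int(kept_labels.max() + 1)
        self.detect_value_ = detect_index(ccov, kept_labels)
        self.ratio_ = ratio_index(ccov, kept_labels)
        self.classification_ = classify(self.detect_value_)
        self.cluster_sizes_ = tuple(
            int(np.sum(kept_labels == c)) for c in range(self.n_clusters_)
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the per-item cluster labels."""
        return self.fit(X).labels_

    def result_(self) -> DetectResult:
        """Fitted outcome bundled as a :class:`DetectResult`."""
        check_is_fitted(self, "labels_")
        return DetectResult(
            dstar=self.detect_value_,
            r=self.ratio_,
            k=self.n_clusters_,
            labels=self.labels_,
            classification=self.classification_,
            cluster_sizes=self.cluster_sizes_,
            dropped_items=self.dropped_items_,
            ccov=self.ccov_,
        )


def run_detect(X, **options) -> DetectResult:
    """Functional one-shot DETECT analysis; see :class:`Detect` for options."""
    return Detect(**options).fit(X).result_()
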