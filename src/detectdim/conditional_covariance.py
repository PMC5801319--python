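"""Pairwise conditional covariances of item scores given an ability proxy.

For a pair of dichotomous items (i, j), the conditional covariance is the
covariance of their scores among examinees at the same level of a composite
ability.  The composite is operationalized through observed scores:

* the pairwise **rest score** — the examinee's number-correct total over all
  items except i and j;
* the **total score** over all items.

Examinees are grouped by the conditioning score, sparse adjacent score groups
are merged until each group reaches a minimum size, the maximum-likelihood
sample covariance of (Xi, Xj) is computed within each group, and the estimate
is the group-size-weighted average.  The default estimator averages the
rest-score-conditioned and total-score-conditioned estimates, the classic
bias-reduction scheme for conditional-covariance methods: conditioning on a
score that includes the pair biases the estimate one way, excluding the pair
biases it the other way, and the two biases largely cancel.

Items measuring the same dominant dimension covary positively given the
composite; items measuring different dimensions covary negatively.  This sign
pattern is what the DETECT index aggregates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateItemError",
    "rest_score",
    "ccov_pair",
    "ccov_matrix",
]

CONDITIONING_MODES = ("both", "rest", "total")


class DegenerateItemError(ValueError):
    """An item with zero score variance (all 0s or all 1s)."""

    def __init__(self, items):
        self.items = list(np.atleast_1d(items))
        super().__init__(
            f"zero-variance item(s) at column index(es) {self.items}; "
            "drop them before estimating conditional covariances"
        )


def _as_score_array(X) -> np.ndarray:
    scores = getattr(X, "scores", X)
    scores = np.asarray(scores)
    if scores.ndim != 2:
        raise ValueError("response matrix must be 2-d (examinees x items)")
    return scores


def degenerate_items(X) -> np.ndarray:
    """Column indexes of zero-variance items."""
    scores = _as_score_array(X)
    means = scores.mean(axis=0)
    return np.flatnonzero((means == 0.0) | (means == 1.0))


def rest_score(X, i: int, j: int) -> np.ndarray:
    """Per-examinee number-correct total excluding items ``i`` and ``j``."""
    if i == j:
        raise IndexError("rest score requires two distinct items")
    scores = _as_score_array(X)
    if scores.shape[1] < 3:
        raise ValueError("rest score needs at least 3 items")
    return scores.sum(axis=1) - scores[:, i] - scores[:, j]


def _merge_groups(counts, s_i, s_j, s_ij, min_group):
    """Merge adjacent nonempty score groups until each has >= min_group members.

    Scans from the low-score extreme upward, pooling adjacent levels until the
    running group reaches ``min_group``; a deficient final (high-extreme) group
    is folded back into the previous one, so sparse extremes are absorbed
    inward.  Returns a list of (count, sum_i, sum_j, sum_ij) tuples.
    """
    groups = []
    cm = ci = cj = cij = 0.0
    for m, a, b, ab in zip(counts, s_i, s_j, s_ij):
        if m == 0:
            continue
        cm += m
        ci += a
        cj += b
        cij += ab
        if cm >= min_group:
            groups.append((cm, ci, cj, cij))
            cm = ci = cj = cij = 0.0
    if cm > 0:
        if groups:
            lm, li, lj, lij = groups[-1]
            groups[-1] = (lm + cm, li + ci, lj + cj, lij + cij)
        else:
            groups.append((cm, ci, cj, cij))
    return groups


def _weighted_ccov(counts, s_i, s_j, s_ij, min_group):
    """Group-size-weighted average of within-group ML covariances.

    The maximum-likelihood (denominator m) covariance of 0/1 scores is
    bounded by +/-0.25 per group, so the weighted average inherits the bound.
    """
    groups = _merge_groups(counts, s_i, s_j, s_ij, min_group)
    n_total = sum(g[0] for g in groups)
    acc = 0.0
    for m, a, b, ab in groups:
        acc += ab - a * b / m  # = m * (E[xy] - E[x]E[y])
    return acc / n_total


def ccov_pair(X, i: int, j: int, min_group: int = 20, conditioning: str = "both") -> float:
    """Conditional-covariance estimate for one item pair.

    Plain reference implementation: groups examinees by the conditioning
    score, merges sparse adjacent groups, and averages within-group sample
    covariances weighted by group size.  ``conditioning`` selects the
    rest-score estimator, the total-score estimator, or their mean (default).
    """
    if conditioning not in CONDITIONING_MODES:
        raise ValueError(f"conditioning must be one of {CONDITIONING_MODES}")
    scores = _as_score_array(X).astype(np.int64)
    if scores.shape[0] < 2 * min_group:
        raise ValueError("need at least 2*min_group examinees")
    deg = degenerate_items(scores[:, [i, j]])
    if deg.size:
        raise DegenerateItemError([(i, j)[k] for k in deg])
    xi = scores[:, i]
    xj = scores[:, j]

    def estimate(cond_score):
        est = 0.0
        levels = np.arange(cond_score.min(), cond_score.max() + 1)
        counts, si, sj, sij = [], [], [], []
        for s in levels:
            mask = cond_score == s
            counts.append(int(mask.sum()))
            si.append(int(xi[mask].sum()))
            sj.append(int(xj[mask].sum()))
            sij.append(int((xi[mask] * xj[mask]).sum()))
        est = _weighted_ccov(counts, si, sj, sij, min_group)
        return est

    parts = []
    if conditioning in ("both", "rest"):
        parts.append(estimate(rest_score(scores, i, j)))
    if conditioning in ("both", "total"):
        parts.append(estimate(scores.sum(axis=1)))
    return float(np.mean(parts))


def ccov_matrix(X, min_group: int = 20, conditioning: str = "both") -> np.ndarray:
    """Symmetric matrix of conditional covariances for all item pairs.

    Vectorized over pairs: responses are tabulated once per total-score level
    (joint counts of (Xi, Xj) per level via one Gram product per level), the
    pairwise rest-score margins are recovered by shifting the total-score
    axis (rest = total - Xi - Xj), and the same merge-and-weight rule as
    :func:`ccov_pair` is applied per pair.  The diagonal is set to NaN; it is
    never used by the DETECT index.
    """
    if conditioning not in CONDITIONING_MODES:
        raise ValueError(f"conditioning must be one of {CONDITIONING_MODES}")
    scores = _as_score_array(X).astype(np.float64)
    n_exam, n_items = scores.shape
    if n_items < 3:
        raise ValueError("need at least 3 items")
    if n_exam < 2 * min_group:
        raise ValueError("need at least 2*min_group examinees")
    deg = degenerate_items(scores)
    if deg.size:
        raise DegenerateItemError(deg)

    total = scores.sum(axis=1).astype(np.int64)
    n_levels = n_items + 1  # total score in 0..n_items

    # Per total-level joint tabulation: m_t, per-item correct counts, pairwise
    # both-correct counts.
    m_t = np.bincount(total, minlength=n_levels).astype(np.float64)
    n1 = np.zeros((n_levels, n_items))
    n11 = np.zeros((n_levels, n_items, n_items))
    for t in np.flatnonzero(m_t):
        Xt = scores[total == t]
        n1[t] = Xt.sum(axis=0)
        n11[t] = Xt.T @ Xt

    iu, ju = np.triu_indices(n_items, k=1)
    n_pairs = iu.size
    n11_p = n11[:, iu, ju]  # (levels, pairs)
    n1i = n1[:, iu]
    n1j = n1[:, ju]

    values = np.full((n_items, n_items), np.nan)
    acc = np.zeros(n_pairs)
    n_modes = 0

    if conditioning in ("both", "rest"):
        # rest score s = t - xi - xj, s in 0..n_items-2; margins per s level
        # come from total levels s (both wrong), s+1 (one right), s+2 (both).
        n_s = n_items - 1
        n10_p = n1i - n11_p
        n01_p = n1j - n11_p
        n00_p = m_t[:, None] - n1i - n1j + n11_p
        one_right = n10_p[1 : n_s + 1]  # rest level s <- total level s+1
        both_right = n11_p[2 : n_s + 2]  # rest level s <- total level s+2
        m_s = n00_p[:n_s] + one_right + n01_p[1 : n_s + 1] + both_right
        si_s = one_right + both_right
        sj_s = n01_p[1 : n_s + 1] + both_right
        sij_s = both_right.copy()
        cols = (m_s.T, si_s.T, sj_s.T, sij_s.T)
        for p in range(n_pairs):
            acc[p] += _weighted_ccov(
                cols[0][p], cols[1][p], cols[2][p], cols[3][p], min_group
            )
        n_modes += 1

    if conditioning in ("both", "total"):
        cols = (
            np.broadcast_to(m_t[:, None], (n_levels, n_pairs)).T,
            n1i.T,
            n1j.T,
            n11_p.T,
        )
        for p in range(n_pairs):
            acc[p] += _weighted_ccov(
                cols[0][p], cols[1][p], cols[2][p], cols[3][p], min_group
            )
        n_modes += 1

    acc /= n_modes
    values[iu, ju] = acc
    values[ju, iu] = acc
    return values


def write_ccov_csv(values: np.ndarray, path, item_ids=None) -> None:
    """Dump a conditional-covariance matrix as CSV for inspection."""
    import pandas as pd

    n = values.shape[0]
    ids = list(item_ids) if item_ids is not None else [f"item{k + 1}" for k in range(n)]
    pd.DataFrame(values, index=ids, columns=ids).to_csv(path)
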