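"""Statistical primitives for the calling pipeline.

Implements the two-sample t statistic (pooled-variance by default, Welch
selectable), the Westfall–Young free step-down maxT permutation
adjustment, Benjamini–Hochberg FDR, the exact upper-tail hypergeometric
probability, and Pearson correlation.

The permutation machinery is two-sided throughout (|t|): both gains and
losses of methylation are reported downstream, so no direction is
privileged.  Zero-variance features with equal group means get t = 0
(uninformative); zero variance with unequal means is guarded to a large
finite sentinel whose significance is then settled by the permutation
distribution, never by a t reference distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats as sps

__all__ = [
    "T_SENTINEL",
    "InsufficientReplicationError",
    "UndefinedCorrelationError",
    "PermTestResult",
    "EnrichmentResult",
    "ConcordanceResult",
    "t_statistic",
    "maxt_stepdown",
    "bh_fdr",
    "hypergeom_tail",
    "pearson",
]

#: replaces an infinite t (zero within-group variance, unequal means)
T_SENTINEL = 1e12

_PERM_CHUNK = 4096  # permutation columns processed at once (memory bound)


class InsufficientReplicationError(ValueError):
    """A group has fewer than 2 usable values for the chosen t variant."""


class UndefinedCorrelationError(ValueError):
    """Pearson r undefined (zero variance in one of the vectors)."""


@dataclass
class PermTestResult:
    """Per-feature permutation test summary.

    ``p_adj`` is the free step-down maxT family-wise adjusted p-value;
    ``p_raw`` the unadjusted permutation p.  Both use the add-one
    estimator when permutations are sampled, and plain proportions
    (identity relabelling included) when the enumeration is exhaustive,
    so both are always > 0.
    """

    feature_ids: np.ndarray
    t_obs: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_perm: int
    exhaustive: bool
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_obs": self.t_obs, "p_raw": self.p_raw, "p_adj": self.p_adj},
            index=self.feature_ids,
        )


@dataclass
class EnrichmentResult:
    """2x2 hypergeometric summary for one category.

    k of n list genes fall in the category, against K of N background
    genes; ``p_hyper`` is the exact upper tail P(X >= k).
    """

    category: str
    k: int
    n: int
    K: int
    N: int
    p_hyper: float

    @property
    def list_fraction(self) -> float:
        return self.k / self.n if self.n else float("nan")

    @property
    def background_fraction(self) -> float:
        return self.K / self.N if self.N else float("nan")


@dataclass
class ConcordanceResult:
    r: float
    p: float
    n_pairs: int


# ---------------------------------------------------------------------------
# t statistic
# ---------------------------------------------------------------------------

def _t_two_group(X: np.ndarray, masks: np.ndarray, variant: str = "pooled") -> np.ndarray:
    """t statistics for every feature (rows of X) under every grouping.

    Parameters
    ----------
    X
        features x samples, NaN allowed (excluded per feature).
    masks
        B x samples boolean matrix; True marks membership of group A.

    Returns
    -------
    ndarray of shape (features, B); t = mean(A) - mean(B) scaled.
    Features where either group has < 2 usable values get t = 0.
    """
    V = np.isfinite(X)
    X0 = np.where(V, X, 0.0)
    X2 = X0 * X0
    Vf = V.astype(float)
    MA = masks.T.astype(float)
    MB = (~masks).T.astype(float)
    nA = Vf @ MA
    nB = Vf @ MB
    sA = X0 @ MA
    sB = X0 @ MB
    qA = X2 @ MA
    qB = X2 @ MB
    with np.errstate(divide="ignore", invalid="ignore"):
        mA = sA / nA
        mB = sB / nB
        ssA = np.maximum(qA - nA * mA * mA, 0.0)
        ssB = np.maximum(qB - nB * mB * mB, 0.0)
        if variant == "pooled":
            se2 = (ssA + ssB) / (nA + nB - 2.0) * (1.0 / nA + 1.0 / nB)
        elif variant == "welch":
            se2 = ssA / (nA * (nA - 1.0)) + ssB / (nB * (nB - 1.0))
        else:
            raise ValueError(f"unknown t variant {variant!r}")
        diff = mA - mB
        t = diff / np.sqrt(se2)
    valid = (nA >= 2) & (nB >= 2)
    # zero standard error: sentinel if the means still differ, else 0
    bad = ~np.isfinite(t)
    t = np.where(bad, np.where(np.abs(diff) > 0, np.sign(diff) * T_SENTINEL, 0.0), t)
    return np.where(valid, t, 0.0)


def t_statistic(group_a, group_b, variant: str = "pooled") -> float:
    """Unpaired two-sample t statistic, ``mean(a) - mean(b)`` scaled.

    Pooled-variance by default; ``variant="welch"`` for unequal
    variances. NaNs are dropped; fewer than 2 values on either side
    raises :class:`InsufficientReplicationError`.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError(
            f"need >=2 values per group, got {len(a)} and {len(b)}"
        )
    X = np.concatenate([a, b])[None, :]
    mask = np.zeros((1, len(a) + len(b)), dtype=bool)
    mask[0, : len(a)] = True
    return float(_t_two_group(X, mask, variant)[0, 0])


# ---------------------------------------------------------------------------
# Westfall-Young free step-down maxT
# ---------------------------------------------------------------------------

def _exhaustive_masks(n: int, k: int):
    for combo in itertools.combinations(range(n), k):
        yield combo


def maxt_stepdown(
    X,
    labels,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive_limit: int = 20000,
    variant: str = "pooled",
    feature_ids=None,
) -> PermTestResult:
    """Free step-down maxT adjusted permutation p-values.

    If the number of distinct two-group relabellings C(n, n_A) is at
    most ``exhaustive_limit`` all are enumerated (the identity is one of
    them, so p >= 1/B); otherwise ``n_perm`` random relabellings are
    drawn and the add-one estimator p = (1 + #{>=}) / (1 + B) is used.

    Step-down construction: features are ordered by decreasing |t_obs|;
    within each permutation the successive maxima of |t| over the
    current feature and all less significant ones are compared with the
    observed values, and monotonicity is enforced by a running maximum
    down the ordering.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    m, n = X.shape
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length does not match number of samples")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    mask_obs = labels == uniq[0]
    ka = int(mask_obs.sum())
    if ka == 0 or ka == n:
        raise ValueError("degenerate labels: one group is empty")
    if feature_ids is None:
        feature_ids = np.arange(m)
    feature_ids = np.asarray(feature_ids)

    total = math.comb(n, ka)
    exhaustive = total <= exhaustive_limit
    if exhaustive:
        B = total

        def mask_iter():
            buf = []
            for combo in _exhaustive_masks(n, ka):
                row = np.zeros(n, dtype=bool)
                row[list(combo)] = True
                buf.append(row)
                if len(buf) == _PERM_CHUNK:
                    yield buf
                    buf = []
            if buf:
                yield buf
    else:
        B = int(n_perm)
        if B < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)

        def mask_iter():
            done = 0
            while done < B:
                size = min(_PERM_CHUNK, B - done)
                # ka smallest entries of a uniform row = a uniform random subset
                picks = np.argsort(rng.random((size, n)), axis=1)[:, :ka]
                masks = np.zeros((size, n), dtype=bool)
                np.put_along_axis(masks, picks, True, axis=1)
                done += size
                yield [masks[i] for i in range(size)]

    t_obs = _t_two_group(X, mask_obs[None, :], variant)[:, 0]
    a_obs = np.abs(t_obs)
    order = np.argsort(-a_obs, kind="mergesort")
    # ties within float noise count as >= : keeps exact permutation
    # symmetries (label swap, complements) intact across BLAS paths
    thr = a_obs - 1e-9 * (1.0 + a_obs)
    thr_sorted = thr[order]

    raw_count = np.zeros(m, dtype=np.int64)
    adj_count = np.zeros(m, dtype=np.int64)
    for buf in mask_iter():
        masks = np.stack(buf)
        T = np.abs(_t_two_group(X, masks, variant))
        raw_count += (T >= thr[:, None]).sum(axis=1)
        A = T[order]
        U = np.maximum.accumulate(A[::-1], axis=0)[::-1]
        adj_count += (U >= thr_sorted[:, None]).sum(axis=1)

    if exhaustive:
        p_raw = raw_count / B
        p_sorted = adj_count / B
    else:
        p_raw = (1.0 + raw_count) / (1.0 + B)
        p_sorted = (1.0 + adj_count) / (1.0 + B)
    p_sorted = np.maximum.accumulate(p_sorted)
    p_adj = np.empty(m, dtype=float)
    p_adj[order] = p_sorted
    p_adj = np.maximum(p_adj, p_raw)
    return PermTestResult(
        feature_ids=feature_ids,
        t_obs=t_obs,
        p_raw=p_raw,
        p_adj=p_adj,
        n_perm=B,
        exhaustive=exhaustive,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j, clipped to 1; stable under ties.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    m = len(p)
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------

def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    k successes in a list of n, against K successes among N background
    items.  The tail is summed over the attainable support
    max(k, n+K-N) ... min(n, K).
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if n > N or K > N or k > min(n, K):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    lo = max(k, n + K - N)
    hi = min(n, K)
    if lo <= max(0, n + K - N):
        return 1.0
    j = np.arange(lo, hi + 1)
    log_pmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, math.exp(logsumexp(log_pmf))))


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> ConcordanceResult:
    """Product-moment correlation with the t-based two-sided p-value.

    NaN pairs are dropped; fewer than 3 complete pairs or zero variance
    raise dedicated errors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientReplicationError(f"need >=3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return ConcordanceResult(r=float(r), p=float(p), n_pairs=int(len(x)))
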