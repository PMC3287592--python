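"""Undersampling strategies for the majority (negative) class.

TIS candidate sets are heavily imbalanced: one positive per molecule against
dozens of negatives.  Training an SVM on the raw set yields a classifier with
excellent specificity and useless sensitivity, so the training folds are
balanced by discarding majority-class samples:

* **random** — uniform draw without replacement down to ``m`` times the
  minority size.
* **SBC** (sampling based on clustering) — k-means over *both* classes with a
  small fixed k; each cluster contributes majority samples in proportion to
  its majority/minority ratio, so clusters that "behave like" the majority
  class contribute more.
* **M-Clus** — k-means over the majority class only, with as many clusters as
  (a fraction of) the minority size; each cluster contributes the member(s)
  nearest its centroid, giving a spread of representatives across majority-
  class structure.

All methods return indices into the majority array: they select existing
samples and never synthesise or duplicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

METHODS = ("none", "random", "sbc", "mclus")


@dataclass(frozen=True)
class BalancerSpec:
    """Which balancing method to apply, and its parameters.

    ``m`` is the target majority:minority ratio after balancing (1 gives a
    1:1 training set).  ``sbc_k`` is SBC's fixed cluster count.
    ``mclus_take`` (s) is the number of sequences taken per M-Clus cluster;
    the cluster count is ceil(minority/s), so s=1 uses one cluster per
    minority sample, s=2 half as many, s=3 a third.
    """

    method: str = "mclus"
    m: float = 1.0
    sbc_k: int = 4
    mclus_take: int = 1
    seed: int = 0
    sbc_selection: str = "random"  # or "centroid"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown balancing method {self.method!r}")
        if self.m <= 0:
            raise ValueError("ratio m must be positive")
        if self.sbc_k < 1:
            raise ValueError("sbc_k must be >= 1")
        if self.mclus_take not in (1, 2, 3):
            raise ValueError("mclus_take must be 1, 2 or 3")
        if self.sbc_selection not in ("random", "centroid"):
            raise ValueError(f"unknown sbc_selection {self.sbc_selection!r}")


def _target_size(n_majority: int, minority_count: int, m: float) -> int:
    return min(n_majority, int(round(m * minority_count)))


def largest_remainder(raw: np.ndarray, total: int, caps: np.ndarray) -> np.ndarray:
    """Apportion non-negative real quotas to integers summing to `total`.

    ``raw`` is expected to sum to `total` (the proportional-quota formula
    guarantees this); floors then never exceed the target.  Floors are
    assigned first, then remaining units go to the largest
    fractional remainders (ties broken by input order).  Per-entry ``caps``
    are respected, with any capped shortfall redistributed by the same rule;
    if the caps sum to less than `total`, every entry is filled to its cap.
    """
    raw = np.asarray(raw, dtype=float)
    caps = np.asarray(caps, dtype=int)
    if total >= caps.sum():
        return caps.copy()
    alloc = np.minimum(np.floor(raw).astype(int), caps)
    remainders = raw - np.floor(raw)
    while alloc.sum() < total:
        spare = alloc < caps
        if not spare.any():  # pragma: no cover - guarded by cap-sum check
            break
        order = sorted(
            np.nonzero(spare)[0], key=lambda i: (-remainders[i], i)
        )
        for i in order:
            if alloc.sum() >= total:
                break
            alloc[i] += 1
            remainders[i] = 0.0  # a remainder is spent once; further units round-robin
    return alloc


def random_undersample(
    n_majority: int, minority_count: int, spec: BalancerSpec
) -> np.ndarray:
    """Uniform draw without replacement; returns sorted majority indices."""
    if n_majority < 1 or minority_count < 1:
        raise ValueError("both classes must be non-empty")
    target = _target_size(n_majority, minority_count, spec.m)
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(n_majority, size=target, replace=False)
    return np.sort(idx)


def sbc_undersample(
    X_majority: np.ndarray, X_minority: np.ndarray, spec: BalancerSpec
) -> np.ndarray:
    """SBC selection: cluster both classes, take per-cluster quotas.

    The per-cluster quota is
    ``(m * Size_MI) * (Size_MA_i / Size_MI_i) / sum_j (Size_MA_j / Size_MI_j)``,
    apportioned to integers by largest remainder.  Clusters without minority
    members use a minority count of 1 in the ratio (the convention of the
    method's authors); quotas are capped at the cluster's majority count with
    the shortfall redistributed.
    """
    X_majority = np.asarray(X_majority, dtype=float)
    X_minority = np.asarray(X_minority, dtype=float)
    n_ma, n_mi = len(X_majority), len(X_minority)
    if n_ma == 0:
        raise ValueError("nothing to select: no majority samples")
    if n_mi == 0:
        raise ValueError("no minority samples")
    X = np.vstack([X_majority, X_minority])
    k = min(spec.sbc_k, len(X))
    km = KMeans(n_clusters=k, n_init=10, random_state=spec.seed)
    assign = km.fit_predict(X)
    maj_assign, min_assign = assign[:n_ma], assign[n_ma:]

    size_ma = np.array([(maj_assign == i).sum() for i in range(k)])
    size_mi = np.array([(min_assign == i).sum() for i in range(k)])
    size_mi_eff = np.where(size_mi == 0, 1, size_mi)
    if (size_mi == 0).any():
        logger.info("SBC: %d cluster(s) without minority members; using Size_MI_i=1",
                    int((size_mi == 0).sum()))
    ratios = size_ma / size_mi_eff
    total = _target_size(n_ma, n_mi, spec.m)
    if ratios.sum() == 0:
        raise ValueError("nothing to select: all clusters empty of majority")
    raw = total * ratios / ratios.sum()
    quotas = largest_remainder(raw, total, caps=size_ma)

    rng = np.random.default_rng(spec.seed)
    selected: list[np.ndarray] = []
    for i in range(k):
        members = np.nonzero(maj_assign == i)[0]
        if quotas[i] == 0 or len(members) == 0:
            continue
        if spec.sbc_selection == "random":
            pick = rng.choice(members, size=quotas[i], replace=False)
        else:  # nearest to centroid
            d = np.linalg.norm(X_majority[members] - km.cluster_centers_[i], axis=1)
            order = np.lexsort((members, d))
            pick = members[order[: quotas[i]]]
        selected.append(pick)
    return np.sort(np.concatenate(selected))


def sbc_quotas(
    size_ma: np.ndarray, size_mi: np.ndarray, m: float = 1.0
) -> np.ndarray:
    """Integer per-cluster majority quotas from cluster class counts alone.

    Exposed separately so the quota arithmetic can be audited without running
    k-means.
    """
    size_ma = np.asarray(size_ma, dtype=int)
    size_mi = np.asarray(size_mi, dtype=int)
    size_mi_eff = np.where(size_mi == 0, 1, size_mi)
    ratios = size_ma / size_mi_eff
    total = _target_size(int(size_ma.sum()), int(size_mi.sum()), m)
    raw = total * ratios / ratios.sum()
    return largest_remainder(raw, total, caps=size_ma)


def mclus_undersample(
    X_majority: np.ndarray, minority_count: int, spec: BalancerSpec
) -> np.ndarray:
    """M-Clus selection: cluster the majority, take nearest-to-centroid.

    k-means with k = ceil(minority_count / s) runs over the majority class
    only (Euclidean distance on the encoded vectors); each cluster contributes
    its s members nearest the final centroid, ties broken by input order.
    Undersized clusters are backfilled — and oversized selections trimmed —
    by global nearest-to-own-centroid rank so the output size is exactly
    ``min(|majority|, m * minority_count)``.
    """
    X_majority = np.asarray(X_majority, dtype=float)
    n_ma = len(X_majority)
    if minority_count < 1:
        raise ValueError("minority_count must be >= 1")
    if n_ma == 0:
        raise ValueError("nothing to select: no majority samples")
    if n_ma < minority_count:
        logger.warning(
            "M-Clus: majority (%d) smaller than minority (%d); taking all",
            n_ma, minority_count,
        )
        return np.arange(n_ma)
    s = spec.mclus_take
    k = min(math.ceil(minority_count / s), n_ma)
    km = KMeans(n_clusters=k, n_init=10, random_state=spec.seed)
    assign = km.fit_predict(X_majority)
    dist = np.linalg.norm(X_majority - km.cluster_centers_[assign], axis=1)
    target = _target_size(n_ma, minority_count, spec.m)

    chosen: list[int] = []
    for i in range(k):
        members = np.nonzero(assign == i)[0]
        if len(members) == 0:
            continue
        order = np.lexsort((members, dist[members]))
        chosen.extend(members[order[:s]].tolist())
    if len(chosen) > target:
        # trim to the globally nearest-to-centroid selections
        chosen.sort(key=lambda i: (dist[i], i))
        chosen = chosen[:target]
    elif len(chosen) < target:
        remaining = sorted(set(range(n_ma)) - set(chosen),
                           key=lambda i: (dist[i], i))
        chosen.extend(remaining[: target - len(chosen)])
    return np.array(sorted(chosen), dtype=int)


def balance(
    X_majority: np.ndarray, X_minority: np.ndarray, spec: BalancerSpec
) -> np.ndarray:
    """Dispatch on ``spec.method``; returns selected majority indices."""
    n_ma = len(X_majority)
    if spec.method == "none":
        return np.arange(n_ma)
    if spec.method == "random":
        return random_undersample(n_ma, len(X_minority), spec)
    if spec.method == "sbc":
        return sbc_undersample(X_majority, X_minority, spec)
    return mclus_undersample(X_majority, len(X_minority), spec)
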