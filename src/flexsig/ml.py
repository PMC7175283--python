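"""Jaccard k-nearest-neighbour activity classification and feature selection.

The classifier measures nearness between binary flexibility-feature rows by
the Jaccard similarity coefficient and predicts by majority vote among the
``k`` most similar training structures (odd ``k`` only).  Feature subsets
are scored by leave-one-out cross-validation (LOOCV) and by out-of-bag
bootstrap resampling, and are searched both greedily (sequential forward /
backward selection, optionally floating) and exhaustively over small
candidate pools.

All subset scoring funnels through one vectorised LOOCV kernel; the
stand-alone :func:`knn_predict` and :func:`jaccard_similarity` provide the
reference semantics (including tie handling) that the kernel reproduces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numba
import numpy as np

from .features import FeatureMatrix, prevalence_profile, select_sensitive_features
from .rigidity import AnalysisConfig

logger = logging.getLogger(__name__)

#: Index bias separating similarity ties in favour of the lower row index.
#: Jaccard values on 87-bit rows are rationals with denominators <= 58*58,
#: so distinct similarities differ by far more than 27 * _TIE_EPS.
_TIE_EPS = 1e-9


def jaccard_similarity(u: Sequence[int], v: Sequence[int]) -> float:
    """Intersection over union of two binary vectors.

    Two all-zero vectors are defined as maximally similar (1.0): identical
    points must be nearest neighbours of each other.  This case can occur
    when rows are restricted to a feature subset.
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    union = np.logical_or(u, v).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(u, v).sum() / union)


def knn_predict(train: np.ndarray, labels: Sequence[int],
                test_row: Sequence[int], k: int = 3) -> int:
    """Majority label among the ``k`` training rows most similar to
    ``test_row`` (Jaccard); ties at the neighbourhood boundary go to the
    lower row index."""
    train = np.asarray(train)
    labels = np.asarray(labels)
    if k % 2 == 0:
        raise ValueError("an odd number of neighbors is required")
    if k > len(train):
        raise ValueError(f"k={k} exceeds {len(train)} training rows")
    sims = np.array([jaccard_similarity(row, test_row) for row in train])
    order = np.argsort(-sims, kind="stable")
    votes = labels[order[:k]].sum()
    return int(votes * 2 > k)


# ---------------------------------------------------------------------------
# Vectorised LOOCV kernel
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _loocv_kernel(X: np.ndarray, y: np.ndarray, subs_flat: np.ndarray,
                  offsets: np.ndarray, k: int, out: np.ndarray) -> None:
    """Exact-arithmetic LOOCV scorer for many column subsets.

    Jaccard similarities are compared as integer cross-products
    (``i_a * u_b > i_b * u_a``), so neighbour order — including the 0/0 -> 1
    convention, represented as 1/1 — is exact; equal similarities keep the
    lower row index because candidates are scanned in ascending order and
    only strictly better ones displace a held neighbour.
    """
    n = X.shape[0]
    inter = np.empty((n, n), dtype=np.int64)
    ones = np.empty(n, dtype=np.int64)
    top_i = np.empty(k, dtype=np.int64)
    top_u = np.empty(k, dtype=np.int64)
    top_j = np.empty(k, dtype=np.int64)
    for t in range(offsets.shape[0] - 1):
        idx = subs_flat[offsets[t]:offsets[t + 1]]
        s = idx.shape[0]
        for i in range(n):
            c = 0
            for q in range(s):
                c += X[i, idx[q]]
            ones[i] = c
        for i in range(n):
            for j in range(i, n):
                c = 0
                for q in range(s):
                    c += X[i, idx[q]] & X[j, idx[q]]
                inter[i, j] = c
                inter[j, i] = c
        out[t] = _loocv_from_inter(inter, ones, y, k, top_i, top_u, top_j)


@numba.njit(cache=True)
def _loocv_from_inter(inter: np.ndarray, ones: np.ndarray, y: np.ndarray,
                      k: int, top_i: np.ndarray, top_u: np.ndarray,
                      top_j: np.ndarray) -> float:
    """LOOCV accuracy given a precomputed pairwise intersection matrix."""
    n = inter.shape[0]
    correct = 0
    for i in range(n):
        for q in range(k):
            top_i[q] = -1
            top_u[q] = 1
            top_j[q] = -1
        worst = 0
        for j in range(n):
            if j == i:
                continue
            itc = inter[i, j]
            union = ones[i] + ones[j] - itc
            if union == 0:
                itc = 1
                union = 1
            if itc * top_u[worst] > top_i[worst] * union:
                top_i[worst] = itc
                top_u[worst] = union
                top_j[worst] = j
                for q in range(k):
                    if top_i[q] * top_u[worst] < top_i[worst] * top_u[q]:
                        worst = q
        votes = 0
        for q in range(k):
            votes += y[top_j[q]]
        pred = 1 if votes * 2 > k else 0
        if pred == y[i]:
            correct += 1
    return 100.0 * correct / n


@numba.njit(cache=True)
def _efs_kernel(X: np.ndarray, y: np.ndarray, max_size: int, k: int,
                accs: np.ndarray, sizes: np.ndarray,
                subs: np.ndarray) -> None:
    """Exhaustive subset enumeration with an incrementally maintained
    intersection matrix.

    Subsets are visited in depth-first lexicographic order (all supersets
    of a prefix before the next sibling); entering/leaving a feature adds/
    subtracts its rank-one contribution to the pairwise intersection
    matrix, so each subset costs one O(n^2) scoring pass instead of an
    O(n^2 s) rebuild.
    """
    n, F = X.shape
    inter = np.zeros((n, n), dtype=np.int64)
    ones = np.zeros(n, dtype=np.int64)
    chosen = np.empty(max_size, dtype=np.int64)
    nxt = np.empty(max_size + 1, dtype=np.int64)
    top_i = np.empty(k, dtype=np.int64)
    top_u = np.empty(k, dtype=np.int64)
    top_j = np.empty(k, dtype=np.int64)
    pos = 0
    depth = 0
    nxt[0] = 0
    while True:
        if depth < max_size and nxt[depth] < F:
            f = nxt[depth]
            for i in range(n):
                xi = X[i, f]
                ones[i] += xi
                if xi:
                    for j in range(n):
                        inter[i, j] += X[j, f]
            chosen[depth] = f
            depth += 1
            nxt[depth] = f + 1
            accs[pos] = _loocv_from_inter(inter, ones, y, k,
                                          top_i, top_u, top_j)
            sizes[pos] = depth
            for q in range(depth):
                subs[pos, q] = chosen[q]
            pos += 1
        else:
            if depth == 0:
                break
            depth -= 1
            g = chosen[depth]
            for i in range(n):
                xi = X[i, g]
                ones[i] -= xi
                if xi:
                    for j in range(n):
                        inter[i, j] -= X[j, g]
            nxt[depth] = g + 1


def _loocv_accuracy_batch(X: np.ndarray, y: np.ndarray,
                          subsets: Sequence[Sequence[int]], k: int,
                          ) -> np.ndarray:
    """LOOCV accuracy (percent) of many column subsets at once."""
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1 rows")
    Xb = np.ascontiguousarray(X.astype(np.int64))
    yb = y.astype(np.int64)
    offsets = np.zeros(len(subsets) + 1, dtype=np.int64)
    for pos, sub in enumerate(subsets):
        offsets[pos + 1] = offsets[pos] + len(sub)
    subs_flat = np.empty(offsets[-1], dtype=np.int64)
    for pos, sub in enumerate(subsets):
        subs_flat[offsets[pos]:offsets[pos + 1]] = sub
    out = np.empty(len(subsets), dtype=np.float64)
    _loocv_kernel(Xb, yb, subs_flat, offsets, k, out)
    return out


def _subset_indices(m: FeatureMatrix, subset: Sequence[str]) -> list[int]:
    try:
        return [m.feature_names.index(f) for f in subset]
    except ValueError as exc:
        raise ValueError(f"unknown feature in subset {list(subset)}") from exc


def loocv_accuracy(m: FeatureMatrix, subset: Sequence[str], k: int = 3) -> float:
    """Leave-one-out accuracy (percent) of the Jaccard KNN on one subset."""
    if k % 2 == 0:
        raise ValueError("an odd number of neighbors is required")
    idx = _subset_indices(m, subset)
    return float(_loocv_accuracy_batch(m.data, m.labels, [idx], k)[0])


def loocv_accuracy_slow(m: FeatureMatrix, subset: Sequence[str], k: int = 3) -> float:
    """Reference LOOCV built from :func:`knn_predict`; used for cross-checks."""
    idx = _subset_indices(m, subset)
    X = m.data[:, idx]
    correct = 0
    for i in range(m.n):
        train = np.delete(X, i, axis=0)
        labels = np.delete(m.labels, i)
        correct += knn_predict(train, labels, X[i], k) == m.labels[i]
    return 100.0 * correct / m.n


def dummy_loocv_accuracy(labels: Sequence[int]) -> float:
    """LOOCV accuracy of a majority-class (dummy) predictor, percent."""
    y = np.asarray(labels)
    correct = 0
    for i in range(len(y)):
        rest = np.delete(y, i)
        majority = 1 if rest.sum() * 2 > len(rest) else 0
        correct += majority == y[i]
    return 100.0 * correct / len(y)


def bootstrap_accuracy(m: FeatureMatrix, subset: Sequence[str] | None, k: int = 3,
                       config: AnalysisConfig | None = None,
                       ) -> tuple[float, float]:
    """Out-of-bag bootstrap accuracy of a feature subset (or of the dummy
    majority predictor when ``subset`` is None).

    Each iteration draws ``n`` training rows with replacement; rows never
    drawn form the test set.  Iterations with an empty out-of-bag set or a
    single-class training sample are skipped.  Returns the mean and the
    sample standard deviation of the per-iteration accuracies, both in
    percent — the spread, not the standard error of the mean.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.rng_seed)
    n = m.n
    y = m.labels.astype(np.int64)
    if subset is not None:
        idx = _subset_indices(m, subset)
        X = m.data[:, idx].astype(np.float64)
        inter = X @ X.T
        ones = X.sum(axis=1)
        union = ones[:, None] + ones[None, :] - inter
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(union == 0, 1.0, inter / np.maximum(union, 1e-300))
    accs: list[float] = []
    for _ in range(config.bootstrap_iters):
        train = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[train] = True
        oob = np.nonzero(~in_bag)[0]
        if oob.size == 0:
            continue
        y_train = y[train]
        if y_train.min() == y_train.max():
            continue
        if subset is None:
            majority = 1 if y_train.sum() * 2 > n else 0
            acc = 100.0 * float((y[oob] == majority).mean())
        else:
            keys = S[np.ix_(oob, train)] - np.arange(n) * _TIE_EPS
            votes = np.zeros(oob.size, dtype=np.int64)
            for _ in range(k):
                j = keys.argmax(axis=1)
                votes += y_train[j]
                np.put_along_axis(keys, j[:, None], -np.inf, axis=1)
            pred = (votes * 2 > k).astype(np.int64)
            acc = 100.0 * float((pred == y[oob]).mean())
        accs.append(acc)
    arr = np.array(accs)
    return float(arr.mean()), float(arr.std(ddof=1))


# ---------------------------------------------------------------------------
# Subset search
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Evaluation of one feature subset."""

    subset: tuple[str, ...]
    loocv_accuracy: float
    bootstrap_mean: float | None = None
    bootstrap_se: float | None = None
    k: int = 3

    def __post_init__(self) -> None:
        if len(set(self.subset)) != len(self.subset) or not self.subset:
            raise ValueError("subset must be non-empty without duplicates")


def _eval_many(m: FeatureMatrix, subsets_idx: Sequence[Sequence[int]],
               k: int) -> np.ndarray:
    return _loocv_accuracy_batch(m.data, m.labels, subsets_idx, k)


@dataclass
class SFSTrajectory:
    """Record of a sequential-selection run: the final set plus the best set
    observed at every visited size."""

    final: list[str]
    best_by_size: dict[int, tuple[float, tuple[str, ...]]]  # size -> (acc, names)

    def best_subset(self, max_size: int | None = None) -> tuple[str, ...]:
        """The best-predictor subset of the run (ties: smaller, then
        lexicographic), optionally restricted to ``max_size``."""
        items = [(acc, size, sub) for size, (acc, sub)
                 in self.best_by_size.items()
                 if max_size is None or size <= max_size]
        if not items:
            raise ValueError("no recorded subset within the size limit")
        acc, size, sub = max(items, key=lambda t: (t[0], -t[1],
                                                   _neg_names(t[2])))
        return sub


def _neg_names(names: tuple[str, ...]):
    return tuple(tuple(-ord(c) for c in n) for n in names)


def sfs_trajectory(m: FeatureMatrix, k: int = 3,
                   mode: Literal["forward", "backward"] = "forward",
                   floating: bool = False, target_size: int = 8,
                   candidate_features: Sequence[str] | None = None,
                   ) -> SFSTrajectory:
    """Sequential feature selection maximising LOOCV accuracy.

    Forward mode grows from the empty set, adding the single feature whose
    addition yields the highest accuracy; backward mode shrinks from the
    full set, removing the feature whose removal loses least accuracy.
    Floating variants may undo earlier moves, but only on a strict accuracy
    improvement over the best set previously recorded at that size.  All
    ties are broken by feature-name lexicographic order.
    """
    names = list(candidate_features if candidate_features is not None
                 else m.feature_names)
    d = len(names)
    if target_size >= d:
        raise ValueError(f"target_size={target_size} must be below the"
                         f" {d} available features")
    cols = _subset_indices(m, names)

    def acc_of(sets: list[list[int]]) -> np.ndarray:
        return _eval_many(m, [[cols[i] for i in s] for s in sets], k)

    def best_move(current: list[int], additions: Iterable[int] | None,
                  removals: Iterable[int] | None) -> tuple[list[int], float]:
        """Evaluate all one-step moves; return the best (set, accuracy)."""
        moves: list[tuple[list[int], int]] = []
        if additions is not None:
            for f in additions:
                moves.append((current + [f], f))
        if removals is not None:
            for f in removals:
                moves.append(([g for g in current if g != f], f))
        accs = acc_of([mv for mv, _ in moves])
        best = min(range(len(moves)),
                   key=lambda i: (-accs[i], names[moves[i][1]]))
        return moves[best][0], float(accs[best])

    best_for_size: dict[int, tuple[float, tuple[str, ...]]] = {}

    def record(current: list[int], acc: float) -> None:
        sub = tuple(sorted(names[i] for i in current))
        prev = best_for_size.get(len(current))
        if prev is None or acc > prev[0]:
            best_for_size[len(current)] = (acc, sub)

    if mode == "forward":
        current: list[int] = []
        while len(current) < target_size:
            remaining = [i for i in range(d) if i not in current]
            current, acc = best_move(current, remaining, None)
            record(current, acc)
            while floating and len(current) > 2:
                cand, acc_r = best_move(current, None, list(current))
                if acc_r > best_for_size.get(len(cand), (-1.0,))[0]:
                    current = cand
                    record(current, acc_r)
                else:
                    break
    elif mode == "backward":
        current = list(range(d))
        while len(current) > target_size:
            current, acc = best_move(current, None, list(current))
            record(current, acc)
            while floating and len(current) < d - 1:
                out = [i for i in range(d) if i not in current]
                cand, acc_a = best_move(current, out, None)
                if acc_a > best_for_size.get(len(cand), (-1.0,))[0]:
                    current = cand
                    record(current, acc_a)
                else:
                    break
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SFSTrajectory(final=[names[i] for i in current],
                         best_by_size=best_for_size)


def sfs_select(m: FeatureMatrix, k: int = 3,
               mode: Literal["forward", "backward"] = "forward",
               floating: bool = False, target_size: int = 8,
               candidate_features: Sequence[str] | None = None,
               ) -> list[str]:
    """The feature subset of the requested size found by sequential
    selection (see :func:`sfs_trajectory`)."""
    return sfs_trajectory(m, k, mode, floating, target_size,
                          candidate_features).final


def _count_subsets(n_candidates: int, max_size: int) -> int:
    return sum(math.comb(n_candidates, j)
               for j in range(1, min(max_size, n_candidates) + 1))


def efs_select(m: FeatureMatrix, candidate_features: Sequence[str],
               k: int = 3, config: AnalysisConfig | None = None,
               limit: int | None = None) -> list[EvalResult]:
    """Exhaustive evaluation of every candidate subset of size 1 to
    ``max_subset_size``, ranked by LOOCV accuracy (descending), then subset
    size (ascending), then lexicographic feature names.

    ``limit`` truncates the returned ranking (the full search always runs).
    """
    config = config or AnalysisConfig()
    names = sorted(dict.fromkeys(candidate_features))
    total = _count_subsets(len(names), config.max_subset_size)
    if total > config.efs_guard:
        raise ValueError(
            f"{total} candidate subsets exceed the exhaustive-search guard of"
            f" {config.efs_guard}; pre-filter the candidates with sequential"
            " selection first")
    cols = _subset_indices(m, names)
    max_size = min(config.max_subset_size, len(names))
    Xc = np.ascontiguousarray(m.data[:, cols].astype(np.int64))
    yb = m.labels.astype(np.int64)
    accs = np.empty(total, dtype=np.float64)
    sizes = np.empty(total, dtype=np.int64)
    subs = np.full((total, max_size), -1, dtype=np.int64)
    _efs_kernel(Xc, yb, max_size, k, accs, sizes, subs)
    # rank: accuracy desc, size asc, lexicographic; the DFS emits subsets of
    # equal size in lexicographic order, so its position is the final key
    order = np.lexsort((np.arange(total), sizes, -accs))
    if limit is not None:
        order = order[:limit]
    return [EvalResult(subset=tuple(names[j] for j in subs[i, :sizes[i]]),
                       loocv_accuracy=float(accs[i]), k=k)
            for i in order]


def mcc_matrix(m: FeatureMatrix, subset: Sequence[str]) -> np.ndarray:
    """Pairwise Matthews correlation coefficients between binary feature
    columns (diagonal 1; undefined denominators mapped to 0)."""
    X = m.columns(subset).astype(np.int64)
    p = len(subset)
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            x, y = X[:, i], X[:, j]
            tp = int(np.sum((x == 1) & (y == 1)))
            tn = int(np.sum((x == 0) & (y == 0)))
            fp = int(np.sum((x == 1) & (y == 0)))
            fn = int(np.sum((x == 0) & (y == 1)))
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            val = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
            out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# Full discovery pipeline
# ---------------------------------------------------------------------------


@dataclass
class DiscoveryResult:
    sensitive_features: list[str]
    sfs_selections: dict[str, list[str]]
    candidates: list[str]
    ranked: list[EvalResult]          # every exhaustive subset, best first
    top: list[EvalResult]             # best subsets with bootstrap statistics
    dummy: EvalResult
    chosen_signature: tuple[str, ...]


def run_signature_discovery(m: FeatureMatrix,
                            config: AnalysisConfig | None = None,
                            with_bootstrap: bool = True,
                            top_n: int = 5) -> DiscoveryResult:
    """Sensitive-feature filter + sequential selections + exhaustive search.

    The exhaustive-search candidate pool is the union of the
    prevalence-sensitive features and the best-predictor subsets of the
    forward, backward, and floating sequential runs (restricted to the
    exhaustive size ceiling).  The chosen signature is the top-ranked
    subset; bootstrap statistics are attached to the ``top_n`` best subsets
    and a majority-class dummy baseline is reported alongside.
    """
    config = config or AnalysisConfig()
    k = config.k_neighbors
    profile = prevalence_profile(m)
    sensitive = select_sensitive_features(profile, config)
    trajectories = {
        "forward": sfs_trajectory(m, k, "forward", False,
                                  config.sfs_target_size),
        "backward": sfs_trajectory(m, k, "backward", False,
                                   config.sfs_target_size),
        "forward_floating": sfs_trajectory(m, k, "forward", True,
                                           config.sfs_target_size),
        "backward_floating": sfs_trajectory(m, k, "backward", True,
                                            config.sfs_target_size),
    }
    sfs_runs = {name: list(t.best_subset(config.max_subset_size))
                for name, t in trajectories.items()}
    candidates = sorted(set(sensitive).union(*sfs_runs.values()))
    # The sequential stage is the pre-filter: if the pooled candidates would
    # overflow the exhaustive-search guard, trim lowest-priority features
    # (weakest sensitive features last to go are the SFS picks) until the
    # enumeration fits.
    max_pool = len(candidates)
    while _count_subsets(max_pool, config.max_subset_size) > config.efs_guard:
        max_pool -= 1
    if max_pool < len(candidates):
        priority: list[str] = []
        for runs in sfs_runs.values():
            priority.extend(f for f in runs if f not in priority)
        priority.extend(f for f in sensitive if f not in priority)
        kept = set(priority[:max_pool])
        logger.warning("exhaustive-search pool trimmed from %d to %d"
                       " candidates", len(candidates), max_pool)
        candidates = sorted(kept)
    ranked = efs_select(m, candidates, k, config, limit=max(top_n, 50))
    top: list[EvalResult] = []
    for res in ranked[:top_n]:
        if with_bootstrap:
            mean, se = bootstrap_accuracy(m, res.subset, k, config)
            res = EvalResult(res.subset, res.loocv_accuracy, mean, se, k)
        top.append(res)
    d_mean, d_se = (bootstrap_accuracy(m, None, k, config)
                    if with_bootstrap else (None, None))
    dummy = EvalResult(subset=("majority_class",),
                       loocv_accuracy=dummy_loocv_accuracy(m.labels),
                       bootstrap_mean=d_mean, bootstrap_se=d_se, k=k)
    return DiscoveryResult(
        sensitive_features=sensitive,
        sfs_selections=sfs_runs,
        candidates=candidates,
        ranked=ranked,
        top=top,
        dummy=dummy,
        chosen_signature=ranked[0].subset,
    )
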