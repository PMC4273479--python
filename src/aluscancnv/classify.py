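"""CNV-feature selection, classification and clustering.

Given a binary samples × windows CNV matrix and a two-class labeling (e.g.
liver vs non-liver cancers), this module

* selects a distinguishing feature subset by correlation-based feature
  selection (CFS) with best-first search,
* scores the subset by repeated two-fold cross-validated Naïve Bayes,
  reporting mean AUC and the F-score 2TP/(2TP + FP + FN), and
* clusters samples hierarchically (Euclidean distance, Ward's method in its
  unsquared "ward.D" form) with plain bootstrap support on the nodes.

CFS merit of a k-feature subset:

    merit = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

with r̄_cf the mean feature–class and r̄_ff the mean feature–feature
correlation, both measured by symmetrical uncertainty
SU(X, Y) = 2·I(X; Y)/(H(X) + H(Y)) on the binary variables.  The formula
rewards subsets correlated with the class and penalizes internal redundancy.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB

__all__ = [
    "ClassifierReport",
    "cfs_merit",
    "best_first_select",
    "naive_bayes_cv",
    "f_score",
    "hier_cluster",
    "ClusteringResult",
]


@dataclass
class ClassifierReport:
    selected_features: list
    auc: float
    f_score: float
    iterations: int
    folds: int
    seed: int
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


@dataclass
class ClusteringResult:
    linkage: np.ndarray = field(repr=False)   # scipy linkage matrix, ward.D heights
    labels: list[str] = field(default_factory=list)
    support: dict = field(default_factory=dict)  # frozenset(leaf idx) -> bootstrap proportion
    newick: str = ""


# ------------------------------------------------------- symmetrical uncertainty


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) from count arrays along the last axis."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, counts / total, 0.0)
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1)


def symmetrical_uncertainty(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """SU between one binary vector ``x`` and each column of binary ``Y``.

    SU = 2 (H(X) + H(Y) − H(X, Y)) / (H(X) + H(Y)); 0 when either variable
    is constant (no information to share).
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = x.size
    n11 = x @ Y
    n10 = (1 - x) @ Y
    n01 = x @ (1 - Y)
    n00 = (1 - x) @ (1 - Y)
    joint = np.stack([n00, n01, n10, n11], axis=-1)
    hx = _entropy(np.array([n - x.sum(), x.sum()]))
    hy = _entropy(np.stack([n - Y.sum(axis=0), Y.sum(axis=0)], axis=-1))
    hxy = _entropy(joint)
    denom = hx + hy
    with np.errstate(divide="ignore", invalid="ignore"):
        su = np.where(denom > 0, 2.0 * (hx + hy - hxy) / denom, 0.0)
    return np.clip(su, 0.0, 1.0)


def cfs_merit(feature_subset, X: np.ndarray, y: np.ndarray) -> float:
    """CFS merit of a subset of feature column indices of binary matrix X."""
    subset = list(feature_subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    k = len(subset)
    su_fc = symmetrical_uncertainty(np.asarray(y, float), X[:, subset])
    sum_cf = float(su_fc.sum())
    sum_ff = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            sum_ff += float(
                symmetrical_uncertainty(X[:, subset[a]], X[:, subset[b]])[0]
            )
    return sum_cf / np.sqrt(k + 2.0 * sum_ff)


def best_first_select(
    X: np.ndarray, y: np.ndarray, max_stale: int = 5, locally_predictive: bool = True
) -> list[int]:
    """Best-first forward search over feature subsets by CFS merit.

    Maintains a priority queue of frontier subsets; repeatedly expands the
    highest-merit subset by each unused feature, and stops after
    ``max_stale`` consecutive expansions that fail to improve the best merit
    seen.  Deterministic: ties break toward the lower feature index.

    With ``locally_predictive`` (the CfsSubsetEval default convention), a
    post-pass rescues features the redundancy penalty squeezed out: unused
    features are visited in decreasing class-correlation order and added
    whenever their class correlation exceeds their strongest correlation
    with any feature already selected.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    su_fc = symmetrical_uncertainty(y, X)
    usable = np.nonzero(X.std(axis=0) > 0)[0]
    if usable.size == 0:
        raise ValueError("no usable (non-constant) feature")

    su_ff_cache: dict[int, np.ndarray] = {}

    def ff_row(j: int) -> np.ndarray:
        if j not in su_ff_cache:
            su_ff_cache[j] = symmetrical_uncertainty(X[:, j], X)
        return su_ff_cache[j]

    # frontier entries: (-merit, subset tuple, sum_cf, sum_ff)
    frontier: list[tuple[float, tuple[int, ...], float, float]] = [(0.0, (), 0.0, 0.0)]
    visited: set[tuple[int, ...]] = {()}
    best_merit, best_subset = 0.0, ()
    stale = 0
    while frontier and stale < max_stale:
        _, subset, sum_cf, sum_ff = heapq.heappop(frontier)
        in_subset = set(subset)
        cand = np.array([j for j in usable if j not in in_subset], dtype=int)
        if cand.size == 0:
            stale += 1
            continue
        add_ff = np.zeros(cand.size)
        for j in subset:
            add_ff += ff_row(j)[cand]
        k = len(subset) + 1
        merits = (sum_cf + su_fc[cand]) / np.sqrt(k + 2.0 * (sum_ff + add_ff))
        improved = False
        order = np.argsort(-merits, kind="stable")
        for pos in order[: min(len(order), 50)]:  # expand the most promising children
            j = int(cand[pos])
            new = tuple(sorted(subset + (j,)))
            if new in visited:
                continue
            visited.add(new)
            heapq.heappush(
                frontier,
                (-float(merits[pos]), new, sum_cf + float(su_fc[j]), sum_ff + float(add_ff[pos])),
            )
        top = float(merits[order[0]])
        if top > best_merit + 1e-12:
            best_merit = top
            best_subset = tuple(sorted(subset + (int(cand[order[0]]),)))
            improved = True
        stale = 0 if improved else stale + 1

    selected = list(best_subset)
    if locally_predictive and selected:
        order = [j for j in np.argsort(-su_fc, kind="stable") if j in set(usable)]
        for j in order:
            if j in selected or su_fc[j] <= 0:
                continue
            strongest = max(float(ff_row(k)[j]) for k in selected)
            if su_fc[j] > strongest:
                selected.append(int(j))
        selected.sort()
    return selected


def f_score(tp: int, fp: int, fn: int) -> float:
    """F-score = 2TP / (2TP + FP + FN)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise ValueError("F-score undefined when TP = FP = FN = 0")
    return 2.0 * tp / denom


def naive_bayes_cv(
    X: np.ndarray,
    y: np.ndarray,
    features: list[int] | None = None,
    iterations: int = 1000,
    folds: int = 2,
    seed: int = 0,
) -> ClassifierReport:
    """Repeated stratified k-fold Naïve Bayes evaluation of a feature subset.

    Each iteration draws a fresh stratified fold split; every sample is
    scored exactly once per iteration by the model trained on the other
    fold(s).  AUC is computed per iteration from the pooled posterior
    probabilities and averaged; the F-score comes from the confusion counts
    pooled over all iterations (positive class = label 1, posterior 0.5
    decision threshold).
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if features is not None:
        X = X[:, list(features)]
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    aucs = np.empty(iterations)
    tp = fp = fn = tn = 0
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + it) % (2**31 - 1))
        post = np.empty(len(y))
        for train, test in skf.split(X, y):
            clf = BernoulliNB(alpha=1.0)
            clf.fit(X[train], y[train])
            post[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
        aucs[it] = roc_auc_score(y, post)
        pred = (post >= 0.5).astype(int)
        tp += int(((pred == 1) & (y == 1)).sum())
        fp += int(((pred == 1) & (y == 0)).sum())
        fn += int(((pred == 0) & (y == 1)).sum())
        tn += int(((pred == 0) & (y == 0)).sum())
    return ClassifierReport(
        selected_features=list(features) if features is not None else list(range(X.shape[1])),
        auc=float(aucs.mean()),
        f_score=f_score(tp, fp, fn),
        iterations=iterations,
        folds=folds,
        seed=seed,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


# ---------------------------------------------------------------- clustering


def _ward_d_linkage(X: np.ndarray) -> np.ndarray:
    """Ward linkage in the unsquared ("ward.D") convention.

    The Lance-Williams Ward update applied directly to Euclidean distances is
    what R's hclust calls ward.D; feeding sqrt-distances to the squared-form
    implementation and squaring the merge heights reproduces it exactly.
    """
    d = pdist(X, metric="euclidean")
    Z = linkage(np.sqrt(d), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return Z


def _clades(Z: np.ndarray, n: int) -> list[frozenset]:
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


def _to_newick(Z: np.ndarray, labels: list[str], support: dict) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h = int(Z[i - n, 0]), int(Z[i - n, 1]), float(Z[i - n, 2])
        heights[i] = h
        left = node(a)
        right = node(b)
        clade = _clades_cache[i - n]
        sup = support.get(clade)
        lab = "" if sup is None else f"{sup:.3f}"
        bl_a = h - heights[a]
        bl_b = h - heights[b]
        return f"({left}:{bl_a:.6g},{right}:{bl_b:.6g}){lab}"

    _clades_cache = _clades(Z, n)
    return node(2 * n - 2) + ";"


def hier_cluster(
    X: np.ndarray,
    labels: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClusteringResult:
    """Euclidean/ward.D hierarchical clustering with bootstrap node support.

    Support of an internal node is the proportion of ``n_boot`` trees, each
    built from a with-replacement resample of the feature columns, that
    contain the same leaf set (plain bootstrap proportions, not multiscale
    "approximately unbiased" probabilities).
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples to cluster")
    labels = labels if labels is not None else [f"s{i}" for i in range(n)]
    Z = _ward_d_linkage(X)
    target = _clades(Z, n)
    counts = dict.fromkeys(target, 0)
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        Zb = _ward_d_linkage(X[:, cols])
        for clade in _clades(Zb, n):
            if clade in counts:
                counts[clade] += 1
    support = {c: counts[c] / n_boot for c in counts}
    nwk = _to_newick(Z, labels, support)
    return ClusteringResult(linkage=Z, labels=labels, support=support, newick=nwk)
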