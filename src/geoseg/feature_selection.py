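"""Discriminative feature reduction: correlation-based subset selection
(CFS) with best-first search, and PCA projection.

CFS scores a feature subset F by the merit

    merit(F) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where k = |F|, r_cf is the mean feature-class correlation and r_ff the
mean pairwise feature-feature correlation, both measured as symmetric
uncertainty over equal-frequency discretized features.  A good subset is
strongly correlated with the class but internally non-redundant.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["FeatureTable", "SelectionResult", "cfs_select", "pca_reduce"]

N_BINS = 10          # equal-frequency discretization bins
MAX_STALE = 5        # best-first: consecutive non-improving expansions


@dataclass
class FeatureTable:
    """Instances x named features plus nominal class labels."""

    data: pd.DataFrame          # numeric features only
    labels: np.ndarray          # instance class labels (strings or ints)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.data) != len(self.labels):
            raise ValueError("feature matrix and labels disagree in length")
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @classmethod
    def from_dict_rows(cls, rows: Sequence[Dict[str, float]], labels) -> "FeatureTable":
        return cls(pd.DataFrame(list(rows)), np.asarray(labels))

    @property
    def feature_names(self) -> List[str]:
        return list(self.data.columns)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(names)].copy(), self.labels.copy())


@dataclass
class SelectionResult:
    selected: List[str]
    merit_trace: List[Tuple[float, Tuple[str, ...]]] = field(default_factory=list)

    @property
    def merit(self) -> float:
        return self.merit_trace[-1][0] if self.merit_trace else 0.0


def _discretize(col: np.ndarray, bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    if np.all(col == col[0]):
        return np.zeros(len(col), dtype=np.intp)
    edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="right")


def _entropy(codes: np.ndarray) -> float:
    p = np.bincount(codes) / len(codes)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha, hb = _entropy(a), _entropy(b)
    if ha + hb == 0:
        return 0.0
    joint = a.astype(np.int64) * (b.max() + 1) + b
    _, joint = np.unique(joint, return_inverse=True)
    hab = _entropy(joint)
    return 2.0 * (ha + hb - hab) / (ha + hb)


class _CorrelationCache:
    def __init__(self, table: FeatureTable):
        self.names = table.feature_names
        X = table.matrix
        self.codes = [_discretize(X[:, j]) for j in range(X.shape[1])]
        _, y = np.unique(table.labels, return_inverse=True)
        self.y = y.astype(np.intp)
        self._cf: Dict[int, float] = {}
        self._ff: Dict[Tuple[int, int], float] = {}

    def cf(self, j: int) -> float:
        if j not in self._cf:
            self._cf[j] = _symmetric_uncertainty(self.codes[j], self.y)
        return self._cf[j]

    def ff(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self._ff:
            self._ff[key] = _symmetric_uncertainty(self.codes[key[0]], self.codes[key[1]])
        return self._ff[key]

    def merit(self, subset: FrozenSet[int]) -> float:
        k = len(subset)
        if k == 0:
            return 0.0
        r_cf = float(np.mean([self.cf(j) for j in subset]))
        if k == 1:
            return r_cf
        pairs = list(itertools.combinations(sorted(subset), 2))
        r_ff = float(np.mean([self.ff(i, j) for i, j in pairs]))
        return k * r_cf / np.sqrt(k + k * (k - 1) * r_ff)


def cfs_select(table: FeatureTable) -> SelectionResult:
    """Best-first search over feature subsets maximizing the CFS merit.

    Starts from the empty set, expands the best open subset by adding one
    feature at a time, and stops after ``MAX_STALE`` consecutive
    expansions that fail to improve the best merit.  Deterministic given
    table column order; ties broken by feature-name order.
    """
    names = table.feature_names
    if len(names) < 2:
        raise ValueError("CFS needs at least 2 features")
    if len(table.classes) < 2:
        raise ValueError("CFS needs at least 2 classes")
    cache = _CorrelationCache(table)
    n = len(names)
    order = {j: names[j] for j in range(n)}

    start: FrozenSet[int] = frozenset()
    best_subset, best_merit = start, 0.0
    trace: List[Tuple[float, Tuple[str, ...]]] = []
    # heap of (-merit, tiebreak names, subset)
    heap: List[Tuple[float, Tuple[str, ...], FrozenSet[int]]] = [(0.0, (), start)]
    seen = {start}
    stale = 0
    while heap and stale < MAX_STALE:
        neg_merit, _, subset = heapq.heappop(heap)
        improved = False
        for j in range(n):
            if j in subset:
                continue
            cand = subset | {j}
            if cand in seen:
                continue
            seen.add(cand)
            m = cache.merit(cand)
            key = tuple(sorted(order[i] for i in cand))
            heapq.heappush(heap, (-m, key, cand))
            if m > best_merit + 1e-12:
                best_subset, best_merit = cand, m
                trace.append((m, key))
                improved = True
        stale = 0 if improved else stale + 1
    if not best_subset:
        # all correlations zero: fall back to the single best-named feature
        j = max(range(n), key=lambda j: (cache.cf(j), -ord(names[j][0])))
        best_subset = frozenset({j})
        trace.append((cache.cf(j), (names[j],)))
    selected = sorted((order[j] for j in best_subset), key=names.index)
    return SelectionResult(selected=selected, merit_trace=trace)


def pca_reduce(table: FeatureTable, variance_fraction: float = 0.95) -> FeatureTable:
    """Standardize columns and project onto leading principal components.

    Zero-variance columns are dropped before standardization; enough
    components are kept to cover >= ``variance_fraction`` of the total
    variance.  Component signs are fixed so the largest-magnitude loading
    of each component is positive (determinism).
    """
    if not (0 < variance_fraction <= 1):
        raise ValueError("variance_fraction must be in (0, 1]")
    X = table.matrix
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 instances")
    std = X.std(axis=0)
    keep = std > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    n_comp = min(Xs.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Xs)
    ratios = pca.explained_variance_ratio_
    ncum = int(np.searchsorted(np.cumsum(ratios), variance_fraction - 1e-12) + 1)
    ncum = min(ncum, n_comp)
    comps = pca.components_[:ncum]
    signs = np.sign(comps[np.arange(ncum), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    scores = scores[:, :ncum] * signs
    cols = {f"pc{i + 1}": scores[:, i] for i in range(ncum)}
    return FeatureTable(pd.DataFrame(cols), table.labels.copy())
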