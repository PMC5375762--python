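"""A compact Hoeffding tree (VFDT) for numeric attributes.

Incremental decision-tree induction for data streams: each leaf keeps
per-class Gaussian summaries of every attribute, and a leaf splits once
the Hoeffding bound guarantees (with confidence 1 - delta) that the
best split's information gain truly beats the runner-up. Candidate
thresholds per attribute are a uniform grid over the observed range,
with class-conditional probabilities taken from the Gaussian
summaries. Learning and prediction are both one pass, constant memory
per leaf.
"""

from __future__ import annotations

import numpy as np


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


class _GaussianStats:
    """Per-class running mean/variance per attribute (Welford)."""

    def __init__(self, n_classes: int, n_attrs: int):
        self.n = np.zeros(n_classes)
        self.mean = np.zeros((n_classes, n_attrs))
        self.m2 = np.zeros((n_classes, n_attrs))
        self.amin = np.full(n_attrs, np.inf)
        self.amax = np.full(n_attrs, -np.inf)

    def update(self, x: np.ndarray, c: int) -> None:
        self.n[c] += 1
        delta = x - self.mean[c]
        self.mean[c] += delta / self.n[c]
        self.m2[c] += delta * (x - self.mean[c])
        np.minimum(self.amin, x, out=self.amin)
        np.maximum(self.amax, x, out=self.amax)

    def sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            var = self.m2 / np.maximum(self.n[:, None] - 1, 1)
        return np.sqrt(np.maximum(var, 1e-12))


class _Node:
    def __init__(self, n_classes: int, n_attrs: int):
        self.stats = _GaussianStats(n_classes, n_attrs)
        self.class_counts = np.zeros(n_classes)
        self.split_attr: int | None = None
        self.threshold = 0.0
        self.left: "_Node" | None = None
        self.right: "_Node" | None = None
        self.seen_since_eval = 0

    @property
    def is_leaf(self) -> bool:
        return self.split_attr is None


class HoeffdingTreeClassifier:
    """One-pass decision-tree learner with the Hoeffding split bound.

    Parameters mirror common VFDT practice: ``grace_period`` examples
    between split attempts, split confidence ``delta``, tie threshold
    ``tau``, ``n_thresholds`` candidate cut points per attribute, and a
    depth cap to bound memory.
    """

    def __init__(self, grace_period: int = 200, delta: float = 1e-6,
                 tau: float = 0.05, n_thresholds: int = 10,
                 max_depth: int = 12):
        self.grace_period = grace_period
        self.delta = delta
        self.tau = tau
        self.n_thresholds = n_thresholds
        self.max_depth = max_depth
        self.classes_: np.ndarray | None = None
        self._root: _Node | None = None
        self._n_attrs = 0

    # -- learning ---------------------------------------------------

    def partial_fit(self, X, y, classes=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.classes_ is None:
            if classes is None:
                raise ValueError("classes required on first call")
            self.classes_ = np.asarray(classes)
        if self._root is None:
            self._n_attrs = X.shape[1]
            self._root = _Node(len(self.classes_), self._n_attrs)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for xi, yi in zip(X, y):
            self._learn_one(xi, class_index[yi])
        return self

    def _route(self, x: np.ndarray) -> list[_Node]:
        path = [self._root]
        node = self._root
        while not node.is_leaf:
            node = node.left if x[node.split_attr] <= node.threshold else node.right
            path.append(node)
        return path

    def _learn_one(self, x: np.ndarray, c: int) -> None:
        path = self._route(x)
        leaf = path[-1]
        leaf.stats.update(x, c)
        leaf.class_counts[c] += 1
        leaf.seen_since_eval += 1
        depth = len(path) - 1
        if (leaf.seen_since_eval >= self.grace_period
                and depth < self.max_depth
                and np.count_nonzero(leaf.class_counts) > 1):
            self._try_split(leaf)
            leaf.seen_since_eval = 0

    def _split_gains(self, leaf: _Node):
        """Best (gain, attr, threshold) and runner-up gain."""
        st = leaf.stats
        counts = leaf.class_counts
        base = _entropy(counts)
        sd = st.sd()
        best = (-np.inf, -1, 0.0)
        second = -np.inf
        for a in range(self._n_attrs):
            lo, hi = st.amin[a], st.amax[a]
            if not np.isfinite(lo) or hi <= lo:
                continue
            thresholds = np.linspace(lo, hi, self.n_thresholds + 2)[1:-1]
            # class-conditional P(x <= t) under the Gaussian summaries
            from scipy.stats import norm
            z = (thresholds[None, :] - st.mean[:, a:a + 1]) / sd[:, a:a + 1]
            p_le = norm.cdf(z)
            left = counts[:, None] * p_le
            right = counts[:, None] - left
            for t_idx in range(thresholds.size):
                l, r = left[:, t_idx], right[:, t_idx]
                nl, nr = l.sum(), r.sum()
                tot = nl + nr
                if nl < 1 or nr < 1:
                    continue
                gain = base - (nl / tot) * _entropy(l) - (nr / tot) * _entropy(r)
                if gain > best[0]:
                    second = best[0]
                    best = (gain, a, float(thresholds[t_idx]))
                elif gain > second:
                    second = gain
        return best, second

    def _try_split(self, leaf: _Node) -> None:
        (gain, attr, thr), second = self._split_gains(leaf)
        if attr < 0:
            return
        n = leaf.class_counts.sum()
        r = np.log2(max(len(self.classes_), 2))
        eps = np.sqrt(r * r * np.log(1.0 / self.delta) / (2.0 * n))
        runner = max(second, 0.0)
        if gain - runner > eps or eps < self.tau:
            if gain <= 0:
                return
            leaf.split_attr = attr
            leaf.threshold = thr
            k, m = len(self.classes_), self._n_attrs
            leaf.left = _Node(k, m)
            leaf.right = _Node(k, m)
            # seed child priors with the parent's class split estimate
            from scipy.stats import norm
            z = (thr - leaf.stats.mean[:, attr]) / leaf.stats.sd()[:, attr]
            p_le = norm.cdf(z)
            leaf.left.class_counts = leaf.class_counts * p_le
            leaf.right.class_counts = leaf.class_counts * (1 - p_le)

    # -- prediction -------------------------------------------------

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._root is None:
            raise ValueError("model has not seen any data")
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for i, x in enumerate(X):
            leaf = self._route(x)[-1]
            counts = leaf.class_counts
            if counts.sum() == 0:
                counts = self._root.class_counts
            out[i] = self.classes_[int(np.argmax(counts))]
        return out
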