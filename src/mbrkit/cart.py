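"""Binary decision trees (CART) over mixed design factors.

Greedy binary splitting on a small factor table (numeric factors by
threshold, categorical factors by exhaustive binary subset partition — exact
for the low-cardinality factors used here).  Classification uses Gini
impurity, regression uses variance (SSE) reduction.  Both estimators follow
the scikit-learn protocol (fit/predict, ``get_params``/``set_params``,
fitted attributes with trailing underscores) and accept a pandas DataFrame
whose object/category columns are treated as categorical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CartClassifier", "CartRegressor", "Node", "LeafPath"]


@dataclass
class Node:
    """A split node or leaf of a fitted tree."""

    n: int
    value: object  # majority class or mean
    sd: float = 0.0
    impurity: float = 0.0
    class_counts: dict | None = None
    feature: str | None = None
    kind: str | None = None  # "num" | "cat"
    threshold: float | None = None
    left_categories: frozenset | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def route(self, row: pd.Series) -> "Node":
        node = self
        while not node.is_leaf:
            x = row[node.feature]
            if node.kind == "num":
                node = node.left if x <= node.threshold else node.right
            else:
                node = node.left if x in node.left_categories else node.right
        return node


@dataclass
class LeafPath:
    """Root-to-leaf factor constraints with the leaf's statistics.

    ``constraints`` maps factor name to an ("interval", (lo, hi]) pair for
    numeric factors or ("set", frozenset) for categorical ones; factors that
    were never split on along the path are absent (meaning "any").
    """

    constraints: dict
    n: int
    value: object
    sd: float = 0.0

    def matches(self, row: pd.Series) -> bool:
        for f, (kind, c) in self.constraints.items():
            x = row[f]
            if kind == "interval":
                lo, hi = c
                if not (lo < x <= hi):
                    return False
            else:
                if x not in c:
                    return False
        return True


class _ParamsMixin:
    _param_names: tuple = ()

    def get_params(self, deep: bool = True) -> dict:
        return {p: getattr(self, p) for p in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"invalid parameter {k!r} for {type(self).__name__}")
            setattr(self, k, v)
        return self


class _CartBase(_ParamsMixin):
    _param_names = ("min_leaf", "max_depth", "min_gain")

    def __init__(self, min_leaf: int = 1, max_depth: int | None = None,
                 min_gain: float = 0.0):
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.min_gain = min_gain

    # --- subclass hooks -------------------------------------------------
    def _impurity(self, y: np.ndarray) -> float:
        raise NotImplementedError

    def _leaf(self, y: np.ndarray, impurity: float) -> Node:
        raise NotImplementedError

    # --- fitting --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.feature_names_ = list(X.columns)
        self._kinds = {
            c: ("cat" if X[c].dtype == object or str(X[c].dtype) == "category"
                else "num")
            for c in X.columns
        }
        self.tree_ = self._grow(X, y, depth=0)
        self.n_leaves_ = sum(1 for p in self.leaf_paths())
        return self

    def _grow(self, X: pd.DataFrame, y: np.ndarray, depth: int) -> Node:
        imp = self._impurity(y)
        leaf = self._leaf(y, imp)
        n = len(y)
        if (imp <= 1e-15 or n < 2 * self.min_leaf
                or (self.max_depth is not None and depth >= self.max_depth)):
            return leaf
        best = None  # (gain, feature, kind, thr_or_set, mask)
        for feat in self.feature_names_:
            col = X[feat]
            if self._kinds[feat] == "num":
                vals = np.sort(col.unique())
                for a, b in zip(vals[:-1], vals[1:]):
                    thr = 0.5 * (float(a) + float(b))
                    mask = col.to_numpy() <= thr
                    cand = self._eval_split(y, imp, mask)
                    if cand is not None and (best is None or cand > best[0]):
                        best = (cand, feat, "num", thr, mask)
            else:
                cats = sorted(map(str, col.unique()))
                if len(cats) < 2:
                    continue
                anchor = cats[0]
                rest = cats[1:]
                for r in range(len(cats) // 2 + 1):
                    for extra in itertools.combinations(rest, r):
                        subset = frozenset((anchor, *extra))
                        if len(subset) == len(cats):
                            continue
                        mask = col.astype(str).isin(subset).to_numpy()
                        cand = self._eval_split(y, imp, mask)
                        if cand is not None and (best is None or cand > best[0]):
                            best = (cand, feat, "cat", subset, mask)
        # guard: the split must explain at least min_gain of this node's
        # impurity, which is where chance splits on unrelated factors live
        if best is None or best[0] <= self.min_gain * max(imp * n, 1e-300):
            return leaf
        gain, feat, kind, spec, mask = best
        node = leaf
        node.feature = feat
        node.kind = kind
        if kind == "num":
            node.threshold = spec
        else:
            node.left_categories = spec
        node.left = self._grow(X[mask], y[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], depth + 1)
        return node

    def _eval_split(self, y, parent_imp, mask) -> float | None:
        nl = int(mask.sum())
        nr = len(y) - nl
        if nl < self.min_leaf or nr < self.min_leaf:
            return None
        n = len(y)
        child = nl * self._impurity(y[mask]) + nr * self._impurity(y[~mask])
        gain = parent_imp * n - child  # weighted-impurity decrease
        return gain if gain > 1e-15 else None

    # --- inspection -----------------------------------------------------
    def predict(self, X: pd.DataFrame):
        X = pd.DataFrame(X)
        return np.asarray([self.tree_.route(row).value for _, row in X.iterrows()])

    def leaf_paths(self) -> list[LeafPath]:
        """All root-to-leaf paths as factor constraints."""
        out: list[LeafPath] = []

        def walk(node: Node, cons: dict):
            if node.is_leaf:
                out.append(LeafPath(constraints={k: v for k, v in cons.items()},
                                    n=node.n, value=node.value, sd=node.sd))
                return
            f = node.feature
            if node.kind == "num":
                lo, hi = cons.get(f, ("interval", (-np.inf, np.inf)))[1]
                walk(node.left, {**cons, f: ("interval", (lo, min(hi, node.threshold)))})
                walk(node.right, {**cons, f: ("interval", (max(lo, node.threshold), hi))})
            else:
                cur = cons.get(f)
                allowed = cur[1] if cur else None
                left_set = (node.left_categories if allowed is None
                            else frozenset(allowed & node.left_categories))
                right_all = (frozenset() if allowed is None
                             else frozenset(allowed - node.left_categories))
                walk(node.left, {**cons, f: ("set", left_set)})
                if allowed is None:
                    walk(node.right, {**cons, f: ("set_complement", node.left_categories)})
                else:
                    walk(node.right, {**cons, f: ("set", right_all)})

        walk(self.tree_, {})
        return out

    def rules(self) -> list[str]:
        """Human-readable IF/THEN rule per leaf."""
        lines = []
        for p in self.leaf_paths():
            conds = []
            for f, (kind, c) in p.constraints.items():
                if kind == "interval":
                    lo, hi = c
                    if np.isfinite(lo):
                        conds.append(f"{f} > {lo:g}")
                    if np.isfinite(hi):
                        conds.append(f"{f} <= {hi:g}")
                elif kind == "set":
                    conds.append(f"{f} in {{{', '.join(sorted(c))}}}")
                else:
                    conds.append(f"{f} not in {{{', '.join(sorted(c))}}}")
            cond = " AND ".join(conds) if conds else "TRUE"
            if isinstance(p.value, float):
                lines.append(f"IF {cond} THEN {p.value:.4g} (n={p.n}, sd={p.sd:.3g})")
            else:
                lines.append(f"IF {cond} THEN {p.value} (n={p.n})")
        return lines

    @property
    def depth_(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.tree_)


class CartClassifier(_CartBase):
    """CART classifier with Gini impurity over mixed factors.

    ``min_gain`` (the fraction of the parent node's weighted Gini a split
    must remove) suppresses splits on factors without a systematic effect on
    the labels.
    """

    def __init__(self, min_leaf: int = 1, max_depth: int | None = None,
                 min_gain: float = 0.2):
        super().__init__(min_leaf=min_leaf, max_depth=max_depth,
                         min_gain=min_gain)

    def _impurity(self, y: np.ndarray) -> float:
        _, counts = np.unique(y, return_counts=True)
        p = counts / counts.sum()
        return float(1.0 - np.sum(p * p))

    def _leaf(self, y: np.ndarray, impurity: float) -> Node:
        vals, counts = np.unique(y, return_counts=True)
        order = np.lexsort((vals.astype(str), -counts))
        return Node(n=len(y), value=vals[order[0]],
                    class_counts=dict(zip(vals.tolist(), counts.tolist())),
                    impurity=impurity)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


class CartRegressor(_CartBase):
    """CART regressor with variance-reduction splitting.

    ``min_gain`` is the fraction of the parent node's SSE a split must
    remove; chance splits on permuted targets rarely exceed ~30%, while
    systematic design-factor effects remove most of a node's SSE.
    """

    def __init__(self, min_leaf: int = 6, max_depth: int | None = None,
                 min_gain: float = 0.35):
        super().__init__(min_leaf=min_leaf, max_depth=max_depth, min_gain=min_gain)

    def _impurity(self, y: np.ndarray) -> float:
        if len(y) == 0:
            return 0.0
        return float(np.var(y))  # SSE/n

    def _leaf(self, y: np.ndarray, impurity: float) -> Node:
        sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
        return Node(n=len(y), value=float(np.mean(y)), sd=sd, impurity=impurity)
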