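"""Design-space optimization by superimposed regression trees.

Four regression trees map the design factors (feed profile, feed rate,
initial substrate, hunger phase) to the four process characteristics of
interest — ethanol concentration and volumetric product activity at an early
and a late time point.  From each tree the decision paths leading to
near-best leaves are extracted (low ethanol, high activity); superimposing
the matched condition sets across all four targets yields the recurring
conditions that are favourable for every objective at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cart import CartRegressor, LeafPath

__all__ = [
    "OptimalPath",
    "SuperpositionReport",
    "fit_regression_tree",
    "extract_optimal_paths",
    "superimpose_targets",
]

FACTORS = ("profile", "mu_set", "S0", "hunger_h")


def fit_regression_tree(
    design_factors: pd.DataFrame,
    y,
    min_leaf: int = 6,
    min_gain: float = 0.35,
    factors: tuple = FACTORS,
) -> CartRegressor:
    """CART with variance-reduction splitting on the design factors.

    ``min_leaf`` defaults to 6 = two conditions' worth of triplicates, so a
    leaf always aggregates whole conditions.  The feed profile is categorical
    (exhaustive binary partitions); the numeric factors split by threshold.
    """
    X = design_factors[list(factors)]
    y = np.asarray(y, float)
    if len(y) < 2 * min_leaf:
        raise ValueError(f"need at least {2*min_leaf} runs")
    return CartRegressor(min_leaf=min_leaf, min_gain=min_gain).fit(X, y)


@dataclass
class OptimalPath:
    """One near-best root-to-leaf path as factor constraints.

    ``constraints`` maps every factor to either ("any", None), an
    ("interval", (lo, hi]) pair or a ("set", frozenset) of allowed
    categories.
    """

    constraints: dict
    n_runs: int
    mean: float
    sd: float
    direction: str

    def describe(self) -> str:
        parts = []
        for f, (kind, c) in self.constraints.items():
            if kind == "any":
                parts.append(f"{f}: -")
            elif kind == "interval":
                lo, hi = c
                if np.isfinite(lo) and np.isfinite(hi):
                    parts.append(f"{f} in ({lo:g}, {hi:g}]")
                elif np.isfinite(hi):
                    parts.append(f"{f} <= {hi:g}")
                else:
                    parts.append(f"{f} > {lo:g}")
            else:
                parts.append(f"{f} in {{{', '.join(sorted(map(str, c)))}}}")
        return (" AND ".join(parts)
                + f"  ->  {self.mean:.3g} +/- {self.sd:.3g} (n={self.n_runs})")

    def matches(self, row: pd.Series) -> bool:
        for f, (kind, c) in self.constraints.items():
            if kind == "any":
                continue
            x = row[f]
            if kind == "interval":
                lo, hi = c
                if not (lo < x <= hi):
                    return False
            else:
                if x not in c:
                    return False
        return True


def _leaf_to_path(leaf: LeafPath, direction: str, all_categories: dict,
                  factors: tuple) -> OptimalPath:
    cons = {}
    for f in factors:
        if f not in leaf.constraints:
            cons[f] = ("any", None)
            continue
        kind, c = leaf.constraints[f]
        if kind == "interval":
            cons[f] = ("interval", c)
        elif kind == "set":
            cons[f] = ("set", frozenset(c))
        else:  # complement of a category subset
            cons[f] = ("set", frozenset(all_categories[f]) - frozenset(c))
    return OptimalPath(constraints=cons, n_runs=leaf.n, mean=float(leaf.value),
                       sd=float(leaf.sd), direction=direction)


def extract_optimal_paths(
    tree: CartRegressor,
    direction: str = "maximize",
    slack: float = 0.15,
    categories: dict | None = None,
) -> list[OptimalPath]:
    """Leaves whose mean is within ``slack * range`` of the best leaf.

    ``slack=0`` returns only the single best leaf; a single-leaf tree yields
    one all-"any" path.  Factors never split on along a path are reported as
    "any" (the '-' convention of the optimal-condition tables).
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    leaves = tree.leaf_paths()
    means = np.asarray([lf.value for lf in leaves], float)
    best = means.max() if direction == "maximize" else means.min()
    span = float(means.max() - means.min())
    tol = slack * span
    if direction == "maximize":
        keep = [lf for lf in leaves if lf.value >= best - tol]
    else:
        keep = [lf for lf in leaves if lf.value <= best + tol]
    cats = categories or {}
    paths = [_leaf_to_path(lf, direction, cats, tuple(tree.feature_names_))
             for lf in keep]
    # best first
    paths.sort(key=lambda p: -p.mean if direction == "maximize" else p.mean)
    return paths


@dataclass
class SuperpositionReport:
    """Overlap of near-optimal condition sets across the four targets."""

    per_target_paths: dict  # target -> list[OptimalPath]
    per_target_conditions: dict  # target -> set of condition_ids
    intersection: set
    common_levels: dict  # factor -> value common to all intersection members
    pairwise_overlap: dict  # (target_a, target_b) -> set

    def summary(self) -> str:
        lines = []
        for tgt, conds in self.per_target_conditions.items():
            lines.append(f"{tgt}: conditions {sorted(conds)}")
        lines.append(f"intersection: {sorted(self.intersection)}")
        if self.common_levels:
            lv = ", ".join(f"{k}={v}" for k, v in self.common_levels.items())
            lines.append(f"recurring levels: {lv}")
        return "\n".join(lines)


def superimpose_targets(
    paths_by_target: dict,
    design: pd.DataFrame,
) -> SuperpositionReport:
    """Intersect matched condition sets across targets.

    ``design`` is a condition-level table (index: condition_id, columns
    include the factor names).  Each path maps to the set of condition ids
    it matches; per target the union over its paths is taken, and the
    intersection across targets gives the recurring optimal conditions.  An
    empty intersection is reported together with all pairwise overlaps for
    diagnosis.
    """
    if not paths_by_target or any(not v for v in paths_by_target.values()):
        raise ValueError("every target needs a non-empty path list")
    per_target: dict = {}
    for tgt, paths in paths_by_target.items():
        matched: set = set()
        for path in paths:
            for cid, row in design.iterrows():
                if path.matches(row):
                    matched.add(cid)
        per_target[tgt] = matched
    sets = list(per_target.values())
    inter = set.intersection(*sets)
    common_levels: dict = {}
    if inter:
        sub = design.loc[sorted(inter)]
        for f in design.columns:
            vals = sub[f].unique()
            if len(vals) == 1:
                v = vals[0]
                common_levels[f] = v if isinstance(v, str) else float(v)
    pairwise = {}
    if not inter:
        for (ta, sa), (tb, sb) in combinations(per_target.items(), 2):
            pairwise[(ta, tb)] = sa & sb
    return SuperpositionReport(
        per_target_paths=dict(paths_by_target),
        per_target_conditions=per_target,
        intersection=inter,
        common_levels=common_levels,
        pairwise_overlap=pairwise,
    )
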