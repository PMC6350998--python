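"""Permutation variable importance from a bootstrap regression-tree ensemble.

"Mean decrease in accuracy" is operationalized the standard way: each tree
is grown on a bootstrap sample; for each predictor, that predictor's values
are permuted among the tree's out-of-bag (OOB) rows and the rise in OOB
squared error, averaged over trees, is the predictor's importance.  The
ensemble follows the regression-forest conventions — bootstrap sample size
n, ⌈p/3⌉ predictors tried per split — and is deterministic given its seed.

The two-stage screen mirrors the field's usual treatment of collinear
climate summaries: rank all candidates, collapse each group of mutually
correlated SST summaries (|r| ≥ 0.7 by default) to its highest-ranked
member, re-rank the reduced set, and keep the top two for the count model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ImportanceReport",
    "SelectionReport",
    "fit_importance",
    "collinear_groups",
    "two_stage_select",
]


@dataclass
class ImportanceReport:
    """Per-predictor OOB permutation importance (mean rise in squared error)."""

    importances: pd.Series  # index predictor, sorted descending
    n_trees: int
    seed: int

    @property
    def ranking(self) -> list:
        return list(self.importances.index)

    def rank_of(self, name: str) -> int:
        """1-based rank of a predictor (1 = most important)."""
        return self.ranking.index(name) + 1


def _as_frame(X) -> pd.DataFrame:
    if hasattr(X, "frame"):  # CovariateTable
        return X.frame
    return pd.DataFrame(X)


def fit_importance(y, X, n_trees: int = 2000, seed: int = 0) -> ImportanceReport:
    """OOB permutation importance of every predictor, deterministic given seed."""
    frame = _as_frame(X)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if frame.isna().any().any():
        raise ValueError("missing cells in predictor table")
    if hasattr(y, "counts"):
        y = y.counts
    y = np.asarray(y, dtype=float)
    n, p = frame.shape
    if y.size != n:
        raise ValueError("response length does not match predictor rows")
    if np.std(y) == 0:
        raise ValueError("constant response: importance undefined")

    Xv = frame.to_numpy(dtype=float)
    max_features = math.ceil(p / 3)
    rng = np.random.default_rng(seed)
    sums = np.zeros(p)
    used = 0
    all_idx = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        tree_seed = int(rng.integers(2**31))
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(max_features=max_features, random_state=tree_seed)
        tree.fit(Xv[boot], y[boot])
        X_oob = Xv[oob]
        base = float(np.mean((tree.predict(X_oob) - y[oob]) ** 2))
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = X_oob.copy()
            Xp[:, j] = X_oob[perm, j]
            mse = float(np.mean((tree.predict(Xp) - y[oob]) ** 2))
            sums[j] += mse - base
        used += 1
    if used == 0:
        raise RuntimeError("no tree had out-of-bag rows")
    imp = pd.Series(sums / used, index=frame.columns).sort_values(ascending=False)
    return ImportanceReport(importances=imp, n_trees=n_trees, seed=seed)


def collinear_groups(X, threshold: float = 0.7, columns=None) -> list[list]:
    """Connected groups of predictors with pairwise |correlation| ≥ threshold.

    Only groups with at least two members are returned; ``columns``
    restricts the analysis to a subset (e.g. the SST summaries).
    """
    frame = _as_frame(X)
    if columns is not None:
        frame = frame[[c for c in columns if c in frame.columns]]
    cols = list(frame.columns)
    k = len(cols)
    if k < 2:
        return []
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list] = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(cols[i])
    return [g for g in groups.values() if len(g) > 1]


@dataclass
class SelectionReport:
    top_two: tuple
    stage1: ImportanceReport
    stage2: ImportanceReport
    dropped: list
    groups: list


def two_stage_select(
    y,
    X,
    n_trees: int = 2000,
    threshold: float = 0.7,
    seed: int = 0,
    sst_columns=None,
) -> SelectionReport:
    """Two-stage collinearity screen returning the top two predictors.

    Stage 1 ranks all predictors.  Within each group of collinear SST
    summaries only the highest-ranked member is kept (non-SST candidates
    are never eliminated here).  Stage 2 re-ranks the reduced set and its
    top two are returned.  With only two predictors a single stage is run.
    """
    frame = _as_frame(X)
    if sst_columns is None:
        sst_columns = [c for c in frame.columns if str(c).startswith("sst_")]
    stage1 = fit_importance(y, frame, n_trees=n_trees, seed=seed)
    if frame.shape[1] <= 2:
        return SelectionReport(
            top_two=tuple(stage1.ranking[:2]), stage1=stage1, stage2=stage1,
            dropped=[], groups=[],
        )
    groups = collinear_groups(frame, threshold=threshold, columns=sst_columns)
    dropped = []
    for group in groups:
        keep = min(group, key=stage1.rank_of)
        dropped.extend(c for c in group if c != keep)
    reduced = frame[[c for c in frame.columns if c not in dropped]]
    stage2 = fit_importance(y, reduced, n_trees=n_trees, seed=seed + 1)
    return SelectionReport(
        top_two=tuple(stage2.ranking[:2]), stage1=stage1, stage2=stage2,
        dropped=dropped, groups=groups,
    )
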