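"""Ranking experimental conditions by their contribution to prediction.

Three complementary strategies mirror common feature-subset practice:
greedy forward (sequential inclusion), greedy backward (sequential
exclusion), and exhaustive enumeration of all three-condition models.  The
step metric is the mean cross-validated R^2 across all predicted features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import ValidationError
from .regression import adjusted_r2, press_cv, select_components


@dataclass
class SelectionResult:
    """Ordered protocol ranking with the per-step mean held-out R^2."""

    ranking: list
    step_r2: list
    method: str  # "inclusion" | "exclusion" | "triplet"
    seed: int

    def to_dict(self) -> dict:
        return {
            "ranking": list(self.ranking),
            "step_r2": [float(v) for v in self.step_r2],
            "method": self.method,
            "seed": self.seed,
        }


def _complete_rows(blocks: Mapping[str, pd.DataFrame], y: pd.DataFrame):
    ok = y.notna().all(axis=1)
    for b in blocks.values():
        ok &= b.notna().all(axis=1)
    return ok


def _assemble(blocks: Mapping[str, pd.DataFrame], pids: Sequence[str]) -> pd.DataFrame:
    pieces = []
    for pid in pids:
        b = blocks[pid].copy()
        b.columns = pd.MultiIndex.from_product([[pid], blocks[pid].columns])
        pieces.append(b)
    return pd.concat(pieces, axis=1)

def _drop_degenerate(blocks, y):
    """Exclude zero-variance protocol blocks (with a warning)."""
    import warnings

    ok_blocks = {}
    for pid, b in blocks.items():
        if (b.std(ddof=1) > 0).all():
            ok_blocks[pid] = b
        else:
            warnings.warn(f"protocol {pid!r} has a zero-variance feature; excluded")
    if len(ok_blocks) < 1:
        raise ValidationError("no usable protocol blocks")
    return ok_blocks


def _mean_cv_r2(blocks, y, pids, k_folds, seed, n_components) -> float:
    x = _assemble(blocks, pids)
    a = n_components or min(10, x.shape[1], len(x) - int(np.ceil(len(x) / k_folds)) - 1)
    a = min(a, x.shape[1])
    rep = press_cv(x, y, a, k_folds=k_folds, seed=seed)
    return rep.mean_r2


def sequential_inclusion(
    blocks: Mapping[str, pd.DataFrame],
    y: pd.DataFrame,
    k_folds: int = 5,
    seed: int = 0,
    n_components: Optional[int] = None,
) -> SelectionResult:
    """Greedy forward ranking: repeatedly add the condition that raises the
    mean cross-validated R^2 the most."""
    blocks = _drop_degenerate(blocks, y)
    ok = _complete_rows(blocks, y)
    blocks = {pid: b.loc[ok].reset_index(drop=True) for pid, b in blocks.items()}
    y = y.loc[ok].reset_index(drop=True)

    remaining = list(blocks)
    chosen: list = []
    step_r2: list = []
    while remaining:
        scores = [
            (_mean_cv_r2(blocks, y, chosen + [pid], k_folds, seed, n_components), pid)
            for pid in remaining
        ]
        best_r2, best_pid = max(scores, key=lambda s: s[0])
        chosen.append(best_pid)
        remaining.remove(best_pid)
        step_r2.append(best_r2)
    return SelectionResult(chosen, step_r2, "inclusion", seed)


def sequential_exclusion(
    blocks: Mapping[str, pd.DataFrame],
    y: pd.DataFrame,
    k_folds: int = 5,
    seed: int = 0,
    n_components: Optional[int] = None,
) -> SelectionResult:
    """Greedy backward ranking: repeatedly drop the condition whose removal
    lowers the mean cross-validated R^2 the least.

    The returned ranking is ordered from most to least informative (the
    condition surviving longest first); step_r2[i] is the metric of the
    model that still contains ranking[i:].
    """
    blocks = _drop_degenerate(blocks, y)
    ok = _complete_rows(blocks, y)
    blocks = {pid: b.loc[ok].reset_index(drop=True) for pid, b in blocks.items()}
    y = y.loc[ok].reset_index(drop=True)

    current = list(blocks)
    removed: list = []
    r2_at: list = []
    while len(current) > 1:
        scores = [
            (_mean_cv_r2(blocks, y, [p for p in current if p != pid],
                         k_folds, seed, n_components), pid)
            for pid in current
        ]
        best_r2, drop_pid = max(scores, key=lambda s: s[0])
        current.remove(drop_pid)
        removed.append(drop_pid)
        r2_at.append(best_r2)
    last = current[0]
    r2_last = _mean_cv_r2(blocks, y, [last], k_folds, seed, n_components)
    ranking = [last] + removed[::-1]
    step_r2 = [r2_last] + r2_at[::-1]
    return SelectionResult(ranking, step_r2, "exclusion", seed)


def enumerate_triplets(
    blocks: Mapping[str, pd.DataFrame],
    y: pd.DataFrame,
    k_folds: int = 5,
    seed: int = 0,
    max_components: int = 10,
    tol: float = 0.05,
) -> pd.DataFrame:
    """Fit and cross-validate one model per 3-condition combination.

    For 8 candidate conditions this gives C(8,3) = 56 models.  Returns a
    frame with one row per combination: the triplet, the PRESS-selected
    component count, and the adjusted R^2 per output plus their mean,
    sortable by any column.
    """
    blocks = _drop_degenerate(blocks, y)
    ok = _complete_rows(blocks, y)
    blocks = {pid: b.loc[ok].reset_index(drop=True) for pid, b in blocks.items()}
    y = y.loc[ok].reset_index(drop=True)

    rows = []
    for trip in itertools.combinations(sorted(blocks), 3):
        x = _assemble(blocks, trip)
        a, _ = select_components(x, y, k_folds=k_folds, seed=seed,
                                 max_components=max_components, tol=tol)
        rep = press_cv(x, y, a, k_folds=k_folds, seed=seed)
        adj = rep.adjusted_r2_per_output
        row = {"triplet": trip, "n_components": a,
               "mean_adj_r2": float(adj.mean())}
        for col, v in adj.items():
            row[f"adj_r2_{col}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)
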