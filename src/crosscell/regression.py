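"""Cross-cell-type regression: PLSR mapping source features to target features.

The mapping is a partial least squares regression (SIMPLS) fitted on paired
population feature matrices.  Strictly positive features (durations,
concentrations, amplitudes, rates) are log-transformed, voltages are left on
their natural scale, and every column is z-scored; the coefficient matrix
B_cross lives on that preprocessed scale.  Model quality is assessed by
k-fold cross-validation with PRESS (predicted residual sum of squares), and
the number of latent components is chosen as the smallest one whose PRESS is
within a tolerance of the minimum.

Drug-induced changes are handled on the same transform scale: a change
vector holds log-ratios (post/pre) for log columns and plain differences for
linear columns, so multiplicative drug effects map linearly through B_cross.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarkers import LOG_FEATURES
from .model_core import ValidationError


def default_log_policy(column) -> bool:
    """Log-transform a column iff its feature name is a strictly positive one."""
    feature = column[-1] if isinstance(column, tuple) else column
    return feature in LOG_FEATURES


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class ColumnStats:
    """Per-column preprocessing statistics (log flag, mean, SD)."""

    columns: list
    log: np.ndarray      # bool per column
    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "columns": [list(c) if isinstance(c, tuple) else c for c in self.columns],
            "log": self.log.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnStats":
        cols = [tuple(c) if isinstance(c, list) else c for c in d["columns"]]
        return cls(cols, np.asarray(d["log"], bool),
                   np.asarray(d["mean"], float), np.asarray(d["sd"], float))


def _check_columns(df: pd.DataFrame, stats: ColumnStats):
    if list(df.columns) != list(stats.columns):
        missing = [c for c in stats.columns if c not in set(df.columns)]
        extra = [c for c in df.columns if c not in set(stats.columns)]
        raise ValidationError(
            f"column mismatch: missing {missing[:5]}, extra {extra[:5]}"
        )


def fit_preprocess(
    df: pd.DataFrame, log_policy: Callable = default_log_policy
) -> tuple[np.ndarray, ColumnStats]:
    """Log/z-score a training matrix; returns (Z, stats for reuse/inverse)."""
    cols = list(df.columns)
    x = df.to_numpy(float)
    logf = np.array([bool(log_policy(c)) for c in cols])
    w = x.copy()
    for j, lg in enumerate(logf):
        if lg:
            if np.nanmin(x[:, j]) <= 0:
                raise ValidationError(
                    f"column {cols[j]!r} marked for log transform has values <= 0"
                )
            w[:, j] = np.log(x[:, j])
    mean = np.nanmean(w, axis=0)
    sd = np.nanstd(w, axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        raise ValidationError(f"zero-variance column: {cols[bad[0]]!r}")
    z = (w - mean) / sd
    return z, ColumnStats(cols, logf, mean, sd)


def apply_preprocess(df: pd.DataFrame, stats: ColumnStats) -> np.ndarray:
    _check_columns(df, stats)
    x = df.to_numpy(float).copy()
    for j, lg in enumerate(stats.log):
        if lg:
            x[:, j] = np.log(x[:, j])
    return (x - stats.mean) / stats.sd


def inverse_preprocess(z: np.ndarray, stats: ColumnStats) -> pd.DataFrame:
    w = z * stats.sd + stats.mean
    for j, lg in enumerate(stats.log):
        if lg:
            w[:, j] = np.exp(w[:, j])
    if stats.columns and isinstance(stats.columns[0], tuple):
        cols = pd.MultiIndex.from_tuples(stats.columns, names=["protocol", "feature"])
    else:
        cols = stats.columns
    return pd.DataFrame(w, columns=cols)


# ---------------------------------------------------------------------------
# SIMPLS core


def simpls(x: np.ndarray, y: np.ndarray, n_components: int) -> np.ndarray:
    """SIMPLS coefficients for centered (here: z-scored) X (n x p), Y (n x m).

    Returns B (p x m) with Y_hat = X @ B.  Deterministic; singular-vector
    sign ambiguity cancels in B.
    """
    n, p = x.shape
    m = y.shape[1]
    max_rank = min(n - 1, p)
    if n_components < 1 or n_components > max_rank:
        raise ValidationError(
            f"n_components must be in [1, {max_rank}] for a {n}x{p} matrix"
        )
    s = x.T @ y
    r_all = np.zeros((p, n_components))
    q_all = np.zeros((m, n_components))
    v_all = np.zeros((p, n_components))
    for a in range(n_components):
        u, sv, _ = np.linalg.svd(s, full_matrices=False)
        if sv[0] <= 1e-14:
            raise ValidationError(
                f"covariance exhausted after {a} components; reduce n_components"
            )
        r = u[:, 0]
        t = x @ r
        normt = np.linalg.norm(t)
        if normt <= 1e-14:
            raise ValidationError("degenerate score vector in SIMPLS")
        t /= normt
        r = r / normt
        p_load = x.T @ t
        q_load = y.T @ t
        v = p_load.copy()
        if a > 0:
            v -= v_all[:, :a] @ (v_all[:, :a].T @ p_load)
        v /= np.linalg.norm(v)
        s = s - np.outer(v, v.T @ s)
        r_all[:, a] = r
        q_all[:, a] = q_load
        v_all[:, a] = v
    return r_all @ q_all.T


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class CrossCellModel:
    """Fitted source->target PLSR mapping with its preprocessing statistics."""

    b_cross: np.ndarray
    x_stats: ColumnStats
    y_stats: ColumnStats
    n_components: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.b_cross.shape != (len(self.x_stats.columns), len(self.y_stats.columns)):
            raise ValidationError("B_cross dimensions do not match column metadata")

    @property
    def x_columns(self):
        return list(self.x_stats.columns)

    @property
    def y_columns(self):
        return list(self.y_stats.columns)

    def predict(self, x_df: pd.DataFrame) -> pd.DataFrame:
        """Absolute mode: preprocess, multiply by B_cross, inverse-transform."""
        z = apply_preprocess(x_df, self.x_stats)
        zy = z @ self.b_cross
        out = inverse_preprocess(zy, self.y_stats)
        out.index = x_df.index
        return out

    def predict_change(self, change: pd.Series) -> pd.Series:
        """Change mode: transform-scale change vector in, predicted out.

        Input values are log-ratios post/pre for log columns and plain
        differences for linear columns (see ``feature_change_vector``).
        Output is on the same convention over the target columns.
        """
        if list(change.index) != list(self.x_stats.columns):
            missing = [c for c in self.x_stats.columns if c not in change.index]
            extra = [c for c in change.index if c not in set(self.x_stats.columns)]
            raise ValidationError(f"change-vector mismatch: missing {missing[:5]}, "
                                  f"extra {extra[:5]}")
        dzx = change.to_numpy(float) / self.x_stats.sd
        dzy = dzx @ self.b_cross
        dy = dzy * self.y_stats.sd
        idx = (pd.MultiIndex.from_tuples(self.y_stats.columns,
                                         names=["protocol", "feature"])
               if self.y_stats.columns and isinstance(self.y_stats.columns[0], tuple)
               else self.y_stats.columns)
        return pd.Series(dy, index=idx)

    def change_to_percent(self, change: pd.Series, stats: Optional[ColumnStats] = None
                          ) -> pd.Series:
        """Express a transform-scale change vector as percent change (log
        columns); linear columns are returned as absolute differences."""
        stats = stats or self.y_stats
        vals = change.to_numpy(float).copy()
        for j, lg in enumerate(stats.log):
            if lg:
                vals[j] = (np.exp(vals[j]) - 1.0) * 100.0
        return pd.Series(vals, index=change.index)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "b_cross": self.b_cross.tolist(),
            "x_stats": self.x_stats.to_dict(),
            "y_stats": self.y_stats.to_dict(),
            "n_components": self.n_components,
            "meta": self.meta,
        })

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "CrossCellModel":
        d = json.loads(text)
        return cls(
            b_cross=np.asarray(d["b_cross"], float),
            x_stats=ColumnStats.from_dict(d["x_stats"]),
            y_stats=ColumnStats.from_dict(d["y_stats"]),
            n_components=int(d["n_components"]),
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "CrossCellModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def fit_plsr(
    x_df: pd.DataFrame,
    y_df: pd.DataFrame,
    n_components: int,
    log_policy: Callable = default_log_policy,
    meta: Optional[dict] = None,
) -> CrossCellModel:
    """Fit the cross-cell PLSR model on aligned feature matrices."""
    if len(x_df) != len(y_df):
        raise ValidationError(
            f"row mismatch: X has {len(x_df)} rows, Y has {len(y_df)}"
        )
    zx, xs = fit_preprocess(x_df, log_policy)
    zy, ys = fit_preprocess(y_df, log_policy)
    b = simpls(zx, zy, n_components)
    return CrossCellModel(b, xs, ys, n_components, meta=dict(meta or {}))


def feature_change_vector(pre: pd.Series, post: pd.Series,
                          log_policy: Callable = default_log_policy) -> pd.Series:
    """Drug-induced change on the transform scale.

    log columns: log(post/pre); linear columns: post - pre.  ``pre`` and
    ``post`` are feature vectors (e.g. population means) over the same
    columns.
    """
    if list(pre.index) != list(post.index):
        raise ValidationError("pre/post column mismatch")
    out = pd.Series(np.nan, index=pre.index, dtype=float)
    for c in pre.index:
        if default_log_policy(c) if log_policy is default_log_policy else log_policy(c):
            out[c] = np.log(post[c] / pre[c])
        else:
            out[c] = post[c] - pre[c]
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVReport:
    """Cross-validation diagnostics for one fitted configuration."""

    r2_per_output: pd.Series
    press: float
    fold_assignment: np.ndarray
    n_components: int
    n_rows: int
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(self.r2_per_output.mean())

    @property
    def adjusted_r2_per_output(self) -> pd.Series:
        return self.r2_per_output.apply(
            lambda r: adjusted_r2(r, self.n_rows, self.n_components)
        )

    def to_dict(self) -> dict:
        return {
            "r2_per_output": {str(k): float(v) for k, v in self.r2_per_output.items()},
            "mean_r2": self.mean_r2,
            "press": self.press,
            "n_components": self.n_components,
            "n_rows": self.n_rows,
            "seed": self.seed,
            "fold_assignment": self.fold_assignment.tolist(),
        }


def make_folds(n_rows: int, k_folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment: a permutation split into k near-equal folds."""
    if k_folds < 2:
        raise ValidationError("k_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    assign = np.empty(n_rows, int)
    for k, idx in enumerate(np.array_split(perm, k_folds)):
        assign[idx] = k
    return assign


def press_cv(
    x_df: pd.DataFrame,
    y_df: pd.DataFrame,
    n_components: int,
    k_folds: int = 5,
    seed: int = 0,
    log_policy: Callable = default_log_policy,
) -> CVReport:
    """k-fold cross-validation: PRESS and per-output held-out R^2.

    Per fold, preprocessing statistics and the PLSR fit use training rows
    only; PRESS accumulates squared held-out residuals on the preprocessed
    (training-stats) scale.  R^2 per output is computed from the pooled
    held-out predictions on the log/linear transform scale.
    """
    n = len(x_df)
    if len(y_df) != n:
        raise ValidationError("row mismatch between X and Y")
    assign = make_folds(n, k_folds, seed)
    press = 0.0
    pred_t = np.full((n, y_df.shape[1]), np.nan)  # transform scale (global)
    ys_global_logs = [default_log_policy(c) if log_policy is default_log_policy
                      else log_policy(c) for c in y_df.columns]
    y_t = y_df.to_numpy(float).copy()
    for j, lg in enumerate(ys_global_logs):
        if lg:
            y_t[:, j] = np.log(y_t[:, j])

    for k in range(assign.max() + 1):
        test = assign == k
        train = ~test
        if train.sum() <= n_components:
            raise ValidationError(
                f"fold {k}: {train.sum()} training rows cannot support "
                f"{n_components} components"
            )
        model = fit_plsr(x_df.loc[train], y_df.loc[train], n_components,
                         log_policy=log_policy)
        zx = apply_preprocess(x_df.loc[test], model.x_stats)
        zy_hat = zx @ model.b_cross
        zy_true = apply_preprocess(y_df.loc[test], model.y_stats)
        press += float(np.sum((zy_hat - zy_true) ** 2))
        # store on the global transform scale for pooled R^2
        w = zy_hat * model.y_stats.sd + model.y_stats.mean
        pred_t[test] = w

    ss_res = np.sum((pred_t - y_t) ** 2, axis=0)
    ss_tot = np.sum((y_t - y_t.mean(axis=0)) ** 2, axis=0)
    r2 = 1.0 - ss_res / ss_tot
    return CVReport(
        r2_per_output=pd.Series(r2, index=y_df.columns),
        press=press,
        fold_assignment=assign,
        n_components=n_components,
        n_rows=n,
        seed=seed,
    )


def select_components(
    x_df: pd.DataFrame,
    y_df: pd.DataFrame,
    k_folds: int = 5,
    seed: int = 0,
    max_components: Optional[int] = None,
    tol: float = 0.05,
    log_policy: Callable = default_log_policy,
) -> tuple[int, list[CVReport]]:
    """Smallest component count whose PRESS is within (1+tol) of the minimum.

    This realizes the parsimony rule "minimize PRESS while keeping R^2
    high": PRESS is computed for 1..max_components and the smallest count
    not significantly worse than the best is returned.  tol=0 reduces to a
    strict argmin with a smallest-count tie-break.
    """
    n = len(x_df)
    cap = min(x_df.shape[1], n - int(np.ceil(n / k_folds)) - 1)
    if max_components is not None:
        cap = min(cap, max_components)
    reports = []
    for a in range(1, cap + 1):
        try:
            reports.append(press_cv(x_df, y_df, a, k_folds, seed, log_policy))
        except ValidationError:
            break
    if not reports:
        raise ValidationError("could not evaluate any component count")
    press = np.array([r.press for r in reports])
    best = press.min()
    chosen = int(np.flatnonzero(press <= (1.0 + tol) * best)[0]) + 1
    return chosen, reports


def adjusted_r2(r2: float, n_rows: int, n_components: int) -> float:
    """1 - (1-R^2)(n-1)/(n-p-1), with p the number of latent components."""
    if n_rows <= n_components + 1:
        raise ValidationError("need n_rows > n_components + 1")
    return 1.0 - (1.0 - r2) * (n_rows - 1) / (n_rows - n_components - 1)


# ---------------------------------------------------------------------------
# population sensitivity analysis


def compute_sensitivities(
    scale_factors: pd.DataFrame,
    outputs: pd.DataFrame,
    n_components: Optional[int] = None,
) -> pd.DataFrame:
    """Regression coefficients of log-outputs on log-scale-factors.

    Uses the same PLSR machinery (at full rank by default, where PLSR
    coincides with ordinary least squares).  For power-law relations
    y = prod_j p_j^a_j the returned coefficients equal the exponents a_j.
    Outputs that can be non-positive (voltages) enter on their natural scale,
    so their coefficients are semi-elasticities.
    Rows of the result: parameter names; columns: output names.
    """
    if len(scale_factors) != len(outputs):
        raise ValidationError("row mismatch")
    keep = scale_factors.notna().all(axis=1) & outputs.notna().all(axis=1)
    sf = scale_factors.loc[keep]
    out = outputs.loc[keep]
    positive = {c: bool((out[c] > 0).all()) for c in out.columns}
    zx, xs = fit_preprocess(sf, log_policy=lambda c: True)
    zy, ys = fit_preprocess(out, log_policy=lambda c: positive[c])
    a = n_components or min(zx.shape[1], zx.shape[0] - 1)
    b = simpls(zx, zy, a)
    # rescale from z-space to the log/linear transform space
    b_raw = (b / xs.sd[:, None]) * ys.sd[None, :]
    return pd.DataFrame(b_raw, index=sf.columns, columns=out.columns)
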