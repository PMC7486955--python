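"""Predicting per-locus Δ log-likelihood from alignment statistics.

A small feed-forward network (one hidden layer of five units, L2 weight
decay 0.01) is fit over repeated random 75/25 train/test splits, with
features min-max scaled on each training split.  Reported are the mean and
SD of R² (squared Pearson correlation of predicted vs observed on the test
split) and of RMSE on the scaled target, plus permutation-based variable
importance rescaled to sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor

__all__ = ["FEATURES", "ModelReport", "mlp_replicates", "perm_importance"]

FEATURES = ("alignment_length", "undetermined", "pis", "variable_sites",
            "gc_content")


@dataclass
class ModelReport:
    n_replicates: int
    mean_r2: float
    sd_r2: float
    mean_rmse: float
    sd_rmse: float
    importance: pd.Series                   # per feature, sums to 100
    per_replicate: pd.DataFrame
    seed: int
    r2_defined: bool = True
    dropped_features: list = field(default_factory=list)


def _minmax(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)
    return (apply_to - lo) / span


def perm_importance(model, X_test: np.ndarray, y_test: np.ndarray,
                    rng: np.random.Generator, n_permutations: int = 10
                    ) -> np.ndarray:
    """Per-feature permutation importance on one fitted model.

    The mean increase in test RMSE when a feature's test column is shuffled
    (``n_permutations`` shuffles per feature), floored at zero.  Values are
    raw RMSE increases; callers aggregate and rescale.
    """
    base_pred = model.predict(X_test)
    base_rmse = np.sqrt(np.mean((base_pred - y_test) ** 2))
    out = np.zeros(X_test.shape[1])
    for fi in range(X_test.shape[1]):
        inc = 0.0
        for _ in range(n_permutations):
            Xp = X_test.copy()
            Xp[:, fi] = Xp[rng.permutation(len(X_test)), fi]
            pp = model.predict(Xp)
            inc += np.sqrt(np.mean((pp - y_test) ** 2)) - base_rmse
        out[fi] = max(inc / n_permutations, 0.0)
    return out


def mlp_replicates(features: pd.DataFrame, target: Sequence[float],
                   n_replicates: int = 100, train_frac: float = 0.75,
                   seed: int = 0, hidden_units: int = 5, decay: float = 0.01,
                   max_iter: int = 500, n_permutations: int = 10,
                   feature_names: Optional[Sequence[str]] = None
                   ) -> ModelReport:
    """Fit the network over repeated random splits and aggregate.

    Zero-variance features are dropped with a warning; a zero-variance
    target yields an undefined R² (flagged, not raised).
    """
    names = list(feature_names) if feature_names is not None else [
        f for f in FEATURES if f in features.columns]
    if not names:
        names = list(features.columns)
    X = features[names].to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if len(y) != len(X):
        raise ValueError("feature/target length mismatch")
    if len(y) < 20:
        raise ValueError("need at least 20 loci")

    dropped = [n for i, n in enumerate(names) if np.ptp(X[:, i]) == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        keep = [i for i, n in enumerate(names) if n not in dropped]
        X = X[:, keep]
        names = [n for n in names if n not in dropped]
    target_flat = np.ptp(y) == 0

    n = len(y)
    n_train = int(round(train_frac * n))
    rows = []
    importance_acc = np.zeros(len(names))
    rng_master = np.random.default_rng(seed)
    rep_seeds = rng_master.integers(0, 2**31 - 1, size=n_replicates)
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        Xtr = _minmax(X[tr], X[tr])
        Xte = _minmax(X[tr], X[te])
        ytr = _minmax(y[tr, None], y[tr, None]).ravel()
        yte = _minmax(y[tr, None], y[te, None]).ravel()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net = MLPRegressor(hidden_layer_sizes=(hidden_units,),
                               alpha=decay, max_iter=max_iter,
                               solver="lbfgs", random_state=int(rs % 2**31))
            net.fit(Xtr, ytr)
        pred = net.predict(Xte)
        rmse = float(np.sqrt(np.mean((pred - yte) ** 2)))
        if target_flat or np.std(pred) == 0 or np.std(yte) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(pred, yte)[0, 1] ** 2)
        rows.append({"replicate": r, "r2": r2, "rmse": rmse})
        importance_acc += perm_importance(net, Xte, yte, rng, n_permutations)

    per_rep = pd.DataFrame(rows)
    r2s = per_rep["r2"].dropna()
    total = importance_acc.sum()
    if total > 0:
        imp = pd.Series(100.0 * importance_acc / total, index=names)
    else:
        imp = pd.Series(np.full(len(names), 100.0 / len(names)), index=names)
    return ModelReport(
        n_replicates=n_replicates,
        mean_r2=float(r2s.mean()) if len(r2s) else np.nan,
        sd_r2=float(r2s.std(ddof=1)) if len(r2s) > 1 else np.nan,
        mean_rmse=float(per_rep["rmse"].mean()),
        sd_rmse=float(per_rep["rmse"].std(ddof=1)),
        importance=imp,
        per_replicate=per_rep,
        seed=seed,
        r2_defined=not target_flat,
        dropped_features=dropped,
    )
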