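"""PLS regression baseline with sequential backward feature selection.

The selector evaluates, at each step, every subset obtained by removing one
feature, scores it by k-fold cross-validated R² (folds fixed once per run
by the seed, optionally grouped by microplot to avoid replicate-image
leakage), removes the least-contributing feature, and descends to a single
feature; the best subset over the whole trace is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PLSModel",
    "SelectionTrace",
    "fit_pls",
    "predict_pls",
    "backward_select",
    "cv_r2",
    "make_folds",
]


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


@dataclass
class PLSModel:
    """A fitted PLS regressor plus its preprocessing contract."""

    n_components: int
    selected_features: tuple[str, ...]
    pls: PLSRegression
    training_label_source: str = "ytrue"

    @property
    def coefficients(self) -> np.ndarray:
        return np.asarray(self.pls.coef_).ravel()


def fit_pls(
    X,
    y,
    n_components: int = 2,
    feature_names=None,
    training_label_source: str = "ytrue",
) -> PLSModel:
    """Fit a PLS regression (columns standardized internally).

    Constant columns are dropped with a warning; ``n_components`` above the
    rank of the (centered) design is an error.
    """
    Xf = _as_frame(X, feature_names)
    y = np.asarray(y, dtype=float)
    if len(Xf) != len(y):
        raise ValueError("X and y length mismatch")
    if len(Xf) < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")

    sd = Xf.std(axis=0, ddof=0)
    constant = [c for c in Xf.columns if sd[c] == 0.0]
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}", stacklevel=2)
        Xf = Xf.drop(columns=constant)
        if Xf.shape[1] == 0:
            raise ValueError("all feature columns are constant")

    rank = np.linalg.matrix_rank(Xf.to_numpy() - Xf.to_numpy().mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds design rank {rank}")

    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(Xf.to_numpy(), y.reshape(len(y), -1))
    return PLSModel(
        n_components=n_components,
        selected_features=tuple(Xf.columns),
        pls=pls,
        training_label_source=training_label_source,
    )


def predict_pls(model: PLSModel, X, feature_names=None) -> np.ndarray:
    """Predict with name-based column alignment; missing columns are errors."""
    Xf = _as_frame(X, feature_names)
    missing = [c for c in model.selected_features if c not in Xf.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    pred = model.pls.predict(Xf[list(model.selected_features)].to_numpy())
    pred = np.asarray(pred)
    return pred.ravel() if pred.ndim == 2 and pred.shape[1] == 1 else pred


# ---------------------------------------------------------------------------
# Cross-validation and backward selection
# ---------------------------------------------------------------------------


def make_folds(
    n_samples: int, folds: int, seed: int, groups=None
) -> list[np.ndarray]:
    """Fixed fold index arrays; group-aware when ``groups`` is given."""
    if n_samples < folds:
        raise ValueError(f"{n_samples} samples cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    if groups is None:
        idx = rng.permutation(n_samples)
        return [np.sort(part) for part in np.array_split(idx, folds)]
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < folds:
        raise ValueError(f"{len(uniq)} groups cannot fill {folds} folds")
    order = rng.permutation(len(uniq))
    out = []
    for part in np.array_split(order, folds):
        members = set(uniq[part])
        out.append(np.flatnonzero([g in members for g in groups]))
    return out


def cv_r2(
    Xf: pd.DataFrame,
    y: np.ndarray,
    features: tuple[str, ...],
    fold_indices: list[np.ndarray],
    n_components: int = 2,
) -> float:
    """Pooled out-of-fold R² of a PLS fit restricted to ``features``."""
    y = np.asarray(y, dtype=float)
    pred = np.full(len(y), np.nan)
    all_idx = np.arange(len(y))
    for test_idx in fold_indices:
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr = Xf.iloc[train_idx][list(features)]
        k = min(n_components, max(1, len(features)))
        sd = Xtr.std(axis=0, ddof=0)
        keep = tuple(c for c in features if sd[c] > 0)
        if not keep:
            pred[test_idx] = y[train_idx].mean()
            continue
        k = min(k, len(keep))
        model = PLSRegression(n_components=k, scale=True)
        model.fit(Xtr[list(keep)].to_numpy(), y[train_idx])
        pred[test_idx] = model.predict(Xf.iloc[test_idx][list(keep)].to_numpy()).ravel()
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class SelectionTrace:
    """Record of a backward-selection descent.

    ``steps[0]`` scores the full set (nothing removed); each later step
    removes exactly one feature.
    """

    steps: list[tuple[str | None, tuple[str, ...], float]] = field(default_factory=list)

    @property
    def best_set(self) -> tuple[str, ...]:
        _, best, _ = max(self.steps, key=lambda s: s[2])
        return best

    @property
    def best_cv_r2(self) -> float:
        return max(s[2] for s in self.steps)


def backward_select(
    X,
    y,
    folds: int = 5,
    seed: int = 0,
    n_components: int = 2,
    groups=None,
    feature_names=None,
) -> SelectionTrace:
    """Sequential backward feature selection under fixed k-fold CV.

    Descends from the full set to a single feature, removing at each step
    the feature whose removal maximizes the CV R² (ties broken by feature
    order); the best-scoring visited subset wins.
    """
    Xf = _as_frame(X, feature_names)
    y = np.asarray(y, dtype=float)
    if Xf.shape[1] < 2:
        raise ValueError("backward selection needs at least 2 features")
    fold_indices = make_folds(len(y), folds, seed, groups=groups)

    current = tuple(Xf.columns)
    trace = SelectionTrace()
    trace.steps.append((None, current, cv_r2(Xf, y, current, fold_indices, n_components)))
    while len(current) > 1:
        best_score, best_removed, best_subset = -np.inf, None, None
        for name in current:
            subset = tuple(c for c in current if c != name)
            score = cv_r2(Xf, y, subset, fold_indices, n_components)
            if score > best_score:
                best_score, best_removed, best_subset = score, name, subset
        current = best_subset
        trace.steps.append((best_removed, current, best_score))
    return trace
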