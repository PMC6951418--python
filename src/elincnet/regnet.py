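"""Regularized regression classifier fit by cyclical coordinate descent.

The model is a linear score y = b0 + sum_j b_j x_j over region-assay
features, trained on high-confidence class labels coded y = +1 (elincRNA)
and y = -1 (canonical lincRNA). A transcript is called an elincRNA when its
score is positive, canonical when negative. A positive fitted coefficient
marks a feature as contributing to the elincRNA class, a negative one to
the canonical class; the coefficient magnitude is the feature's
*contribution rate*.

The objective is the penalized residual sum of squares

    PRSS(b0, b) = RSS / (2n) + lambda * sum_j [ (1-alpha)/2 * b_j^2 + alpha * |b_j| ]

with mixing parameter alpha in [0, 1]: alpha = 1 is the lasso, alpha = 0
ridge, in between the elastic net. Columns are standardized to zero mean
and unit variance during fitting and coefficients are returned on the
original feature scale; the intercept is never penalized. The minimizer is
found by cyclical coordinate descent with soft-thresholding updates,
sweeping coordinates until the largest coefficient change falls below
``tol``. lambda is chosen on a log-spaced path by k-fold cross-validated
mean squared error, with warm starts along the path; alpha by comparing the
best CV error across a grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix

LABEL_CODES = {"elinc": 1.0, "canonical": -1.0}


class ConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to converge; carries the last iterate."""

    def __init__(self, message: str, model: "RegNetModel"):
        super().__init__(message)
        self.model = model


@dataclass
class RegNetModel:
    """A fitted regularized linear model on the original feature scale."""

    alpha: float
    lam: float
    beta0: float
    betas: pd.Series
    standardization: dict = field(default_factory=dict)
    n_iter: int = 0
    objective_path: list = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.betas.index)

    def nonzero_features(self, tol: float = 1e-10) -> list[str]:
        return [n for n, b in self.betas.items() if abs(b) > tol]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "lambda": self.lam,
            "intercept": self.beta0,
            "coefficients": {k: float(v) for k, v in self.betas.items()},
            "standardization": {
                k: {n: float(x) for n, x in v.items()}
                for k, v in self.standardization.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RegNetModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            alpha=d["alpha"],
            lam=d["lambda"],
            beta0=d["intercept"],
            betas=pd.Series(d["coefficients"], dtype=float),
            standardization=d.get("standardization", {}),
        )


@dataclass(frozen=True)
class PublishedModel:
    """A fixed linear classifier with printed intercept and coefficients."""

    beta0: float
    betas: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.betas.index)


#: The final fitted 7-feature model (lasso on TSS/body epigenetic features
#: of mouse-ESC lincRNAs). Positive coefficients mark the elincRNA class,
#: negative the canonical class.
PUBLISHED_MODEL = PublishedModel(
    beta0=2.0860,
    betas=pd.Series(
        {
            "TSS_DNAme": 5.79,
            "TSS_H3K4me1": 3.16,
            "Body_DNAme": 0.53,
            "Body_H3K122ac": 0.46,
            "Body_H3K36me3": -5.17,
            "TSS_H3K9ac": -4.13,
            "TSS_H3K4me3": -0.87,
        }
    ),
)


@dataclass
class LambdaPath:
    """A decreasing lambda grid with cross-validated MSE per value."""

    lambdas: np.ndarray
    cv_mse: np.ndarray
    chosen: float
    alpha: float

    @property
    def best_mse(self) -> float:
        return float(self.cv_mse.min())


# ---------------------------------------------------------------------------
# Core numerics
# ---------------------------------------------------------------------------


def soft_threshold(z: float, gamma: float) -> float:
    """sign(z) * max(|z| - gamma, 0); the lasso coordinate update."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return np.sign(z) * max(abs(z) - gamma, 0.0)


def response_vector(labels: Sequence[str]) -> np.ndarray:
    """Code class labels as +1 (elinc) / -1 (canonical)."""
    try:
        return np.array([LABEL_CODES[l] for l in labels], dtype=float)
    except KeyError as e:
        raise ValueError(f"unknown class label {e.args[0]!r}") from None


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, FeatureMatrix):
        return X.to_numpy(), X.feature_names
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def prss(
    betas: np.ndarray,
    beta0: float,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
) -> float:
    """Penalized residual sum of squares: RSS/(2n) + lambda * P_alpha(beta)."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    betas = np.asarray(betas, dtype=float)
    r = y - beta0 - X @ betas
    penalty = np.sum(0.5 * (1 - alpha) * betas**2 + alpha * np.abs(betas))
    return float(r @ r / (2 * len(y)) + lam * penalty)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    if np.any(scales == 0):
        j = int(np.argmin(scales))
        raise ValueError(f"feature column {j} is constant; cannot standardize")
    return (X - means) / scales, means, scales


def fit(
    X,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    beta_init: np.ndarray | None = None,
) -> RegNetModel:
    """Minimize the PRSS by cyclical coordinate descent.

    Fitting happens on standardized columns with a centered response; the
    reported intercept and coefficients are back on the original feature
    scale. Convergence is declared when the largest single-coordinate update
    in a full sweep is below ``tol`` (standardized scale); non-convergence
    raises :class:`ConvergenceError` carrying the last iterate.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Xarr, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xarr.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if len(y) != n:
        raise ValueError("X and y have different lengths")

    Xs, means, scales = _standardize(Xarr)
    ymean = y.mean()
    yc = y - ymean

    b = np.zeros(p) if beta_init is None else np.array(beta_init, dtype=float)
    # covariance (Gram) updates: each coordinate step costs O(p), not O(n)
    G = Xs.T @ Xs / n  # unit diagonal on standardized columns
    c = Xs.T @ yc / n
    yvar = float(yc @ yc) / n
    l1 = lam * alpha
    denom = 1.0 + lam * (1.0 - alpha)

    def objective(bvec: np.ndarray) -> float:
        rss_over_n = yvar - 2.0 * float(c @ bvec) + float(bvec @ G @ bvec)
        penalty = np.sum(0.5 * (1 - alpha) * bvec**2 + alpha * np.abs(bvec))
        return 0.5 * rss_over_n + lam * penalty

    def sweep_once(indices) -> float:
        max_delta = 0.0
        for j in indices:
            old = b[j]
            z = c[j] - float(G[j] @ b) + old
            new = soft_threshold(z, l1) / denom
            if new != old:
                b[j] = new
                max_delta = max(max_delta, abs(new - old))
        return max_delta

    objective_path = []
    n_iter = 0
    all_indices = range(p)
    for sweep in range(max_iter):
        n_iter = sweep + 1
        max_delta = sweep_once(all_indices)
        objective_path.append(objective(b))
        if max_delta < tol:
            break
        # iterate the active set to convergence before the next full sweep
        active = np.flatnonzero(b)
        while len(active) and n_iter < max_iter:
            n_iter += 1
            if sweep_once(active) < tol:
                break
    else:
        model = _unstandardized_model(
            alpha, lam, b, names, means, scales, ymean, n_iter, objective_path
        )
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps", model
        )
    return _unstandardized_model(
        alpha, lam, b, names, means, scales, ymean, n_iter, objective_path
    )


def _unstandardized_model(
    alpha, lam, b_std, names, means, scales, ymean, n_iter, objective_path
) -> RegNetModel:
    betas = b_std / scales
    beta0 = ymean - float(means @ betas)
    return RegNetModel(
        alpha=alpha,
        lam=lam,
        beta0=beta0,
        betas=pd.Series(betas, index=names),
        standardization={
            "mean": pd.Series(means, index=names),
            "scale": pd.Series(scales, index=names),
        },
        n_iter=n_iter,
        objective_path=objective_path,
    )


# ---------------------------------------------------------------------------
# Lambda path and cross-validated selection
# ---------------------------------------------------------------------------


def lambda_grid(
    X, y: np.ndarray, alpha: float, n_lambda: int = 100, min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max (all-zero model) down.

    lambda_max = max_j |x_j' y_c| / (n * alpha) on standardized columns; for
    small alpha the divisor is floored at 0.001 so the ridge grid is finite.
    """
    Xarr, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(Xarr)
    yc = y - y.mean()
    lam_max = np.abs(Xs.T @ yc).max() / (len(y) * max(alpha, 1e-3))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Fold assignment balanced within each class; returns test-index arrays.

    Class-stratified when y takes few distinct values (the +1/-1 coding);
    a plain shuffled split for continuous responses.
    """
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    uniques = np.unique(y)
    groups = [np.flatnonzero(y == u) for u in uniques] if len(uniques) <= 2 else [
        np.arange(len(y))
    ]
    for idx in groups:
        idx = idx[rng.permutation(len(idx))]
        assignment[idx] = np.arange(len(idx)) % k
    return [np.flatnonzero(assignment == f) for f in range(k)]


def _path_fits(Xarr, y, alpha, lambdas, tol, max_iter) -> list[RegNetModel]:
    """Warm-started fits along a decreasing lambda grid."""
    models = []
    Xs, means, scales = _standardize(Xarr)
    b = np.zeros(Xarr.shape[1])
    for lam in lambdas:
        m = fit(Xarr, y, alpha, lam, tol=tol, max_iter=max_iter, beta_init=b)
        b = (m.betas.to_numpy() * scales).astype(float)
        models.append(m)
    return models


def lambda_path_cv(
    X,
    y: np.ndarray,
    alpha: float,
    k: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    min_ratio: float = 1e-4,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> LambdaPath:
    """Choose lambda by k-fold cross-validated mean squared error.

    The grid is computed on the full data; each training fold is fit along
    the whole grid with warm starts, held-out squared errors are pooled per
    lambda, and the lambda minimizing CV MSE is chosen (ties break to the
    larger lambda). Folds are stratified by class so no fold is single-class.
    """
    Xarr, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if len(y) < k:
        raise ValueError(f"need at least k={k} observations")
    lambdas = lambda_grid(Xarr, y, alpha, n_lambda, min_ratio)
    folds = _stratified_folds(y, k, seed)
    sse = np.zeros(len(lambdas))
    for test_idx in folds:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        models = _path_fits(
            Xarr[train_mask], y[train_mask], alpha, lambdas, tol, max_iter
        )
        Xte, yte = Xarr[test_idx], y[test_idx]
        for i, m in enumerate(models):
            pred = m.beta0 + Xte @ m.betas.to_numpy()
            sse[i] += float(np.sum((yte - pred) ** 2))
    cv_mse = sse / len(y)
    chosen = float(lambdas[int(np.argmin(cv_mse))])  # grid decreasing: tie -> larger
    return LambdaPath(lambdas=lambdas, cv_mse=cv_mse, chosen=chosen, alpha=alpha)


def select_alpha(
    X,
    y: np.ndarray,
    alphas: Sequence[float],
    k: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    **kwargs,
) -> tuple[float, LambdaPath]:
    """Pick the mixing parameter whose best CV MSE is minimal.

    All alphas share the same folds (same seed) so the comparison is paired;
    ties break toward the larger alpha (sparser model).
    """
    alphas = list(alphas)
    if not alphas:
        raise ValueError("empty alpha grid")
    if any(not (0.0 <= a <= 1.0) for a in alphas):
        raise ValueError("alphas must lie in [0, 1]")
    best: tuple[float, LambdaPath] | None = None
    for a in sorted(alphas):
        path = lambda_path_cv(X, y, a, k=k, n_lambda=n_lambda, seed=seed, **kwargs)
        if best is None or path.best_mse <= best[1].best_mse:
            best = (a, path)
    return best


def train(
    X,
    y: np.ndarray,
    alpha: float | str = "auto",
    alphas: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
    k: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> tuple[RegNetModel, LambdaPath]:
    """Full training: select (alpha,) lambda by CV, then refit on all data."""
    if alpha == "auto":
        a, path = select_alpha(
            X, y, alphas, k=k, n_lambda=n_lambda, seed=seed, tol=tol, max_iter=max_iter
        )
    else:
        a = float(alpha)
        path = lambda_path_cv(
            X, y, a, k=k, n_lambda=n_lambda, seed=seed, tol=tol, max_iter=max_iter
        )
    model = fit(X, y, a, path.chosen, tol=tol, max_iter=max_iter)
    return model, path


# ---------------------------------------------------------------------------
# Scoring and classification
# ---------------------------------------------------------------------------


def _align(model: RegNetModel | PublishedModel, x) -> np.ndarray:
    names = model.feature_names
    if isinstance(x, pd.DataFrame):
        missing = [n for n in names if n not in x.columns]
        if missing:
            raise KeyError(f"feature vector missing {missing}")
        return x[names].to_numpy(dtype=float)
    if isinstance(x, (pd.Series, Mapping)):
        x = pd.Series(x, dtype=float)
        missing = [n for n in names if n not in x.index]
        if missing:
            raise KeyError(f"feature vector missing {missing}")
        return x[names].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != len(names):
        raise ValueError(
            f"feature vector length {x.shape[-1]} != model size {len(names)}"
        )
    return x


def score(model: RegNetModel | PublishedModel, x) -> float | np.ndarray:
    """Linear score b0 + sum_j b_j x_j; accepts a vector, Series, dict,
    DataFrame or FeatureMatrix (aligned by feature name where named)."""
    if isinstance(x, FeatureMatrix):
        x = x.values
    xa = _align(model, x)
    out = model.beta0 + xa @ model.betas.to_numpy()
    return float(out) if np.ndim(out) == 0 else out


def classify(model: RegNetModel | PublishedModel, x) -> str | np.ndarray:
    """Sign rule: elinc if score > 0, canonical if < 0, indeterminate at 0."""
    s = score(model, x)
    def one(v: float) -> str:
        return "elinc" if v > 0 else ("canonical" if v < 0 else "indeterminate")
    if np.ndim(s) == 0:
        return one(float(s))
    return np.array([one(float(v)) for v in np.asarray(s)])
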