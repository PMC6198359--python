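"""The penalized linear age clock.

The clock is an elastic-net regression of chronological age (years) on
region mean beta values: minimize

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2
        + lambda * [ alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2 ]

where ``alpha`` in [0, 1] mixes the lasso (sparsity) and ridge
(shrinkage) penalties and ``lambda`` scales the overall penalty —
the glmnet parameterization. Features are standardized to unit variance
during optimization and coefficients are reported back on the original
beta scale, so model files are interpretable as years-per-unit-beta.

Coordinate descent is delegated to scikit-learn (``ElasticNet`` /
``enet_path``, which minimize exactly the objective above after the
``alpha``/``lambda`` name swap); the unpenalized limit is solved by least
squares directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, enet_path

from ._folds import kfold_indices
from .exceptions import InputError, ValidationError
from .regions import RegionFeatureMatrix

#: convergence tolerance on the (scaled) coordinate-descent dual gap
TOL = 1e-7
#: looser tolerance for the inner CV paths used only to rank lambdas
CV_TOL = 1e-4
MAX_ITER = 100_000


@dataclass
class ClockModel:
    """A fitted germ-line age clock.

    ``coefficients`` are years per unit beta on the original feature
    scale; ``feature_means`` are training-set feature means used to
    impute features missing at prediction time.
    """

    region_names: list[str]
    coefficients: np.ndarray
    intercept: float
    alpha: float
    lam: float
    feature_means: np.ndarray
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        n = len(self.region_names)
        if len(self.coefficients) != n or len(self.feature_means) != n:
            raise ValidationError(
                f"{n} regions but {len(self.coefficients)} coefficients / "
                f"{len(self.feature_means)} feature means"
            )
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0.0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")

    @property
    def nonzero_regions(self) -> list[str]:
        return [r for r, c in zip(self.region_names, self.coefficients) if c != 0.0]

    def predict(self, features) -> pd.Series:
        return predict_age(self, features)


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, RegionFeatureMatrix):
        return features.values
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError(f"expected RegionFeatureMatrix or DataFrame, got {type(features)}")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale to unit (population) variance; constant columns get scale 1."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0.0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def elastic_net_objective(X: np.ndarray, y: np.ndarray, coef: np.ndarray,
                          intercept: float, alpha: float, lam: float) -> float:
    """Value of the penalized least-squares objective (for audits and oracles)."""
    resid = y - intercept - X @ coef
    n = len(y)
    penalty = lam * (alpha * np.abs(coef).sum() + 0.5 * (1.0 - alpha) * (coef ** 2).sum())
    return float(0.5 * resid @ resid / n + penalty)


def fit_elastic_net(
    features,
    ages: Sequence[float],
    alpha: float = 0.5,
    lam: float = 0.0,
    seed: int | None = None,
    provenance: dict | None = None,
) -> ClockModel:
    """Fit the elastic-net age regression at a fixed penalty strength.

    Deterministic for fixed inputs (cyclic coordinate descent, no random
    feature selection). ``lam = 0`` falls back to an exact least-squares
    solve (minimum-norm when the problem is rank deficient).
    """
    frame = _as_frame(features)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(ages, dtype=float)
    if X.shape[0] != len(y):
        raise InputError(f"{X.shape[0]} samples in features but {len(y)} ages")
    if X.shape[0] < 2:
        raise InputError("need at least 2 samples to fit")
    if not np.isfinite(y).all():
        raise ValidationError("ages contain non-finite values")
    if not np.isfinite(X).all():
        raise ValidationError(
            "feature matrix contains missing/non-finite entries; impute upstream"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if lam < 0.0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")

    Xs, mean, scale = _standardize(X)
    if lam == 0.0:
        yc = y - y.mean()
        coef_std, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
        intercept_std = float(y.mean())  # Xs has zero column means
    else:
        en = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True,
                        tol=TOL, max_iter=MAX_ITER, selection="cyclic")
        en.fit(Xs, y)
        coef_std = en.coef_
        intercept_std = float(en.intercept_)

    coef = coef_std / scale
    intercept = intercept_std - float((coef_std * mean / scale).sum())
    return ClockModel(
        region_names=list(frame.columns),
        coefficients=coef,
        intercept=intercept,
        alpha=alpha,
        lam=lam,
        feature_means=mean,
        seed=seed,
        provenance=provenance or {},
    )


def default_lambda_grid(features, ages, alpha: float = 0.5, n_lambdas: int = 30,
                        ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max (all coefficients zero) downward."""
    frame = _as_frame(features)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(ages, dtype=float)
    Xs, _, _ = _standardize(X)
    yc = y - y.mean()
    # below lambda_max = max|X's yc| / (n * alpha) every coefficient is zero
    lam_max = float(np.abs(Xs.T @ yc).max() / (len(y) * max(alpha, 1e-3)))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def select_lambda_cv(
    features,
    ages: Sequence[float],
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    k: int = 10,
    seed: int = 0,
    rule: str = "min",
) -> tuple[float, pd.DataFrame]:
    """Choose the penalty strength by k-fold cross-validated squared error.

    Returns the selected lambda and the CV curve (mean and standard error
    of out-of-fold MSE per grid value). ``rule='min'`` takes the grid
    minimum (ties broken toward the larger, more parsimonious lambda);
    ``rule='1se'`` takes the largest lambda within one standard error of
    the minimum. Fold assignment is a deterministic function of ``seed``.
    """
    frame = _as_frame(features)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(ages, dtype=float)
    n = len(y)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(frame, y, alpha=alpha)
    lambdas = np.unique(np.asarray(lambda_grid, dtype=float))[::-1]  # descending
    if lambdas.size == 0:
        raise InputError("lambda grid is empty")
    if (lambdas < 0).any():
        raise ValidationError("lambda grid contains negative values")

    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, k, rng)
    sq_err = np.full((n, lambdas.size), np.nan)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        Xtr, ytr = X[train_mask], y[train_mask]
        Xs, mean, scale = _standardize(Xtr)
        yc_mean = ytr.mean()
        pos = lambdas > 0
        preds = np.empty((len(test_idx), lambdas.size))
        Xts = (X[test_idx] - mean) / scale
        if pos.any():
            # one warm-started coordinate-descent path over the whole grid
            _, coefs, _ = enet_path(Xs, ytr - yc_mean, l1_ratio=alpha,
                                    alphas=lambdas[pos],
                                    tol=CV_TOL, max_iter=MAX_ITER)
            preds[:, pos] = yc_mean + Xts @ coefs
        if (~pos).any():
            coef0, *_ = np.linalg.lstsq(Xs, ytr - yc_mean, rcond=None)
            preds[:, ~pos] = (yc_mean + Xts @ coef0)[:, None]
        sq_err[test_idx, :] = (preds - y[test_idx][:, None]) ** 2

    mean_mse = sq_err.mean(axis=0)
    # SE of the CV estimate from per-fold means, the glmnet convention
    fold_means = np.array([[sq_err[idx, j].mean() for j in range(lambdas.size)]
                           for idx in folds])
    se_mse = fold_means.std(axis=0, ddof=1) / np.sqrt(len(folds))
    curve = pd.DataFrame({"lambda": lambdas, "mean_mse": mean_mse, "se_mse": se_mse})

    best = int(np.argmin(mean_mse))
    ties = np.flatnonzero(mean_mse == mean_mse[best])
    best = int(ties[0])  # lambdas are descending: first tie = largest lambda
    if rule == "min":
        lam_best = float(lambdas[best])
    elif rule == "1se":
        within = np.flatnonzero(mean_mse <= mean_mse[best] + se_mse[best])
        lam_best = float(lambdas[int(within[0])])
    else:
        raise ValueError(f"unknown rule {rule!r}; expected 'min' or '1se'")
    return lam_best, curve


def predict_age(model: ClockModel, features) -> pd.Series:
    """Predict ages (years) for a feature matrix, matching features by name.

    Features absent from the supplied matrix, and missing entries within
    it, are imputed with the model's stored training means. Predictions
    are the plain affine map — no clipping.
    """
    frame = _as_frame(features)
    overlap = [r for r in model.region_names if r in frame.columns]
    if not overlap:
        raise InputError(
            "no overlap between supplied features and the model's regions"
        )
    aligned = frame.reindex(columns=model.region_names)
    means = pd.Series(model.feature_means, index=model.region_names)
    aligned = aligned.fillna(means)
    pred = model.intercept + aligned.to_numpy(dtype=float) @ model.coefficients
    return pd.Series(pred, index=frame.index, name="predicted_age")
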