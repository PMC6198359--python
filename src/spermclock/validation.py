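"""Repeated k-fold cross-validation, stability selection, and design comparison.

The training protocol is 10-fold cross-validation repeated 10 times on
freshly shuffled partitions. Within every fold the penalty strength is
re-selected by an inner CV on the training portion only, so held-out
samples never influence any modelling choice. Feature stability is the
fraction of fold-models in which a region receives a nonzero elastic-net
coefficient; regions at or above the threshold (default 80%) form the
"optimized" region list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._folds import kfold_indices
from .exceptions import InputError
from .model import ClockModel, fit_elastic_net, predict_age, select_lambda_cv


def _squared_pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def make_cv_folds(
    sample_ids: Sequence[str], k: int, repeats: int, seed: int
) -> list[list[np.ndarray]]:
    """Per-repeat partitions of sample positions into k near-equal folds.

    Each repeat is an independent shuffle; fold sizes differ by at most
    one. Deterministic in ``seed``. Returns, for each repeat, a list of k
    arrays of positional indices into ``sample_ids``.
    """
    n = len(sample_ids)
    rng = np.random.default_rng(seed)
    return [kfold_indices(n, k, rng) for _ in range(repeats)]


@dataclass
class FoldRecord:
    """One fold-model from the repeated-CV procedure."""

    design: str
    repeat_index: int  # 1-based
    fold_index: int    # 1-based
    lam: float
    train_r2: float
    test_r2: float
    train_ids: list[str]
    test_ids: list[str]
    model: ClockModel

    @property
    def nonzero_features(self) -> list[str]:
        return self.model.nonzero_regions


@dataclass
class CVResult:
    """All fold-models plus pooled out-of-fold predictions per repeat."""

    design: str
    k: int
    repeats: int
    seed: int
    ages: pd.Series
    records: list[FoldRecord]
    oof_predictions: pd.DataFrame  # samples x repeats

    def per_repeat_test_r2(self) -> np.ndarray:
        """Squared correlation of pooled out-of-fold predictions per repeat."""
        actual = self.ages.to_numpy(dtype=float)
        return np.array([
            _squared_pearson(self.oof_predictions.iloc[:, r].to_numpy(), actual)
            for r in range(self.repeats)
        ])

    def per_repeat_train_r2(self) -> np.ndarray:
        """Mean training-set squared correlation over each repeat's folds."""
        out = np.zeros(self.repeats)
        for rec in self.records:
            out[rec.repeat_index - 1] += rec.train_r2
        return out / self.k

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "design": [r.design for r in self.records],
            "repeat": [r.repeat_index for r in self.records],
            "fold": [r.fold_index for r in self.records],
            "lambda": [r.lam for r in self.records],
            "train_r2": [r.train_r2 for r in self.records],
            "test_r2": [r.test_r2 for r in self.records],
            "n_nonzero": [len(r.nonzero_features) for r in self.records],
        })


def _inner_seed(seed: int, repeat: int, fold: int) -> int:
    # deterministic child seed per (repeat, fold), independent of iteration order
    return int(np.random.default_rng([seed, repeat, fold]).integers(2**31))


def run_repeated_cv(
    features,
    ages: Sequence[float],
    design: str = "regional",
    alpha: float = 0.5,
    lambda_grid: Sequence[float] | None = None,
    lambda_rule: str = "min",
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    inner_k: int = 10,
) -> CVResult:
    """Run the repeated k-fold CV protocol for one feature design.

    For every repeat x fold: select lambda by inner CV on the training
    portion, fit there, and predict the held-out fold. Per-repeat test
    r-squared is computed on the repeat's pooled out-of-fold predictions.
    """
    from .model import _as_frame  # late import: avoid polluting module surface

    frame = _as_frame(features)
    y = pd.Series(np.asarray(ages, dtype=float), index=frame.index, name="age")
    n = len(y)
    folds_by_repeat = make_cv_folds(list(frame.index), k, repeats, seed)

    records: list[FoldRecord] = []
    oof = pd.DataFrame(np.nan, index=frame.index,
                       columns=[f"repeat_{r + 1}" for r in range(repeats)])
    for r, folds in enumerate(folds_by_repeat, start=1):
        for f, test_idx in enumerate(folds, start=1):
            train_mask = np.ones(n, dtype=bool)
            train_mask[test_idx] = False
            X_train, y_train = frame.iloc[train_mask], y.iloc[train_mask]
            X_test, y_test = frame.iloc[test_idx], y.iloc[test_idx]
            lam, _ = select_lambda_cv(
                X_train, y_train, alpha=alpha, lambda_grid=lambda_grid,
                k=min(inner_k, len(y_train)), seed=_inner_seed(seed, r, f),
                rule=lambda_rule,
            )
            fold_model = fit_elastic_net(X_train, y_train, alpha=alpha, lam=lam,
                                         seed=seed)
            train_pred = predict_age(fold_model, X_train)
            test_pred = predict_age(fold_model, X_test)
            oof.iloc[test_idx, r - 1] = test_pred.to_numpy()
            records.append(FoldRecord(
                design=design,
                repeat_index=r,
                fold_index=f,
                lam=lam,
                train_r2=_squared_pearson(train_pred.to_numpy(), y_train.to_numpy()),
                test_r2=_squared_pearson(test_pred.to_numpy(), y_test.to_numpy()),
                train_ids=list(X_train.index),
                test_ids=list(X_test.index),
                model=fold_model,
            ))
    return CVResult(design=design, k=k, repeats=repeats, seed=seed,
                    ages=y, records=records, oof_predictions=oof)


@dataclass
class StabilityReport:
    """Per-region inclusion frequency across fold-models and the selected set."""

    inclusion_frequency: dict[str, float]
    threshold: float
    selected: list[str]
    n_models: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "region": list(self.inclusion_frequency),
            "inclusion_frequency": list(self.inclusion_frequency.values()),
        })
        frame["selected"] = frame["region"].isin(self.selected)
        return frame.sort_values(
            ["inclusion_frequency", "region"], ascending=[False, True]
        ).reset_index(drop=True)


def compute_feature_stability(cv: CVResult, threshold: float = 0.80) -> StabilityReport:
    """Inclusion frequency = fraction of fold-models with a nonzero coefficient.

    A region is selected when its frequency is greater than or equal to
    the threshold (boundary inclusive). The denominator is every
    fold-model across every repeat (k x repeats).
    """
    if not cv.records:
        raise InputError("CV result contains no fold-models")
    counts: dict[str, int] = {}
    all_regions: list[str] = []
    seen: set[str] = set()
    for rec in cv.records:
        for region in rec.model.region_names:
            if region not in seen:
                seen.add(region)
                all_regions.append(region)
                counts[region] = 0
        for region in rec.nonzero_features:
            counts[region] += 1
    n_models = len(cv.records)
    freq = {region: counts[region] / n_models for region in all_regions}
    selected = sorted([r for r, f in freq.items() if f >= threshold])
    return StabilityReport(inclusion_frequency=freq, threshold=threshold,
                           selected=selected, n_models=n_models)


def two_sample_ttest(a: Sequence[float], b: Sequence[float],
                     welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t-test (Student pooled by default, Welch optional).

    Shared statistical engine for design comparison and group
    age-acceleration tests. Degenerate case: both groups constant with
    equal means gives (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("t-test needs at least 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def compare_designs_ttest(r2_a: Sequence[float], r2_b: Sequence[float],
                          welch: bool = False) -> tuple[float, float]:
    """Compare two designs' per-repeat r-squared lists by two-tailed t-test."""
    return two_sample_ttest(r2_a, r2_b, welch=welch)
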