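"""Accuracy metrics and technical-replicate precision.

MAE is in years, MAPE in percent of chronological age, and r-squared is
the squared Pearson correlation of predicted against actual age (which
equals the r-squared of the least-squares line of predicted on actual).
Replicate precision summarizes, per individual, the sample standard
deviation of predicted age across technical replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    mae: float                 # years
    mape: float | None         # percent; None when any actual age <= 0
    r2: float
    n: int
    slope: float               # predicted-on-actual regression
    intercept: float
    regression_p: float        # p-value of the slope test
    mape_warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "mae": self.mae, "mape": self.mape, "r2": self.r2, "n": self.n,
            "slope": self.slope, "intercept": self.intercept,
            "regression_p": self.regression_p,
        }


def compute_metrics(predicted: Sequence[float], actual: Sequence[float]) -> EvaluationReport:
    """MAE, MAPE, r-squared and the predicted-on-actual regression line."""
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape:
        raise InputError(f"length mismatch: {pred.shape} predicted vs {act.shape} actual")
    if len(pred) < 2:
        raise InputError("need at least 2 (predicted, actual) pairs")
    mae = float(np.mean(np.abs(pred - act)))
    mape: float | None
    warning = None
    if (act <= 0).any():
        mape = None
        warning = "MAPE undefined: non-positive actual ages present"
        logger.warning(warning)
    else:
        mape = float(100.0 * np.mean(np.abs(pred - act) / act))
    if act.std() == 0.0 or pred.std() == 0.0:
        # degenerate regression: no variance to explain
        r2, slope, intercept, p = 0.0, 0.0, float(pred.mean()), 1.0
        if np.array_equal(pred, act):
            r2 = 1.0
    else:
        fit = stats.linregress(act, pred)
        r2 = float(fit.rvalue ** 2)
        slope, intercept, p = float(fit.slope), float(fit.intercept), float(fit.pvalue)
    return EvaluationReport(mae=mae, mape=mape, r2=r2, n=len(pred),
                            slope=slope, intercept=intercept, regression_p=p,
                            mape_warning=warning)


@dataclass
class ReplicatePrecisionReport:
    per_individual_sd: dict[str, float]    # years
    per_individual_mean: dict[str, float]  # years
    summary_sd: float                      # mean of per-individual SDs, years
    n_individuals: int
    n_replicates: int
    excluded_singletons: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate_group": list(self.per_individual_sd),
            "mean_predicted_age": list(self.per_individual_mean.values()),
            "sd_predicted_age": list(self.per_individual_sd.values()),
        })


def replicate_precision(predicted: pd.Series,
                        replicate_group: pd.Series) -> ReplicatePrecisionReport:
    """Per-individual SD of predicted age across technical replicates.

    ``predicted`` and ``replicate_group`` are aligned per-sample series.
    Groups with a single member are excluded with a warning; the summary
    is the unweighted mean of per-group sample SDs (n-1 denominator).
    """
    frame = pd.DataFrame({"pred": predicted, "group": replicate_group}).dropna(subset=["group"])
    if frame.empty:
        raise InputError("no replicate groups present")
    sizes = frame.groupby("group").size()
    singletons = sorted(str(g) for g in sizes[sizes < 2].index)
    if singletons:
        logger.warning("excluding singleton replicate groups: %s", singletons[:10])
    usable = frame[frame["group"].isin(sizes[sizes >= 2].index)]
    if usable.empty:
        raise InputError("no replicate group has >= 2 members")
    grouped = usable.groupby("group")["pred"]
    sds = grouped.std(ddof=1)
    means = grouped.mean()
    return ReplicatePrecisionReport(
        per_individual_sd={str(g): float(v) for g, v in sds.items()},
        per_individual_mean={str(g): float(v) for g, v in means.items()},
        summary_sd=float(sds.mean()),
        n_individuals=int(len(sds)),
        n_replicates=int(len(usable)),
        excluded_singletons=singletons,
    )
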