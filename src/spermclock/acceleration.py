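"""Germ-line age acceleration and exposure-group comparison.

Age acceleration is the signed percent difference between predicted and
chronological age, 100 * (predicted - chronological) / chronological:
positive values mean the germ line looks older than the calendar says.
Group comparisons (e.g. smokers vs never smokers, optionally restricted
to men under a given age) use the same two-sample t-test engine as the
design comparisons, two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError
from .validation import two_sample_ttest


def age_acceleration(predicted, actual):
    """Signed percent age acceleration per sample.

    Accepts scalars or aligned vectors; chronological age must be
    positive. Returns the same shape as the input.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if (act <= 0).any():
        raise InputError("age acceleration undefined for non-positive chronological age")
    accel = 100.0 * (pred - act) / act
    if isinstance(predicted, pd.Series):
        return pd.Series(accel, index=predicted.index, name="acceleration_pct")
    if np.isscalar(predicted) or pred.ndim == 0:
        return float(accel)
    return accel


@dataclass
class AccelerationReport:
    group_a: str
    group_b: str
    mean_a: float          # percent
    mean_b: float          # percent
    n_a: int
    n_b: int
    t: float
    p: float               # two-tailed
    age_max: float | None  # strict upper age filter applied, if any
    welch: bool = False

    @property
    def difference(self) -> float:
        """Mean acceleration difference, group_a minus group_b (percent)."""
        return self.mean_a - self.mean_b

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a, "group_b": self.group_b,
            "mean_acceleration_a_pct": self.mean_a,
            "mean_acceleration_b_pct": self.mean_b,
            "difference_pct": self.difference,
            "n_a": self.n_a, "n_b": self.n_b,
            "t": self.t, "p": self.p, "age_max": self.age_max,
        }


def group_acceleration_test(
    acceleration: pd.Series,
    metadata: pd.DataFrame,
    groups: tuple[str, str] = ("smoker", "never"),
    age_max: float | None = None,
    welch: bool = False,
) -> AccelerationReport:
    """Compare percent age acceleration between two smoking-status groups.

    ``acceleration`` is indexed by sample ID; ``metadata`` carries
    ``sample_id``, ``age`` and ``smoking_status``. When ``age_max`` is
    given, only samples strictly younger than it are kept before the
    two-tailed t-test.
    """
    meta = metadata.set_index("sample_id").loc[acceleration.index]
    keep = pd.Series(True, index=acceleration.index)
    if age_max is not None:
        keep &= meta["age"] < age_max
    values = {}
    for label in groups:
        sel = keep & (meta["smoking_status"] == label)
        vals = acceleration[sel].to_numpy(dtype=float)
        if len(vals) == 0:
            flt = f" under age filter '< {age_max}'" if age_max is not None else ""
            raise InputError(f"group {label!r} is empty{flt}")
        values[label] = vals
    a, b = values[groups[0]], values[groups[1]]
    t, p = two_sample_ttest(a, b, welch=welch)
    return AccelerationReport(
        group_a=groups[0], group_b=groups[1],
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        n_a=len(a), n_b=len(b), t=t, p=p, age_max=age_max, welch=welch,
    )
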