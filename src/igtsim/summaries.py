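"""Block-trajectory analytics.

Power-function fits to block preferences (the exponent is the rate of
change of preference), quartile-based subgrouping of a cohort, and
paired correlation/RMSE between two sets of block means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .agent import ParameterError

__all__ = [
    "PowerFit",
    "SubgroupAssignment",
    "BlockCorrelation",
    "fit_power",
    "quartile_subgroups",
    "correlate_blocks",
    "subgroup_block_means",
]

# Zeros are clamped to this before the power fit so the exponent stays
# defined for subjects who never choose an advantageous deck.
_POWER_CLAMP = 1e-6


@dataclass
class PowerFit:
    """``y = a * x**b`` fit: amplitude, rate-of-change exponent, residual RMSE."""

    a: float
    b: float
    rmse: float

    @property
    def ok(self) -> bool:
        return bool(np.isfinite(self.a) and np.isfinite(self.b))


def _power(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.power(x, b)


def fit_power(
    block_prefs: Sequence[float], x: Sequence[float] | None = None
) -> PowerFit:
    """Nonlinear least-squares fit of ``y = a * x**b`` to block preferences.

    ``x`` defaults to the 1-based block indices. Initialized at
    ``a = y[0], b = 0``; zeros in ``y`` are clamped to 1e-6 so the model
    stays defined. Optimizer failure is reported as NaN coefficients
    rather than raised.
    """
    y = np.asarray(block_prefs, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ParameterError(f"need at least 3 block values, got shape {y.shape}")
    if np.any(y < 0):
        raise ParameterError("block preferences must be non-negative")
    x = np.arange(1, y.size + 1, dtype=float) if x is None else np.asarray(x, float)
    if x.shape != y.shape:
        raise ParameterError("x and block_prefs must have the same length")
    y = np.maximum(y, _POWER_CLAMP)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_power, x, y, p0=(y[0], 0.0), maxfev=10_000)
    except RuntimeError:
        return PowerFit(a=float("nan"), b=float("nan"), rmse=float("nan"))
    a, b = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((_power(x, a, b) - y) ** 2)))
    return PowerFit(a=a, b=b, rmse=rmse)


@dataclass(frozen=True)
class SubgroupAssignment:
    """Subject's overall preference and its quartile subgroup (Q1/Q2/Q3)."""

    subject_id: str
    overall_preference: float
    subgroup: str


def quartile_subgroups(
    overall_prefs: Sequence[float],
    subject_ids: Sequence[str] | None = None,
) -> list[SubgroupAssignment]:
    """Partition a cohort by overall advantageous-choice proportion.

    Q1: below the first quartile; Q3: at or above the third quartile;
    Q2: between. Quartiles use linear interpolation within the cohort
    being partitioned; with zero spread everybody satisfies the Q3 rule.
    """
    prefs = np.asarray(overall_prefs, dtype=float)
    if prefs.size < 4:
        raise ParameterError(f"need at least 4 subjects, got {prefs.size}")
    if subject_ids is None:
        subject_ids = [f"s{i + 1:03d}" for i in range(prefs.size)]
    if len(subject_ids) != prefs.size:
        raise ParameterError("subject_ids and overall_prefs lengths differ")
    q25, q75 = np.quantile(prefs, [0.25, 0.75])
    out = []
    for sid, p in zip(subject_ids, prefs):
        if p >= q75:
            group = "Q3"
        elif p < q25:
            group = "Q1"
        else:
            group = "Q2"
        out.append(SubgroupAssignment(sid, float(p), group))
    return out


class BlockCorrelation(NamedTuple):
    """Pearson r with two-sided p, and RMSE of the paired means."""

    r: float
    p: float
    rmse: float


def correlate_blocks(
    human_block_means: Sequence[float], agent_block_means: Sequence[float]
) -> BlockCorrelation:
    """Pearson correlation and RMSE between two paired mean vectors.

    The inputs are typically subgroup-by-block mean matrices flattened to
    vectors (block 5 excluded upstream when it served as a fitting
    objective). Zero variance in either vector leaves r and p undefined
    (NaN); the RMSE is still reported.
    """
    x = np.asarray(human_block_means, dtype=float).ravel()
    y = np.asarray(agent_block_means, dtype=float).ravel()
    if x.shape != y.shape:
        raise ParameterError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ParameterError("need at least 2 paired means")
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.std(x) == 0 or np.std(y) == 0:
        return BlockCorrelation(float("nan"), float("nan"), rmse)
    r, p = stats.pearsonr(x, y)
    return BlockCorrelation(float(r), float(p), rmse)


def subgroup_block_means(
    block_prefs: np.ndarray,
    assignments: Sequence[SubgroupAssignment],
    exclude_last_block: bool = False,
) -> pd.DataFrame:
    """Mean block trajectory per subgroup.

    ``block_prefs`` is (n_subjects, n_blocks) in the same subject order as
    ``assignments``. Rows are Q1/Q2/Q3 (only those present); optionally
    drops the final block before averaging.
    """
    prefs = np.asarray(block_prefs, dtype=float)
    if prefs.ndim != 2 or prefs.shape[0] != len(assignments):
        raise ParameterError(
            f"block_prefs shape {prefs.shape} does not match "
            f"{len(assignments)} assignments"
        )
    if exclude_last_block:
        prefs = prefs[:, :-1]
    groups = np.array([a.subgroup for a in assignments])
    rows = {}
    for g in ("Q1", "Q2", "Q3"):
        mask = groups == g
        if mask.any():
            rows[g] = prefs[mask].mean(axis=0)
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"b{i + 1}" for i in range(frame.shape[1])]
    frame.index.name = "subgroup"
    return frame
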