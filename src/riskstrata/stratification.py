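"""Expected-utilization quintiles and their calibration statistics.

Beneficiaries in the study arm are ranked by expected performance-year
utilization and cut into five equal quintiles (label 5 = highest expected).
Per quintile we report the mean expected and mean observed counts, the
predictive ratio (mean expected / mean observed; 1.0 means the model is
calibrated at the group level), a 95% confidence half-width on the observed
mean, and empirical bounds containing 99% of individual observed counts.
The global individual-level fit is the ordinary coefficient of
determination computed on the held-out study arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

Z_95 = 1.96  # CI level on the observed quintile mean


@dataclass(frozen=True)
class QuintileSummary:
    label: int
    n: int
    mean_expected: float
    mean_observed: float
    predictive_ratio: float  # NaN when the observed mean is zero
    ci_half_width: float
    lower_99: float
    upper_99: float


def assign_quintiles(expected, ids) -> pd.Series:
    """Quintile labels 1..5 (5 = highest expected utilization).

    Stable sort by (expected ascending, beneficiary id ascending) fixes the
    tie-break; quintile sizes differ by at most one (exact fifths whenever
    5 divides n), any remainder going to the highest-risk quintiles so the
    top segment is never empty.  Returns labels indexed by id.
    """
    expected = np.asarray(expected, dtype=float)
    ids = np.asarray(ids)
    if expected.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(expected).all():
        raise ValueError("expected values must be finite")
    order = np.lexsort((ids, expected))
    n = expected.size
    labels = np.empty(n, dtype=int)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if q + 1 > 5 - rem else 0) for q in range(5)]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for q in range(5):
        labels[order[bounds[q] : bounds[q + 1]]] = q + 1
    return pd.Series(labels, index=pd.Index(ids, name="beneficiary_id"), name="quintile")


def quintile_summary(assignment: pd.Series, expected, observed) -> list[QuintileSummary]:
    """Per-quintile calibration statistics (aligned with ``assignment``)."""
    expected = np.asarray(expected, dtype=float)
    observed = np.asarray(observed, dtype=float)
    labels = assignment.to_numpy()
    if not (expected.size == observed.size == labels.size):
        raise ValueError("assignment, expected and observed must be aligned")
    out = []
    for q in range(1, 6):
        mask = labels == q
        n = int(mask.sum())
        if n == 0:  # possible only for tiny populations (n < 5)
            nan = math.nan
            out.append(QuintileSummary(q, 0, nan, nan, nan, nan, nan, nan))
            continue
        obs = observed[mask]
        exp = expected[mask]
        mean_obs = float(obs.mean())
        mean_exp = float(exp.mean())
        ratio = mean_exp / mean_obs if mean_obs != 0 else math.nan
        sd = float(obs.std(ddof=1)) if n > 1 else 0.0
        ci = Z_95 * sd / math.sqrt(n)
        lower, upper = _percentile_bounds(obs)
        out.append(
            QuintileSummary(q, n, mean_exp, mean_obs, ratio, ci, lower, upper)
        )
    return out


def _percentile_bounds(values: np.ndarray) -> tuple[float, float]:
    """Empirical [0.5th, 99.5th] percentile bounds, nearest-rank convention."""
    lo, hi = np.percentile(values, [0.5, 99.5], method="closest_observation")
    return float(lo), float(hi)


def r_squared(observed, expected) -> float:
    """Coefficient of determination 1 - SSE/SST on the study arm.

    Returns NaN when the observed counts are constant (SST = 0).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.size != expected.size:
        raise ValueError("observed and expected must be aligned")
    if observed.size < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return math.nan
    sse = float(np.sum((observed - expected) ** 2))
    return 1.0 - sse / sst
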