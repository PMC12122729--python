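"""Cumulative risk segments, the study's two outcome measures, and reports.

A cumulative risk segment is the top-k% of the study arm ranked by expected
utilization, formed by unioning quintiles from the top: top20 = quintile 5,
top40 = quintiles {4,5}, ..., all100 = everyone.  For each segment we report
expected and actual admission totals and rates (admissions per beneficiary,
as a percent -- a count rate that can exceed 100%), the *capture fraction*
(share of all observed admissions falling in the segment), the *zero
fraction* (share of segment members with no admissions), the distinct
any-admission probability, and the count histogram.  The capture and zero
fractions are the two outcome measures that decide whether prospective risk
segments can guide hospital-avoidance resource allocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

SEGMENT_LABELS = ("top20", "top40", "top60", "top80", "all100")
#: report histograms are capped here, with an overflow bin; the full tail is
#: kept on the SegmentSummary itself
HISTOGRAM_CAP = 15


@dataclass(frozen=True)
class SegmentSummary:
    label: str
    n: int
    expected_total: float
    expected_rate_pct: float  # expected admissions per beneficiary, as %
    actual_total: int
    actual_rate_pct: float
    capture_fraction: float
    zero_fraction: float
    any_admission_pct: float  # P(>=1 admission), distinct from the count rate
    histogram: dict[int, int]  # full tail, uncapped


def cumulative_segments(assignment: pd.Series) -> dict[str, pd.Index]:
    """Nested segment memberships from quintile labels (5 = highest risk)."""
    labels = assignment.to_numpy()
    if not np.isin(labels, [1, 2, 3, 4, 5]).all():
        raise ValueError("quintile labels must lie in 1..5")
    out = {}
    for i, name in enumerate(SEGMENT_LABELS):
        cutoff = 5 - i  # top20 keeps label 5, top40 keeps {4,5}, ...
        out[name] = assignment.index[labels >= cutoff]
    return out


def segment_summary(
    memberships: dict[str, pd.Index],
    observed: pd.Series,
    expected: pd.Series,
) -> list[SegmentSummary]:
    """Per-segment totals, rates, capture/zero fractions and histograms.

    ``observed`` and ``expected`` are indexed by beneficiary id over the
    whole study arm; the population actual total (capture denominator) is
    taken from the full ``observed`` vector.
    """
    population_total = float(observed.sum())
    out = []
    for label in SEGMENT_LABELS:
        ids = memberships[label]
        if len(ids) == 0:
            raise ValueError(f"segment {label} is empty")
        obs = observed.loc[ids].to_numpy()
        exp = expected.loc[ids].to_numpy(dtype=float)
        n = len(ids)
        actual_total = int(obs.sum())
        counts = np.bincount(obs.astype(int))
        histogram = {int(c): int(v) for c, v in enumerate(counts) if v > 0}
        out.append(
            SegmentSummary(
                label=label,
                n=n,
                expected_total=float(exp.sum()),
                expected_rate_pct=100.0 * float(exp.sum()) / n,
                actual_total=actual_total,
                actual_rate_pct=100.0 * actual_total / n,
                capture_fraction=(
                    actual_total / population_total if population_total else np.nan
                ),
                zero_fraction=float((obs == 0).mean()),
                any_admission_pct=100.0 * float((obs > 0).mean()),
                histogram=histogram,
            )
        )
    return out


def capped_histogram(histogram: dict[int, int], cap: int = HISTOGRAM_CAP) -> dict[str, int]:
    """Histogram with counts above ``cap`` pooled into an overflow bin."""
    out = {str(c): 0 for c in range(cap + 1)}
    overflow = 0
    for c, v in histogram.items():
        if c > cap:
            overflow += v
        else:
            out[str(c)] += v
    out[f"{cap + 1}+"] = overflow
    return out


def segments_frame(summaries: list[SegmentSummary]) -> pd.DataFrame:
    """Segment summaries as a tidy table (rates rounded to one decimal,
    matching how such tables are conventionally printed)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "segment": s.label,
                "n_beneficiaries": s.n,
                "expected_admissions": round(s.expected_total, 1),
                "expected_rate_pct": round(s.expected_rate_pct, 1),
                "actual_admissions": s.actual_total,
                "actual_rate_pct": round(s.actual_rate_pct, 1),
                "capture_fraction": round(s.capture_fraction, 4),
                "zero_fraction": round(s.zero_fraction, 4),
                "any_admission_pct": round(s.any_admission_pct, 1),
            }
        )
    return pd.DataFrame(rows)


def quintiles_frame(quintile_summaries) -> pd.DataFrame:
    return pd.DataFrame([asdict(q) for q in quintile_summaries])


def histograms_frame(summaries: list[SegmentSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for bin_label, count in capped_histogram(s.histogram).items():
            rows.append({"segment": s.label, "admissions": bin_label, "count": count})
    return pd.DataFrame(rows)


def write_report(
    path,
    quintile_summaries,
    segment_summaries,
    r_squared: float,
    metadata: dict,
    csv_dir=None,
) -> dict:
    """Write the structured JSON report (and optional CSV companions).

    The report carries every statistic, the run metadata (seeds, generator
    configuration echo, package version) and a timestamp; keys are sorted so
    two runs with the same seeds differ only in the timestamp field.
    Returns the report dict.
    """
    from . import __version__

    report = {
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "metadata": metadata,
        "r_squared": r_squared,
        "quintiles": [asdict(q) for q in quintile_summaries],
        "segments": [
            {**asdict(s), "histogram": capped_histogram(s.histogram)}
            for s in segment_summaries
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, allow_nan=True))
    if csv_dir is not None:
        csv_dir = Path(csv_dir)
        csv_dir.mkdir(parents=True, exist_ok=True)
        segments_frame(segment_summaries).to_csv(csv_dir / "segments.csv", index=False)
        quintiles_frame(quintile_summaries).to_csv(
            csv_dir / "quintiles.csv", index=False
        )
        histograms_frame(segment_summaries).to_csv(
            csv_dir / "histograms.csv", index=False
        )
    return report


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
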