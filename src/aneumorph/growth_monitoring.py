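"""Longitudinal growth classification and its reliability under noise.

Clinically, an aneurysm whose size increases by at least 1 mm between scans
is classified as growing (a surrogate of elevated rupture risk); the
mirrored criterion defines shrinking, anything in between is stable. When
the measurement noise SD is comparable to the 1 mm threshold — as it is for
human raters — a truly stable aneurysm has a substantial probability of
being misclassified, which this module quantifies in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from aneumorph.errors import ValidationError

DEFAULT_GROWTH_THRESHOLD_MM = 1.0

STATUS_GROWING = "growing"
STATUS_STABLE = "stable"
STATUS_SHRINKING = "shrinking"


@dataclass(frozen=True)
class GrowthAssessment:
    """Status of one follow-up interval of one case."""

    case_id: str
    interval: tuple[int, int]  # (timepoint t, t+1)
    delta_mm: float  # follow-up minus baseline
    status: str
    threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM


def classify_interval(
    baseline_mm: float,
    followup_mm: float,
    threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM,
    case_id: str = "",
    interval: tuple[int, int] = (0, 1),
) -> GrowthAssessment:
    """Classify one interval: growing if the size increased by at least the
    threshold ("at least 1 mm" read as >=), shrinking if it decreased by at
    least the threshold, otherwise stable."""
    if baseline_mm <= 0 or followup_mm <= 0:
        raise ValidationError("sizes must be positive")
    if threshold_mm <= 0:
        raise ValidationError("threshold must be positive")
    delta = followup_mm - baseline_mm
    if delta >= threshold_mm:
        status = STATUS_GROWING
    elif delta <= -threshold_mm:
        status = STATUS_SHRINKING
    else:
        status = STATUS_STABLE
    return GrowthAssessment(
        case_id=case_id, interval=interval, delta_mm=delta, status=status, threshold_mm=threshold_mm
    )


def trajectory_status(
    series,
    threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM,
    case_id: str = "",
    aggregation: str = "any_growing",
) -> tuple[list[GrowthAssessment], str]:
    """Per-interval assessments of a size series plus an overall status.

    The overall label aggregates intervals: growing if any interval grew,
    else shrinking if any shrank, else stable (growth dominates because it
    is the clinically actionable finding).
    """
    sizes = np.asarray(series, dtype=float).ravel()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 timepoints for a trajectory")
    if aggregation != "any_growing":
        raise ValidationError(f"unknown aggregation rule {aggregation!r}")
    assessments = [
        classify_interval(sizes[t], sizes[t + 1], threshold_mm, case_id=case_id, interval=(t, t + 1))
        for t in range(len(sizes) - 1)
    ]
    statuses = {a.status for a in assessments}
    if STATUS_GROWING in statuses:
        overall = STATUS_GROWING
    elif STATUS_SHRINKING in statuses:
        overall = STATUS_SHRINKING
    else:
        overall = STATUS_STABLE
    return assessments, overall


def assessments_from_table(
    table, threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM, session: int = 1
) -> dict[str, dict[tuple[str, tuple[int, int]], str]]:
    """Per-rater interval statuses from a long measurement table.

    Returns {rater_id: {(case_id, (t, t+1)): status}} using consecutive
    timepoints of the given session.
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    out: dict[str, dict] = {}
    for rater, sub in df[df.session == session].groupby("rater_id"):
        statuses: dict[tuple[str, tuple[int, int]], str] = {}
        for case, rows in sub.groupby("case_id"):
            rows = rows.sort_values("timepoint")
            tps = rows.timepoint.to_numpy()
            sizes = rows.size_mm.to_numpy()
            for t in range(len(tps) - 1):
                a = classify_interval(
                    sizes[t], sizes[t + 1], threshold_mm, case_id=str(case),
                    interval=(int(tps[t]), int(tps[t + 1])),
                )
                statuses[(str(case), a.interval)] = a.status
        out[str(rater)] = statuses
    return out


def concordance_vs_reference(
    assessments_by_source: dict[str, dict], reference_source: str
) -> dict[str, float]:
    """Fraction of intervals on which each source agrees with the reference.

    All sources must cover exactly the reference's (case, interval) set.
    The returned mapping includes every non-reference source plus a
    ``"pooled"`` entry over all of them.
    """
    if reference_source not in assessments_by_source:
        raise ValidationError(f"reference source {reference_source!r} missing")
    ref = assessments_by_source[reference_source]
    keys = set(ref)
    result: dict[str, float] = {}
    agree_total = n_total = 0
    for source, statuses in assessments_by_source.items():
        if source == reference_source:
            continue
        if set(statuses) != keys:
            raise ValidationError(
                f"source {source!r} covers a different (case, interval) set than the reference"
            )
        agree = sum(statuses[k] == ref[k] for k in keys)
        result[source] = agree / len(keys)
        agree_total += agree
        n_total += len(keys)
    result["pooled"] = agree_total / n_total if n_total else float("nan")
    return result


def false_growth_probability(
    per_measurement_sd_mm: float, threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM
) -> float:
    """Probability a truly stable case is called growing or shrinking.

    Two independent measurements with Normal(0, sigma^2) errors differ by
    Normal(0, 2 sigma^2), so
        P(|delta| >= t) = 2 Phi(-t / (sigma sqrt(2))).
    This is the misclassification probability of the >= t rule on a truly
    unchanged aneurysm; it exceeds 0.5 once sigma is well above t.
    """
    if per_measurement_sd_mm < 0:
        raise ValidationError("sd must be non-negative")
    if threshold_mm <= 0:
        raise ValidationError("threshold must be positive")
    if per_measurement_sd_mm == 0:
        return 0.0
    return float(2.0 * norm.cdf(-threshold_mm / (per_measurement_sd_mm * np.sqrt(2.0))))


def false_growth_probability_mc(
    per_measurement_sd_mm: float,
    threshold_mm: float = DEFAULT_GROWTH_THRESHOLD_MM,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo companion of :func:`false_growth_probability`."""
    if per_measurement_sd_mm < 0:
        raise ValidationError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, per_measurement_sd_mm or 0.0, n_draws)
    e2 = rng.normal(0.0, per_measurement_sd_mm or 0.0, n_draws)
    return float(np.mean(np.abs(e2 - e1) >= threshold_mm))
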