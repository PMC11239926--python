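"""Rater-agreement statistics: Bland-Altman, two-way ICC, Cohen's d.

These are the metrics used to compare aneurysm-size measurements between
raters, between repeat sessions of one rater, and between raters and the
computerized pipeline, optionally stratified by rupture status (ruptured
aneurysms are measured with higher variability because of the adjacent
blood pool).

The ICC is computed from the two-way ANOVA mean squares of a complete
targets x raters matrix. Two single-rater variants are implemented: the
two-way random-effects absolute-agreement form (ICC(2,1); sensitive to
systematic rater offsets) and the two-way mixed consistency form
(ICC(3,1); offsets among the fixed rater panel are eliminated while
target x rater interactions still count against agreement). The variant is
always carried in the result because the two answer different questions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from aneumorph.errors import DegenerateStatisticError, ValidationError

ICC_VARIANTS = ("two_way_random_absolute_single", "two_way_mixed_consistency_single")


@dataclass
class BlandAltmanResult:
    """Systematic (mean) and random (SD) error of paired differences.

    Differences are second minus first; limits of agreement are the
    mean +/- 1.96 SD interval expected to contain 95% of differences.
    """

    n_pairs: int
    mean_diff_mm: float
    sd_diff_mm: float
    loa_low: float
    loa_high: float


@dataclass
class ICCResult:
    icc_value: float
    variant: str
    n_targets: int
    k_raters: int
    label: str


@dataclass
class EffectSizeResult:
    d: float
    n_a: int
    n_b: int
    pooled_sd: float


@dataclass
class AgreementResult:
    """One rater-pair (or rater-vs-computerized) comparison in one stratum."""

    first: str
    second: str
    stratum: str
    bland_altman: BlandAltmanResult
    icc: ICCResult
    cohens_d: EffectSizeResult


def bland_altman(first, second) -> BlandAltmanResult:
    """Bland-Altman difference statistics for paired measurements.

    ``first`` and ``second`` are equal-length paired size arrays;
    differences are computed as second - first, SD uses the n-1 denominator.
    """
    a = np.asarray(first, dtype=float).ravel()
    b = np.asarray(second, dtype=float).ravel()
    if len(a) != len(b):
        raise ValidationError(f"unpaired inputs: {len(a)} vs {len(b)} values")
    if len(a) < 2:
        raise ValidationError("Bland-Altman needs >= 2 pairs")
    d = b - a
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        n_pairs=len(d),
        mean_diff_mm=mean,
        sd_diff_mm=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
    )


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares of a complete n x k matrix.

    Returns (MSR, MSC, MSE): rows/targets, columns/raters, residual.
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(table, variant: str = "two_way_random_absolute_single") -> ICCResult:
    """Single-rater intraclass correlation of a complete targets x raters matrix.

    Absolute agreement (two-way random):
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    Consistency (two-way mixed):
        (MSR - MSE) / (MSR + (k-1) MSE)
    """
    if variant not in ICC_VARIANTS:
        raise ValidationError(f"unknown ICC variant {variant!r}; use one of {ICC_VARIANTS}")
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ICC expects a 2D targets x raters matrix")
    if np.isnan(x).any():
        raise ValidationError("ICC matrix has missing cells; no imputation is performed")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need >= 2 targets and >= 2 raters, got {n} x {k}")
    if np.ptp(x) == 0:
        raise DegenerateStatisticError("all cells equal: total variance is zero, ICC undefined")
    msr, msc, mse = _anova_mean_squares(x)
    if variant == "two_way_random_absolute_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        raise DegenerateStatisticError("zero ANOVA denominator, ICC undefined")
    value = float((msr - mse) / denom)
    return ICCResult(
        icc_value=value, variant=variant, n_targets=n, k_raters=k, label=interpret_icc(value)
    )


def interpret_icc(value: float) -> str:
    """Reliability label for an ICC value.

    Bins (left-closed): below 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good,
    above 0.9 excellent — so 0.75 and 0.9 both read "good".
    """
    if value > 0.9:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def cohens_d(group_a, group_b, absolute: bool = False) -> EffectSizeResult:
    """Cohen's d standardized mean difference with the pooled SD.

    d = (mean_a - mean_b) / s_pooled with
    s_pooled = sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2)).
    Conventional anchors: 0.2 small, 0.5 medium, 0.8 large.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    diff = a.mean() - b.mean()
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        if abs(diff) > 0:
            raise DegenerateStatisticError(
                "zero pooled SD with unequal means: effect size infinite"
            )
        d = 0.0
    else:
        d = float(diff / pooled)
    if absolute:
        d = abs(d)
    return EffectSizeResult(d=d, n_a=len(a), n_b=len(b), pooled_sd=float(pooled))


# ---------------------------------------------------------------------------
# Table-level reports


def _pivot(df: pd.DataFrame, raters: list[str], session: int) -> pd.DataFrame:
    sub = df[(df.rater_id.isin(raters)) & (df.session == session)]
    wide = sub.pivot_table(
        index=["case_id", "timepoint"], columns="rater_id", values="size_mm", aggfunc="first"
    )
    return wide.dropna()


def _pair_block(
    first_vals: np.ndarray, second_vals: np.ndarray, first: str, second: str, stratum: str
) -> AgreementResult:
    ba = bland_altman(first_vals, second_vals)
    icc_res = icc(np.column_stack([first_vals, second_vals]))
    d = cohens_d(first_vals, second_vals, absolute=True)
    return AgreementResult(
        first=first, second=second, stratum=stratum, bland_altman=ba, icc=icc_res, cohens_d=d
    )


def pairwise_agreement_report(
    table,
    mode: str = "inter",
    reference: str | None = None,
    strata: str | None = "rupture_status",
    session: int = 1,
):
    """Per-pair, per-stratum agreement blocks plus an all-rater Cohen's d matrix.

    Modes
    -----
    inter : every unordered rater pair, one session.
    intra : per rater, session 1 vs session 2 of the same cases.
    vs_reference : every other rater against ``reference`` (e.g. the
        computerized pipeline or the senior rater), reference first.

    Returns (list of AgreementResult, Cohen's d DataFrame). Cases are
    matched on (case_id, timepoint); rows with a missing member of a pair
    are dropped listwise per pair. Row order is deterministic
    (lexicographic pairs, strata sorted with "all" first).
    """
    df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
    raters = sorted(df.rater_id.unique())
    results: list[AgreementResult] = []

    def strata_masks(frame: pd.DataFrame):
        yield "all", np.ones(len(frame), dtype=bool)
        if strata is not None and strata in ("rupture_status",):
            for level in sorted(df.rupture_status.unique()):
                yield level, (frame["_stratum"] == level).to_numpy()

    if mode == "inter":
        pairs = [(a, b) for i, a in enumerate(raters) for b in raters[i + 1 :]]
    elif mode == "vs_reference":
        if reference is None or reference not in raters:
            raise ValidationError(f"reference rater {reference!r} not in table")
        pairs = [(reference, b) for b in raters if b != reference]
    elif mode == "intra":
        pairs = [(r, r) for r in raters]
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    rupture_by_case = df.groupby("case_id").rupture_status.first()

    for first, second in pairs:
        if mode == "intra":
            sub = df[df.rater_id == first]
            wide = sub.pivot_table(
                index=["case_id", "timepoint"], columns="session", values="size_mm", aggfunc="first"
            )
            if 1 not in wide.columns or 2 not in wide.columns:
                raise ValidationError(f"rater {first!r} lacks two sessions")
            wide = wide[[1, 2]].dropna()
            cols = (1, 2)
        else:
            wide = _pivot(df, [first, second], session)
            if first not in wide.columns or second not in wide.columns:
                raise ValidationError(f"no overlapping cases for pair ({first}, {second})")
            wide = wide[[first, second]].dropna()
            cols = (first, second)
        if len(wide) < 2:
            raise ValidationError(f"no overlapping cases for pair ({first}, {second})")
        wide = wide.reset_index()
        wide["_stratum"] = wide.case_id.map(rupture_by_case)
        for name, mask in strata_masks(wide):
            if mask.sum() < 2:
                continue
            results.append(
                _pair_block(
                    wide.loc[mask, cols[0]].to_numpy(),
                    wide.loc[mask, cols[1]].to_numpy(),
                    first,
                    second,
                    name,
                )
            )

    # all-rater Cohen's d matrix (session 1, absolute values, zero diagonal)
    d_matrix = pd.DataFrame(0.0, index=raters, columns=raters)
    by_rater = {
        r: df[(df.rater_id == r) & (df.session == session)].size_mm.to_numpy() for r in raters
    }
    for i, a in enumerate(raters):
        for b in raters[i + 1 :]:
            d = cohens_d(by_rater[a], by_rater[b], absolute=True).d
            d_matrix.loc[a, b] = d_matrix.loc[b, a] = d
    return results, d_matrix


def report_to_frame(results: list[AgreementResult]) -> pd.DataFrame:
    """Flatten AgreementResult blocks to a tidy DataFrame."""
    rows = []
    for r in results:
        rows.append(
            {
                "first": r.first,
                "second": r.second,
                "stratum": r.stratum,
                "n_pairs": r.bland_altman.n_pairs,
                "mean_diff_mm": r.bland_altman.mean_diff_mm,
                "sd_diff_mm": r.bland_altman.sd_diff_mm,
                "loa_low": r.bland_altman.loa_low,
                "loa_high": r.bland_altman.loa_high,
                "icc": r.icc.icc_value,
                "icc_variant": r.icc.variant,
                "icc_label": r.icc.label,
                "cohens_d": r.cohens_d.d,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience figures (no numeric contracts)


def bland_altman_plot(first, second, ax=None, label: str | None = None):
    """Classic difference plot: mean vs difference with LoA lines."""
    import matplotlib.pyplot as plt

    a = np.asarray(first, float)
    b = np.asarray(second, float)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2, b - a, s=12, alpha=0.6)
    for y, style in ((res.mean_diff_mm, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods (mm)")
    ax.set_ylabel("difference (mm)")
    if label:
        ax.set_title(label)
    return ax


def connected_box_plot(groups: dict[str, np.ndarray], ax=None):
    """Adjacent box plots with per-case connecting lines showing trends."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(groups)
    data = [np.asarray(groups[n], float) for n in names]
    ax.boxplot(data, tick_labels=names)
    lengths = {len(d) for d in data}
    if len(lengths) == 1:
        for row in np.column_stack(data):
            ax.plot(range(1, len(names) + 1), row, color="gray", alpha=0.3, linewidth=0.7)
    ax.set_ylabel("size (mm)")
    return ax
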