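"""Differential-miRNA screening with data-driven test selection.

For each miRNA the comparison groups are first checked for normality
(Shapiro–Wilk per group) and variance homogeneity (Levene). Two groups get
Student's t when both checks pass and Welch's t otherwise; more than two
groups get one-way ANOVA or Welch's ANOVA by the same rule. A feature is
called significant when its linear fold change departs from 1 by strictly
more than the 1.5× threshold in either direction *and* p is strictly below
alpha — both boundaries exclusive.

Fold change is case-group mean over control-group mean on normalized
linear intensities, so down-regulation reads as a value below 1. Volcano
coordinates are (fold change, −log10 p). p-values are raw by default;
Benjamini–Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ODTimeSeries

__all__ = [
    "ScreenParams",
    "DiffResult",
    "select_test",
    "run_test",
    "welch_anova",
    "fold_change",
    "screen",
    "top_table",
    "volcano_points",
    "od_summary",
    "results_frame",
]

log = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    fc_threshold: float = 1.5
    alpha: float = 0.05
    normality_alpha: float = 0.05
    variance_alpha: float = 0.05
    top_k: int = 5
    p_floor: float = 1e-300  # underflow cap before taking log10
    adjust_bh: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class DiffResult:
    """Per-miRNA screening outcome for one control-vs-case comparison."""

    mirna: str
    comparison: tuple[str, str]  # (control, case)
    fold_change: float
    p_value: float
    neg_log10_p: float
    test_used: str  # student-t | welch-t | anova | welch-anova
    direction: str  # up | down | none
    significant: bool


def _groups_ok(groups) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < 3:
            raise ValueError(
                f"group {i} has {len(g)} values; need >= 3 to assess normality"
            )


def select_test(groups: list[np.ndarray], params: ScreenParams | None = None) -> str:
    """Choose the comparison test from normality and variance checks."""
    params = params or ScreenParams()
    _groups_ok(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns on tiny/near-constant input
        normal = all(stats.shapiro(g).pvalue > params.normality_alpha for g in groups)
        equal_var = stats.levene(*groups).pvalue > params.variance_alpha
    if len(groups) == 2:
        return "student-t" if (normal and equal_var) else "welch-t"
    return "anova" if (normal and equal_var) else "welch-anova"


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, p).

    Weights each group by n/s²; the denominator degrees of freedom follow
    the Welch–Satterthwaite approximation.
    """
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    var = np.array([np.var(g, ddof=1) for g in groups])
    w = n / var
    wsum = w.sum()
    grand = (w * means).sum() / wsum
    a = ((w * (means - grand) ** 2).sum()) / (k - 1)
    r = ((1 - w / wsum) ** 2 / (n - 1)).sum()
    b = 1 + 2 * (k - 2) / (k * k - 1) * r
    f = a / b
    df2 = (k * k - 1) / (3 * r)
    p = float(stats.f.sf(f, k - 1, df2))
    return float(f), p


def run_test(groups: list[np.ndarray], params: ScreenParams | None = None) -> tuple[str, float]:
    """Apply the selected test; returns (test name, p-value)."""
    params = params or ScreenParams()
    test = select_test(groups, params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if test == "student-t":
            p = stats.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
        elif test == "welch-t":
            p = stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue
        elif test == "anova":
            p = stats.f_oneway(*groups).pvalue
        else:
            _, p = welch_anova(groups)
    p = float(p)
    if math.isnan(p):
        # degenerate zero-variance groups: identical means are maximally
        # unsurprising, distinct means maximally surprising
        means = [float(np.mean(g)) for g in groups]
        p = 1.0 if max(means) == min(means) else 0.0
    return test, p


def fold_change(control: np.ndarray, case: np.ndarray) -> float:
    """Linear fold change, mean(case) / mean(control).

    Antisymmetric under swapping the roles: FC(a, b) × FC(b, a) = 1.
    """
    mc, mk = float(np.mean(control)), float(np.mean(case))
    if mc <= 0 or mk <= 0:
        raise ValueError("fold change needs positive group means")
    return mk / mc


def _neg_log10(p: float, floor: float) -> float:
    return -math.log10(max(p, floor))


def screen(
    m: pd.DataFrame,
    design: pd.DataFrame,
    comparison: tuple[str, str],
    params: ScreenParams | None = None,
) -> list[DiffResult]:
    """Screen every retained miRNA for one (control, case) comparison."""
    params = params or ScreenParams()
    control, case = comparison
    for g in comparison:
        if g not in set(design["group"]):
            raise ValueError(f"group {g!r} not present in design")
    ctrl_cols = design.loc[design["group"] == control, "sample_id"].tolist()
    case_cols = design.loc[design["group"] == case, "sample_id"].tolist()
    results: list[DiffResult] = []
    pvals = []
    for mirna, row in m.iterrows():
        a = row[ctrl_cols].to_numpy(dtype=float)
        b = row[case_cols].to_numpy(dtype=float)
        test, p = run_test([a, b], params)
        fc = fold_change(a, b)
        pvals.append(p)
        results.append(DiffResult(
            mirna=str(mirna), comparison=comparison, fold_change=fc,
            p_value=p, neg_log10_p=_neg_log10(p, params.p_floor),
            test_used=test,
            direction="up" if fc > 1 else ("down" if fc < 1 else "none"),
            significant=False,
        ))
    if params.adjust_bh and results:
        from statsmodels.stats.multitest import multipletests

        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, padj):
            r.p_value = float(q)
            r.neg_log10_p = _neg_log10(r.p_value, params.p_floor)
    thr = params.fc_threshold
    n_sig = 0
    for r in results:
        r.significant = (
            (r.fold_change > thr or r.fold_change < 1 / thr)
            and r.p_value < params.alpha
        )
        n_sig += r.significant
    log.info("screen %s vs %s: %d/%d significant (FC>%g or <%g, p<%g)",
             control, case, n_sig, len(results), thr, 1 / thr, params.alpha)
    return results


def top_table(
    results: list[DiffResult],
    params: ScreenParams | None = None,
    require_fc_threshold: bool = False,
) -> tuple[list[DiffResult], list[DiffResult]]:
    """Top-k up- and down-regulated miRNAs with the largest difference.

    Up list: the k largest fold changes among up-regulated results with
    p < alpha. Down list: the k smallest fold changes among down-regulated
    results with p < alpha. Both are presented fold-change descending
    (most extreme up first; most extreme down last), ties broken by
    ascending p then id, mirroring the conventional screen-table layout.

    Candidates are gated on p alone by default: the published screens list
    down-regulated hits with fold changes inside the 1.5× volcano band, so
    gating on the full compound significance rule would discard them.
    Pass ``require_fc_threshold=True`` to restrict to results that carry
    the ``significant`` flag.
    """
    if not results:
        raise ValueError("no results to rank")
    params = params or ScreenParams()
    k = params.top_k

    def eligible(r: DiffResult) -> bool:
        return r.significant if require_fc_threshold else r.p_value < params.alpha

    key = lambda r: (-r.fold_change, r.p_value, r.mirna)
    up = sorted((r for r in results if eligible(r) and r.fold_change > 1), key=key)
    down = sorted((r for r in results if eligible(r) and r.fold_change < 1), key=key)
    up_k = up[:k]
    down_k = down[-k:] if len(down) > k else down
    if len(up_k) < k or len(down_k) < k:
        log.info("fewer than %d significant hits: %d up, %d down",
                 k, len(up_k), len(down_k))
    return up_k, down_k


def volcano_points(results: list[DiffResult]) -> list[tuple[float, float, bool]]:
    """(fold change, −log10 p, significant) triplets for plotting."""
    return [(r.fold_change, r.neg_log10_p, r.significant) for r in results]


def od_summary(series: list[ODTimeSeries]) -> pd.DataFrame:
    """Per-day mean and sample SD of replicate-well OD readings."""
    if not series:
        raise ValueError("no OD series")
    rows = []
    for s in series:
        wells = np.asarray(s.well_ods, dtype=float)
        if len(wells) == 1:
            warnings.warn(f"day {s.day}: single well, SD reported as 0",
                          stacklevel=2)
        rows.append({
            "day": s.day,
            "mean_od": float(wells.mean()),
            "sd_od": float(wells.std(ddof=1)) if len(wells) > 1 else 0.0,
            "n_wells": len(wells),
        })
    return pd.DataFrame(rows).sort_values("day", ignore_index=True)


def results_frame(results: list[DiffResult]) -> pd.DataFrame:
    """Flatten screen results into the output-table layout."""
    return pd.DataFrame([
        {
            "miRNA": r.mirna, "control": r.comparison[0],
            "case": r.comparison[1], "fold_change": r.fold_change,
            "p_value": r.p_value, "neg_log10_p": r.neg_log10_p,
            "test_used": r.test_used, "direction": r.direction,
            "significant": r.significant,
        }
        for r in results
    ])
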