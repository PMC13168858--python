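"""Cohort labelling, statistical tests and classifier feature selection.

Follows the convention: Shapiro-Wilk for normality, paired t when the
differences look normal and Wilcoxon signed-rank otherwise, Mann-Whitney
U between groups, McNemar for paired proportions; all two-tailed at
alpha = .05.  Group summaries switch between mean (95% CI) and
median (IQR) based on the normality check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

DETERIORATION_THRESHOLD = 3  # CVS-Q point increase
BASELINE_ASTHENOPIA_THRESHOLD = 6  # CVS-Q score


@dataclass
class GroupComparisonResult:
    feature_name: str
    test: str
    statistic: float
    p_value: float
    group_summaries: dict = field(default_factory=dict)
    note: str = ""

    @property
    def degenerate(self) -> bool:
        return self.test == "degenerate"


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------


def label_deterioration(cvsq_pre: float, cvsq_post: float) -> str:
    """Deteriorated iff the post score rose by >= 3 points (inclusive)."""
    if cvsq_pre < 0 or cvsq_post < 0:
        raise ValueError("CVS-Q scores must be non-negative")
    return (
        "deteriorated"
        if cvsq_post - cvsq_pre >= DETERIORATION_THRESHOLD
        else "nondeteriorated"
    )


def flag_baseline_asthenopia(cvsq: float) -> bool:
    """Baseline asthenopia is a CVS-Q score of at least 6."""
    if cvsq < 0:
        raise ValueError("CVS-Q score must be non-negative")
    return cvsq >= BASELINE_ASTHENOPIA_THRESHOLD


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def _mean_ci(values: np.ndarray) -> dict:
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values)))
    half = 1.96 * se
    return {"kind": "mean_ci", "mean": mean, "ci_low": mean - half, "ci_high": mean + half}


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = (float(v) for v in np.percentile(values, [25, 50, 75]))
    return {"kind": "median_iqr", "median": med, "q1": q1, "q3": q3}


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def paired_change_test(
    pre_values, post_values, feature_name: str = ""
) -> GroupComparisonResult:
    """Shapiro-Wilk on the differences, then paired t or Wilcoxon (two-tailed)."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post must be equal-length paired samples")
    if len(pre) < 3:
        raise ValueError("need at least 3 pairs")
    d = post - pre
    if np.allclose(d, 0):
        return GroupComparisonResult(
            feature_name, "degenerate", float("nan"), float("nan"),
            note="all paired differences are zero",
        )
    sw_stat, sw_p = sps.shapiro(d)
    if sw_p >= ALPHA:
        stat, p = sps.ttest_rel(post, pre)
        return GroupComparisonResult(
            feature_name, "paired_t", float(stat), float(p),
            group_summaries={"pre": _mean_ci(pre), "post": _mean_ci(post)},
            note=f"shapiro_wilk_p={sw_p:.4g}",
        )
    stat, p = sps.wilcoxon(d)
    return GroupComparisonResult(
        feature_name, "wilcoxon_signed_rank", float(stat), float(p),
        group_summaries={"pre": _median_iqr(pre), "post": _median_iqr(post)},
        note=f"shapiro_wilk_p={sw_p:.4g}",
    )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def compare_groups(feature_values, labels, feature_name: str = "") -> GroupComparisonResult:
    """Two-tailed Mann-Whitney U between two labelled groups.

    Exact enumeration when both groups have <= 20 untied samples,
    otherwise the normal approximation with tie and continuity
    correction.  Attaches median (IQR) per group.
    """
    values = np.asarray(feature_values, dtype=float)
    labels = np.asarray(labels)
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(names)}")
    x = values[labels == names[0]]
    y = values[labels == names[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    keep = np.isfinite(x), np.isfinite(y)
    x, y = x[keep[0]], y[keep[1]]
    use_exact = max(len(x), len(y)) <= 20 and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return GroupComparisonResult(
        feature_name,
        "mann_whitney_u",
        float(res.statistic),
        float(res.pvalue),
        group_summaries={str(names[0]): _median_iqr(x), str(names[1]): _median_iqr(y)},
        note="exact" if use_exact else "asymptotic",
    )


def mcnemar_paired(pre_flags, post_flags, feature_name: str = "") -> GroupComparisonResult:
    """Continuity-corrected McNemar test on discordant pairs.

    Also reports the net paired proportion change with a 95% Wald CI.
    """
    pre = np.asarray(pre_flags, dtype=bool)
    post = np.asarray(post_flags, dtype=bool)
    if pre.shape != post.shape:
        raise ValueError("flag vectors must have equal length")
    n = len(pre)
    b = int(np.sum(~pre & post))  # became positive
    c = int(np.sum(pre & ~post))  # became negative
    diff = (b - c) / n
    se = np.sqrt(max(b + c - (b - c) ** 2 / n, 0.0)) / n
    ci = {"diff": diff, "ci_low": diff - 1.96 * se, "ci_high": diff + 1.96 * se}
    if b + c == 0:
        return GroupComparisonResult(
            feature_name, "degenerate", float("nan"), float("nan"),
            group_summaries={"net_change": ci}, note="no discordant pairs",
        )
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(sps.chi2.sf(stat, df=1))
    return GroupComparisonResult(
        feature_name, "mcnemar", float(stat), p,
        group_summaries={"net_change": ci, "discordant": {"b": b, "c": c}},
    )


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def select_features(
    results: list[GroupComparisonResult],
    alpha: float = ALPHA,
    always_include: tuple[str, ...] = (),
) -> list[str]:
    """Features with P < alpha, most significant first.

    Names in ``always_include`` (e.g. the CFF) are appended regardless of
    significance.  Selection on the full dataset precedes cross-validation
    and therefore leaks label information into model inputs; callers are
    warned once.
    """
    usable = [r for r in results if np.isfinite(r.p_value)]
    selected = sorted(
        (r for r in usable if r.p_value < alpha), key=lambda r: (r.p_value, r.feature_name)
    )
    names = [r.feature_name for r in selected]
    for extra in always_include:
        if extra not in names:
            names.append(extra)
    if names:
        warnings.warn(
            "features were filtered on the full dataset (not per CV fold); "
            "downstream performance estimates may be optimistic",
            UserWarning,
            stacklevel=2,
        )
    return names


def group_comparison_table(
    df: pd.DataFrame, feature_cols: list[str], label_col: str = "label"
) -> tuple[pd.DataFrame, list[GroupComparisonResult]]:
    """Mann-Whitney comparison of every feature column between label groups."""
    results = []
    rows = []
    for col in feature_cols:
        mask = np.isfinite(df[col].to_numpy(dtype=float))
        sub = df[mask]
        try:
            res = compare_groups(sub[col].to_numpy(dtype=float), sub[label_col].to_numpy(), col)
        except ValueError:
            continue
        results.append(res)
        row = {"feature": col, "test": res.test, "statistic": res.statistic, "p_value": res.p_value}
        for group, summary in res.group_summaries.items():
            row[f"{group}_median"] = summary["median"]
            row[f"{group}_iqr"] = f"{summary['q1']:.3g} to {summary['q3']:.3g}"
        rows.append(row)
    return pd.DataFrame(rows), results
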