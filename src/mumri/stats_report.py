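"""Study-level summaries: scan-rescan repeatability and group
comparisons, plus a small combined report builder."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RepeatabilityResult", "ComparisonResult", "repeatability", "compare_groups", "make_report"]


@dataclass
class RepeatabilityResult:
    """Scan-rescan absolute percentage differences for one metric."""

    per_subject: np.ndarray  # %, one entry per retained subject
    mean_percentage_difference: float  # %
    metric: str
    n_subjects: int


@dataclass
class ComparisonResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: float
    p_value: float
    paired: bool
    n_a: int
    n_b: int
    degenerate: bool = False


def repeatability(
    scan1, scan2, metric: str = "", denominator: str = "pair_mean"
) -> RepeatabilityResult:
    """Absolute percentage difference between two scans, averaged over
    subjects.

    Per subject: 100*|s1 - s2| / ((s1 + s2)/2) with the symmetric
    pair-mean denominator (``denominator="scan1"`` selects 100*|s1-s2|/s1).
    Subjects whose denominator is zero are excluded with a warning.
    """
    s1 = np.asarray(scan1, dtype=float)
    s2 = np.asarray(scan2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("scan lists must have equal length")
    if denominator == "pair_mean":
        den = (s1 + s2) / 2.0
    elif denominator == "scan1":
        den = s1.astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    keep = den != 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} subject(s) with zero denominator")
    pct = 100.0 * np.abs(s1[keep] - s2[keep]) / np.abs(den[keep])
    return RepeatabilityResult(
        per_subject=pct,
        mean_percentage_difference=float(pct.mean()) if pct.size else float("nan"),
        metric=metric,
        n_subjects=int(keep.sum()),
    )


def compare_groups(values_a, values_b, paired: bool = False) -> ComparisonResult:
    """Two-sided Student's t-test between two groups of subject-level
    values (paired or unpaired)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length groups")
        diff = a - b
        degenerate = float(diff.std(ddof=1)) == 0.0
        if degenerate:
            warnings.warn("zero-variance paired difference: t-test degenerate")
            stat = 0.0 if np.allclose(diff, 0) else float(np.sign(diff.mean()) * np.inf)
            p = 1.0 if np.allclose(diff, 0) else 0.0
        else:
            res = sps.ttest_rel(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        degenerate = float(a.std(ddof=1)) == 0.0 and float(b.std(ddof=1)) == 0.0
        if degenerate:
            warnings.warn("zero variance in both groups: t-test degenerate")
            same = np.isclose(a.mean(), b.mean())
            stat = 0.0 if same else float(np.sign(a.mean() - b.mean()) * np.inf)
            p = 1.0 if same else 0.0
        else:
            res = sps.ttest_ind(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        statistic=stat,
        p_value=p,
        paired=paired,
        n_a=len(a),
        n_b=len(b),
        degenerate=degenerate,
    )


def make_report(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    metrics: Optional[Sequence[str]] = None,
    paired: bool = True,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Combine two per-subject summary tables into a comparison report.

    Both tables need a ``subject`` column plus one column per metric.
    Rows are matched on ``subject`` for paired comparisons.
    """
    if "subject" not in baseline or "subject" not in followup:
        raise ValueError("summary tables need a 'subject' column")
    if metrics is None:
        metrics = [c for c in baseline.columns if c != "subject" and c in followup.columns]
    merged = baseline.merge(followup, on="subject", suffixes=("_baseline", "_followup"))
    rows = []
    n_tests = len(metrics)
    for m in metrics:
        a = merged[f"{m}_baseline"].to_numpy(dtype=float)
        b = merged[f"{m}_followup"].to_numpy(dtype=float)
        cmp = compare_groups(a, b, paired=paired)
        row = {
            "metric": m,
            "baseline_mean": cmp.mean_a,
            "baseline_sd": cmp.sd_a,
            "followup_mean": cmp.mean_b,
            "followup_sd": cmp.sd_b,
            "t": cmp.statistic,
            "p": cmp.p_value,
            "n": cmp.n_a,
            "paired": paired,
        }
        if bonferroni:
            row["p_bonferroni"] = min(1.0, cmp.p_value * n_tests)
        rows.append(row)
    return pd.DataFrame(rows)
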