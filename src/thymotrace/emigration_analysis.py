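"""Stage-wise accumulation under thymic-emigration blockade.

Blocking S1P1-mediated thymic export (FTY720 treatment) makes export-ready
populations pile up in the thymus: a stage whose cell count keeps growing
between an early (5 d) and a late (10 d) treatment point is a candidate
terminal stage of a developmental pathway, whereas transit stages
saturate. This module computes per-stage fold changes relative to
untreated mice, calls terminal stages from the late fold and the
sustained-growth ratio, and provides the two-sample Student's t test used
for group comparisons (two-sided, equal variance by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AccumulationResult:
    """Per-stage counts, treatment fold changes and terminal calls."""

    counts: pd.DataFrame          # stages x groups
    folds: pd.DataFrame           # stages x non-baseline groups
    baseline: str
    growth_ratio: pd.Series | None = None   # fold(late) / fold(early)
    terminal: set = field(default_factory=set)


def fold_changes(
    counts_by_group: pd.DataFrame,
    baseline: str = "untreated",
) -> AccumulationResult:
    """Per-stage fold change of every treatment group over the baseline.

    ``counts_by_group`` is a stage x group table of cell counts (replicate
    means are acceptable). Every baseline count must be positive.
    """
    if baseline not in counts_by_group.columns:
        raise ValueError(f"baseline group {baseline!r} not in table")
    base = counts_by_group[baseline]
    if (base <= 0).any():
        bad = list(base.index[base <= 0])
        raise ValueError(
            f"zero/negative baseline count for stage(s) {bad}; "
            "add a pseudocount or exclude those stages"
        )
    others = [c for c in counts_by_group.columns if c != baseline]
    folds = counts_by_group[others].div(base, axis=0)
    return AccumulationResult(counts_by_group.copy(), folds, baseline)


def call_terminal_stages(
    result: AccumulationResult,
    late: str = "FTY720_10d",
    early: str = "FTY720_5d",
    min_fold_late: float = 3.0,
    min_growth_ratio: float = 1.5,
) -> set:
    """Call terminal stages: strong late accumulation that is still growing.

    A stage is terminal iff fold(late) >= ``min_fold_late`` and
    fold(late)/fold(early) >= ``min_growth_ratio``. With no early group the
    ratio criterion is skipped (warned).
    """
    if late not in result.folds.columns:
        raise ValueError(f"late group {late!r} has no fold changes")
    fold_late = result.folds[late]
    passes = fold_late >= min_fold_late
    if early in result.folds.columns:
        ratio = fold_late / result.folds[early]
        result.growth_ratio = ratio
        passes &= ratio >= min_growth_ratio
    else:
        warnings.warn(f"no early group {early!r}: growth-ratio criterion skipped")
    result.terminal = set(fold_late.index[passes])
    return result.terminal


def student_t_test(
    x: np.ndarray | list,
    y: np.ndarray | list,
    paired: bool = False,
) -> tuple[float, float, int]:
    """Two-sided Student's t test (pooled equal variance when unpaired).

    Returns (t, p, degrees of freedom); df = n_x + n_y - 2 unpaired,
    n - 1 paired.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        diff = x - y
        df = len(x) - 1
        if np.allclose(diff, 0.0):
            return 0.0, 1.0, df  # identical pairs: no effect by convention
        if np.isclose(diff.std(ddof=1), 0.0):
            raise ValueError("zero variance of paired differences")
        res = stats.ttest_rel(x, y)
    else:
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        if sp2 == 0:
            raise ValueError("zero pooled variance; t test undefined")
        res = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
    t = float(res.statistic)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    if t == 0.0:
        p = 1.0
    return t, p, int(df)
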