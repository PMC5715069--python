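"""Surface-marker candidate screen and effector-signature scoring.

The screen asks which genes separate two developmental compartments
(e.g. CD24+CD73- vs CD24+CD73+ thymocytes) strongly enough, and are
surface-expressed, to serve as new cytometry gating markers. A gene is a
candidate when all four hold:

* |log2 fold change| > 3 between the two groups,
* Benjamini-Hochberg adjusted one-way-ANOVA p < 0.05,
* annotated with a cell-surface GO term (GO:0009986 cell surface or
  GO:0005886 plasma membrane),
* mean log2 expression > 7 in at least one group (detectably expressed).

The module expects an already normalized, batch-corrected expression
matrix; ``normalize_log2`` provides a simple library-size log2(CPM+1)
normalization for raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SURFACE_GO_TERMS = frozenset({"GO:0009986", "GO:0005886"})


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample metadata.

    ``values`` has gene identifiers as the index and sample identifiers as
    columns; ``sample_meta`` is indexed by sample and may carry ``stage``,
    ``subset`` and ``replicate`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.columns)
        if not self.sample_meta.index.equals(self.values.columns):
            self.sample_meta = self.sample_meta.reindex(self.values.columns)
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def population_means(self, by: str = "stage") -> pd.DataFrame:
        """Genes x population matrix of replicate-mean expression."""
        if by not in self.sample_meta.columns:
            raise KeyError(f"sample metadata lacks column {by!r}")
        groups = self.sample_meta[by]
        return self.values.T.groupby(groups.to_numpy()).mean().T


def normalize_log2(counts: pd.DataFrame, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(1e6 * c / library_size + pseudocount) library-size normalization."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + pseudocount))


def differential_f_test(
    expr: ExpressionMatrix | pd.DataFrame,
    group_labels: pd.Series | np.ndarray | list,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across groups, vectorized over genes.

    Returns a DataFrame with columns ``F``, ``p``, ``log2FC`` (two-group
    case: second group mean minus first, groups in sorted label order) and
    ``mean_<group>`` per group. Genes with zero variance everywhere get
    F = NaN and p = 1 by convention.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    labels = np.asarray(group_labels)
    if len(labels) != values.shape[1]:
        raise ValueError("group_labels must align with samples")
    group_names = sorted(pd.unique(labels))
    if len(group_names) < 2:
        raise ValueError("need at least two groups")
    X = values.to_numpy(dtype=float)
    n = X.shape[1]
    g = len(group_names)
    grand = X.mean(axis=1)
    ssb = np.zeros(len(values))
    ssw = np.zeros(len(values))
    means = {}
    for name in group_names:
        cols = labels == name
        ni = int(cols.sum())
        if ni < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
        mi = X[:, cols].mean(axis=1)
        means[name] = mi
        ssb += ni * (mi - grand) ** 2
        ssw += ((X[:, cols] - mi[:, None]) ** 2).sum(axis=1)
    df1, df2 = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
        p = stats.f.sf(F, df1, df2)
    degenerate = (ssw == 0) & (ssb == 0)
    F[degenerate] = np.nan
    p[degenerate] = 1.0
    p[(ssw == 0) & (ssb > 0)] = 0.0
    out = pd.DataFrame({"F": F, "p": p}, index=values.index)
    if g == 2:
        out["log2FC"] = means[group_names[1]] - means[group_names[0]]
    for name in group_names:
        out[f"mean_{name}"] = means[name]
    return out


def bh_adjust(pvals: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, original order restored."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class ScreenResult:
    """Annotated per-gene screen table with the candidate pass flag."""

    table: pd.DataFrame  # log2FC, F, p, q, mean_*, surface_go, passed
    thresholds: dict = field(default_factory=dict)
    n_unannotated: int = 0

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])


def candidate_filter(
    screen: pd.DataFrame,
    go_map: dict[str, list[str]],
    thresholds: dict | None = None,
    surface_terms: frozenset[str] | set[str] = SURFACE_GO_TERMS,
    signed: bool = False,
) -> ScreenResult:
    """Apply the four-way candidate filter to a differential screen table.

    ``screen`` must carry ``log2FC``, ``q`` and per-group ``mean_*``
    columns (``differential_f_test`` output plus ``q = bh_adjust(p)``).
    A gene missing from ``go_map`` counts as a non-member (logged). All
    inequalities are strict. With ``signed=True`` only positive fold
    changes pass.
    """
    thr = {"fc": 3.0, "q": 0.05, "expr": 7.0}
    thr.update(thresholds or {})
    surface_terms = set(surface_terms)
    missing = [g for g in screen.index if g not in go_map]
    if missing:
        logger.info("%d gene(s) absent from GO map; treated as non-members", len(missing))
    go_flag = pd.Series(
        [bool(surface_terms & set(go_map.get(g, []))) for g in screen.index],
        index=screen.index,
    )
    fc = screen["log2FC"] if signed else screen["log2FC"].abs()
    mean_cols = [c for c in screen.columns if c.startswith("mean_")]
    if not mean_cols:
        raise ValueError("screen table lacks per-group mean columns")
    max_mean = screen[mean_cols].max(axis=1)
    table = screen.copy()
    table["surface_go"] = go_flag
    table["passed"] = (
        (fc > thr["fc"])
        & (screen["q"] < thr["q"])
        & go_flag
        & (max_mean > thr["expr"])
    )
    return ScreenResult(table, thresholds=thr, n_unannotated=len(missing))


def signature_score(
    expr: ExpressionMatrix,
    panel: list[str],
    by: str = "stage",
) -> tuple[pd.DataFrame, pd.Series]:
    """Effector-signature score: per-gene z across populations, averaged.

    Each panel gene is z-scored across population means (mean 0, sd 1 over
    populations); the panel score of a population is the mean z over panel
    genes. Missing panel genes are logged and skipped; zero-variance genes
    get z = 0.
    """
    means = expr.population_means(by=by)
    present = [g for g in panel if g in means.index]
    absent = [g for g in panel if g not in means.index]
    if absent:
        logger.info("panel gene(s) not in matrix, skipped: %s", absent)
    if not present:
        raise ValueError("no panel genes present in the expression matrix")
    sub = means.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        logger.info("zero-variance panel gene(s), z set to 0: %s", list(sub.index[flat]))
    z = sub.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z, z.mean(axis=0).rename("panel_score")
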