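"""Expression-dynamics categorization and correlation analysis.

Gene x stage FPKM tables are summarised per stage transition: a gene is
"downregulated" when expression decreases with a fold change strictly
greater than two, "upregulated" when it increases likewise, and "stable"
otherwise; genes below 5 FPKM in both compared stages are flagged as
low-expression. Per-individual score matrices (e.g. regeneration scores
over time points) are analysed by pairwise Spearman correlation with a
Holm step-down adjustment over the whole matrix family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TransitionRecord",
    "CorrelationMatrix",
    "load_expression_table",
    "fold_change",
    "categorize_transition",
    "transition_summary",
    "spearman_holm",
]


@dataclass(frozen=True)
class TransitionRecord:
    gene: str
    stage_pair: tuple[str, str]
    fold_change: float  # max/min orientation, >= 1
    direction: str  # "up", "down" or "none"
    category: str  # "upregulated", "stable", "downregulated"
    low_expression: bool


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    significant: pd.DataFrame  # adjusted p < 0.05


def load_expression_table(path) -> pd.DataFrame:
    """Gene-rows x ordered-stage-columns FPKM TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return df


def fold_change(a: float, b: float, pseudocount: float = 0.0) -> float:
    """max/min fold change between two non-negative expression values."""
    if a < 0 or b < 0:
        raise ValueError("expression values must be non-negative")
    x, y = a + pseudocount, b + pseudocount
    if min(x, y) == 0:
        return float("inf") if max(x, y) > 0 else 1.0
    return max(x, y) / min(x, y)


def categorize_transition(
    fpkm_from: float,
    fpkm_to: float,
    gene: str = "",
    stage_pair: tuple[str, str] = ("", ""),
    fc_threshold: float = 2.0,
    low_threshold: float = 5.0,
    pseudocount: float = 0.01,
) -> TransitionRecord:
    """Categorise one gene's change between two stages.

    The fold change is computed on pseudocount-shifted values (zeros are
    otherwise undefined); only a fold change *strictly* greater than
    ``fc_threshold`` counts as up-/downregulation, so FC exactly 2 is
    stable. The low-expression flag requires both stages below
    ``low_threshold`` FPKM.
    """
    if fpkm_from < 0 or fpkm_to < 0:
        raise ValueError("FPKM values must be non-negative")
    fc = fold_change(fpkm_from, fpkm_to, pseudocount=pseudocount)
    if fpkm_to > fpkm_from:
        direction = "up"
    elif fpkm_to < fpkm_from:
        direction = "down"
    else:
        direction = "none"
    if fc > fc_threshold and direction == "up":
        category = "upregulated"
    elif fc > fc_threshold and direction == "down":
        category = "downregulated"
    else:
        category = "stable"
    return TransitionRecord(
        gene=gene,
        stage_pair=stage_pair,
        fold_change=fc,
        direction=direction,
        category=category,
        low_expression=(fpkm_from < low_threshold and fpkm_to < low_threshold),
    )


def transition_summary(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    fc_threshold: float = 2.0,
    low_threshold: float = 5.0,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Category proportions per stage pair over all genes.

    Returns one row per pair with proportions over all genes
    (``up``/``stable``/``down``, summing to 1), the same proportions
    restricted to genes above the low-expression flag
    (``up_expressed``/...), and the list of low-expression genes. Both
    denominators are reported because pie-chart conventions differ on
    whether greyed low-expression genes are counted.
    """
    if table.empty:
        raise ValueError("expression table has no genes")
    rows = []
    for frm, to in pairs:
        if frm not in table.columns or to not in table.columns:
            raise ValueError(f"stage pair ({frm!r}, {to!r}) not in table columns")
        recs = [
            categorize_transition(
                table.loc[g, frm],
                table.loc[g, to],
                gene=str(g),
                stage_pair=(frm, to),
                fc_threshold=fc_threshold,
                low_threshold=low_threshold,
                pseudocount=pseudocount,
            )
            for g in table.index
        ]
        n = len(recs)
        cats = pd.Series([r.category for r in recs])
        expressed = [r for r in recs if not r.low_expression]
        cats_expr = pd.Series([r.category for r in expressed])
        ne = len(expressed)
        rows.append(
            {
                "from": frm,
                "to": to,
                "up": (cats == "upregulated").sum() / n,
                "stable": (cats == "stable").sum() / n,
                "down": (cats == "downregulated").sum() / n,
                "up_expressed": (cats_expr == "upregulated").sum() / ne if ne else np.nan,
                "stable_expressed": (cats_expr == "stable").sum() / ne if ne else np.nan,
                "down_expressed": (cats_expr == "downregulated").sum() / ne if ne else np.nan,
                "low_expression_genes": tuple(r.gene for r in recs if r.low_expression),
            }
        )
    return pd.DataFrame(rows)


def spearman_holm(scores: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlation with Holm-adjusted p values.

    ``scores`` has individuals as rows and variables (time points) as
    columns. Ties receive average ranks. Constant columns yield undefined
    rho for their pairs; those pairs are flagged NaN and excluded from the
    Holm family, which otherwise spans all unordered variable pairs of the
    matrix.
    """
    if scores.shape[0] < 3:
        raise ValueError("need >= 3 individuals")
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    cols = tuple(str(c) for c in scores.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p_raw = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    constant = [scores.iloc[:, i].nunique() <= 1 for i in range(k)]
    pairs, pvals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                r, p = np.nan, np.nan
            else:
                r, p = spearmanr(scores.iloc[:, i], scores.iloc[:, j])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            p_raw.iloc[i, j] = p_raw.iloc[j, i] = p
            if not np.isnan(p):
                pairs.append((i, j))
                pvals.append(p)
    p_holm = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    p_holm.values[:] = np.nan
    np.fill_diagonal(p_holm.values, 0.0)
    if pvals:
        _, adj, _, _ = multipletests(pvals, method="holm")
        for (i, j), a in zip(pairs, adj):
            p_holm.iloc[i, j] = p_holm.iloc[j, i] = a
    significant = p_holm < alpha
    return CorrelationMatrix(
        variables=cols, rho=rho, p_raw=p_raw, p_holm=p_holm, significant=significant
    )
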