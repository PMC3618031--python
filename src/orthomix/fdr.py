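"""Single-species differential-expression baseline.

Per-gene two-sample t statistics (equal-variance form, consistent with the
common residual variance in the per-gene linear model) with Benjamini-
Hochberg FDR control at configurable levels.  This is the one-species
comparison arm against which the two-species mixture selection is judged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .effects import ExpressionSet

DEFAULT_LEVELS = (0.01, 0.00001)


def gene_t_tests(expr: ExpressionSet) -> pd.DataFrame:
    """Pooled-variance two-sample t test per gene, two-sided p-values.

    Genes with zero pooled variance are flagged ``degenerate``; their p-value
    is 0 when the class means differ and 1 otherwise.
    """
    n0, n1 = expr.class_counts()
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 samples per class for a t test")
    vals = expr.values.to_numpy(dtype=float)
    t_ind = expr.treatment
    x0 = vals[:, t_ind == 0]
    x1 = vals[:, t_ind == 1]
    mean0 = x0.mean(axis=1)
    mean1 = x1.mean(axis=1)
    sp2 = (x0.var(axis=1, ddof=1) * (n0 - 1) + x1.var(axis=1, ddof=1) * (n1 - 1)) / (n0 + n1 - 2)
    se = np.sqrt(sp2 * (1 / n0 + 1 / n1))

    degenerate = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean0) / se
    df = n0 + n1 - 2
    p = 2 * stats.t.sf(np.abs(t), df)
    diff = mean1 - mean0
    t = np.where(degenerate, np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)), t)
    p = np.where(degenerate, np.where(diff != 0, 0.0, 1.0), p)

    return pd.DataFrame(
        {"t_statistic": t, "p_value": p, "degenerate": degenerate}, index=expr.gene_ids
    )


def bh_select(p_values, level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up selection mask at the given FDR level."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return reject


def gene_test_table(expr: ExpressionSet, levels=DEFAULT_LEVELS) -> pd.DataFrame:
    """Full baseline table: t, p, BH-adjusted q and a selection flag per level."""
    table = gene_t_tests(expr)
    _, q, _, _ = multipletests(table["p_value"].to_numpy(), method="fdr_bh")
    table["adjusted_q"] = q
    for level in levels:
        table[f"selected_{level:g}"] = bh_select(table["p_value"].to_numpy(), level)
    return table
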