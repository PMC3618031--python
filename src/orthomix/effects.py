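"""Per-gene OLS treatment-effect estimation and ortholog pairing.

Each gene is fit with the linear model  X_ij = beta0_i + beta1_i * T_j + e_ij
where T is a {0, 1} subtype indicator.  With a binary regressor the OLS
solution is closed form: beta1 is the difference of class means and beta0 the
reference-class mean; the residual variance is the pooled estimate
SSE / (n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionSet:
    """One species' genes x samples log-expression matrix plus class labels.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``treatment`` is the aligned per-sample {0, 1} indicator (class 0 is the
    reference class).
    """

    values: pd.DataFrame
    treatment: np.ndarray

    def __post_init__(self) -> None:
        self.treatment = np.asarray(self.treatment, dtype=int)
        if self.treatment.shape != (self.values.shape[1],):
            raise ValueError("treatment must have one label per sample column")
        if not set(np.unique(self.treatment)) <= {0, 1}:
            raise ValueError("treatment labels must be 0/1")
        if len(set(np.unique(self.treatment))) < 2:
            raise ValueError("both classes must be present")
        if self.values.index.has_duplicates:
            raise ValueError("gene ids must be unique")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def drop_sample(self, sample_id) -> "ExpressionSet":
        """Return a copy without the given sample (for hold-out folds)."""
        keep = self.values.columns != sample_id
        if keep.all():
            raise KeyError(f"sample {sample_id!r} not found")
        return ExpressionSet(values=self.values.loc[:, keep], treatment=self.treatment[keep])

    def class_counts(self) -> tuple[int, int]:
        return int((self.treatment == 0).sum()), int((self.treatment == 1).sum())


def estimate_effects(expr: ExpressionSet) -> pd.DataFrame:
    """OLS fit of the per-gene treatment-effect model.

    Returns a DataFrame indexed by gene with columns ``beta0``, ``beta1``,
    ``residual_variance`` and ``degenerate``.  Missing expression values are
    ignored sample-wise; a gene is degenerate (variance NaN, effect still
    reported) when fewer than 3 samples or fewer than 1 per class remain.
    """
    vals = expr.values.to_numpy(dtype=float)
    t = expr.treatment
    m0 = ~np.isnan(vals[:, t == 0])
    m1 = ~np.isnan(vals[:, t == 1])
    n0 = m0.sum(axis=1)
    n1 = m1.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean0 = np.nanmean(np.where(m0, vals[:, t == 0], np.nan), axis=1)
        mean1 = np.nanmean(np.where(m1, vals[:, t == 1], np.nan), axis=1)
    beta0 = mean0
    beta1 = mean1 - mean0

    sse = np.nansum((vals[:, t == 0] - beta0[:, None]) ** 2, axis=1) + np.nansum(
        (vals[:, t == 1] - (beta0 + beta1)[:, None]) ** 2, axis=1
    )
    ntot = n0 + n1
    degenerate = (ntot < 3) | (n0 < 1) | (n1 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid_var = np.where(ntot > 2, sse / np.maximum(ntot - 2, 1), np.nan)
    resid_var = np.where(degenerate, np.nan, resid_var)

    return pd.DataFrame(
        {
            "beta0": beta0,
            "beta1": beta1,
            "residual_variance": resid_var,
            "degenerate": degenerate,
        },
        index=expr.gene_ids,
    )


def pair_orthologs(
    effects_a: pd.DataFrame,
    effects_h: pd.DataFrame,
    ortholog_map: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join two per-gene effect tables on an ortholog map.

    ``ortholog_map`` has columns ``gene_a`` and ``gene_h``.  Rows of the
    effect tables sharing a gene id (multiple probes per gene) are averaged
    first; map rows referencing a gene absent on either side are dropped and
    counted.  Output rows keep the map's order, with columns ``gene_a``,
    ``gene_h``, ``beta1a``, ``beta1h``.  Returns ``(pairs, report)`` where
    the report records retained and dropped pair counts.
    """
    if not {"gene_a", "gene_h"} <= set(ortholog_map.columns):
        raise ValueError("ortholog_map needs columns gene_a, gene_h")

    def collapse(effects: pd.DataFrame) -> pd.Series:
        b = effects["beta1"]
        if effects.index.has_duplicates:
            b = b.groupby(level=0).mean()
        return b

    beta_a = collapse(effects_a)
    beta_h = collapse(effects_h)

    ga = ortholog_map["gene_a"].to_numpy()
    gh = ortholog_map["gene_h"].to_numpy()
    a_vals = beta_a.reindex(ga).to_numpy()
    h_vals = beta_h.reindex(gh).to_numpy()
    keep = np.isfinite(a_vals) & np.isfinite(h_vals)

    pairs = pd.DataFrame(
        {"gene_a": ga[keep], "gene_h": gh[keep], "beta1a": a_vals[keep], "beta1h": h_vals[keep]}
    ).reset_index(drop=True)
    report = {"n_pairs": int(keep.sum()), "n_dropped": int((~keep).sum())}
    return pairs, report
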