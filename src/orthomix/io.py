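"""TSV / JSON readers and writers for the pipeline's on-disk formats.

Expression matrices are TSV with the gene id in the first column and one
column per sample; sample metadata is a two-column TSV (sample, class in
{0, 1}); ortholog maps are two-column TSV (gene_a, gene_h); effect-pair
tables are TSV with gene_a, gene_h, beta1a, beta1h.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .effects import ExpressionSet


def write_expression(expr: ExpressionSet, expr_path, meta_path) -> None:
    # full precision so downstream numbers are exactly recomputable from disk
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    pd.DataFrame({"sample": expr.sample_ids, "class": expr.treatment}).to_csv(
        meta_path, sep="\t", index=False
    )


def read_expression(expr_path, meta_path) -> ExpressionSet:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t")
    if list(meta.columns[:2]) != ["sample", "class"]:
        raise ValueError(f"{meta_path}: expected columns 'sample', 'class'")
    meta = meta.set_index("sample").reindex(values.columns)
    if meta["class"].isna().any():
        raise ValueError(f"{meta_path}: missing class label for some samples")
    return ExpressionSet(values=values, treatment=meta["class"].to_numpy(dtype=int))


def write_ortholog_map(pairs_of_ids: pd.DataFrame, path) -> None:
    pairs_of_ids[["gene_a", "gene_h"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_h"} <= set(m.columns):
        raise ValueError(f"{path}: expected columns gene_a, gene_h")
    return m


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_h", "beta1a", "beta1h"}
    if not required <= set(pairs.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return pairs


def write_truth(truth, pairs: pd.DataFrame, path) -> None:
    truth.to_frame(gene_a=pairs["gene_a"], gene_h=pairs["gene_h"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_dataset(out_dir, expr_a, expr_h, truth, pairs: pd.DataFrame | None = None) -> dict:
    """Write a full synthetic dataset; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_a": out / "expression_a.tsv",
        "meta_a": out / "samples_a.tsv",
        "expr_h": out / "expression_h.tsv",
        "meta_h": out / "samples_h.tsv",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression(expr_a, paths["expr_a"], paths["meta_a"])
    write_expression(expr_h, paths["expr_h"], paths["meta_h"])
    if pairs is None:
        pairs = pd.DataFrame(
            {"gene_a": expr_a.gene_ids.to_numpy(), "gene_h": expr_h.gene_ids.to_numpy()}
        )
    write_ortholog_map(pairs, paths["orthologs"])
    write_truth(truth, pairs, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def write_categories(pairs: pd.DataFrame, categories: np.ndarray, resp: np.ndarray, path) -> None:
    out = pairs[["gene_a", "gene_h"]].copy()
    out["category"] = categories
    for k in range(resp.shape[1]):
        out[f"posterior_{k}"] = resp[:, k]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
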