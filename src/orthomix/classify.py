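"""Two-cluster centroid classification and the LOOCV driver.

Subjects are clustered with 2-means on the expression of a selected gene
list; clusters get subtype labels by minimizing the training
misclassification count; a held-out subject is assigned to the nearest
centroid in squared Euclidean distance.  ``run_loocv`` ties the whole
procedure together: for every held-out human subject, the human treatment
effects, the mixture fit, the gene list, the centroids and the cluster
labels are all re-derived from the remaining subjects only (the animal
species' effects use all of its samples, since no animal is ever held out).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import ExpressionSet, estimate_effects, pair_orthologs
from .fdr import bh_select, gene_t_tests
from .mixture import fit_em

MIXTURE_SELECTIONS = {
    # differentially expressed in both species
    "both-species": frozenset({1, 2, 3, 4}),
    # differentially expressed in human (possibly also in the animal)
    "human-de": frozenset({1, 2, 3, 4, 5, 6}),
}


@dataclass
class ConfusionMatrix:
    """2x2 contingency of true subtype (rows) against cluster/prediction (columns)."""

    n11: int
    n12: int
    n21: int
    n22: int

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def as_frame(self, row_labels=("ABC", "GCB"), col_labels=("cluster 1", "cluster 2")):
        return pd.DataFrame(
            [[self.n11, self.n12], [self.n21, self.n22]],
            index=list(row_labels),
            columns=list(col_labels),
        )


@dataclass
class CentroidModel:
    """Nearest-centroid rule over a selected gene list."""

    gene_ids: list
    centroid_1: np.ndarray
    centroid_2: np.ndarray
    label_1: str
    label_2: str

    def __post_init__(self) -> None:
        self.centroid_1 = np.asarray(self.centroid_1, dtype=float)
        self.centroid_2 = np.asarray(self.centroid_2, dtype=float)
        m = len(self.gene_ids)
        if m < 1 or self.centroid_1.shape != (m,) or self.centroid_2.shape != (m,):
            raise ValueError("centroids must both have one entry per selected gene (M >= 1)")
        if self.label_1 == self.label_2:
            raise ValueError("cluster labels must be distinct")


def kmeans_2(
    data: np.ndarray, seed: int | np.random.Generator | None = None,
    n_restarts: int = 10, max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's 2-means with seeded restarts.

    Each restart starts from two distinct random subjects as centroids; the
    partition with the lowest within-cluster sum of squares wins.  An empty
    cluster is reseeded at the point farthest from the other centroid.
    Returns ``(centroids (2, M), assignments (n,), wcss)`` with assignments
    in {0, 1}.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects to form 2 clusters")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(n, size=2, replace=False)
        centroids = x[idx].copy()
        assign = np.full(n, -1)
        for _ in range(max_iter):
            d1 = ((x - centroids[0]) ** 2).sum(axis=1)
            d2 = ((x - centroids[1]) ** 2).sum(axis=1)
            new_assign = np.where(d1 < d2, 0, 1)
            for c in (0, 1):
                if not np.any(new_assign == c):
                    far = np.argmax(((x - centroids[1 - c]) ** 2).sum(axis=1))
                    new_assign[far] = c
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for c in (0, 1):
                centroids[c] = x[assign == c].mean(axis=0)
        d1 = ((x - centroids[0]) ** 2).sum(axis=1)
        d2 = ((x - centroids[1]) ** 2).sum(axis=1)
        wcss = float(np.where(assign == 0, d1, d2).sum())
        if best is None or wcss < best[2]:
            best = (centroids.copy(), assign.copy(), wcss)
    return best


def assign_cluster_labels(
    cm: ConfusionMatrix,
    seed: int | np.random.Generator | None = None,
    labels: tuple[str, str] = ("ABC", "GCB"),
) -> dict[int, str]:
    """Designate clusters so the training misclassification count is minimal.

    Rows of ``cm`` are the true classes in the order of ``labels``; columns
    are clusters 1 and 2.  If the two designations tie, the assignment is
    drawn at random from the seeded generator.
    """
    off = cm.n12 + cm.n21
    diag = cm.n11 + cm.n22
    if off < diag:
        flip = False
    elif off > diag:
        flip = True
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        flip = bool(rng.integers(2))
    first, second = labels
    return {1: second, 2: first} if flip else {1: first, 2: second}


def classify_subject(x, model: CentroidModel) -> str:
    """Nearest-centroid assignment in squared Euclidean distance.

    Strictly closer to centroid 1 gives cluster 1's label; ties (and
    anything else) give cluster 2's label.
    """
    v = np.asarray(x, dtype=float)
    if v.shape != model.centroid_1.shape:
        raise ValueError(f"subject vector has shape {v.shape}, model expects {model.centroid_1.shape}")
    d1 = float(((v - model.centroid_1) ** 2).sum())
    d2 = float(((v - model.centroid_2) ** 2).sum())
    return model.label_1 if d1 < d2 else model.label_2


def misclassification_rate(cm: ConfusionMatrix) -> float:
    """Off-diagonal proportion of a label-resolved confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.n12 + cm.n21) / cm.total


# ---------------------------------------------------------------------------
# LOOCV driver
# ---------------------------------------------------------------------------


@dataclass
class LoocvConfig:
    """Settings for the leave-one-out cross-validation run.

    ``class_names`` maps the {0, 1} treatment coding to subtype names
    (class 1 = ABC by default, mirroring the coding used throughout).
    EM settings apply to the per-fold mixture fits.
    """

    class_names: tuple[str, str] = ("GCB", "ABC")  # index = treatment code
    em_tol: float = 1e-8
    em_max_iter: int = 2000
    em_starts: int = 5
    kmeans_restarts: int = 10
    seed: int = 0


@dataclass
class LoocvResult:
    """Per-fold records plus the aggregated confusion matrix."""

    folds: pd.DataFrame  # subject, true/predicted class, M, checksum, ...
    confusion: ConfusionMatrix
    gene_lists: list[list]  # selected human genes per classified fold
    n_unclassifiable: int
    class_names: tuple[str, str]

    @property
    def misclassification_rate(self) -> float:
        return misclassification_rate(self.confusion)

    @property
    def intersection_genes(self) -> set:
        """Genes selected in every classifiable fold."""
        if not self.gene_lists:
            return set()
        out = set(self.gene_lists[0])
        for genes in self.gene_lists[1:]:
            out &= set(genes)
        return out

    @property
    def union_genes(self) -> set:
        out: set = set()
        for genes in self.gene_lists:
            out |= set(genes)
        return out


def _parse_selection(selection: str):
    if selection in MIXTURE_SELECTIONS:
        return "mixture", MIXTURE_SELECTIONS[selection]
    if selection.startswith("fdr:"):
        level = float(selection.split(":", 1)[1])
        if not 0 < level < 1:
            raise ValueError(f"FDR level must be in (0, 1), got {level}")
        return "fdr", level
    raise ValueError(
        f"unknown selection rule {selection!r}; use 'both-species', 'human-de' or 'fdr:<alpha>'"
    )


def _training_checksum(expr: ExpressionSet) -> str:
    h = hashlib.sha256()
    h.update("|".join(map(str, expr.sample_ids)).encode())
    h.update(np.ascontiguousarray(expr.values.to_numpy()).tobytes())
    h.update(expr.treatment.tobytes())
    return h.hexdigest()


def run_loocv(
    expr_a: ExpressionSet,
    expr_h: ExpressionSet,
    ortholog_map: pd.DataFrame,
    selection: str = "both-species",
    config: LoocvConfig | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of subtype classification.

    For each held-out human subject: re-estimate human effects on the
    remaining subjects (the animal effects use all animal samples), refit
    the mixture, select genes by ``selection`` ('both-species' = categories
    1-4, 'human-de' = categories 1-6, or 'fdr:<alpha>' for the
    single-species baseline), build 2-means centroids on the training
    subjects over the selected genes, label the clusters by the minimal
    training misclassification rule, and classify the held-out subject.

    A fold selecting zero genes is recorded as unclassifiable and skipped in
    the confusion matrix.
    """
    config = config or LoocvConfig()
    mode, rule = _parse_selection(selection)
    n0, n1 = expr_h.class_counts()
    if min(n0, n1) < 3:
        raise ValueError("LOOCV needs at least 3 human subjects per class")

    effects_a = estimate_effects(expr_a)  # all animal samples, every fold
    names = config.class_names
    ss = np.random.SeedSequence(config.seed)
    fold_seeds = ss.spawn(len(expr_h.sample_ids))

    records = []
    gene_lists = []
    n_unclassifiable = 0
    # aggregate confusion: rows true (ABC first), cols predicted (ABC first)
    agg = np.zeros((2, 2), dtype=int)
    abc, gcb = names[1], names[0]

    for fold, (subject, fseed) in enumerate(zip(expr_h.sample_ids, fold_seeds)):
        rng = np.random.default_rng(fseed)
        train_h = expr_h.drop_sample(subject)
        true_class = names[expr_h.treatment[fold]]
        checksum = _training_checksum(train_h)

        if mode == "mixture":
            effects_h = estimate_effects(train_h)
            pairs, _ = pair_orthologs(effects_a, effects_h, ortholog_map)
            fit = fit_em(
                pairs,
                tol=config.em_tol,
                max_iter=config.em_max_iter,
                starts=config.em_starts,
                seed=int(rng.integers(2**31)),
            )
            selected = pairs.loc[np.isin(fit.categories, list(rule)), "gene_h"].tolist()
        else:
            universe = ortholog_map["gene_h"].unique()
            sub = ExpressionSet(
                values=train_h.values.loc[train_h.values.index.intersection(universe)],
                treatment=train_h.treatment,
            )
            tests = gene_t_tests(sub)
            mask = bh_select(tests["p_value"].to_numpy(), rule)
            selected = tests.index[mask].tolist()

        record = {
            "fold": fold,
            "subject": subject,
            "true_class": true_class,
            "predicted_class": None,
            "M": len(selected),
            "n_train": len(train_h.sample_ids),
            "training_samples": ",".join(map(str, train_h.sample_ids)),
            "training_checksum": checksum,
        }
        if len(selected) == 0:
            n_unclassifiable += 1
            records.append(record)
            continue

        train_mat = train_h.values.loc[selected].to_numpy().T  # subjects x M
        centroids, assign, _ = kmeans_2(
            train_mat, seed=rng, n_restarts=config.kmeans_restarts
        )
        train_true = train_h.treatment  # 1 = ABC under default naming
        cm_train = ConfusionMatrix(
            n11=int(((train_true == 1) & (assign == 0)).sum()),
            n12=int(((train_true == 1) & (assign == 1)).sum()),
            n21=int(((train_true == 0) & (assign == 0)).sum()),
            n22=int(((train_true == 0) & (assign == 1)).sum()),
        )
        label_map = assign_cluster_labels(cm_train, seed=rng, labels=(abc, gcb))
        model = CentroidModel(
            gene_ids=selected,
            centroid_1=centroids[0],
            centroid_2=centroids[1],
            label_1=label_map[1],
            label_2=label_map[2],
        )
        x = expr_h.values.loc[selected, subject].to_numpy()
        predicted = classify_subject(x, model)
        record["predicted_class"] = predicted
        records.append(record)
        gene_lists.append(selected)

        i = 0 if true_class == abc else 1
        j = 0 if predicted == abc else 1
        agg[i, j] += 1

    confusion = ConfusionMatrix(
        n11=int(agg[0, 0]), n12=int(agg[0, 1]), n21=int(agg[1, 0]), n22=int(agg[1, 1])
    )
    return LoocvResult(
        folds=pd.DataFrame(records),
        confusion=confusion,
        gene_lists=gene_lists,
        n_unclassifiable=n_unclassifiable,
        class_names=names,
    )
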