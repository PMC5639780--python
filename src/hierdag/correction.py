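"""Hierarchical correction engines: HTD-DAG and TPR-DAG with its variants.

Both engines take a flat gene × term score matrix (entries in [0, 1],
columns covering exactly the ontology's terms) and return a corrected matrix
that obeys the true path rule: along every parent→child edge the parent score
is at least the child score, for every gene.

HTD-DAG visits terms top-down by increasing level (level = longest path from
the root) and caps each score at the minimum of its parents' corrected
scores; the closed form is ``corrected(i) = min over {i} ∪ ancestors(i) of
flat``.  TPR-DAG first runs a bottom-up per-level pass that averages each
term's flat score with the scores of its "positive" children (or descendants,
variant D), then applies the HTD top-down pass to restore consistency.

Positive-children strategies
----------------------------
T   constant threshold: children with bottom-up score > t̄.
AT  adaptive per-term thresholds fitted on training annotations.
TF  threshold-free: children whose bottom-up score exceeds the parent's flat
    score (never lowers a score, hence sensitivity ≥ HTD at any threshold).
W   weighted blend ``w·flat + (1−w)·mean(positive children)`` on top of any
    of the three strategies above; w = 1 reduces exactly to HTD.
D   positives drawn from all descendants rather than children only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import fmax
from .ontology import OntologyDAG, compute_levels

__all__ = [
    "TprConfig",
    "htd_correct",
    "tpr_correct",
    "tpr_node_update",
    "select_positive_children",
    "fit_adaptive_thresholds",
    "tune_weight",
    "DEFAULT_AT_GRID",
]

#: Grid over which per-term adaptive thresholds are fitted.
DEFAULT_AT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass
class TprConfig:
    """Configuration of a TPR-DAG run.

    Parameters
    ----------
    variant:
        One of ``"T"``, ``"AT"``, ``"TF"``, ``"W"``, ``"D"``.
    constant_threshold:
        t̄ for variants T and D (ignored otherwise).
    weight:
        w ∈ [0, 1] for variant W.
    child_strategy_for_w:
        Which positive-children rule variant W blends over (T, AT or TF).
    at_threshold_grid:
        Candidate thresholds for the adaptive strategy.
    """

    variant: str = "TF"
    constant_threshold: float = 0.5
    weight: float | None = None
    child_strategy_for_w: str = "TF"
    at_threshold_grid: tuple[float, ...] = field(default=DEFAULT_AT_GRID)

    def __post_init__(self) -> None:
        if self.variant not in {"T", "AT", "TF", "W", "D"}:
            raise ValueError(f"unknown TPR variant {self.variant!r}")
        if self.variant == "W":
            if self.weight is None:
                raise ValueError("variant W requires a weight in [0, 1]")
            if not 0.0 <= self.weight <= 1.0:
                raise ValueError(f"weight must be in [0, 1], got {self.weight}")
            if self.child_strategy_for_w not in {"T", "AT", "TF"}:
                raise ValueError(
                    f"unknown child strategy {self.child_strategy_for_w!r}"
                )
        if self.variant in {"T", "D"} and not 0.0 < self.constant_threshold < 1.0:
            raise ValueError("constant_threshold must lie in (0, 1)")

    @property
    def selection_strategy(self) -> str:
        return self.child_strategy_for_w if self.variant == "W" else self.variant


def _validate_inputs(
    dag: OntologyDAG, levels: dict[str, int], scores: pd.DataFrame
) -> None:
    if set(scores.columns) != set(dag.terms):
        raise ValueError("score matrix columns must match the ontology terms")
    values = scores.to_numpy(dtype=float)
    if np.isnan(values).any() or values.min() < 0.0 or values.max() > 1.0:
        raise ValueError("flat scores must lie in [0, 1]; rescale before correcting")


def _check_levels(dag: OntologyDAG, levels: dict[str, int]) -> None:
    for parent, child in dag.graph.edges:
        if levels[parent] >= levels[child]:
            raise ValueError(
                "level map is not strictly increasing along edge "
                f"({parent!r}, {child!r}); levels must be max-distance from "
                "the root (min-distance levels break consistency)"
            )


def _term_order(scores: pd.DataFrame, levels: dict[str, int]) -> list[int]:
    """Column indices sorted by (level, column position)."""
    return sorted(range(scores.shape[1]), key=lambda j: (levels[scores.columns[j]], j))


def htd_correct(
    dag: OntologyDAG,
    levels: dict[str, int],
    flat: pd.DataFrame,
    validate_levels: bool = True,
) -> pd.DataFrame:
    """Hierarchical top-down correction.

    Terms are visited by increasing level; each score is replaced by the
    minimum of itself and its parents' already-corrected scores.  The result
    is guaranteed consistent and equals, per gene and term, the minimum flat
    score over the term and all its ancestors.

    ``validate_levels=False`` skips the strict-increase check on the level
    map; it exists only to demonstrate why shortest-path levels are unsound.
    """
    _validate_inputs(dag, levels, flat)
    if validate_levels:
        _check_levels(dag, levels)
    values = flat.to_numpy(dtype=float).copy()
    col = {t: j for j, t in enumerate(flat.columns)}
    for j in _term_order(flat, levels):
        parents = dag.parents(flat.columns[j])
        if not parents:
            continue
        parent_min = np.min(values[:, [col[p] for p in parents]], axis=1)
        values[:, j] = np.minimum(values[:, j], parent_min)
    return pd.DataFrame(values, index=flat.index, columns=flat.columns)


def tpr_node_update(
    flat_score: float,
    positive_children_values,
    config: TprConfig,
) -> float:
    """Bottom-up update of a single term score for one gene.

    Base variants average the flat score with the positive children's scores;
    variant W blends them with weight ``w`` (returning the flat score
    unchanged when no child is positive, the limit of the average form).
    """
    vals = np.asarray(list(positive_children_values), dtype=float)
    if config.variant == "W":
        if vals.size == 0:
            return float(flat_score)
        w = config.weight
        return float(w * flat_score + (1.0 - w) * vals.mean())
    return float((flat_score + vals.sum()) / (1.0 + vals.size))


def select_positive_children(
    term: str,
    dag: OntologyDAG,
    working_scores: dict[str, float],
    flat_scores: dict[str, float],
    config: TprConfig,
    adaptive_thresholds: dict[str, float] | None = None,
) -> set[str]:
    """Positive children of ``term`` for a single gene.

    ``working_scores`` holds the bottom-up values already computed for every
    child.  Comparisons are strict: a child exactly at its threshold is
    negative.
    """
    strategy = config.selection_strategy
    children = dag.children(term)
    if strategy == "T":
        return {c for c in children if working_scores[c] > config.constant_threshold}
    if strategy == "TF":
        return {c for c in children if working_scores[c] > flat_scores[term]}
    if strategy == "AT":
        if adaptive_thresholds is None:
            raise ValueError(
                "adaptive strategy requires thresholds fitted on training "
                "annotations (fit_adaptive_thresholds)"
            )
        return {c for c in children if working_scores[c] > adaptive_thresholds[c]}
    raise ValueError(f"unknown selection strategy {strategy!r}")


def fit_adaptive_thresholds(
    train_scores: pd.DataFrame,
    train_annotations: pd.DataFrame,
    grid: tuple[float, ...] = DEFAULT_AT_GRID,
) -> dict[str, float]:
    """Per-term thresholds maximising the F-score on training data.

    For each term the grid point maximising the F-score of the binary rule
    ``score > t`` against the training labels is kept (smallest grid point on
    ties).  Thresholds are fitted on flat training scores so they exist before
    the bottom-up pass runs.
    """
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    labels = train_annotations.reindex(
        index=train_scores.index, columns=train_scores.columns, fill_value=0
    ).to_numpy(dtype=bool)
    values = train_scores.to_numpy(dtype=float)
    grid_arr = np.asarray(sorted(grid), dtype=float)
    thresholds: dict[str, float] = {}
    n_pos = labels.sum(axis=0)
    for j, term in enumerate(train_scores.columns):
        # predicted positives per grid point: shape (n_grid,)
        pred = values[:, j][None, :] > grid_arr[:, None]
        tp = (pred & labels[:, j][None, :]).sum(axis=1)
        n_pred = pred.sum(axis=1)
        denom = n_pred + n_pos[j]
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(denom > 0, 2.0 * tp / np.maximum(denom, 1), 0.0)
        thresholds[term] = float(grid_arr[int(np.argmax(f1))])
    return thresholds


def tpr_correct(
    dag: OntologyDAG,
    levels: dict[str, int],
    flat: pd.DataFrame,
    config: TprConfig,
    training_annotations: pd.DataFrame | None = None,
    training_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """True-path-rule correction (bottom-up pass followed by top-down pass).

    The bottom-up pass visits terms from the deepest level up to the root,
    updating each term's score from its positive children (variant D: positive
    descendants).  The subsequent top-down pass is exactly
    :func:`htd_correct` on the intermediate scores, which restores true-path
    consistency.

    For the adaptive (AT) strategy, ``training_annotations`` is required;
    thresholds are fitted on ``training_scores`` when given (defaulting to the
    flat matrix restricted to the training genes).
    """
    _validate_inputs(dag, levels, flat)
    _check_levels(dag, levels)

    thresholds = None
    if config.selection_strategy == "AT":
        if training_annotations is None:
            raise ValueError("AT strategy requires training annotations")
        fit_scores = training_scores
        if fit_scores is None:
            train_genes = [g for g in flat.index if g in training_annotations.index]
            fit_scores = flat.loc[train_genes]
        thresholds = fit_adaptive_thresholds(
            fit_scores, training_annotations, config.at_threshold_grid
        )

    flat_values = flat.to_numpy(dtype=float)
    values = flat_values.copy()
    col = {t: j for j, t in enumerate(flat.columns)}
    strategy = config.selection_strategy

    for j in reversed(_term_order(flat, levels)):
        term = flat.columns[j]
        if config.variant == "D":
            group = dag.descendants(term)
        else:
            group = dag.children(term)
        if not group:
            continue
        idx = np.fromiter((col[t] for t in sorted(group)), dtype=np.intp)
        group_vals = values[:, idx]  # (n_genes, n_group)
        if config.variant == "D" or strategy == "T":
            positive = group_vals > config.constant_threshold
        elif strategy == "TF":
            positive = group_vals > flat_values[:, j][:, None]
        else:  # AT
            thr = np.array([thresholds[flat.columns[k]] for k in idx])
            positive = group_vals > thr[None, :]
        pos_sum = np.where(positive, group_vals, 0.0).sum(axis=1)
        pos_count = positive.sum(axis=1)
        if config.variant == "W":
            w = config.weight
            mean = np.divide(
                pos_sum, pos_count, out=np.zeros_like(pos_sum), where=pos_count > 0
            )
            updated = np.where(
                pos_count > 0,
                w * flat_values[:, j] + (1.0 - w) * mean,
                flat_values[:, j],
            )
        else:
            updated = (flat_values[:, j] + pos_sum) / (1.0 + pos_count)
        values[:, j] = updated

    intermediate = pd.DataFrame(values, index=flat.index, columns=flat.columns)
    return htd_correct(dag, levels, intermediate)


def tune_weight(
    dag: OntologyDAG,
    levels: dict[str, int],
    flat: pd.DataFrame,
    training_annotations: pd.DataFrame,
    weight_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
    n_folds: int = 3,
    seed: int = 0,
    child_strategy: str = "TF",
) -> float:
    """Select the TPR-W weight by internal cross-validation on training genes.

    Genes are split into ``n_folds`` seeded folds; for every candidate weight
    the held-out fold scores are corrected with TPR-W and scored with Fmax
    against the training annotations.  The weight with the best mean fold
    Fmax is returned (smallest weight on ties).
    """
    weight_grid = list(weight_grid)
    if not weight_grid:
        raise ValueError("weight grid must be nonempty")
    if len(weight_grid) == 1:
        return float(weight_grid[0])
    genes = [g for g in flat.index if g in training_annotations.index]
    if len(genes) < n_folds:
        raise ValueError(f"need at least {n_folds} genes for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    fold_of = np.arange(len(genes)) % n_folds
    fold_assign = np.empty(len(genes), dtype=int)
    fold_assign[order] = fold_of

    non_root = [t for t in flat.columns if t != dag.root]
    mean_fmax = []
    for w in weight_grid:
        config = TprConfig(variant="W", weight=float(w), child_strategy_for_w=child_strategy)
        scores = []
        for fold in range(n_folds):
            held = [g for g, f in zip(genes, fold_assign) if f == fold]
            corrected = tpr_correct(
                dag,
                levels,
                flat.loc[held],
                config,
                training_annotations=training_annotations,
            )
            f, *_ = fmax(
                corrected.loc[:, non_root],
                training_annotations.loc[held, non_root],
            )
            scores.append(f)
        mean_fmax.append(float(np.mean(scores)))
    best = int(np.argmax(mean_fmax))
    return float(weight_grid[best])
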