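"""Gene-centric (Fmax) and term-centric (AUROC/AUPRC) evaluation.

Gene-centric metrics answer "which phenotypes belong to this gene?": at a
threshold τ the prediction set of a gene is every term scored ≥ τ, and
precision/recall are averaged over genes.  Fmax is the maximum over τ of the
harmonic mean of the averaged precision and recall — the CAFA convention.
Note Fmax selects τ a posteriori and is therefore an optimistic summary.

Term-centric metrics answer "which genes belong to this term?": per-term
AUROC (Mann–Whitney, ties counted half) and AUPRC (area under the
precision–recall step curve) over the gene ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "DEFAULT_TAU_GRID",
    "EvaluationReport",
    "gene_centric_pr_rc",
    "fmax",
    "term_centric_curves",
    "evaluate",
]

#: CAFA-style threshold grid {0.00, 0.01, ..., 1.00}.
DEFAULT_TAU_GRID: tuple[float, ...] = tuple(np.round(np.linspace(0.0, 1.0, 101), 2))


def _aligned(scores: pd.DataFrame, annotations: pd.DataFrame):
    labels = annotations.reindex(
        index=scores.index, columns=scores.columns, fill_value=0
    ).to_numpy(dtype=bool)
    return scores.to_numpy(dtype=float), labels


def gene_centric_pr_rc(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    tau: float,
    empty_prediction_as_zero: bool = False,
) -> tuple[float, float]:
    """Gene-averaged precision and recall at threshold ``tau``.

    A gene's prediction set at τ is every term with score ≥ τ.  Recall is
    averaged over the N genes carrying at least one annotation.  Precision is
    averaged over the genes with a nonempty prediction set among those N
    (their per-gene precision is otherwise 0/0); set
    ``empty_prediction_as_zero`` to count such genes as precision 0 instead.
    The root term must be excluded from both inputs by the caller.
    """
    values, labels = _aligned(scores, annotations)
    annotated = labels.any(axis=1)
    if not annotated.any():
        raise ValueError("no annotated genes: gene-centric metrics undefined")
    values = values[annotated]
    labels = labels[annotated]
    predicted = values >= tau
    tp = (predicted & labels).sum(axis=1).astype(float)
    n_pred = predicted.sum(axis=1)
    n_true = labels.sum(axis=1)
    recall = float((tp / n_true).mean())
    has_pred = n_pred > 0
    if not has_pred.any():
        return 0.0, recall
    per_gene_precision = tp[has_pred] / n_pred[has_pred]
    if empty_prediction_as_zero:
        precision = float(per_gene_precision.sum() / len(tp))
    else:
        precision = float(per_gene_precision.mean())
    return precision, recall


def fmax(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    tau_grid=DEFAULT_TAU_GRID,
) -> tuple[float, float, float, float]:
    """Maximum harmonic mean of gene-averaged precision and recall.

    Returns ``(fmax, tau_star, precision_at_tau_star, recall_at_tau_star)``
    where ``tau_star`` is the smallest grid threshold attaining the maximum.
    F is defined as 0 when precision + recall = 0.
    """
    grid = sorted(tau_grid)
    if not grid:
        raise ValueError("tau grid must be nonempty")
    best = (-1.0, 0.0, 0.0, 0.0)
    for tau in grid:
        pr, rc = gene_centric_pr_rc(scores, annotations, tau)
        f = 0.0 if pr + rc == 0 else 2.0 * pr * rc / (pr + rc)
        if f > best[0]:
            best = (f, float(tau), pr, rc)
    return best


def term_centric_curves(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    term: str,
) -> tuple[float, float]:
    """AUROC and AUPRC of one term's gene ranking.

    AUROC equals the Mann–Whitney statistic with the probabilistic tie
    convention (tied pairs count one half).  Raises if the term has a single
    class (no positives or no negatives).
    """
    y = annotations.reindex(index=scores.index)[term].to_numpy(dtype=bool)
    s = scores[term].to_numpy(dtype=float)
    if y.all() or not y.any():
        raise ValueError(f"term {term!r} has a single class; AUROC undefined")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


@dataclass
class EvaluationReport:
    """Per-term and per-gene metrics with overall summaries.

    ``per_term`` has columns ``auroc`` and ``auprc`` (NaN for single-class
    terms, which are excluded from the means); ``per_gene`` holds each gene's
    precision, recall and F at the Fmax threshold τ*.
    """

    per_term: pd.DataFrame
    per_gene: pd.DataFrame
    summary: dict = field(default_factory=dict)


def evaluate(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    root: str | None = None,
    tau_grid=DEFAULT_TAU_GRID,
) -> EvaluationReport:
    """Full gene-centric + term-centric evaluation of a score matrix.

    ``root`` names the ontology root, which is dropped from both matrices
    before computing gene-centric metrics (every gene trivially scores the
    root).  Single-class terms are reported as NaN and excluded from the mean
    AUROC/AUPRC with a warning.
    """
    if root is not None and root in scores.columns:
        scores = scores.drop(columns=[root])
    labels = annotations.reindex(
        index=scores.index, columns=scores.columns, fill_value=0
    )

    rows = {}
    skipped = 0
    for term in scores.columns:
        col = labels[term].to_numpy(dtype=bool)
        if col.all() or not col.any():
            rows[term] = (np.nan, np.nan)
            skipped += 1
            continue
        rows[term] = term_centric_curves(scores, labels, term)
    per_term = pd.DataFrame.from_dict(rows, orient="index", columns=["auroc", "auprc"])
    per_term.index.name = "term"
    if skipped:
        warnings.warn(
            f"{skipped} single-class term(s) excluded from AUROC/AUPRC means",
            stacklevel=2,
        )

    f, tau_star, pr, rc = fmax(scores, labels, tau_grid)

    values, lab = _aligned(scores, labels)
    annotated = lab.any(axis=1)
    predicted = values >= tau_star
    tp = (predicted & lab).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_pr = np.where(predicted.sum(axis=1) > 0, tp / predicted.sum(axis=1), np.nan)
        g_rc = np.where(lab.sum(axis=1) > 0, tp / lab.sum(axis=1), np.nan)
        g_f = np.where(
            np.nan_to_num(g_pr) + np.nan_to_num(g_rc) > 0,
            2 * np.nan_to_num(g_pr) * np.nan_to_num(g_rc)
            / (np.nan_to_num(g_pr) + np.nan_to_num(g_rc)),
            0.0,
        )
    per_gene = pd.DataFrame(
        {"precision": g_pr, "recall": g_rc, "f": g_f, "annotated": annotated},
        index=scores.index,
    )
    per_gene.index.name = "gene"

    summary = {
        "mean_auroc": float(per_term["auroc"].mean()),
        "mean_auprc": float(per_term["auprc"].mean()),
        "fmax": f,
        "tau_star": tau_star,
        "precision_at_fmax": pr,
        "recall_at_fmax": rc,
    }
    return EvaluationReport(per_term=per_term, per_gene=per_gene, summary=summary)
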