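"""Nomination of unannotated genes as candidates for new term annotations.

Given corrected prediction scores and the current annotation table, the
procedure first keeps only the terms a method predicts reliably (AUROC above
a cut-off, optionally restricted to leaf terms, the most specific ones), then
for each such term nominates the unannotated genes that outrank every
annotated gene among the top of the ranking:

1. sort genes by descending score;
2. take the top-k set S;
3. let A be the annotated genes within S;
4. let s̄ be the maximum score within A;
5. candidates are the unannotated genes in S with score ≥ s̄ — or all of S
   when A is empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .metrics import EvaluationReport
from .ontology import OntologyDAG

__all__ = ["Candidate", "select_best_terms", "select_candidate_genes",
           "candidate_report"]


@dataclass
class Candidate:
    gene: str
    score: float


def select_best_terms(
    report: EvaluationReport,
    dag: OntologyDAG,
    auroc_min: float = 0.95,
    leaves_only: bool = True,
) -> list[str]:
    """Terms predicted with AUROC strictly above ``auroc_min``.

    With ``leaves_only`` the list is restricted to terms without children
    (the most specific terms of the ontology).  Order follows the report.
    """
    good = report.per_term.index[report.per_term["auroc"] > auroc_min]
    if leaves_only:
        leaves = dag.leaves()
        good = [t for t in good if t in leaves]
    return list(good)


def select_candidate_genes(
    term: str,
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    top_k: int = 5,
) -> list[Candidate]:
    """Unannotated genes within the term's top-k that outrank the annotated.

    Ties in score are broken lexicographically by gene id so the top-k set is
    well defined.  Returns candidates in descending score order; every
    returned gene is unannotated for ``term`` and scores at least the best
    annotated gene in the top-k (all of the top-k when none is annotated).
    """
    col = scores[term]
    if len(col) < top_k:
        warnings.warn(
            f"only {len(col)} genes available; using all of them", stacklevel=2
        )
        top_k = len(col)
    ranked = pd.DataFrame({"gene": col.index, "score": col.to_numpy(dtype=float)})
    ranked = ranked.sort_values(["score", "gene"], ascending=[False, True],
                                kind="mergesort")
    top = ranked.head(top_k)
    annotated = annotations.reindex(index=scores.index, fill_value=0)[term]
    is_annot = top["gene"].map(lambda g: bool(annotated.get(g, 0))).to_numpy()
    if is_annot.any():
        s_bar = top.loc[is_annot, "score"].max()
        chosen = top[(~is_annot) & (top["score"] >= s_bar)]
    else:
        chosen = top
    return [Candidate(g, float(s)) for g, s in zip(chosen["gene"], chosen["score"])]


def candidate_report(
    report: EvaluationReport,
    dag: OntologyDAG,
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    auroc_min: float = 0.95,
    leaves_only: bool = True,
    top_k: int = 5,
) -> dict[str, list[Candidate]]:
    """Candidates for every reliably predicted (leaf) term."""
    terms = select_best_terms(report, dag, auroc_min=auroc_min,
                              leaves_only=leaves_only)
    return {
        t: select_candidate_genes(t, scores, annotations, top_k=top_k)
        for t in terms
    }
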