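"""Synthetic benchmark generator: DAGs, closed annotations, noisy flat scores.

The generator emulates the structural facts the correction engines rely on:
a sparse single-rooted layered DAG, gene annotations that are true-path
closed, and flat scores that correlate with the labels but violate the true
path rule.  It deliberately does not reproduce any real ontology's fan-out or
annotation-frequency statistics; conclusions drawn from it concern the
algorithms' contracts (consistency, dominance, degeneracies), not absolute
performance on real data.

Seed terms for a gene are sampled with probability proportional to
``level + 1`` so deep terms are annotated often enough for the bottom-up pass
to matter; uniform sampling concentrates annotations near the root and makes
correction trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import TprConfig, htd_correct, tpr_correct, tune_weight
from .metrics import EvaluationReport, evaluate
from .ontology import OntologyDAG, check_consistency, compute_levels, \
    propagate_annotations

__all__ = [
    "SyntheticSpec",
    "generate_dag",
    "generate_annotations",
    "generate_flat_scores",
    "generate_instance",
    "HoldoutResult",
    "holdout_experiment",
]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    ``edge_density`` is the probability that any given strictly-shallower
    term becomes an *extra* parent of a term (every non-root term always gets
    one parent from the level directly above, so its level is exact).
    ``mean_annotations_per_gene`` drives a Poisson draw of seed terms per
    gene, before ancestor closure.  ``noise_model`` is ``("gaussian", sigma)``
    — labels plus clipped Gaussian noise — or ``("flip", p)`` — each entry
    replaced by a uniform draw with probability p.
    """

    n_terms: int = 300
    n_genes: int = 400
    n_levels: int = 6
    edge_density: float = 0.01
    mean_annotations_per_gene: float = 4.0
    noise_model: tuple[str, float] = ("gaussian", 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 2 and self.n_terms > 1:
            raise ValueError("need at least 2 levels for a multi-term ontology")
        if self.n_terms > 1 and self.n_terms < self.n_levels:
            raise ValueError("n_terms must be at least n_levels")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        kind, _ = self.noise_model
        if kind not in {"gaussian", "flip"}:
            raise ValueError(f"unknown noise model {kind!r}")


def _term_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"T:{i:0{width}d}" for i in range(n)]


def generate_dag(spec: SyntheticSpec) -> OntologyDAG:
    """Layered random DAG with a single root, deterministic under the seed.

    The root sits alone at level 0; remaining terms are spread evenly over
    levels 1..n_levels−1.  Each non-root term receives exactly one parent
    from the level directly above (fixing its longest-path level) plus each
    strictly shallower term independently with probability ``edge_density``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = _term_ids(spec.n_terms)
    if spec.n_terms == 1:
        return OntologyDAG.from_edges([], extra_terms=ids)
    layers: list[list[str]] = [[ids[0]]]
    rest = ids[1:]
    n_layers = spec.n_levels - 1
    splits = np.array_split(np.arange(len(rest)), n_layers)
    for chunk in splits:
        layers.append([rest[i] for i in chunk])
    if any(len(layer) == 0 for layer in layers):
        raise ValueError("too few terms to populate every level")
    edges: list[tuple[str, str]] = []
    shallower: list[str] = [ids[0]]
    for depth in range(1, len(layers)):
        above = layers[depth - 1]
        for term in layers[depth]:
            primary = above[rng.integers(len(above))]
            edges.append((primary, term))
            extra = rng.random(len(shallower)) < spec.edge_density
            for cand, take in zip(shallower, extra):
                if take and cand != primary:
                    edges.append((cand, term))
        shallower = shallower + layers[depth]
    return OntologyDAG.from_edges(edges, extra_terms=ids)


def generate_annotations(dag: OntologyDAG, spec: SyntheticSpec) -> pd.DataFrame:
    """True-path-closed gene annotations with depth-biased seed terms.

    Each gene draws Poisson(``mean_annotations_per_gene``) seed terms with
    probability ∝ level + 1 (without replacement), which are then closed
    under ancestors.  Every gene is annotated to the root.
    """
    rng = np.random.default_rng(spec.seed + 1)
    levels = compute_levels(dag)
    terms = dag.terms
    weight = np.array([levels[t] + 1 for t in terms], dtype=float)
    prob = weight / weight.sum()
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    pairs: list[tuple[str, str]] = []
    for gene in genes:
        pairs.append((gene, dag.root))
        k = rng.poisson(spec.mean_annotations_per_gene)
        k = min(k, len(terms))
        if k:
            chosen = rng.choice(len(terms), size=k, replace=False, p=prob)
            pairs.extend((gene, terms[j]) for j in chosen)
    return propagate_annotations(dag, pairs, genes=genes)


def generate_flat_scores(
    annotations: pd.DataFrame, spec: SyntheticSpec
) -> pd.DataFrame:
    """Noisy flat scores correlated with the labels, in [0, 1].

    Gaussian model: ``clip(label + N(0, sigma), 0, 1)`` — at sigma 0 the
    scores equal the labels.  Flip model: each entry is independently
    replaced by a Uniform(0, 1) draw with probability p.
    """
    rng = np.random.default_rng(spec.seed + 2)
    labels = annotations.to_numpy(dtype=float)
    kind, param = spec.noise_model
    if kind == "gaussian":
        if param == 0:
            noisy = labels.copy()
        else:
            noisy = np.clip(labels + rng.normal(0.0, param, labels.shape), 0.0, 1.0)
    else:  # flip
        mask = rng.random(labels.shape) < param
        noisy = np.where(mask, rng.random(labels.shape), labels)
    return pd.DataFrame(noisy, index=annotations.index, columns=annotations.columns)


def generate_instance(spec: SyntheticSpec):
    """Convenience: ``(dag, levels, annotations, flat_scores)`` for one spec."""
    dag = generate_dag(spec)
    levels = compute_levels(dag)
    annotations = generate_annotations(dag, spec)
    flat = generate_flat_scores(annotations, spec)
    return dag, levels, annotations, flat


@dataclass
class HoldoutResult:
    """Paired flat vs corrected evaluation on held-out genes."""

    flat_report: EvaluationReport
    corrected_report: EvaluationReport
    flat_violations: int
    corrected_violations: int
    selected_weight: float | None = None


def holdout_experiment(
    spec: SyntheticSpec,
    train_fraction: float = 0.7,
    config: TprConfig | None = None,
    method: str = "tpr",
    tune_w: bool = False,
    weight_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
) -> HoldoutResult:
    """Scaled-down hold-out comparison of flat vs hierarchically corrected.

    Genes are split train/test by the spec's seed; anything fitted (adaptive
    thresholds, the TPR-W weight when ``tune_w``) uses training genes only;
    the test genes' flat scores are corrected and both versions are evaluated
    against the test annotations.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    dag, levels, annotations, flat = generate_instance(spec)
    rng = np.random.default_rng(spec.seed + 3)
    genes = list(annotations.index)
    order = rng.permutation(len(genes))
    n_train = int(round(train_fraction * len(genes)))
    if n_train == 0 or n_train == len(genes):
        raise ValueError("degenerate train/test split")
    train = [genes[i] for i in order[:n_train]]
    test = [genes[i] for i in order[n_train:]]

    config = config or TprConfig(variant="W", weight=0.5, child_strategy_for_w="TF")
    selected_w = None
    if method == "tpr" and config.variant == "W" and tune_w:
        selected_w = tune_weight(
            dag, levels, flat.loc[train], annotations.loc[train],
            weight_grid=weight_grid, seed=spec.seed + 4,
            child_strategy=config.child_strategy_for_w,
        )
        config = TprConfig(variant="W", weight=selected_w,
                           child_strategy_for_w=config.child_strategy_for_w,
                           at_threshold_grid=config.at_threshold_grid)

    flat_test = flat.loc[test]
    if method == "htd":
        corrected = htd_correct(dag, levels, flat_test)
    elif method == "tpr":
        corrected = tpr_correct(
            dag, levels, flat_test, config,
            training_annotations=annotations.loc[train],
            training_scores=flat.loc[train],
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    truth = annotations.loc[test]
    return HoldoutResult(
        flat_report=evaluate(flat_test, truth, root=dag.root),
        corrected_report=evaluate(corrected, truth, root=dag.root),
        flat_violations=len(check_consistency(dag, flat_test)),
        corrected_violations=len(check_consistency(dag, corrected)),
        selected_weight=selected_w,
    )
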