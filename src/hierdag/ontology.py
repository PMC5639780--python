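"""DAG-structured ontologies, annotation tables and the true path rule.

An ontology is held as an :class:`OntologyDAG`: a directed acyclic graph whose
edges point from parent (more general) to child (more specific) terms, with a
single root from which every term is reachable.  Annotation tables are binary
``pandas.DataFrame`` objects (genes on the index, terms on the columns); a
table is *true-path closed* when every gene annotated to a term is also
annotated to all of that term's ancestors.

Score matrices follow the same DataFrame convention with real entries in
``[0, 1]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Identifier used for the synthetic root inserted when an ontology has
#: several source roots.  Stripped from corrected outputs.
VIRTUAL_ROOT = "VIRTUAL:ROOT"

#: Score slack below which a child exceeding its parent is not reported as a
#: true-path violation (absorbs float rounding from averaging).
CONSISTENCY_TOL = 1e-9


class OntologyError(ValueError):
    """Fatal structural problem in an ontology or annotation input."""


@dataclass
class OntologyDAG:
    """A rooted DAG of ontology terms with parent→child edges.

    Parameters
    ----------
    graph:
        ``networkx.DiGraph`` with edges oriented parent → child.
    root:
        The unique term with no parents (possibly :data:`VIRTUAL_ROOT`).
    alt_id_map:
        Mapping from alternate (historical) term ids to primary ids.
    """

    graph: nx.DiGraph
    root: str
    alt_id_map: dict[str, str] = field(default_factory=dict)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        alt_id_map: Mapping[str, str] | None = None,
        extra_terms: Iterable[str] = (),
    ) -> "OntologyDAG":
        """Build and validate a DAG from ``(parent, child)`` pairs.

        If several roots are present a virtual root is inserted above them so
        the single-root invariant always holds downstream.
        """
        g = nx.DiGraph()
        g.add_nodes_from(extra_terms)
        g.add_edges_from(edges)
        if g.number_of_nodes() == 0:
            raise OntologyError("empty ontology")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if not roots:
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        if len(roots) > 1:
            for r in roots:
                g.add_edge(VIRTUAL_ROOT, r)
            root = VIRTUAL_ROOT
        else:
            root = roots[0]
        dag = cls(graph=g, root=root, alt_id_map=dict(alt_id_map or {}))
        dag.validate()
        return dag

    # -- accessors --------------------------------------------------------
    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.predecessors(term))

    def children(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        # networkx "ancestors" follows edge direction, so with parent→child
        # edges the graph-theoretic ancestors are the ontological ones.
        return nx.ancestors(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def leaves(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def resolve(self, term: str) -> str | None:
        """Map a possibly-alternate id to its primary id, else ``None``."""
        if term in self.graph:
            return term
        return self.alt_id_map.get(term)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        if g.in_degree(self.root) != 0:
            raise OntologyError(f"root {self.root!r} has an incoming edge")
        reachable = {self.root} | nx.descendants(g, self.root)
        missing = set(g.nodes) - reachable
        if missing:
            raise OntologyError(
                f"{len(missing)} term(s) unreachable from root "
                f"{self.root!r}, e.g. {sorted(missing)[:5]}"
            )
        bad_alt = {v for v in self.alt_id_map.values() if v not in g}
        if bad_alt:
            raise OntologyError(
                f"alt-id targets not in ontology: {sorted(bad_alt)[:5]}"
            )


def parse_obo(obo_source) -> OntologyDAG:
    """Parse an OBO document into an :class:`OntologyDAG`.

    Only ``is_a`` relationships become edges; obsolete terms are excluded.
    ``alt_id`` lines populate the alternate-id map.  A term referenced as an
    ``is_a`` target but never defined is a fatal error, as is any cycle.

    Parameters
    ----------
    obo_source:
        Path, URL or open text handle of an OBO document.
    """
    multigraph = obonet.read_obo(obo_source, ignore_obsolete=True)
    # obonet orients is_a edges child→parent and may keep non-is_a typedefs
    # as parallel keyed edges; keep is_a only and flip to parent→child.
    edges = [
        (parent, child)
        for child, parent, key in multigraph.edges(keys=True)
        if key == "is_a"
    ]
    defined = {n for n, data in multigraph.nodes(data=True) if data}
    undefined = set(multigraph.nodes) - defined
    if undefined:
        raise OntologyError(
            "is_a target(s) never defined in the document: "
            f"{sorted(undefined)[:5]}"
        )
    alt_id_map: dict[str, str] = {}
    for term, data in multigraph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_id_map[alt] = term
    return OntologyDAG.from_edges(
        edges, alt_id_map=alt_id_map, extra_terms=multigraph.nodes
    )


def compute_levels(dag: OntologyDAG) -> dict[str, int]:
    """Longest-path distance of every term from the root.

    The level of a term is the length of the longest directed path from the
    root to it; the root sits at level 0.  Computed in a single topological
    sweep, so linear in terms plus edges.  These max-distance levels (not
    shortest-path levels) are what make per-level top-down correction sound.
    """
    dag.validate()
    level = {t: 0 for t in dag.graph.nodes}
    for node in nx.topological_sort(dag.graph):
        for child in dag.graph.successors(node):
            if level[node] + 1 > level[child]:
                level[child] = level[node] + 1
    return level


def min_distance_levels(dag: OntologyDAG) -> dict[str, int]:
    """Shortest-path distance from the root (for comparison/diagnostics only).

    Using these levels for hierarchical correction is unsound; they exist so
    the failure mode can be demonstrated and rejected.
    """
    return nx.single_source_shortest_path_length(dag.graph, dag.root)


def propagate_annotations(
    dag: OntologyDAG,
    raw_annotations: pd.DataFrame | Iterable[tuple[str, str]],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """True-path closure of raw gene–term annotations.

    Every gene annotated to a term becomes annotated to all its ancestors.
    Accepts either a binary DataFrame (genes × terms) or an iterable of
    ``(gene, term)`` pairs.  Unknown term ids are remapped through the
    alternate-id map when possible, otherwise skipped with a warning (the
    skipped count is logged).  Idempotent.

    Returns
    -------
    pandas.DataFrame
        Binary int8 matrix over all ontology terms (columns in ``dag.terms``
        order), true-path closed.
    """
    if isinstance(raw_annotations, pd.DataFrame):
        pairs = [
            (g, t)
            for g, row in raw_annotations.iterrows()
            for t in raw_annotations.columns[row.values.astype(bool)]
        ]
        genes = list(raw_annotations.index)
    else:
        pairs = list(raw_annotations)
        if genes is None:
            genes = sorted({g for g, _ in pairs})
        else:
            genes = list(genes)

    terms = dag.terms
    col = {t: i for i, t in enumerate(terms)}
    row = {g: i for i, g in enumerate(genes)}
    labels = np.zeros((len(genes), len(terms)), dtype=np.int8)

    # ancestor closure per term, memoised
    closure_cache: dict[str, np.ndarray] = {}

    def closure_cols(term: str) -> np.ndarray:
        cached = closure_cache.get(term)
        if cached is None:
            members = {term} | dag.ancestors(term)
            cached = np.fromiter((col[t] for t in members), dtype=np.intp)
            closure_cache[term] = cached
        return cached

    skipped = 0
    for gene, term in pairs:
        primary = dag.resolve(term)
        if primary is None:
            skipped += 1
            continue
        if gene not in row:
            row[gene] = len(row)
            labels = np.vstack([labels, np.zeros((1, len(terms)), np.int8)])
            genes.append(gene)
        labels[row[gene], closure_cols(primary)] = 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} annotation pair(s) with unknown term ids",
            stacklevel=2,
        )
    return pd.DataFrame(labels, index=pd.Index(genes, name="gene"), columns=terms)


def prune_terms(
    dag: OntologyDAG,
    annotations: pd.DataFrame,
    min_count: int,
) -> tuple[OntologyDAG, pd.DataFrame]:
    """Drop terms annotated to fewer than ``min_count`` genes and rewire.

    ``annotations`` must already be true-path closed.  Each surviving term is
    re-attached to its nearest surviving ancestors so that ancestor relations
    among survivors — and reachability from the root — are preserved.  The
    root is never pruned.  ``min_count=0`` is the identity.
    """
    counts = annotations.reindex(columns=dag.terms, fill_value=0).sum(axis=0)
    survivors = {t for t in dag.terms if counts[t] >= min_count}
    survivors.add(dag.root)
    if survivors == set(dag.terms):
        return dag, annotations.loc[:, dag.terms]

    order = list(nx.topological_sort(dag.graph))
    # nearest surviving ancestors, propagated along topological order: for a
    # surviving node its "frontier" is itself; for a pruned node, the union of
    # its parents' frontiers.
    frontier: dict[str, set[str]] = {}
    new_edges: list[tuple[str, str]] = []
    for node in order:
        parent_front: set[str] = set()
        for p in dag.graph.predecessors(node):
            parent_front |= frontier[p]
        # drop ancestors dominated by a deeper frontier member
        minimal = {
            a
            for a in parent_front
            if not any(a in nx.ancestors(dag.graph, b) for b in parent_front if b != a)
        }
        if node in survivors:
            frontier[node] = {node}
            for a in minimal:
                new_edges.append((a, node))
        else:
            frontier[node] = minimal

    pruned = OntologyDAG.from_edges(
        new_edges,
        alt_id_map={a: p for a, p in dag.alt_id_map.items() if p in survivors},
        extra_terms=[t for t in dag.terms if t in survivors],
    )
    if set(pruned.terms) != survivors:
        raise OntologyError("pruning disconnected a surviving term from the root")
    kept = [t for t in dag.terms if t in survivors]
    return pruned, annotations.loc[:, kept]


def check_consistency(
    dag: OntologyDAG,
    scores: pd.DataFrame,
    tol: float = CONSISTENCY_TOL,
) -> list[tuple[str, str, str]]:
    """List every true-path violation in a score matrix.

    A violation is a ``(gene, parent, child)`` triple where the child score
    exceeds the parent score by more than ``tol``.  An empty list means the
    matrix is consistent (every parent score ≥ every child score).
    """
    missing = set(scores.columns) - set(dag.terms)
    if missing:
        raise OntologyError(f"score columns not in ontology: {sorted(missing)[:5]}")
    values = scores.to_numpy(dtype=float)
    col = {t: i for i, t in enumerate(scores.columns)}
    genes = scores.index
    violations: list[tuple[str, str, str]] = []
    for parent, child in dag.graph.edges:
        if parent not in col or child not in col:
            continue
        bad = np.nonzero(values[:, col[child]] > values[:, col[parent]] + tol)[0]
        for g in bad:
            violations.append((genes[g], parent, child))
    return violations
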