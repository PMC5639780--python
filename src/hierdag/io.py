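"""Plain-text readers and writers for the formats the pipeline exchanges.

Edge lists are two-column TSV (``parent<TAB>child``, no header); annotations
are ``gene<TAB>term`` pairs; score matrices are TSV with a ``gene`` first
column and term-id headers; networks are ``geneA<TAB>geneB<TAB>weight`` edge
lists.  Floats are printed with 10 significant digits so writer→reader
round-trips are exact at that precision and diffs are reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .ontology import OntologyDAG

__all__ = [
    "read_edge_list", "write_edge_list",
    "read_annotations", "write_annotations",
    "read_scores", "write_scores",
    "read_network", "write_network",
    "write_obo",
]

FLOAT_FMT = "%.10g"


# -- ontology edge lists --------------------------------------------------

def read_edge_list(path) -> OntologyDAG:
    """Parent→child TSV edge list into a validated ontology."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"],
                     dtype=str, comment="#")
    return OntologyDAG.from_edges(df.itertuples(index=False, name=None))


def write_edge_list(dag: OntologyDAG, path) -> None:
    with open(path, "w") as fh:
        for parent, child in sorted(dag.edges):
            fh.write(f"{parent}\t{child}\n")


# -- annotation pairs ------------------------------------------------------

def read_annotation_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                     dtype=str, comment="#")
    return list(df.itertuples(index=False, name=None))


def read_annotations(path, dag: OntologyDAG) -> pd.DataFrame:
    """Gene–term pair TSV, true-path closed over ``dag``."""
    from .ontology import propagate_annotations

    return propagate_annotations(dag, read_annotation_pairs(path))


def write_annotations(annotations: pd.DataFrame, path) -> None:
    """Write a binary annotation matrix back to gene–term pairs."""
    with open(path, "w") as fh:
        for gene, row in annotations.iterrows():
            for term in annotations.columns[row.values.astype(bool)]:
                fh.write(f"{gene}\t{term}\n")


# -- score matrices ---------------------------------------------------------

def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene":
        raise ValueError(
            f"{path}: first column of a score matrix must be 'gene' "
            f"(found {df.columns[0]!r} on line 1)"
        )
    return df.set_index("gene")


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.rename_axis("gene").to_csv(path, sep="\t", float_format=FLOAT_FMT)


# -- gene networks ----------------------------------------------------------

def read_network(path) -> pd.DataFrame:
    """Undirected weighted edge list into a symmetric adjacency DataFrame.

    Duplicate edges (either orientation) are averaged with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["a", "b", "weight"], dtype={0: str, 1: str},
                     comment="#")
    df["weight"] = df["weight"].astype(float)
    key = df.apply(lambda r: tuple(sorted((r["a"], r["b"]))), axis=1)
    grouped = df.groupby(key)["weight"].mean()
    if (df.groupby(key).size() > 1).any():
        warnings.warn("duplicate network edges averaged", stacklevel=2)
    genes = sorted({g for pair in grouped.index for g in pair})
    mat = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=genes)
    for (a, b), w in grouped.items():
        mat.loc[a, b] = w
        mat.loc[b, a] = w
    return mat


def write_network(network: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        genes = list(network.index)
        w = network.to_numpy(dtype=float)
        for i, a in enumerate(genes):
            for j in range(i, len(genes)):
                if w[i, j] != 0.0:
                    fh.write(f"{a}\t{genes[j]}\t{FLOAT_FMT % w[i, j]}\n")


# -- OBO writer (reading is delegated to obonet via ontology.parse_obo) ----

def write_obo(dag: OntologyDAG, path, name: str = "hierdag-export") -> None:
    """Minimal OBO serialisation: id/name/is_a/alt_id stanzas only."""
    rev_alt: dict[str, list[str]] = {}
    for alt, primary in dag.alt_id_map.items():
        rev_alt.setdefault(primary, []).append(alt)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {name}\n")
        for term in dag.terms:
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for alt in sorted(rev_alt.get(term, [])):
                fh.write(f"alt_id: {alt}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")
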