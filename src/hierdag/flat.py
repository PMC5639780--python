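"""Flat-score normalisation, gene-network construction and integration.

These utilities sit upstream of the hierarchical correction engines: they
turn heterogeneous per-term scores into comparable [0, 1] columns, build
gene–gene similarity networks from binary annotation profiles, merge several
networks into one consensus, and provide a simple kernelised neighbour scorer
so a full prediction pipeline can run end-to-end.

The neighbour scorer is a deliberately plain construction — the mean, over a
term's annotated genes, of the symmetric-normalised adjacency raised to a
small power.  It is a generic network smoother, not a re-implementation of
any published ranking method, and exists so the pipeline has a flat learner.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "normalize_max",
    "normalize_quantile",
    "jaccard_network",
    "ua_integrate",
    "kernel_average_score",
    "validate_network",
]


def normalize_max(scores: pd.DataFrame) -> pd.DataFrame:
    """Divide each term column by its own maximum so column maxima become 1.

    All-zero columns are left untouched with a warning.  Within-column rank
    order is preserved.
    """
    values = scores.to_numpy(dtype=float).copy()
    col_max = values.max(axis=0)
    zero = col_max <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero column(s) left unnormalised", stacklevel=2
        )
    safe = np.where(zero, 1.0, col_max)
    return pd.DataFrame(values / safe, index=scores.index, columns=scores.columns)


def normalize_quantile(scores: pd.DataFrame, axis: str = "terms") -> pd.DataFrame:
    """Quantile-normalise so all columns share one empirical distribution.

    Each column is mapped onto the reference distribution formed by the mean
    of the column-wise sorted values; tied entries receive the mean of the
    reference values they would have occupied.  ``axis="genes"`` transposes
    first, normalising across genes instead of terms.
    """
    if axis not in {"terms", "genes"}:
        raise ValueError("axis must be 'terms' or 'genes'")
    if axis == "genes":
        return normalize_quantile(scores.T, axis="terms").T
    if scores.shape[1] < 2:
        warnings.warn("fewer than two columns; quantile normalisation is identity",
                      stacklevel=2)
        return scores.copy()
    values = scores.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # average reference values over tied input blocks
        s = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return pd.DataFrame(out, index=scores.index, columns=scores.columns)


def jaccard_network(binary_features: pd.DataFrame) -> pd.DataFrame:
    """Gene–gene network weighted by the Jaccard index of feature profiles.

    ``weight(g, h) = |features(g) ∩ features(h)| / |features(g) ∪ features(h)|``
    with weight 0 when the union is empty.  Input entries must be 0/1.
    """
    values = binary_features.to_numpy(dtype=float)
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("feature matrix must be binary (0/1 entries)")
    inter = values @ values.T
    sizes = values.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    genes = binary_features.index
    return pd.DataFrame(weights, index=genes, columns=genes)


def validate_network(network: pd.DataFrame, tol: float = 1e-12) -> None:
    """Check symmetry, [0, 1] range and matching gene labels."""
    if not network.index.equals(network.columns):
        raise ValueError("network rows and columns must list the same genes")
    w = network.to_numpy(dtype=float)
    if not np.allclose(w, w.T, atol=tol):
        raise ValueError("network weights must be symmetric")
    if w.min() < -tol or w.max() > 1 + tol:
        raise ValueError("network weights must lie in [0, 1]")


def _minmax(network: pd.DataFrame) -> pd.DataFrame:
    w = network.to_numpy(dtype=float)
    lo, hi = w.min(), w.max()
    if hi <= lo:
        return network.copy()
    return pd.DataFrame((w - lo) / (hi - lo), index=network.index,
                        columns=network.columns)


def ua_integrate(networks: list[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted-average consensus of several gene networks.

    Gene universes are unioned (absent edges weigh 0); each network is first
    min–max normalised onto [0, 1] over its observed weights, then the
    consensus weight is the plain mean across networks.  Permutation-invariant
    in the network list and idempotent for identical inputs.
    """
    if not networks:
        raise ValueError("need at least one network")
    genes = sorted(set().union(*(set(n.index) for n in networks)))
    total = np.zeros((len(genes), len(genes)))
    for net in networks:
        validate_network(net)
        norm = _minmax(net).reindex(index=genes, columns=genes, fill_value=0.0)
        total += norm.to_numpy(dtype=float)
    out = pd.DataFrame(total / len(networks), index=pd.Index(genes, name="gene"),
                       columns=genes)
    return out


def kernel_average_score(
    network: pd.DataFrame,
    positives: set[str],
    steps: int = 1,
) -> pd.Series:
    """Score genes by smoothed proximity to a term's annotated genes.

    The kernel is ``K = (D^{-1/2} W D^{-1/2})^steps`` with ``D`` the degree
    diagonal (isolated genes are given self-degree 1 so the normalisation is
    defined); a gene's score is the mean of ``K[g, p]`` over the positive
    genes ``p``, max-normalised so the best gene scores 1.
    """
    if not positives:
        raise ValueError("positives must be a nonempty gene set")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    validate_network(network)
    missing = positives - set(network.index)
    if missing:
        raise ValueError(f"positive genes absent from network: {sorted(missing)[:5]}")
    w = network.to_numpy(dtype=float)
    degree = w.sum(axis=1)
    degree[degree <= 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    k = d_inv_sqrt[:, None] * w * d_inv_sqrt[None, :]
    k = np.linalg.matrix_power(k, steps)
    pos_idx = [network.index.get_loc(p) for p in sorted(positives)]
    raw = k[:, pos_idx].mean(axis=1)
    top = raw.max()
    if top > 0:
        raw = raw / top
    return pd.Series(raw, index=network.index, name="score")
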