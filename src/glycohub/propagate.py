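"""Cell-type co-expression network, topological overlap, and random
walk with restart for seed-gene neighborhood prioritization.

The network is built WGCNA-style on the normalized expression of one
annotated cell type: signed-absolute soft adjacency a_ij = |cor|^beta,
smoothed into a topological overlap measure (TOM), thresholded at a
percentile of the unique off-diagonal values, and propagated from seed
genes (e.g. BCL6 and SGK1) by RWR. Metacell aggregation is deliberately
omitted: the adjacency is computed on single cells directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from glycohub.enrich import ora_hypergeom
from glycohub.io import GeneSetCollection

__all__ = [
    "WeightedNetwork",
    "soft_adjacency",
    "tom_matrix",
    "threshold_edges",
    "PropagationResult",
    "rwr",
    "top_neighbors",
    "neighbor_enrichment",
    "fit_soft_threshold",
]


@dataclass
class WeightedNetwork:
    """Symmetric non-negative gene-gene weight matrix in [0, 1].

    ``kind`` is "adjacency" (zero diagonal) or "tom" (unit diagonal).
    """

    genes: list[str]
    weights: np.ndarray
    kind: str = "adjacency"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if w.size and (w.min() < -1e-12 or w.max() > 1 + 1e-9):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.genes)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle nonzero weights as (gene_a, gene_b, weight)."""
        iu, ju = np.triu_indices(self.n, k=1)
        mask = self.weights[iu, ju] > 0
        return pd.DataFrame(
            {
                "gene_a": np.asarray(self.genes)[iu[mask]],
                "gene_b": np.asarray(self.genes)[ju[mask]],
                "weight": self.weights[iu, ju][mask],
            }
        )


def soft_adjacency(
    expr: pd.DataFrame, beta: float = 8.0
) -> WeightedNetwork:
    """Soft-thresholded co-expression adjacency |Pearson r|^beta.

    ``expr`` is genes x cells (normalized values). Zero-variance genes
    are dropped with a warning; the diagonal is zero.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    mat = expr.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} zero-variance genes dropped")
    genes = [g for g, k in zip(expr.index, keep) if k]
    if len(genes) < 3 or mat.shape[1] < 3:
        raise ValueError("need >=3 usable genes and >=3 cells")
    r = np.corrcoef(mat[keep])
    a = np.abs(np.clip(r, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(genes, a, kind="adjacency")


def tom_matrix(adj: WeightedNetwork) -> WeightedNetwork:
    """Topological overlap measure of a soft adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, with k_i the weighted degree; TOM_ii = 1. Shared-neighbor
    structure boosts the similarity of weakly connected but strongly
    co-embedded genes.
    """
    a = adj.weights
    if adj.kind != "adjacency":
        raise ValueError("tom_matrix expects an adjacency network")
    k = a.sum(axis=0)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize roundoff
    return WeightedNetwork(list(adj.genes), tom, kind="tom")


def threshold_edges(net: WeightedNetwork, percentile: float = 90.0) -> WeightedNetwork:
    """Keep edges strictly above a percentile of unique pair weights.

    The threshold is the linear-interpolation percentile of the strict
    upper triangle; surviving edges retain their weights. An all-equal
    matrix yields an empty edge set with a warning.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    iu, ju = np.triu_indices(net.n, k=1)
    vals = net.weights[iu, ju]
    thr = float(np.percentile(vals, percentile))
    keep = vals > thr
    if not keep.any():
        warnings.warn("no edge above the percentile threshold; empty network")
    w = np.zeros_like(net.weights)
    w[iu[keep], ju[keep]] = vals[keep]
    w += w.T
    if net.kind == "tom":
        np.fill_diagonal(w, 1.0)
    return WeightedNetwork(list(net.genes), w, kind=net.kind)


@dataclass
class PropagationResult:
    """RWR steady state: per-gene visiting probability (sums to 1)."""

    probabilities: pd.Series
    seeds: tuple[str, ...]
    restart: float
    iterations: int
    converged: bool


def rwr(
    net: WeightedNetwork,
    seeds: Sequence[str],
    r: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PropagationResult:
    """Random walk with restart from uniform seed mass.

    The transition matrix is the column-normalized edge-weight matrix
    (off-diagonal weights only; nodes with no edges get a self-loop).
    Iterates p <- (1-r) W p + r p0 until the L1 change drops below
    ``tol``. Non-convergence raises.
    """
    if not 0 < r <= 1:
        raise ValueError("restart probability must lie in (0, 1]")
    missing = [s for s in seeds if s not in net.genes]
    if missing:
        raise KeyError(f"seed genes absent from network: {missing}")
    w = net.weights.copy()
    np.fill_diagonal(w, 0.0)
    if not (w > 0).any():
        raise ValueError("network has no edges")
    col = w.sum(axis=0)
    dangling = col == 0
    if dangling.any():
        w[dangling, dangling] = 1.0
        col = w.sum(axis=0)
    wn = w / col

    idx = {g: i for i, g in enumerate(net.genes)}
    p0 = np.zeros(net.n)
    for s in set(seeds):
        p0[idx[s]] = 1.0
    p0 /= p0.sum()

    p = p0.copy()
    for it in range(1, max_iter + 1):
        nxt = (1.0 - r) * (wn @ p) + r * p0
        delta = float(np.abs(nxt - p).sum())
        p = nxt
        if delta < tol:
            p = p / p.sum()
            return PropagationResult(
                pd.Series(p, index=net.genes), tuple(dict.fromkeys(seeds)), r, it, True
            )
    raise RuntimeError(f"RWR did not converge within {max_iter} iterations")


def top_neighbors(result: PropagationResult, k: int = 30) -> list[str]:
    """The k non-seed genes with the highest steady-state probability.

    Ties break alphabetically; seeds are always excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seeds = set(result.seeds)
    items = [(g, p) for g, p in result.probabilities.items() if g not in seeds]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [g for g, _ in items[:k]]


def neighbor_enrichment(
    neighbors: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """ORA of an RWR neighborhood against a gene-set collection."""
    if len(neighbors) == 0:
        raise ValueError("empty neighbor list")
    return ora_hypergeom(neighbors, collection, universe)


def fit_soft_threshold(
    expr: pd.DataFrame, betas: Sequence[float] = tuple(range(1, 21))
) -> tuple[float, pd.DataFrame]:
    """Pick beta by scale-free topology fit (max R^2 of log-log degree fit).

    For each candidate beta the weighted degree distribution is binned
    and log10(freq) regressed on log10(degree); the beta with the best
    R^2 is returned along with the diagnostics table.
    """
    rows = []
    best, best_r2 = betas[0], -np.inf
    for beta in betas:
        net = soft_adjacency(expr, beta=beta)
        k = net.weights.sum(axis=0)
        k = k[k > 0]
        if k.size < 5:
            rows.append({"beta": beta, "r2": np.nan})
            continue
        hist, edges = np.histogram(k, bins=min(10, max(3, k.size // 5)))
        centers = (edges[:-1] + edges[1:]) / 2
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            rows.append({"beta": beta, "r2": np.nan})
            continue
        x, y = np.log10(centers[ok]), np.log10(hist[ok])
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"beta": beta, "r2": r2})
        if r2 > best_r2:
            best, best_r2 = beta, r2
    return float(best), pd.DataFrame(rows)
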