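"""Random walk with restart (RWR) over a gene functional network.

The walk iterates s <- (1-p) * W @ s + p * s0, where W is the
column-stochastic transition matrix of the network (columns normalized by
degree, or by weighted degree when ``weighted=True``), p is the restart
probability, and s0 is the restart distribution: uniform over the seed genes
present in the network. A larger p keeps probability mass closer to the
seeds. Columns of genes with no neighbours (dangling genes) are replaced by
the restart distribution, the standard teleport fix that keeps the score
vector summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network_io import GeneNetwork

__all__ = ["PropagationResult", "rwr", "rwr_exact", "SeedError"]


class SeedError(ValueError):
    """No seed gene is present in the network."""


@dataclass
class PropagationResult:
    """Converged per-gene RWR score vector for one seed gene set."""

    genes: tuple[str, ...]
    scores: np.ndarray
    seed_genes: frozenset[str]
    restart_p: float
    iterations: int
    converged: bool

    @property
    def M(self) -> float:
        """Maximum score of the updated score vector."""
        return float(self.scores.max())

    @property
    def m(self) -> float:
        """Minimum score of the updated score vector."""
        return float(self.scores.min())

    def to_frame(self) -> pd.DataFrame:
        """(gene, score) table sorted by descending score, then gene id."""
        df = pd.DataFrame({"gene": self.genes, "score": self.scores})
        return df.sort_values(
            ["score", "gene"], ascending=[False, True], ignore_index=True
        )


def _restart_vector(net: GeneNetwork, seeds: Iterable[str]) -> tuple[np.ndarray, frozenset[str]]:
    present = sorted(net.restrict(seeds))
    if not present:
        raise SeedError("no seed gene overlaps the network")
    s0 = np.zeros(net.n_genes)
    idx = [net.index[g] for g in present]
    s0[idx] = 1.0 / len(idx)
    return s0, frozenset(present)


def _transition(net: GeneNetwork, weighted: bool) -> tuple[sp.csr_array, np.ndarray]:
    """Column-normalized transition matrix and the dangling-column mask."""
    adj = net.adjacency
    if not weighted:
        adj = adj.copy()
        adj.data = np.ones_like(adj.data)
    colsum = np.asarray(adj.sum(axis=0)).ravel()
    dangling = colsum == 0
    inv = np.zeros_like(colsum)
    np.divide(1.0, colsum, out=inv, where=~dangling)
    w = (adj @ sp.diags_array(inv)).tocsr()
    return w, dangling


def rwr(
    net: GeneNetwork,
    seeds: Iterable[str],
    restart_p: float = 0.9,
    tol: float = 1e-10,
    max_iter: int = 1000,
    weighted: bool = False,
) -> PropagationResult:
    """Iterate the restart walk to its fixed point.

    Stops when the L1 change between successive score vectors drops below
    ``tol`` (or after ``max_iter`` iterations, flagged via ``converged``).
    """
    if not (0.0 < restart_p <= 1.0):
        raise ValueError(f"restart_p must be in (0, 1], got {restart_p}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    s0, seed_genes = _restart_vector(net, seeds)
    if restart_p == 1.0:
        return PropagationResult(net.genes, s0.copy(), seed_genes, restart_p, 0, True)
    w, dangling = _transition(net, weighted)
    s = s0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        dangling_mass = float(s[dangling].sum()) if dangling.any() else 0.0
        s_new = (1.0 - restart_p) * (w @ s)
        s_new += ((1.0 - restart_p) * dangling_mass + restart_p) * s0
        delta = float(np.abs(s_new - s).sum())
        s = s_new
        if delta < tol:
            converged = True
            break
    return PropagationResult(net.genes, s, seed_genes, restart_p, iterations, converged)


def rwr_exact(
    net: GeneNetwork,
    seeds: Iterable[str],
    restart_p: float = 0.9,
    weighted: bool = False,
) -> PropagationResult:
    """Direct dense linear solve of (I - (1-p) W) s = p s0.

    Equivalent to the fixed point of :func:`rwr`; intended for small networks
    and as an independent numerical cross-check of the iterative walk.
    """
    if not (0.0 < restart_p <= 1.0):
        raise ValueError(f"restart_p must be in (0, 1], got {restart_p}")
    s0, seed_genes = _restart_vector(net, seeds)
    if restart_p == 1.0:
        return PropagationResult(net.genes, s0.copy(), seed_genes, restart_p, 0, True)
    w, dangling = _transition(net, weighted)
    wd = w.toarray()
    if dangling.any():
        wd[:, dangling] = s0[:, None]
    n = net.n_genes
    s = np.linalg.solve(np.eye(n) - (1.0 - restart_p) * wd, restart_p * s0)
    return PropagationResult(net.genes, s, seed_genes, restart_p, 0, True)
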