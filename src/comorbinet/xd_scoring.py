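"""XD score: bin-based network relatedness of two diseases' gene sets.

Given the converged RWR score vector seeded by disease d1, all network genes
are sorted by score and discretized into ``n`` equal-width bins spanning
[m, M] (bin 1 holds the highest scores). With P_ic the fraction of the
target disease's (d2) genes in bin i and P_ia the fraction of all network
genes in bin i, the directed score is the rank-weighted difference

    XD(d1 -> d2) = sum_i (P_ic - P_ia) / i.

It is zero when the target distributes like the background, positive when
target genes concentrate in high-score bins (closer-than-average network
association), and negative when they sit in low bins. The reverse direction
(d2 seeds the walk, d1 is the target) is computed the same way and the final
pair score is the minimum of the two directions. The 1/i weighting is a
pluggable strategy (``weights=``) shared by both directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .network_io import DiseaseGeneMap, GeneNetwork
from .propagation import PropagationResult, rwr

__all__ = [
    "BinProfile",
    "PairScores",
    "UnscorablePairError",
    "CATEGORY_BOTH",
    "CATEGORY_NG_ONLY",
    "CATEGORY_XD_ONLY",
    "CATEGORY_NEITHER",
    "CATEGORY_UNSCORABLE",
    "CATEGORIES",
    "bin_scores",
    "xd_directed",
    "xd_score",
    "count_shared_genes",
    "classify_pair",
    "score_all_pairs",
]

CATEGORY_BOTH = "+XDand+NG"
CATEGORY_NG_ONLY = "+NGnot+XD"
CATEGORY_XD_ONLY = "+XDnot+NG"
CATEGORY_NEITHER = "not+XDnot+NG"
CATEGORY_UNSCORABLE = "unscorable"
CATEGORIES = (CATEGORY_BOTH, CATEGORY_NG_ONLY, CATEGORY_XD_ONLY, CATEGORY_NEITHER)


class UnscorablePairError(ValueError):
    """A gene set shares no gene with the network; XD is undefined, not zero."""


WeightSpec = Callable[[int], np.ndarray] | Sequence[float] | str | None

_WEIGHTINGS: dict[str, Callable[[int], np.ndarray]] = {
    "reciprocal_rank": lambda n: 1.0 / np.arange(1, n + 1, dtype=float),
    "geometric": lambda n: 0.5 ** np.arange(n, dtype=float),
}


def _resolve_weights(weights: WeightSpec, n_bins: int) -> np.ndarray:
    if weights is None:
        weights = "reciprocal_rank"
    if isinstance(weights, str):
        try:
            return _WEIGHTINGS[weights](n_bins)
        except KeyError:
            raise ValueError(
                f"unknown weighting {weights!r}; options: {sorted(_WEIGHTINGS)}"
            ) from None
    if callable(weights):
        w = np.asarray(weights(n_bins), dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n_bins,):
        raise ValueError(f"weights must have length {n_bins}")
    return w


@dataclass
class BinProfile:
    """Equal-width score bins with background (P_ia) and target (P_ic) fractions."""

    n_bins: int
    bin_edges: np.ndarray  # descending, length n_bins + 1, spanning [M, m]
    p_all: np.ndarray  # P_ia
    p_target: np.ndarray  # P_ic
    bin_of: np.ndarray  # 1-based bin index per network gene
    genes: tuple[str, ...]
    target_genes: frozenset[str]
    degenerate: bool = False

    @property
    def genes_per_bin(self) -> list[set[str]]:
        bins: list[set[str]] = [set() for _ in range(self.n_bins)]
        for g, b in zip(self.genes, self.bin_of):
            bins[b - 1].add(g)
        return bins


def _assign_bins(scores: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """1-based bin per gene plus descending edges; degenerate when M == m."""
    big_m = float(scores.max())
    small_m = float(scores.min())
    if big_m == small_m:
        return np.ones(len(scores), dtype=np.int64), np.array([big_m, small_m]), True
    span = big_m - small_m
    idx = np.floor(n_bins * (big_m - scores) / span).astype(np.int64) + 1
    np.minimum(idx, n_bins, out=idx)
    edges = big_m - np.arange(n_bins + 1) * span / n_bins
    return idx, edges, False


def bin_scores(
    prop: PropagationResult, target: Iterable[str], n_bins: int = 10
) -> BinProfile:
    """Discretize a propagation result against a target disease's gene set.

    A gene with score s lands in bin ``min(n, floor(n*(M-s)/(M-m)) + 1)``:
    half-open intervals, the maximum score in bin 1 and the minimum in bin n.
    If every score is identical the profile collapses to one flagged
    degenerate bin.
    """
    index = {g: i for i, g in enumerate(prop.genes)}
    target_in = frozenset(g for g in target if g in index)
    if not target_in:
        raise UnscorablePairError("target gene set shares no gene with the network")
    bin_of, edges, degenerate = _assign_bins(prop.scores, n_bins)
    n_eff = 1 if degenerate else n_bins
    counts_all = np.bincount(bin_of, minlength=n_eff + 1)[1:].astype(float)
    target_rows = np.fromiter((index[g] for g in target_in), dtype=np.int64)
    counts_target = np.bincount(bin_of[target_rows], minlength=n_eff + 1)[1:].astype(float)
    return BinProfile(
        n_bins=n_eff,
        bin_edges=edges,
        p_all=counts_all / len(prop.genes),
        p_target=counts_target / len(target_in),
        bin_of=bin_of,
        genes=prop.genes,
        target_genes=target_in,
        degenerate=degenerate,
    )


def xd_directed(profile: BinProfile, weights: WeightSpec = None) -> float:
    """Rank-weighted bin difference sum_i (P_ic - P_ia) * w_i (w_i = 1/i)."""
    if profile.degenerate:
        warnings.warn(
            "degenerate single-bin profile (all scores equal); XD set to 0",
            stacklevel=2,
        )
        return 0.0
    w = _resolve_weights(weights, profile.n_bins)
    return float(np.dot(profile.p_target - profile.p_all, w))


def count_shared_genes(genes_a: Iterable[str], genes_b: Iterable[str]) -> int:
    """NG: number of genes directly shared by the two full association sets."""
    return len(set(genes_a) & set(genes_b))


def classify_pair(xd: float | None, ng: int) -> str:
    """Four exclusive labels from the sign of XD and the presence of shared genes.

    Zero XD is not positive; an unscorable pair (xd=None) keeps its own label
    rather than being coerced to zero.
    """
    if xd is None:
        return CATEGORY_UNSCORABLE
    pos_xd = xd > 0
    pos_ng = ng >= 1
    if pos_xd and pos_ng:
        return CATEGORY_BOTH
    if pos_ng:
        return CATEGORY_NG_ONLY
    if pos_xd:
        return CATEGORY_XD_ONLY
    return CATEGORY_NEITHER


@dataclass
class PairScores:
    """Directed and symmetrized XD plus shared-gene count for one disease pair."""

    disease_a: str
    disease_b: str
    xd_ab: float | None
    xd_ba: float | None
    xd: float | None
    ng: int
    category: str
    scorable: bool


def _directed_xd(
    prop: PropagationResult,
    target: frozenset[str],
    seeds: frozenset[str],
    n_bins: int,
    exclude_overlap: bool,
    weights: WeightSpec,
) -> float:
    eff_target = target - seeds if exclude_overlap else target
    profile = bin_scores(prop, eff_target, n_bins=n_bins)
    return xd_directed(profile, weights=weights)


def xd_score(
    net: GeneNetwork,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    restart_p: float = 0.9,
    n_bins: int = 10,
    weighted: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
    exclude_overlap: bool = False,
    weights: WeightSpec = None,
    disease_a: str = "a",
    disease_b: str = "b",
) -> PairScores:
    """Symmetrized XD for one disease pair: min of the two directed scores.

    A pair where either gene set misses the network entirely is returned as
    unscorable (xd=None) — never as XD = 0.
    """
    set_a, set_b = frozenset(genes_a), frozenset(genes_b)
    ng = count_shared_genes(set_a, set_b)
    in_a, in_b = net.restrict(set_a), net.restrict(set_b)
    if not in_a or not in_b:
        return PairScores(
            disease_a, disease_b, None, None, None, ng, CATEGORY_UNSCORABLE, False
        )
    kw = dict(restart_p=restart_p, tol=tol, max_iter=max_iter, weighted=weighted)
    prop_a = rwr(net, in_a, **kw)
    prop_b = rwr(net, in_b, **kw)
    try:
        xd_ab = _directed_xd(
            prop_a, frozenset(in_b), prop_a.seed_genes, n_bins, exclude_overlap, weights
        )
        xd_ba = _directed_xd(
            prop_b, frozenset(in_a), prop_b.seed_genes, n_bins, exclude_overlap, weights
        )
    except UnscorablePairError:
        return PairScores(
            disease_a, disease_b, None, None, None, ng, CATEGORY_UNSCORABLE, False
        )
    xd = min(xd_ab, xd_ba)
    return PairScores(
        disease_a, disease_b, xd_ab, xd_ba, xd, ng, classify_pair(xd, ng), True
    )


class _CachedPropagation:
    """Per-disease RWR result with its bin assignment, reused across pairs."""

    def __init__(self, prop: PropagationResult, n_bins: int):
        self.prop = prop
        self.index = {g: i for i, g in enumerate(prop.genes)}
        self.bin_of, self.edges, self.degenerate = _assign_bins(prop.scores, n_bins)
        n_eff = 1 if self.degenerate else n_bins
        self.n_bins = n_eff
        self.p_all = np.bincount(self.bin_of, minlength=n_eff + 1)[1:] / len(prop.genes)

    def xd_against(self, target: set[str], weights: np.ndarray) -> float:
        if self.degenerate:
            return 0.0
        rows = np.fromiter((self.index[g] for g in target), dtype=np.int64)
        p_t = np.bincount(self.bin_of[rows], minlength=self.n_bins + 1)[1:] / len(rows)
        return float(np.dot(p_t - self.p_all, weights))


def score_all_pairs(
    net: GeneNetwork,
    dgmap: DiseaseGeneMap,
    restart_p: float = 0.9,
    n_bins: int = 10,
    weighted: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
    exclude_overlap: bool = False,
    weights: WeightSpec = None,
) -> pd.DataFrame:
    """Score every unordered disease pair; one RWR per disease, not per pair.

    Output rows are ordered lexicographically by (disease_a, disease_b) with
    columns disease_a, disease_b, xd_ab, xd_ba, xd, ng, category, scorable.
    Unscorable pairs are flagged, with NaN score fields.
    """
    diseases = dgmap.diseases
    if len(diseases) < 2:
        raise ValueError("need at least two diseases to score pairs")
    w_arr = _resolve_weights(weights, n_bins)
    cache: dict[str, _CachedPropagation | None] = {}
    for d in diseases:
        in_net = net.restrict(dgmap[d])
        if in_net:
            prop = rwr(
                net, in_net, restart_p=restart_p, tol=tol, max_iter=max_iter,
                weighted=weighted,
            )
            cache[d] = _CachedPropagation(prop, n_bins)
        else:
            cache[d] = None
    rows = []
    for i, da in enumerate(diseases):
        for db in diseases[i + 1 :]:
            ng = count_shared_genes(dgmap[da], dgmap[db])
            ca, cb = cache[da], cache[db]
            tgt_b = net.restrict(dgmap[db])
            tgt_a = net.restrict(dgmap[da])
            if exclude_overlap and ca is not None and cb is not None:
                tgt_b = tgt_b - ca.prop.seed_genes
                tgt_a = tgt_a - cb.prop.seed_genes
            if ca is None or cb is None or not tgt_b or not tgt_a:
                rows.append(
                    dict(
                        disease_a=da, disease_b=db, xd_ab=np.nan, xd_ba=np.nan,
                        xd=np.nan, ng=ng, category=CATEGORY_UNSCORABLE, scorable=False,
                    )
                )
                continue
            xd_ab = ca.xd_against(tgt_b, w_arr)
            xd_ba = cb.xd_against(tgt_a, w_arr)
            xd = min(xd_ab, xd_ba)
            rows.append(
                dict(
                    disease_a=da, disease_b=db, xd_ab=xd_ab, xd_ba=xd_ba, xd=xd,
                    ng=ng, category=classify_pair(xd, ng), scorable=True,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["disease_a", "disease_b", "xd_ab", "xd_ba", "xd", "ng",
                 "category", "scorable"],
    )
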