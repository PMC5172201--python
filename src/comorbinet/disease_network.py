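"""Predicted disease network and its category structure under an edge-shuffle null.

The network links every disease pair with a positive XD score and at least
one shared gene (the +XDand+NG category), weighted by XD. Disease categories
(e.g. the 18 ICD-9-CM chapter-style groups) organize the network; the number
of links within and between categories is compared against randomized
networks produced by degree-preserving double-edge swaps, giving an
empirical enrichment p-value per category pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np
import pandas as pd

from .network_io import CategoryMap
from .xd_scoring import CATEGORY_BOTH

__all__ = [
    "build_disease_network",
    "average_degree",
    "category_link_density",
    "edge_shuffle_null",
    "ShuffleNullResult",
    "top_category_pairs",
]


def build_disease_network(pairs: pd.DataFrame, categories: CategoryMap) -> nx.Graph:
    """Graph over diseases with one edge per +XDand+NG pair, weighted by XD.

    Diseases that qualify for no edge are excluded. Every edge endpoint must
    carry a category; offenders are listed in the raised error.
    """
    edges = pairs[pairs["category"] == CATEGORY_BOTH]
    involved = sorted(set(edges["disease_a"]) | set(edges["disease_b"]))
    missing = [d for d in involved if d not in categories]
    if missing:
        raise ValueError(
            "diseases missing from the category map: " + ", ".join(missing)
        )
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.disease_a, row.disease_b, xd=float(row.xd), ng=int(row.ng))
    nx.set_node_attributes(
        g, {d: categories[d] for d in g.nodes}, name="category"
    )
    return g


def average_degree(g: nx.Graph) -> tuple[pd.DataFrame, float]:
    """Per-category mean degree (links to any category) and the overall mean."""
    if g.number_of_nodes() == 0:
        raise ValueError("disease network is empty")
    cat_of = nx.get_node_attributes(g, "category")
    rows = []
    for cat in sorted(set(cat_of.values())):
        members = [d for d in g.nodes if cat_of[d] == cat]
        degs = [g.degree(d) for d in members]
        rows.append(
            dict(category=cat, n_diseases=len(members), mean_degree=float(np.mean(degs)))
        )
    overall = 2.0 * g.number_of_edges() / g.number_of_nodes()
    return pd.DataFrame(rows), overall


def _category_sizes(g: nx.Graph) -> dict[str, int]:
    cat_of = nx.get_node_attributes(g, "category")
    sizes: dict[str, int] = {}
    for c in cat_of.values():
        sizes[c] = sizes.get(c, 0) + 1
    return sizes


def _count_links(edges, cat_of) -> dict[tuple[str, str], int]:
    counts: dict[tuple[str, str], int] = {}
    for u, v in edges:
        key = tuple(sorted((cat_of[u], cat_of[v])))
        counts[key] = counts.get(key, 0) + 1
    return counts


def category_link_density(g: nx.Graph) -> pd.DataFrame:
    """Observed link counts per category pair, normalized by category sizes.

    Between categories A != B the normalizer is |A|*|B|; within A it is
    C(|A|, 2) (NA for singleton categories). Every category pair among the
    categories present in the network appears, including zero-link pairs.
    """
    cat_of = nx.get_node_attributes(g, "category")
    sizes = _category_sizes(g)
    counts = _count_links(g.edges(), cat_of)
    rows = []
    for ca, cb in combinations_with_replacement(sorted(sizes), 2):
        if ca == cb:
            possible = sizes[ca] * (sizes[ca] - 1) // 2
        else:
            possible = sizes[ca] * sizes[cb]
        observed = counts.get((ca, cb), 0)
        rows.append(
            dict(
                category_a=ca, category_b=cb, within=(ca == cb),
                n_links=observed, n_possible=possible,
                density=observed / possible if possible else np.nan,
            )
        )
    return pd.DataFrame(rows)


def top_category_pairs(density: pd.DataFrame, top_fraction: float = 0.10) -> pd.DataFrame:
    """Category pairs in the top fraction by normalized link score, ties kept."""
    ranked = density.dropna(subset=["density"]).sort_values(
        "density", ascending=False, ignore_index=True
    )
    if ranked.empty:
        return ranked
    k = max(1, int(np.ceil(top_fraction * len(ranked))))
    threshold = ranked["density"].iloc[k - 1]
    return ranked[ranked["density"] >= threshold].reset_index(drop=True)


@dataclass
class ShuffleNullResult:
    """Category-pair link statistics against the randomized-network null."""

    stats: pd.DataFrame  # category_a, category_b, within, observed, null stats, p
    n_shuffles: int
    alpha: float
    mode: str  # "degree_preserving" or "label_permutation"
    frac_within_significant: float
    frac_between_significant: float


def _attempt_swaps(
    edges: list[tuple[int, int]],
    edge_set: set[tuple[int, int]],
    pick_a: np.ndarray,
    pick_b: np.ndarray,
    orient: np.ndarray,
) -> int:
    """In-place double-edge swaps; returns the number of successful swaps."""
    success = 0
    for t in range(len(pick_a)):
        ia, ib = int(pick_a[t]), int(pick_b[t])
        if ia == ib:
            continue
        u, v = edges[ia]
        x, y = edges[ib]
        if orient[t]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if u == x or v == y:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            continue
        old1 = edges[ia] if edges[ia][0] < edges[ia][1] else (edges[ia][1], edges[ia][0])
        old2 = edges[ib] if edges[ib][0] < edges[ib][1] else (edges[ib][1], edges[ib][0])
        edge_set.discard(old1)
        edge_set.discard(old2)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[ia] = e1
        edges[ib] = e2
        success += 1
    return success


def edge_shuffle_null(
    g: nx.Graph,
    n_shuffles: int = 1_000_000,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    alpha: float = 0.05,
    mode: str = "degree_preserving",
) -> ShuffleNullResult:
    """Empirical significance of category link counts under edge shuffling.

    Each randomized network applies ``swaps_per_edge * |E|`` attempted
    double-edge swaps starting from the observed network, preserving every
    node's degree. Per category pair, p = (# randomized networks with link
    count >= observed) / n_shuffles, floored at 1/n_shuffles. A graph
    admitting no valid swap (or ``mode="label_permutation"``) falls back to
    permuting category labels across nodes. Summary fractions report how many
    within- and between-category entries are significant at ``alpha``.
    """
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("need at least two edges for an edge-shuffle null")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    node_idx = {d: i for i, d in enumerate(nodes)}
    cat_of_name = nx.get_node_attributes(g, "category")
    cats = sorted(set(cat_of_name.values()))
    cat_idx = {c: i for i, c in enumerate(cats)}
    node_cat = np.array([cat_idx[cat_of_name[d]] for d in nodes])
    base_edges = [
        tuple(sorted((node_idx[u], node_idx[v]))) for u, v in g.edges()
    ]
    nc = len(cats)

    def count(edge_list, cat_arr) -> np.ndarray:
        counts = np.zeros((nc, nc), dtype=np.int64)
        for u, v in edge_list:
            a, b = cat_arr[u], cat_arr[v]
            if a > b:
                a, b = b, a
            counts[a, b] += 1
        return counts

    observed = count(base_edges, node_cat)

    eff_mode = mode
    if mode == "degree_preserving":
        trial_edges = list(base_edges)
        trial_set = set(trial_edges)
        na = swaps_per_edge * m
        ok = _attempt_swaps(
            trial_edges, trial_set,
            rng.integers(0, m, na), rng.integers(0, m, na), rng.integers(0, 2, na),
        )
        if ok == 0:
            warnings.warn(
                "no valid double-edge swap exists; falling back to a "
                "category-label permutation null",
                stacklevel=2,
            )
            eff_mode = "label_permutation"

    ge_count = np.zeros((nc, nc), dtype=np.int64)
    total = np.zeros((nc, nc), dtype=np.float64)
    total_sq = np.zeros((nc, nc), dtype=np.float64)
    na = swaps_per_edge * m
    for _ in range(n_shuffles):
        if eff_mode == "degree_preserving":
            edges = list(base_edges)
            edge_set = set(edges)
            _attempt_swaps(
                edges, edge_set,
                rng.integers(0, m, na), rng.integers(0, m, na),
                rng.integers(0, 2, na),
            )
            null_counts = count(edges, node_cat)
        else:
            null_counts = count(base_edges, rng.permutation(node_cat))
        ge_count += null_counts >= observed
        total += null_counts
        total_sq += null_counts.astype(float) ** 2

    rows = []
    for a in range(nc):
        for b in range(a, nc):
            obs = int(observed[a, b])
            mean = total[a, b] / n_shuffles
            var = max(total_sq[a, b] / n_shuffles - mean**2, 0.0)
            p = max(int(ge_count[a, b]), 1) / n_shuffles
            rows.append(
                dict(
                    category_a=cats[a], category_b=cats[b], within=(a == b),
                    observed=obs, null_mean=mean, null_sd=float(np.sqrt(var)),
                    p_value=p, significant=bool(p < alpha),
                )
            )
    stats = pd.DataFrame(rows)
    within = stats[stats["within"]]
    between = stats[~stats["within"]]
    return ShuffleNullResult(
        stats=stats,
        n_shuffles=n_shuffles,
        alpha=alpha,
        mode=eff_mode,
        frac_within_significant=(
            float(within["significant"].mean()) if len(within) else float("nan")
        ),
        frac_between_significant=(
            float(between["significant"].mean()) if len(between) else float("nan")
        ),
    )
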