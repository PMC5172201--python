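"""GO-term enrichment of disease gene sets and shared-mechanism comparison.

A disease's gene set is tested against each annotation term with the
upper-tail hypergeometric probability of observing at least the overlap seen,
over the universe of annotated genes; terms with p below the cutoff (default
0.05, uncorrected) are called enriched. For a disease pair, the enriched term
sets are intersected: shared terms suggest a common perturbed mechanism even
when the diseases share no gene. Whether two diseases share more enriched
terms than chance is assessed with a one-sided Fisher's exact test over the
annotation term universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "SharedTerms",
    "load_annotations",
    "write_annotations",
    "hypergeom_enrich",
    "shared_go",
    "go_sharing_significance",
]


@dataclass
class AnnotationSet:
    """Term -> gene-set collection; the universe is every annotated gene."""

    terms: dict[str, frozenset[str]]
    descriptions: dict[str, str] | None = None

    def __post_init__(self):
        empty = [t for t, g in self.terms.items() if not g]
        if empty:
            raise ValueError(f"terms with empty gene sets: {empty}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out.update(genes)
        return frozenset(out)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load annotations from GMT or two-column (term_id, gene_id) TSV.

    GMT lines are ``term <tab> description <tab> gene...``; the format is
    recognized by a ``.gmt`` suffix or by rows of three or more fields.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty annotation file")
    rows = [ln.rstrip("\n").split("\t") for ln in lines]
    is_gmt = path.suffix.lower() == ".gmt" or all(len(r) >= 3 for r in rows)
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    if is_gmt:
        for r in rows:
            term = r[0].strip()
            descriptions[term] = r[1].strip() if len(r) > 1 else ""
            terms.setdefault(term, set()).update(
                g.strip() for g in r[2:] if g.strip()
            )
    else:
        start = 0
        if [f.strip().lower() for f in rows[0][:2]] == ["term_id", "gene_id"]:
            start = 1
        for r in rows[start:]:
            if len(r) < 2 or not r[0].strip() or not r[1].strip():
                raise ValueError(f"{path}: malformed annotation row: {r}")
            terms.setdefault(r[0].strip(), set()).add(r[1].strip())
    return AnnotationSet(
        terms={t: frozenset(g) for t, g in terms.items() if g},
        descriptions=descriptions or None,
    )


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tgene_id\n")
        for t in sorted(annotations.terms):
            for g in sorted(annotations.terms[t]):
                fh.write(f"{t}\t{g}\n")


@dataclass
class EnrichmentResult:
    """Per-term hypergeometric tests of one disease gene set."""

    disease_id: str
    table: pd.DataFrame  # term_id, overlap, term_size, query_size, universe_size, p
    cutoff: float

    @property
    def enriched(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["enriched"], "term_id"])


def hypergeom_enrich(
    genes: Iterable[str],
    annotations: AnnotationSet,
    cutoff: float = 0.05,
    disease_id: str = "query",
    bh_correct: bool = False,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a gene set over all terms.

    The universe is the set of annotated genes and the query is restricted to
    it. For overlap k, p = P(X >= k) with X hypergeometric(universe, term,
    query); enrichment is called at raw p < cutoff (``bh_correct`` applies a
    Benjamini-Hochberg adjustment instead, off by default).
    """
    universe = annotations.universe
    query = frozenset(genes) & universe
    if not query:
        raise ValueError("gene set has no overlap with the annotation universe")
    n_u = len(universe)
    n_q = len(query)
    term_ids = sorted(annotations.terms)
    overlap = np.array(
        [len(annotations.terms[t] & query) for t in term_ids], dtype=np.int64
    )
    term_size = np.array([len(annotations.terms[t]) for t in term_ids], dtype=np.int64)
    p = stats.hypergeom.sf(overlap - 1, n_u, term_size, n_q)
    table = pd.DataFrame(
        dict(
            term_id=term_ids, overlap=overlap, term_size=term_size,
            query_size=n_q, universe_size=n_u, p=p,
        )
    )
    if bh_correct:
        order = np.argsort(p, kind="stable")
        ranked = p[order] * len(p) / np.arange(1, len(p) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty_like(adj)
        q[order] = np.minimum(adj, 1.0)
        table["p_adjusted"] = q
        table["enriched"] = q < cutoff
    else:
        table["enriched"] = p < cutoff
    return EnrichmentResult(disease_id=disease_id, table=table, cutoff=cutoff)


@dataclass
class SharedTerms:
    """Overlap of two diseases' enriched term sets."""

    shared: frozenset[str]
    jaccard: float
    shared_fraction: float  # |shared| / min(|a|, |b|)


def shared_go(a: EnrichmentResult, b: EnrichmentResult) -> SharedTerms:
    """Shared enriched terms with both overlap measures.

    The headline fraction divides by the smaller enriched set; the Jaccard
    index is always reported alongside since the denominator convention
    matters when enrichment counts differ.
    """
    ea, eb = a.enriched, b.enriched
    shared = ea & eb
    union = ea | eb
    smaller = min(len(ea), len(eb))
    return SharedTerms(
        shared=frozenset(shared),
        jaccard=len(shared) / len(union) if union else 0.0,
        shared_fraction=len(shared) / smaller if smaller else 0.0,
    )


def go_sharing_significance(
    a_enriched: Iterable[str], b_enriched: Iterable[str], all_terms: int
) -> float:
    """One-sided Fisher's exact p for over-shared enriched terms.

    The 2x2 table classifies each of ``all_terms`` testable terms by
    membership in each disease's enriched set; the alternative is that
    shared terms are over-represented. Degenerate tables (either set empty)
    return p = 1.
    """
    ea, eb = set(a_enriched), set(b_enriched)
    if all_terms < len(ea | eb):
        raise ValueError("all_terms smaller than the union of enriched sets")
    if not ea or not eb:
        return 1.0
    s = len(ea & eb)
    table = [
        [s, len(ea) - s],
        [len(eb) - s, all_terms - len(ea) - len(eb) + s],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])
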