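"""Readers, writers, and the core data model for gene networks and tabular inputs.

All on-disk formats are tab-delimited UTF-8 text with a header line:

* gene network: ``gene1  gene2  weight`` (the weight column is optional on
  input; unweighted files get weight 1.0)
* disease-gene associations: ``disease_id  gene_id``
* patient diagnosis records: ``patient_id  disease_id`` (a blank disease
  field registers an enrolled patient with no mapped diagnosis, so the total
  patient count N survives a round trip)
* disease categories: ``disease_id  category``

Gene, disease, and patient identifiers are opaque strings; no identifier
conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "GeneNetwork",
    "DiseaseGeneMap",
    "PatientRecords",
    "CategoryMap",
    "load_network",
    "load_disease_genes",
    "load_patient_records",
    "load_category_map",
    "write_network",
    "write_disease_genes",
    "write_patient_records",
    "write_category_map",
    "network_coverage",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending 1-based line."""


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return path.read_text(encoding="utf-8").splitlines()


@dataclass
class GeneNetwork:
    """Simple undirected weighted gene network.

    ``genes`` is the deterministic (lexicographically sorted) node order and
    ``adjacency`` the symmetric non-negative weight matrix in that order.
    Self-loops are removed on construction and duplicate edges are merged
    keeping the maximum weight, so the graph is always simple.
    """

    genes: tuple[str, ...]
    adjacency: sp.csr_array
    index: dict[str, int] = field(repr=False)

    @classmethod
    def from_edges(
        cls, edges: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]]
    ) -> "GeneNetwork":
        if not isinstance(edges, Mapping):
            merged: dict[tuple[str, str], float] = {}
            for u, v, w in edges:
                if u == v:
                    continue
                key = (u, v) if u <= v else (v, u)
                merged[key] = max(w, merged.get(key, -np.inf))
            edges = merged
        else:
            edges = {
                ((u, v) if u <= v else (v, u)): w
                for (u, v), w in edges.items()
                if u != v
            }
        genes = tuple(sorted({g for pair in edges for g in pair}))
        index = {g: i for i, g in enumerate(genes)}
        n = len(genes)
        if edges:
            rows, cols, data = [], [], []
            for (u, v), w in edges.items():
                if w < 0:
                    raise ValueError(f"negative edge weight {w} on {u}-{v}")
                iu, iv = index[u], index[v]
                rows += [iu, iv]
                cols += [iv, iu]
                data += [w, w]
            adj = sp.csr_array(
                (np.asarray(data, dtype=float), (rows, cols)), shape=(n, n)
            )
        else:
            adj = sp.csr_array((n, n), dtype=float)
        return cls(genes=genes, adjacency=adj, index=index)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degree(self) -> np.ndarray:
        """Per-gene neighbour count (edge count, not weighted degree)."""
        return np.diff(self.adjacency.indptr)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once as (u, v, weight) with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self.genes[i], self.genes[j], float(w)

    def restrict(self, genes: Iterable[str]) -> set[str]:
        """Intersection of an arbitrary gene collection with the network."""
        return {g for g in genes if g in self.index}


@dataclass
class DiseaseGeneMap:
    """Mapping from disease identifier to its associated gene set."""

    associations: dict[str, frozenset[str]]

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted(self.associations))

    @property
    def n_diseases(self) -> int:
        return len(self.associations)

    def __getitem__(self, disease_id: str) -> frozenset[str]:
        return self.associations[disease_id]

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.associations


@dataclass
class PatientRecords:
    """Per-patient deduplicated diagnosis sets; N is the distinct patient count."""

    diagnoses: dict[str, frozenset[str]]

    @property
    def n_patients(self) -> int:
        return len(self.diagnoses)

    @property
    def diseases(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for ds in self.diagnoses.values():
            seen.update(ds)
        return tuple(sorted(seen))


@dataclass
class CategoryMap:
    """Disease identifier -> category label from a closed label set."""

    category_of: dict[str, str]

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.category_of.values())))

    def __getitem__(self, disease_id: str) -> str:
        return self.category_of[disease_id]

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.category_of


# ---------------------------------------------------------------------------
# loaders


def load_network(
    path: str | Path,
    weight_column: str | None = None,
    min_weight: float | None = None,
) -> GeneNetwork:
    """Load a TSV edge list (STRING/BioGRID style).

    The first two columns are gene identifiers. The third column, when
    numeric, is the edge weight; files without a weight column load with
    weight 1.0. A header line is detected by a non-numeric third field (or by
    canonical column names for two-column files). ``min_weight`` drops edges
    below the threshold before merging; ``weight_column`` selects a named
    weight column from the header of a wider table.
    """
    lines = _read_lines(path)
    start = 0
    weight_idx: int | None = None
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            fields = raw.rstrip("\n").split("\t")
            lowered = [f.strip().lower() for f in fields]
            is_header = (len(fields) >= 3 and not _is_number(fields[2])) or lowered[
                :2
            ] == ["gene1", "gene2"]
            if is_header:
                header = [f.strip() for f in fields]
                start = lineno
            break
    if weight_column is not None:
        if header is None or weight_column not in header:
            raise FormatError(
                f"weight column {weight_column!r} not found in header of {path}"
            )
        weight_idx = header.index(weight_column)
    elif header is not None and len(header) >= 3:
        weight_idx = 2

    merged: dict[tuple[str, str], float] = {}
    for lineno in range(start, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}: malformed edge row at line {lineno + 1}")
        u, v = fields[0].strip(), fields[1].strip()
        if weight_idx is not None:
            if weight_idx >= len(fields) or not _is_number(fields[weight_idx]):
                raise FormatError(
                    f"{path}: non-numeric or missing weight at line {lineno + 1}"
                )
            w = float(fields[weight_idx])
        elif len(fields) >= 3 and _is_number(fields[2]):
            w = float(fields[2])
        else:
            w = 1.0
        if w < 0:
            raise FormatError(f"{path}: negative weight at line {lineno + 1}")
        if min_weight is not None and w < min_weight:
            continue
        if u == v:
            continue
        key = (u, v) if u <= v else (v, u)
        merged[key] = max(w, merged.get(key, -np.inf))
    return GeneNetwork.from_edges(merged)


def _load_two_column(
    path: str | Path,
    header_names: tuple[str, str],
    allow_blank_second: bool = False,
) -> Iterator[tuple[str, str]]:
    lines = _read_lines(path)
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: file is empty")
    start = 0
    for lineno, raw in enumerate(lines, start=1):
        if raw.strip():
            lowered = [f.strip().lower() for f in raw.split("\t")]
            if lowered[: len(header_names)] == list(header_names):
                start = lineno
            break
    for lineno in range(start, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        first = fields[0].strip() if fields else ""
        second = fields[1].strip() if len(fields) > 1 else ""
        if not first or (not second and not allow_blank_second):
            raise FormatError(
                f"{path}: missing field at line {lineno + 1} "
                f"(expected {header_names[0]}, {header_names[1]})"
            )
        yield first, second


def load_disease_genes(path: str | Path) -> DiseaseGeneMap:
    """Load a two-column (disease_id, gene_id) TSV, deduplicating rows."""
    assoc: dict[str, set[str]] = {}
    for disease_id, gene_id in _load_two_column(path, ("disease_id", "gene_id")):
        assoc.setdefault(disease_id, set()).add(gene_id)
    return DiseaseGeneMap({d: frozenset(g) for d, g in assoc.items()})


def load_patient_records(path: str | Path) -> PatientRecords:
    """Load a two-column (patient_id, disease_id) TSV.

    A blank disease field registers the patient with an empty diagnosis set
    (an enrolled patient with no mapped diagnosis); such rows keep N exact
    across a write/load round trip.
    """
    diag: dict[str, set[str]] = {}
    for patient_id, disease_id in _load_two_column(
        path, ("patient_id", "disease_id"), allow_blank_second=True
    ):
        diag.setdefault(patient_id, set())
        if disease_id:
            diag[patient_id].add(disease_id)
    return PatientRecords({p: frozenset(d) for p, d in diag.items()})


def load_category_map(path: str | Path) -> CategoryMap:
    """Load a two-column (disease_id, category) TSV; conflicting rows error."""
    cat: dict[str, str] = {}
    for disease_id, category in _load_two_column(path, ("disease_id", "category")):
        if disease_id in cat and cat[disease_id] != category:
            raise FormatError(
                f"{path}: disease {disease_id} mapped to conflicting categories "
                f"{cat[disease_id]!r} and {category!r}"
            )
        cat[disease_id] = category
    return CategoryMap(cat)


# ---------------------------------------------------------------------------
# writers (repr keeps float weights exact across a round trip)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")


def write_disease_genes(dgmap: DiseaseGeneMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\n")
        for d in dgmap.diseases:
            for g in sorted(dgmap.associations[d]):
                fh.write(f"{d}\t{g}\n")


def write_patient_records(records: PatientRecords, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tdisease_id\n")
        for p in sorted(records.diagnoses):
            ds = sorted(records.diagnoses[p])
            if not ds:
                fh.write(f"{p}\t\n")
            for d in ds:
                fh.write(f"{p}\t{d}\n")


def write_category_map(categories: CategoryMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tcategory\n")
        for d in sorted(categories.category_of):
            fh.write(f"{d}\t{categories.category_of[d]}\n")


# ---------------------------------------------------------------------------


def network_coverage(dgmap: DiseaseGeneMap, net: GeneNetwork) -> pd.DataFrame:
    """Per-disease fraction of associated genes present in the network."""
    rows = []
    for d in dgmap.diseases:
        genes = dgmap.associations[d]
        n_in = sum(1 for g in genes if g in net.index)
        rows.append(
            {
                "disease_id": d,
                "n_genes": len(genes),
                "n_in_network": n_in,
                "coverage": n_in / len(genes) if genes else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["disease_id", "n_genes", "n_in_network", "coverage"])
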