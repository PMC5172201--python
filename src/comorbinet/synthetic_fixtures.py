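"""Seeded generators for every pipeline input, with plantable ground truth.

The generators emulate the study's five inputs at desk scale: a functional
gene network (Erdős–Rényi, Barabási–Albert, or planted modules whose
within-module edge probability far exceeds the between-module one), disease
gene sets (planted comorbid pairs draw from the same module and share a
configurable number of genes; background diseases draw uniformly), patient
diagnosis records (independent per-disease prevalences except for planted
pairs, whose joint probability is lifted above the product of marginals by a
known factor, making the target relative risk analytic), a disease category
map, and module-aligned annotation terms so planted pairs share enriched
mechanisms. Everything is bit-reproducible for a fixed seed, and each
generator records its truth so downstream recovery is testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationSet, write_annotations
from .network_io import (
    CategoryMap,
    DiseaseGeneMap,
    GeneNetwork,
    PatientRecords,
    write_category_map,
    write_disease_genes,
    write_network,
    write_patient_records,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "generate_network",
    "generate_disease_genes",
    "generate_patients",
    "generate_categories",
    "generate_annotations",
    "generate_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults define the standard test condition: 100 genes in 4 planted
    modules, 12 diseases of 8–15 genes with 2 planted comorbid pairs sharing
    3 genes, 50,000 patients with log-uniform prevalences in [0.01, 0.1] and
    a joint-probability lift of 5 on planted pairs, and 30 annotation terms
    aligned to the network modules.
    """

    n_genes: int = 100
    network_model: str = "planted-modules"  # or "erdos-renyi", "barabasi-albert"
    n_modules: int = 4
    p_within: float = 0.5
    p_between: float = 0.01
    er_p: float = 0.05
    ba_m: int = 3
    n_diseases: int = 12
    genes_per_disease: tuple[int, int] = (8, 15)
    n_planted_pairs: int = 2
    planted_overlap: int = 3
    n_patients: int = 50_000
    prevalence_range: tuple[float, float] = (0.01, 0.1)
    lift: float = 5.0
    n_categories: int = 4
    n_go_terms: int = 30
    term_size_range: tuple[int, int] = (5, 20)
    module_aligned_terms: bool = True
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_within, self.p_between, self.er_p, *self.prevalence_range):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.lift < 1.0:
            raise ValueError("comorbidity lift must be >= 1")
        if 2 * self.n_planted_pairs > self.n_diseases:
            raise ValueError("planted pairs reference more diseases than exist")
        if self.network_model == "planted-modules" and self.n_genes < self.n_modules:
            raise ValueError("module size would be zero")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _disease_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"D{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(spec: FixtureSpec) -> tuple[GeneNetwork, dict[str, int]]:
    """Generate the gene network plus the module membership truth.

    Non-modular models assign every gene to module 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genes = _gene_names(spec.n_genes)
    modules = {g: 0 for g in genes}
    edges: dict[tuple[str, str], float] = {}
    if spec.network_model == "planted-modules":
        membership = np.arange(spec.n_genes) % spec.n_modules
        membership.sort()
        modules = {g: int(m) for g, m in zip(genes, membership)}
        for i in range(spec.n_genes):
            for j in range(i + 1, spec.n_genes):
                p = (
                    spec.p_within
                    if membership[i] == membership[j]
                    else spec.p_between
                )
                if rng.random() < p:
                    edges[(genes[i], genes[j])] = 1.0
    elif spec.network_model == "erdos-renyi":
        for i in range(spec.n_genes):
            for j in range(i + 1, spec.n_genes):
                if rng.random() < spec.er_p:
                    edges[(genes[i], genes[j])] = 1.0
    elif spec.network_model == "barabasi-albert":
        g = nx.barabasi_albert_graph(
            spec.n_genes, spec.ba_m, seed=int(rng.integers(2**31))
        )
        edges = {(genes[u], genes[v]): 1.0 for u, v in g.edges()}
    else:
        raise ValueError(f"unknown network model {spec.network_model!r}")
    net = GeneNetwork.from_edges(edges)
    # keep isolated genes in the node set so coverage statistics stay honest
    if len(net.genes) < spec.n_genes:
        present = set(net.genes)
        isolated = [g for g in genes if g not in present]
        net = _with_isolated(net, isolated)
    return net, modules


def _with_isolated(net: GeneNetwork, isolated: list[str]) -> GeneNetwork:
    import scipy.sparse as sp

    genes = tuple(sorted(set(net.genes) | set(isolated)))
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    edges = {(u, v): w for u, v, w in net.edges()}
    if edges:
        rows, cols, data = [], [], []
        for (u, v), w in edges.items():
            rows += [index[u], index[v]]
            cols += [index[v], index[u]]
            data += [w, w]
        adj = sp.csr_array((np.asarray(data), (rows, cols)), shape=(n, n))
    else:
        adj = sp.csr_array((n, n), dtype=float)
    return GeneNetwork(genes=genes, adjacency=adj, index=index)


def generate_disease_genes(
    spec: FixtureSpec, net: GeneNetwork, modules: dict[str, int]
) -> tuple[DiseaseGeneMap, pd.DataFrame]:
    """Disease gene sets plus the planted-pair truth table.

    Planted pair k uses diseases (2k, 2k+1): both draw from module k mod
    n_modules and share ``planted_overlap`` genes, so NG >= overlap by
    construction and the pair is network-proximal. Background diseases draw
    genes uniformly from the whole gene universe.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    diseases = _disease_names(spec.n_diseases)
    by_module: dict[int, list[str]] = {}
    for g, m in modules.items():
        by_module.setdefault(m, []).append(g)
    for m in by_module:
        by_module[m].sort()
    all_genes = sorted(modules)
    lo, hi = spec.genes_per_disease
    assoc: dict[str, frozenset[str]] = {}
    truth_rows = []
    planted_diseases = set()
    for k in range(spec.n_planted_pairs):
        da, db = diseases[2 * k], diseases[2 * k + 1]
        planted_diseases.update((da, db))
        module = k % max(len(by_module), 1)
        pool = by_module.get(module, all_genes)
        overlap_k = min(spec.planted_overlap, len(pool))
        shared = rng.choice(pool, size=overlap_k, replace=False).tolist()
        for d in (da, db):
            size = int(rng.integers(lo, hi + 1))
            extra_n = max(size - overlap_k, 0)
            remaining = [g for g in pool if g not in shared]
            extra_n = min(extra_n, len(remaining))
            extra = rng.choice(remaining, size=extra_n, replace=False).tolist()
            assoc[d] = frozenset(shared + extra)
        truth_rows.append(
            dict(
                disease_a=da, disease_b=db, module=module,
                n_shared=len(frozenset(assoc[da]) & frozenset(assoc[db])),
            )
        )
    for d in diseases:
        if d in planted_diseases:
            continue
        size = int(rng.integers(lo, hi + 1))
        assoc[d] = frozenset(rng.choice(all_genes, size=size, replace=False).tolist())
    truth = pd.DataFrame(
        truth_rows, columns=["disease_a", "disease_b", "module", "n_shared"]
    )
    return DiseaseGeneMap(assoc), truth


def generate_patients(
    spec: FixtureSpec, diseases: list[str], planted_pairs: pd.DataFrame
) -> tuple[PatientRecords, pd.DataFrame]:
    """Patient diagnosis records with planted above-independence co-occurrence.

    Every disease has a log-uniform prevalence; diseases of a planted pair
    are drawn jointly with P(both) = lift * p_a * p_b (capped at the smaller
    marginal, with a warning), all other diseases independently. All
    simulated patients — including the many with no diagnosis — are kept in
    the records so N matches the cohort size and realized relative risks
    concentrate near the planted lift.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    lo, hi = spec.prevalence_range
    prev = np.exp(rng.uniform(math.log(lo), math.log(hi), size=len(diseases)))
    prev_of = dict(zip(diseases, prev))
    n = spec.n_patients
    width = len(str(n))
    patient_ids = [f"P{i:0{width}d}" for i in range(n)]
    carrier: dict[str, np.ndarray] = {}
    paired = set()
    truth_rows = []
    for row in planted_pairs.itertuples(index=False):
        da, db = row.disease_a, row.disease_b
        paired.update((da, db))
        pa, pb = prev_of[da], prev_of[db]
        q = spec.lift * pa * pb
        if q > min(pa, pb):
            warnings.warn(
                f"lift {spec.lift} infeasible for ({da}, {db}); capping joint "
                "probability at the smaller marginal",
                stacklevel=2,
            )
            q = min(pa, pb)
        u = rng.random(n)
        both = u < q
        a_only = (u >= q) & (u < pa)
        b_only = (u >= pa) & (u < pa + pb - q)
        carrier[da] = both | a_only
        carrier[db] = both | b_only
        truth_rows.append(
            dict(
                disease_a=da, disease_b=db, prevalence_a=pa, prevalence_b=pb,
                joint_probability=q, target_rr=q / (pa * pb),
            )
        )
    for d in diseases:
        if d not in paired:
            carrier[d] = rng.random(n) < prev_of[d]
    diagnoses: dict[str, set[str]] = {p: set() for p in patient_ids}
    for d in diseases:
        for i in np.flatnonzero(carrier[d]):
            diagnoses[patient_ids[i]].add(d)
    records = PatientRecords({p: frozenset(s) for p, s in diagnoses.items()})
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "disease_a", "disease_b", "prevalence_a", "prevalence_b",
            "joint_probability", "target_rr",
        ],
    )
    prev_table = pd.DataFrame({"disease_id": diseases, "prevalence": prev})
    truth.attrs["prevalences"] = prev_table
    return records, truth


def generate_categories(spec: FixtureSpec, diseases: list[str]) -> CategoryMap:
    """Round-robin assignment of diseases to a closed category label set.

    Both diseases of planted pair k land in category ``k mod n_categories``,
    so planted comorbidity also concentrates within categories.
    """
    labels = [f"CAT{c + 1:02d}" for c in range(spec.n_categories)]
    cat: dict[str, str] = {}
    for k in range(spec.n_planted_pairs):
        label = labels[k % spec.n_categories]
        cat[diseases[2 * k]] = label
        cat[diseases[2 * k + 1]] = label
    rest = [d for d in diseases if d not in cat]
    for i, d in enumerate(rest):
        cat[d] = labels[i % spec.n_categories]
    return CategoryMap(cat)


def generate_annotations(
    spec: FixtureSpec, modules: dict[str, int]
) -> AnnotationSet:
    """Annotation terms, optionally aligned to network modules.

    With ``module_aligned_terms`` each module spawns one term covering ~80%
    of its genes (so same-module disease pairs share enriched terms); the
    remaining terms draw genes uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    genes = sorted(modules)
    terms: dict[str, frozenset[str]] = {}
    idx = 0
    if spec.module_aligned_terms:
        by_module: dict[int, list[str]] = {}
        for g, m in modules.items():
            by_module.setdefault(m, []).append(g)
        for m in sorted(by_module):
            pool = sorted(by_module[m])
            size = max(1, int(round(0.8 * len(pool))))
            idx += 1
            terms[f"T{idx:04d}"] = frozenset(
                rng.choice(pool, size=size, replace=False).tolist()
            )
    lo, hi = spec.term_size_range
    while idx < spec.n_go_terms:
        idx += 1
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        terms[f"T{idx:04d}"] = frozenset(
            rng.choice(genes, size=size, replace=False).tolist()
        )
    if not terms:
        raise ValueError("annotation density parameters produced no terms")
    return AnnotationSet(terms=terms)


@dataclass
class Fixture:
    """All five generated inputs plus their ground truth."""

    spec: FixtureSpec
    network: GeneNetwork
    modules: dict[str, int]
    disease_genes: DiseaseGeneMap
    planted_pairs: pd.DataFrame
    records: PatientRecords
    patient_truth: pd.DataFrame
    categories: CategoryMap
    annotations: AnnotationSet

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit the five input TSVs plus truth TSVs; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": out / "network.tsv",
            "disease_genes": out / "disease_genes.tsv",
            "patients": out / "patients.tsv",
            "categories": out / "categories.tsv",
            "annotations": out / "annotations.tsv",
            "truth_planted_pairs": out / "truth_planted_pairs.tsv",
            "truth_modules": out / "truth_modules.tsv",
            "truth_prevalences": out / "truth_prevalences.tsv",
        }
        write_network(self.network, paths["network"])
        write_disease_genes(self.disease_genes, paths["disease_genes"])
        write_patient_records(self.records, paths["patients"])
        write_category_map(self.categories, paths["categories"])
        write_annotations(self.annotations, paths["annotations"])
        truth = self.planted_pairs.merge(
            self.patient_truth, on=["disease_a", "disease_b"], how="left"
        )
        truth.to_csv(paths["truth_planted_pairs"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.modules.items()), columns=["gene_id", "module"]
        ).to_csv(paths["truth_modules"], sep="\t", index=False)
        self.patient_truth.attrs["prevalences"].to_csv(
            paths["truth_prevalences"], sep="\t", index=False
        )
        return paths


def generate_fixture(spec: FixtureSpec | None = None, seed: int | None = None) -> Fixture:
    """Generate all inputs from one spec (optionally overriding its seed)."""
    spec = spec or FixtureSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    net, modules = generate_network(spec)
    dgmap, planted = generate_disease_genes(spec, net, modules)
    diseases = list(dgmap.diseases)
    records, patient_truth = generate_patients(spec, diseases, planted)
    categories = generate_categories(spec, diseases)
    annotations = generate_annotations(spec, modules)
    return Fixture(
        spec=spec, network=net, modules=modules, disease_genes=dgmap,
        planted_pairs=planted, records=records, patient_truth=patient_truth,
        categories=categories, annotations=annotations,
    )
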