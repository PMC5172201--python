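"""End-to-end pipeline: XD scoring -> clinical statistics -> disease network
-> shuffle null -> shared-mechanism enrichment, with a run manifest.

All randomness flows from a single root seed, split per stage with
``numpy.random.SeedSequence``; identical configuration and seed produce
byte-identical output files. Results go only to files; logging goes to
stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .comorbidity_stats import category_correlations, category_summaries, cooccurrence
from .disease_network import average_degree, build_disease_network, edge_shuffle_null
from .enrichment import (
    go_sharing_significance,
    hypergeom_enrich,
    load_annotations,
    shared_go,
)
from .network_io import (
    load_category_map,
    load_disease_genes,
    load_network,
    load_patient_records,
    network_coverage,
)
from .xd_scoring import score_all_pairs

logger = logging.getLogger("comorbinet")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Numeric defaults are the study defaults: restart probability 0.9, 10
    score bins, 2,000,000 correlation permutations, 1,000,000 network
    shuffles, significance level 0.05, enrichment cutoff 0.05.
    """

    network: Path
    disease_genes: Path
    patients: Path
    categories: Path
    annotations: Path | None = None
    out_dir: Path = Path("comorbinet_run")
    restart_p: float = 0.9
    n_bins: int = 10
    weighted: bool = False
    min_weight: float | None = None
    exclude_overlap: bool = False
    n_perm: int = 2_000_000
    n_shuffles: int = 1_000_000
    swaps_per_edge: int = 10
    alpha: float = 0.05
    go_cutoff: float = 0.05
    skip_enrichment: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("network", "disease_genes", "patients", "categories"):
            setattr(self, name, Path(getattr(self, name)))
        if self.annotations is not None:
            self.annotations = Path(self.annotations)
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_jsonable(self) -> dict:
        # out_dir is excluded so reruns into different directories stay
        # byte-identical for the same inputs, parameters, and seed
        out = dataclasses.asdict(self)
        out.pop("out_dir")
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in out.items()}


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False)
    return len(df)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Stages: xd_pairs, cooccurrence, correlations, disease_network,
    shuffle_null, enrichment (skippable). Any stage failure aborts with the
    stage named in the raised error.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    manifest = {
        "package": "comorbinet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "stages": stages,
    }
    net = load_network(config.network, min_weight=config.min_weight)
    dgmap = load_disease_genes(config.disease_genes)
    records = load_patient_records(config.patients)
    categories = load_category_map(config.categories)
    _write(network_coverage(dgmap, net), out / "network_coverage.tsv")

    current = "xd_pairs"
    try:
        t0 = time.perf_counter()
        pairs = score_all_pairs(
            net, dgmap,
            restart_p=config.restart_p, n_bins=config.n_bins,
            weighted=config.weighted, exclude_overlap=config.exclude_overlap,
        )
        n = _write(pairs, out / "pairs.tsv")
        logger.info("stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0)
        stages.append({"stage": current, "rows": n})

        current = "cooccurrence"
        t0 = time.perf_counter()
        cooc = cooccurrence(records)
        n = _write(cooc, out / "cooccurrence.tsv")
        logger.info("stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0)
        stages.append({"stage": current, "rows": n})

        current = "correlations"
        t0 = time.perf_counter()
        corr = category_correlations(
            pairs, cooc, n_perm=config.n_perm, seed=config.seed
        )
        summaries = category_summaries(pairs, cooc)
        n = _write(corr, out / "correlations.tsv")
        _write(summaries, out / "category_summaries.tsv")
        logger.info("stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0)
        stages.append({"stage": current, "rows": n})

        current = "disease_network"
        t0 = time.perf_counter()
        dnet = build_disease_network(pairs, categories)
        edge_rows = pd.DataFrame(
            [
                dict(disease_a=u, disease_b=v, xd=d["xd"], ng=d["ng"])
                for u, v, d in sorted(dnet.edges(data=True))
            ],
            columns=["disease_a", "disease_b", "xd", "ng"],
        )
        n = _write(edge_rows, out / "disease_network_edges.tsv")
        if dnet.number_of_nodes():
            deg, overall = average_degree(dnet)
            deg = pd.concat(
                [
                    deg,
                    pd.DataFrame(
                        [dict(category="ALL", n_diseases=dnet.number_of_nodes(),
                              mean_degree=overall)]
                    ),
                ],
                ignore_index=True,
            )
            _write(deg, out / "category_degree.tsv")
            nx.write_graphml(dnet, out / "disease_network.graphml")
        logger.info("stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0)
        stages.append({"stage": current, "rows": n})

        current = "shuffle_null"
        t0 = time.perf_counter()
        if dnet.number_of_edges() >= 2:
            null = edge_shuffle_null(
                dnet, n_shuffles=config.n_shuffles,
                swaps_per_edge=config.swaps_per_edge,
                seed=config.seed, alpha=config.alpha,
            )
            n = _write(null.stats, out / "category_link_stats.tsv")
            manifest["shuffle_null"] = {
                "mode": null.mode,
                "frac_within_significant": null.frac_within_significant,
                "frac_between_significant": null.frac_between_significant,
            }
        else:
            n = 0
            logger.warning("disease network has < 2 edges; shuffle null skipped")
        logger.info("stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0)
        stages.append({"stage": current, "rows": n})

        if not config.skip_enrichment:
            current = "enrichment"
            t0 = time.perf_counter()
            if config.annotations is None:
                raise ValueError("annotations path required unless skip_enrichment")
            annotations = load_annotations(config.annotations)
            enriched = {}
            rows = []
            for d in dgmap.diseases:
                try:
                    res = hypergeom_enrich(
                        dgmap[d], annotations, cutoff=config.go_cutoff, disease_id=d
                    )
                except ValueError:
                    continue
                enriched[d] = res
                for r in res.table[res.table["enriched"]].itertuples(index=False):
                    rows.append(
                        dict(disease_id=d, term_id=r.term_id, overlap=r.overlap,
                             term_size=r.term_size, p=r.p)
                    )
            _write(
                pd.DataFrame(
                    rows, columns=["disease_id", "term_id", "overlap", "term_size", "p"]
                ),
                out / "disease_enrichment.tsv",
            )
            pair_rows = []
            n_terms = annotations.n_terms
            for u, v in sorted(dnet.edges()):
                if u not in enriched or v not in enriched:
                    continue
                sh = shared_go(enriched[u], enriched[v])
                pair_rows.append(
                    dict(
                        disease_a=u, disease_b=v, n_shared_terms=len(sh.shared),
                        shared_fraction=sh.shared_fraction, jaccard=sh.jaccard,
                        fisher_p=go_sharing_significance(
                            enriched[u].enriched, enriched[v].enriched, n_terms
                        ),
                        shared_terms=";".join(sorted(sh.shared)),
                    )
                )
            n = _write(
                pd.DataFrame(
                    pair_rows,
                    columns=["disease_a", "disease_b", "n_shared_terms",
                             "shared_fraction", "jaccard", "fisher_p", "shared_terms"],
                ),
                out / "pair_enrichment.tsv",
            )
            logger.info(
                "stage %s: %d rows in %.2fs", current, n, time.perf_counter() - t0
            )
            stages.append({"stage": current, "rows": n})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
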