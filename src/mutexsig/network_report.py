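"""Edge classification, network assembly and the end-to-end pipeline.

An unordered gene pair becomes a network edge when both of its ordered CP
relationships are elevated: both sigmas at least the dashed threshold (1.5)
and at least one at the solid threshold (2, i.e. p <= 0.05).  The edge's tier
is set by the weaker relationship: min sigma above 2.7 (or the observed CP
falling outside every permuted value in both directions) draws a double line,
min sigma >= 2 a solid line, otherwise a dashed line.

``run_pipeline`` chains the full analysis — ingest, consensus tiers, impact
filter, gene-list + chance-rate filter, pair statistics, edge classification,
network merge — over the four standard data subsets and emits a run manifest
with per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from mutexsig import __version__
from mutexsig.consensus import MutationMatrix, build_matrix, consensus_subset
from mutexsig.exclusivity import PairExclusivity, evaluate_all_pairs, pairs_table
from mutexsig.gene_filter import (
    FdrConfig,
    apply_rate_filter,
    bundled_gene_list,
    estimate_fdr_threshold,
    restrict_gene_list,
)
from mutexsig.maf_io import filter_cohort, filter_impact, read_clinical, read_gene_list, read_maf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeThresholds:
    dashed: float = 1.5
    solid: float = 2.0
    double: float = 2.7


@dataclass
class SubsetSpec:
    """One analysis subset: a consensus tier plus an impact selection."""

    label: str
    min_callers: int
    impacts: frozenset = frozenset({"HIGH", "MODERATE"})


#: The four standard subsets; high-impact-only is run on the least-conservative
#: tier only (the stricter tiers keep too few high-impact calls to be reliable).
STANDARD_SUBSETS = [
    SubsetSpec("least_hm", 1, frozenset({"HIGH", "MODERATE"})),
    SubsetSpec("least_h", 1, frozenset({"HIGH"})),
    SubsetSpec("mid_hm", 2, frozenset({"HIGH", "MODERATE"})),
    SubsetSpec("most_hm", 4, frozenset({"HIGH", "MODERATE"})),
]


@dataclass
class EdgeRecord:
    """An undirected mutual-exclusivity edge from one data subset."""

    gene_a: str
    gene_b: str
    subset_label: str
    sigma_forward: float
    sigma_reverse: float
    tier: str  # double | solid | dashed
    double_reason: str = ""  # "sigma", "outside_null", or "" for non-double edges

    @property
    def min_sigma(self) -> float:
        return min(self.sigma_forward, self.sigma_reverse)


def classify_pair(
    forward: PairExclusivity,
    reverse: PairExclusivity,
    thresholds: EdgeThresholds = EdgeThresholds(),
    subset_label: str = "",
) -> EdgeRecord | None:
    """Classify an unordered pair from its two ordered relationships.

    Returns None unless both sigmas are positive, both reach the dashed
    threshold, and at least one reaches the solid threshold.
    """
    if forward.excluded or reverse.excluded:
        return None
    s_fwd, s_rev = forward.sigma, reverse.sigma
    lo, hi = min(s_fwd, s_rev), max(s_fwd, s_rev)
    if not (lo >= thresholds.dashed and hi >= thresholds.solid and lo > 0):
        return None
    double_reason = ""
    if lo > thresholds.double:
        tier, double_reason = "double", "sigma"
    elif forward.outside_null and reverse.outside_null:
        tier, double_reason = "double", "outside_null"
    elif lo >= thresholds.solid:
        tier = "solid"
    else:
        tier = "dashed"
    a, b = sorted((forward.pair[1], forward.pair[0]))
    return EdgeRecord(
        gene_a=a, gene_b=b, subset_label=subset_label,
        sigma_forward=s_fwd, sigma_reverse=s_rev,
        tier=tier, double_reason=double_reason,
    )


def edges_from_results(
    results: list[PairExclusivity],
    thresholds: EdgeThresholds = EdgeThresholds(),
    subset_label: str = "",
) -> list[EdgeRecord]:
    """Pair up the two orderings of each unordered pair and classify them."""
    by_pair: dict[tuple[str, str], dict[tuple[str, str], PairExclusivity]] = {}
    for r in results:
        key = tuple(sorted(r.pair))
        by_pair.setdefault(key, {})[r.pair] = r
    edges = []
    for key, both in sorted(by_pair.items()):
        if len(both) != 2:
            continue
        fwd, rev = both.values()
        edge = classify_pair(fwd, rev, thresholds, subset_label)
        if edge is not None:
            edges.append(edge)
    return edges


def build_network(
    edge_lists: dict[str, list[EdgeRecord]],
    gene_classes: dict[str, str] | None = None,
) -> nx.MultiGraph:
    """Merge per-subset edge lists into one multigraph.

    Nodes are genes on any edge, annotated with their DDR/CM class; the same
    unordered pair qualifying in several subsets keeps one parallel edge per
    subset.  Graph-level ``tier_counts`` summarises edges per tier.
    """
    gene_classes = gene_classes or {}
    g = nx.MultiGraph()
    tier_counts = {"double": 0, "solid": 0, "dashed": 0}
    for label, edges in edge_lists.items():
        for e in edges:
            for node in (e.gene_a, e.gene_b):
                if node not in g:
                    g.add_node(node, functional_class=gene_classes.get(node, ""))
            g.add_edge(
                e.gene_a, e.gene_b, key=label,
                subset=label, tier=e.tier,
                sigma_forward=e.sigma_forward, sigma_reverse=e.sigma_reverse,
                double_reason=e.double_reason,
            )
            tier_counts[e.tier] += 1
    # scalar graph attributes only, so GraphML export stays valid
    for tier, count in tier_counts.items():
        g.graph[f"n_{tier}"] = count
    return g


def tier_counts(graph: nx.MultiGraph) -> dict[str, int]:
    return {tier: graph.graph.get(f"n_{tier}", 0) for tier in ("double", "solid", "dashed")}


def edges_table(edge_lists: dict[str, list[EdgeRecord]]) -> pd.DataFrame:
    rows = [
        {
            "geneA": e.gene_a, "geneB": e.gene_b, "subset": label,
            "sigma_forward": e.sigma_forward, "sigma_reverse": e.sigma_reverse,
            "min_sigma": e.min_sigma, "tier": e.tier, "double_reason": e.double_reason,
        }
        for label, edges in edge_lists.items()
        for e in edges
    ]
    return pd.DataFrame(
        rows,
        columns=["geneA", "geneB", "subset", "sigma_forward", "sigma_reverse", "min_sigma", "tier", "double_reason"],
    )


_DOT_STYLE = {"double": 'penwidth=3 style=bold', "solid": 'penwidth=1.5 style=solid', "dashed": 'style=dashed'}
_DOT_SHAPE = {"DDR": "box", "CM": "ellipse", "both": "box", "": "ellipse"}


def write_dot(graph: nx.MultiGraph, path) -> None:
    """Plain DOT export with line styles per tier and node shapes per class."""
    lines = ["graph mutex {"]
    for node, data in graph.nodes(data=True):
        cls = data.get("functional_class", "")
        shape = _DOT_SHAPE.get(cls, "ellipse")
        style = ' style=rounded' if cls == "both" else ""
        lines.append(f'  "{node}" [shape={shape}{style} label="{node}"];')
    for u, v, data in graph.edges(data=True):
        lines.append(
            f'  "{u}" -- "{v}" [{_DOT_STYLE[data["tier"]]} label="{data["subset"]}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PipelineConfig:
    """Inputs and settings for a full run.

    Mutation input is either ``maf_paths`` (pipeline name -> file) with
    ``clinical_path``, or in-memory ``records`` / ``clinical`` tables (as
    produced by the simulator).  ``fdr_threshold=None`` triggers the bootstrap
    estimator with ``fdr_config`` (whose mutation total defaults to the active
    subset's count).
    """

    maf_paths: dict[str, str] | None = None
    clinical_path: str | None = None
    records: dict[str, pd.DataFrame] | None = None
    clinical: pd.DataFrame | None = None
    gene_list_path: str | None = None  # None -> bundled DDR/CM panel
    histology: str = "muscle invasive urothelial carcinoma"
    subsets: list[SubsetSpec] = field(default_factory=lambda: list(STANDARD_SUBSETS))
    allow_high_only_everywhere: bool = False
    fdr_threshold: float | None = 0.07
    fdr_config: FdrConfig | None = None
    n_permutations: int = 2000
    seed: int = 0
    null: str = "pergene"
    thresholds: EdgeThresholds = field(default_factory=EdgeThresholds)
    outdir: str | None = None


@dataclass
class PipelineResult:
    network: nx.MultiGraph
    edge_lists: dict[str, list[EdgeRecord]]
    pair_tables: dict[str, pd.DataFrame]
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute ingest -> consensus -> filters -> exclusivity -> network."""
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "null": config.null,
        "stages": {},
    }

    # --- ingest ---------------------------------------------------------
    @_stage("ingest")
    def ingest():
        if config.records is not None:
            records = {k: v.copy() for k, v in config.records.items()}
            clinical = config.clinical
        else:
            if not config.maf_paths or not config.clinical_path:
                raise ValueError("need maf_paths + clinical_path or in-memory records + clinical")
            records = {name: read_maf(path, name) for name, path in config.maf_paths.items()}
            clinical = read_clinical(config.clinical_path)
        if clinical is None:
            raise ValueError("clinical table is required")
        filtered = {
            name: filter_cohort(t, clinical, histology=config.histology) for name, t in records.items()
        }
        # the cohort is every clinically eligible case; cases without a single
        # qualifying call stay in n as all-zero matrix rows
        from mutexsig.maf_io import ELIGIBLE_STAGES, normalize_stage

        stages = clinical["stage"].map(normalize_stage)
        eligible = (
            clinical["histology"].str.strip().str.lower() == config.histology.strip().lower()
        ) & stages.isin(ELIGIBLE_STAGES)
        universe = sorted(clinical.loc[eligible, "case_id"])
        return filtered, universe

    records, case_universe = ingest()
    manifest["stages"]["ingest"] = {
        "pipelines": {k: int(len(v)) for k, v in records.items()},
        "n_cases": len(case_universe),
    }
    if not case_universe:
        raise StageError("stage 'ingest' failed: no eligible cases after cohort filter")

    if config.gene_list_path:
        gene_classes = read_gene_list(config.gene_list_path)
    else:
        gene_classes = bundled_gene_list()

    n_pipelines = len(records)
    edge_lists: dict[str, list[EdgeRecord]] = {}
    pair_tables: dict[str, pd.DataFrame] = {}

    for spec in config.subsets:
        if (
            spec.impacts == frozenset({"HIGH"})
            and spec.min_callers > 1
            and not config.allow_high_only_everywhere
        ):
            logger.warning(
                "subset %s: high-impact-only analysis is restricted to the least-conservative "
                "tier (too few high-impact calls elsewhere); skipping", spec.label,
            )
            continue

        @_stage("consensus")
        def consensus_stage():
            return consensus_subset(records, spec.min_callers, total_callers=n_pipelines)

        subset_records = consensus_stage()

        @_stage("impact_filter")
        def impact_stage():
            return filter_impact(subset_records, set(spec.impacts))

        impact_records = impact_stage()

        @_stage("gene_filter")
        def gene_stage():
            matrix = build_matrix(impact_records, case_universe)
            matrix = restrict_gene_list(matrix, gene_classes)
            if config.fdr_threshold is not None:
                threshold = config.fdr_threshold
                fdr_info = {"mode": "fixed", "threshold": threshold}
            else:
                base = config.fdr_config or FdrConfig(total_mutations=0, n_cases=len(case_universe))
                cfg = FdrConfig(
                    total_mutations=base.total_mutations or int(len(impact_records)),
                    n_cases=len(case_universe),
                    n_genes_genomewide=base.n_genes_genomewide,
                    n_iterations=base.n_iterations,
                    seed=base.seed,
                    statistic=base.statistic,
                    quantile=base.quantile,
                )
                est = estimate_fdr_threshold(cfg)
                threshold = est.threshold
                fdr_info = {
                    "mode": "simulated", "threshold": est.threshold, "se": est.se,
                    "total_mutations": cfg.total_mutations, "n_iterations": cfg.n_iterations,
                }
            return apply_rate_filter(matrix, threshold), fdr_info

        matrix, fdr_info = gene_stage()
        stage_counts = {
            "n_variants_consensus": int(len(subset_records)),
            "n_variants_impact": int(len(impact_records)),
            "n_cases": matrix.n,
            "n_genes_after_filters": len(matrix.genes),
            "fdr": fdr_info,
        }

        if len(matrix.genes) < 2:
            logger.warning("subset %s: fewer than 2 genes survive filtering; no pairs", spec.label)
            edge_lists[spec.label] = []
            pair_tables[spec.label] = pairs_table([])
            stage_counts["n_pairs"] = 0
            manifest["stages"][spec.label] = stage_counts
            continue

        @_stage("exclusivity")
        def exclusivity_stage():
            return evaluate_all_pairs(
                matrix, n_permutations=config.n_permutations, seed=config.seed, null=config.null,
            )

        results = exclusivity_stage()
        pair_tables[spec.label] = pairs_table(results)

        @_stage("classify")
        def classify_stage():
            return edges_from_results(results, config.thresholds, spec.label)

        edge_lists[spec.label] = classify_stage()
        stage_counts["n_pairs"] = len(results)
        stage_counts["n_edges"] = len(edge_lists[spec.label])
        manifest["stages"][spec.label] = stage_counts

    @_stage("network")
    def network_stage():
        return build_network(edge_lists, gene_classes)

    network = network_stage()
    manifest["tier_counts"] = tier_counts(network)
    manifest["n_over_2sigma_pairs"] = len(
        {
            (e.gene_a, e.gene_b)
            for edges in edge_lists.values()
            for e in edges
            if e.min_sigma >= config.thresholds.solid
        }
    )
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(
            {
                "subsets": [(s.label, s.min_callers, sorted(s.impacts)) for s in config.subsets],
                "fdr_threshold": config.fdr_threshold,
                "n_permutations": config.n_permutations,
                "seed": config.seed,
                "null": config.null,
                "thresholds": [config.thresholds.dashed, config.thresholds.solid, config.thresholds.double],
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, table in pair_tables.items():
            table.to_csv(outdir / f"pairs_{label}.tsv", sep="\t", index=False)
        edges_table(edge_lists).to_csv(outdir / "edges.tsv", sep="\t", index=False)
        nx.write_graphml(network, outdir / "network.graphml")
        write_dot(network, outdir / "network.dot")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(network=network, edge_lists=edge_lists, pair_tables=pair_tables, manifest=manifest)
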