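"""DDR/CM gene-list restriction and the bootstrap chance-rate filter.

The chance ceiling asks: if the observed mutation total were scattered
uniformly over a genome-wide gene set (default 20,500 genes) and the cohort's
cases, how high a per-gene case-mutation rate would arise by chance alone?
The estimator redistributes the total many times and summarises the maximum
per-gene case rate per iteration (or an upper quantile of the per-gene rates,
config-switchable).  Genes whose observed rate does not exceed the resulting
threshold are removed — their recurrence is attainable by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np

from mutexsig.consensus import MutationMatrix

logger = logging.getLogger(__name__)

GENOME_WIDE_GENES = 20_500


@dataclass
class FdrConfig:
    """Configuration of the chance-rate bootstrap.

    ``n_iterations`` defaults to the full 1e6 redistribution count; tests and
    desk-scale runs use 1e4 or fewer (the estimate's standard error is
    reported so precision is visible either way).
    """

    total_mutations: int
    n_cases: int
    n_genes_genomewide: int = GENOME_WIDE_GENES
    n_iterations: int = 1_000_000
    seed: int = 0
    statistic: str = "max"  # "max" or "quantile"
    quantile: float = 1.0  # used when statistic == "quantile"

    def __post_init__(self) -> None:
        if self.total_mutations < 0:
            raise ValueError("total_mutations must be >= 0")
        for name in ("n_cases", "n_genes_genomewide", "n_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.statistic not in ("max", "quantile"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass
class FdrEstimate:
    threshold: float  # mean per-iteration chance ceiling, a case rate in [0, 1]
    se: float  # Monte Carlo standard error of the mean
    n_iterations: int


def restrict_gene_list(matrix: MutationMatrix, gene_list) -> MutationMatrix:
    """Restrict matrix columns to ``gene_list`` (set or symbol->class mapping).

    The case universe (and hence n) is unchanged.  An empty intersection is a
    warning, not an error: the result is a zero-column matrix.
    """
    symbols = set(gene_list)
    if not symbols:
        raise ValueError("gene list may not be empty")
    kept = [g for g in matrix.genes if g in symbols]
    if not kept:
        logger.warning("gene list shares no symbols with the matrix")
    return matrix.restrict_genes(kept)


def estimate_fdr_threshold(cfg: FdrConfig) -> FdrEstimate:
    """Monte Carlo estimate of the per-gene chance mutation-rate ceiling.

    Each iteration drops ``total_mutations`` independently and uniformly onto
    (gene, case) slots, binarises per (gene, case), computes each gene's case
    rate, and records the iteration's summary (max over genes by default).
    The threshold is the mean of these summaries; deterministic under seed.
    """
    if cfg.total_mutations == 0:
        return FdrEstimate(threshold=0.0, se=0.0, n_iterations=cfg.n_iterations)
    rng = np.random.default_rng(cfg.seed)
    g, n, m = cfg.n_genes_genomewide, cfg.n_cases, cfg.total_mutations
    maxima = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        gene_idx = rng.integers(0, g, size=m)
        case_idx = rng.integers(0, n, size=m)
        slots = np.unique(gene_idx.astype(np.int64) * n + case_idx)
        counts = np.bincount(slots // n, minlength=g)
        if cfg.statistic == "max":
            maxima[it] = counts.max() / n
        else:
            maxima[it] = np.quantile(counts / n, cfg.quantile)
    threshold = float(maxima.mean())
    se = float(maxima.std(ddof=1) / np.sqrt(cfg.n_iterations)) if cfg.n_iterations > 1 else 0.0
    return FdrEstimate(threshold=threshold, se=se, n_iterations=cfg.n_iterations)


def apply_rate_filter(matrix: MutationMatrix, threshold: float) -> MutationMatrix:
    """Keep genes mutated at a case rate strictly greater than ``threshold``.

    Genes at the threshold or below could be that recurrent by chance and are
    excluded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    rates = matrix.per_gene_counts / matrix.n
    kept = [g for g in matrix.genes if rates[g] > threshold]
    return matrix.restrict_genes(kept)


def bundled_gene_list() -> dict[str, str]:
    """The DDR/CM gene list shipped with the package (symbol -> class).

    Classes are best-effort pathway annotations used only to label network
    nodes; see docs for caveats.
    """
    text = resources.files("mutexsig").joinpath("data/ddr_cm_genes.tsv").read_text()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, _, cls = line.partition("\t")
        mapping[sym.strip()] = cls.strip()
    return mapping
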