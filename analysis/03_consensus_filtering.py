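#!/usr/bin/env python
"""Consensus tiers, impact filter, gene-panel restriction and chance-rate filter.

Tracks the per-stage variant/gene counts for the least (any caller),
mid (>= 2 callers) and most (all 4) conservative subsets, and estimates the
genome-wide chance mutation-rate ceiling by bootstrap at reduced iteration
count (the estimate's Monte Carlo SE is printed alongside).
"""

from pathlib import Path

import pandas as pd

from cohort_config import get_cohort
from mutexsig.consensus import build_matrix, consensus_subset
from mutexsig.gene_filter import FdrConfig, apply_rate_filter, bundled_gene_list, estimate_fdr_threshold, restrict_gene_list
from mutexsig.maf_io import filter_impact

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

TIERS = {"least": 1, "mid": 2, "most": 4}
FDR_ITERATIONS = 2000


def main() -> None:
    truth, tables, clinical = get_cohort()
    panel = bundled_gene_list()
    universe = sorted(clinical["case_id"])
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for tier, min_callers in TIERS.items():
        subset = consensus_subset(tables, min_callers)
        hm = filter_impact(subset, {"HIGH", "MODERATE"})
        matrix = restrict_gene_list(build_matrix(hm, universe), panel)

        est = estimate_fdr_threshold(
            FdrConfig(
                total_mutations=len(hm), n_cases=len(universe),
                n_iterations=FDR_ITERATIONS, seed=11,
            )
        )
        kept = apply_rate_filter(matrix, est.threshold)
        rows.append(
            {
                "tier": tier,
                "min_callers": min_callers,
                "n_variants": len(subset),
                "n_variants_high_moderate": len(hm),
                "n_panel_genes_mutated": len(matrix.genes),
                "chance_rate_threshold": round(est.threshold, 4),
                "threshold_se": round(est.se, 5),
                "n_genes_above_threshold": len(kept.genes),
                "genes_kept": ",".join(kept.genes),
            }
        )
        print(
            f"{tier:>5} (>= {min_callers} callers): {len(subset)} variants, "
            f"{len(hm)} high/moderate; chance ceiling {est.threshold:.3f} "
            f"(SE {est.se:.4f}) keeps {len(kept.genes)}/{len(matrix.genes)} panel genes"
        )

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "03_subset_counts.tsv", sep="\t", index=False)
    print(f"\nwrote {RESULTS / '03_subset_counts.tsv'}")


if __name__ == "__main__":
    main()
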