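#!/usr/bin/env python
"""Generate the synthetic study cohort and verify its file round-trip.

Writes the bulky per-pipeline MAF-dialect tables to scratch/cohort/ and a
small per-gene frequency summary (configured vs realized) to results/.
"""

from pathlib import Path

import pandas as pd

from cohort_config import GENE_FREQS, get_cohort
from mutexsig.maf_io import read_maf
from mutexsig.synthetic_data import write_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"


def main() -> None:
    truth, tables, clinical = get_cohort()
    paths = write_cohort(tables, clinical, SCRATCH)

    # round-trip: the MAF reader recovers exactly what the generator emitted
    for name, table in tables.items():
        back = read_maf(paths[name], name)
        assert len(back) == len(table), name
        assert set(back["case_id"]) == set(table["case_id"]), name

    realized = truth.incidence.mean()
    summary = pd.DataFrame(GENE_FREQS, columns=["gene", "configured_freq"])
    summary["realized_freq"] = summary["gene"].map(realized).round(4)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "01_gene_frequencies.tsv", sep="\t", index=False)

    print(f"cohort: {truth.incidence.shape[0]} cases x {truth.incidence.shape[1]} genes")
    print(f"per-pipeline calls: { {k: len(v) for k, v in tables.items()} }")
    print(f"stage counts: {clinical['stage'].value_counts().to_dict()}")
    worst = (summary["configured_freq"] - summary["realized_freq"]).abs().max()
    print(f"largest |configured - realized| gene frequency gap: {worst:.3f}")
    print(f"MAF round-trip through the reader verified for all {len(tables)} pipelines")
    print(f"wrote {RESULTS / '01_gene_frequencies.tsv'}")


if __name__ == "__main__":
    main()
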