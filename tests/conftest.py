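import numpy as np
import pandas as pd
import pytest

from mutexsig.consensus import MutationMatrix
from mutexsig.records import RECORD_COLUMNS
from mutexsig.synthetic_data import PipelineSpec, SimulationConfig, simulate_cohort


def make_records(rows, pipeline="p1"):
    """Build a record table from (case, gene, chrom, start, ref, alt, impact) tuples."""
    df = pd.DataFrame(
        rows, columns=["case_id", "gene", "chromosome", "start", "ref_allele", "alt_allele", "impact"]
    )
    df["pipeline"] = pipeline
    return df[RECORD_COLUMNS]


def make_matrix(incidence: dict[str, list[int]], case_ids=None) -> MutationMatrix:
    """Matrix from {gene: 0/1 column}; cases default to c0, c1, ..."""
    df = pd.DataFrame(incidence, dtype=np.int8)
    df.index = case_ids or [f"c{i}" for i in range(len(df))]
    return MutationMatrix(df)


@pytest.fixture(scope="session")
def four_caller_config():
    """A small four-pipeline cohort with one fully exclusive planted pair."""
    return SimulationConfig(
        n_cases=400,
        gene_specs=[
            ("KDM6A", 0.30),
            ("KMT2D", 0.30),
            ("TP53", 0.40),
            ("RB1", 0.20),
            ("EP300", 0.15),
        ],
        exclusive_pairs=[("KDM6A", "KMT2D", 1.0)],
        pipeline_specs=[
            PipelineSpec("muse", 0.90, 0.05),
            PipelineSpec("mutect2", 0.95, 0.10),
            PipelineSpec("somaticsniper", 0.80, 0.02),
            PipelineSpec("varscan2", 0.90, 0.05),
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def four_caller_cohort(four_caller_config):
    return simulate_cohort(four_caller_config)
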