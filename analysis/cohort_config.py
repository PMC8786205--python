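"""The synthetic study cohort shared by the numbered analysis scripts.

Emulates a muscle-invasive bladder cancer cohort at the scale the method is
designed for: 407 staged cases, four calling pipelines with distinct
sensitivity/false-call profiles, the bundled DDR/CM panel with plausible
per-gene mutation frequencies, and four planted exclusive pairs (the pair
KDM6A-KMT2D strongest) that the network stage should recover.
"""

from mutexsig.synthetic_data import PipelineSpec, SimulationConfig, simulate_cohort

N_CASES = 407
SEED = 2022

#: per-gene marginal case-mutation probabilities (DDR/CM panel)
GENE_FREQS = [
    ("TP53", 0.48), ("KMT2D", 0.28), ("KDM6A", 0.26), ("ARID1A", 0.25),
    ("KMT2C", 0.18), ("RB1", 0.17), ("EP300", 0.15), ("STAG2", 0.14),
    ("ATM", 0.14), ("CREBBP", 0.12), ("KMT2A", 0.11), ("BRCA2", 0.10),
    ("ERCC2", 0.09), ("ASXL2", 0.09), ("CDKN1A", 0.09), ("NCOR1", 0.08),
    ("TRRAP", 0.08), ("SRCAP", 0.08), ("CDKN2A", 0.07), ("ATR", 0.06),
    ("BPTF", 0.06), ("CHD6", 0.06), ("CHD7", 0.06), ("SETD2", 0.06),
    ("ARID2", 0.05), ("ASH1L", 0.05), ("HUWE1", 0.05), ("POLQ", 0.05),
    ("UBR5", 0.05), ("KANSL1", 0.03),
]

#: planted exclusive pairs (disjoint gene sets; strength in [0, 1])
PLANTED_PAIRS = [
    ("KDM6A", "KMT2D", 0.95),
    ("RB1", "KMT2C", 0.80),
    ("TP53", "CDKN1A", 0.60),
    ("ARID1A", "STAG2", 0.70),
]

PIPELINES = [
    PipelineSpec("muse", sensitivity=0.88, false_call_rate=0.05),
    PipelineSpec("mutect2", sensitivity=0.95, false_call_rate=0.12),
    PipelineSpec("somaticsniper", sensitivity=0.78, false_call_rate=0.03),
    PipelineSpec("varscan2", sensitivity=0.90, false_call_rate=0.08),
]


def study_config(seed: int = SEED) -> SimulationConfig:
    return SimulationConfig(
        n_cases=N_CASES,
        gene_specs=GENE_FREQS,
        exclusive_pairs=PLANTED_PAIRS,
        pipeline_specs=PIPELINES,
        seed=seed,
    )


def get_cohort(seed: int = SEED):
    """(truth, per-pipeline record tables, clinical table), deterministic."""
    return simulate_cohort(study_config(seed))
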