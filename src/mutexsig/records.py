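"""Shared record-table conventions.

Mutation calls are carried as pandas DataFrames with one row per called
variant and the columns below; a "variant" is identified across calling
pipelines by the exact 5-tuple in :data:`VARIANT_KEY_FIELDS` (no position
fuzzing or allele normalisation).
"""

from __future__ import annotations

import pandas as pd

#: Column order of a mutation-record table.
RECORD_COLUMNS = [
    "case_id",
    "gene",
    "chromosome",
    "start",
    "ref_allele",
    "alt_allele",
    "impact",
    "pipeline",
]

#: VEP-style predicted-impact vocabulary, most severe first.
IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

#: Severity rank used to break modal-impact ties (higher = more severe).
IMPACT_SEVERITY = {"HIGH": 3, "MODERATE": 2, "LOW": 1, "MODIFIER": 0}

#: Fields whose equality across pipelines means "same variant".
VARIANT_KEY_FIELDS = ["case_id", "chromosome", "start", "ref_allele", "alt_allele"]

#: Clinical-table columns.
CLINICAL_COLUMNS = ["case_id", "histology", "stage"]


def empty_records() -> pd.DataFrame:
    """An empty mutation-record table with the canonical columns."""
    return pd.DataFrame(columns=RECORD_COLUMNS)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a record table's columns and impact vocabulary; returns it unchanged."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    if len(records):
        bad = set(records["impact"].unique()) - set(IMPACT_LEVELS)
        if bad:
            raise ValueError(f"unknown impact levels: {sorted(bad)}")
    return records
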