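"""MAF-dialect ingestion and cohort/impact filtering.

Readers accept tab-separated mutation tables with the usual MAF column names
(matched case-insensitively) and normalise them to the package's record
layout.  TCGA-style sample barcodes are truncated to the 12-character case
level: mutual exclusivity is a per-case property, and the same case may appear
with different portion/analyte suffixes across pipelines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from mutexsig.records import CLINICAL_COLUMNS, IMPACT_LEVELS, RECORD_COLUMNS

logger = logging.getLogger(__name__)

#: required MAF column -> canonical record field
_MAF_COLUMNS = {
    "hugo_symbol": "gene",
    "tumor_sample_barcode": "case_id",
    "chromosome": "chromosome",
    "start_position": "start",
    "reference_allele": "ref_allele",
    "tumor_seq_allele2": "alt_allele",
    "impact": "impact",
}

_STAGE_ALIASES = {
    "ii": "ii", "2": "ii", "stage ii": "ii", "stage 2": "ii",
    "iii": "iii", "3": "iii", "stage iii": "iii", "stage 3": "iii",
    "iv": "iv", "4": "iv", "stage iv": "iv", "stage 4": "iv",
}

ELIGIBLE_STAGES = frozenset({"ii", "iii", "iv"})
DEFAULT_HISTOLOGY = "muscle invasive urothelial carcinoma"


def normalize_case_id(barcode: str) -> str:
    """Truncate a TCGA-style barcode to the 12-character case level.

    Non-TCGA identifiers pass through unchanged.
    """
    barcode = str(barcode).strip()
    if barcode.upper().startswith("TCGA-") and len(barcode) > 12:
        return barcode[:12]
    return barcode


def normalize_stage(stage) -> str:
    """Map common stage dialects ("Stage II", "2", "iii") onto {ii, iii, iv}.

    Unmapped values become "other".
    """
    return _STAGE_ALIASES.get(str(stage).strip().lower(), "other")


def read_maf(path, pipeline_name: str) -> pd.DataFrame:
    """Read one pipeline's MAF-dialect TSV into a mutation-record table.

    Rows with a missing gene symbol or sample barcode are dropped (with a
    logged count); impact strings are matched to the four-level vocabulary
    case-insensitively.  A missing required column is a hard error naming it.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except OSError as exc:
        raise OSError(f"cannot read MAF file {path}: {exc}") from exc
    lower_map = {c.lower(): c for c in raw.columns}
    for required in _MAF_COLUMNS:
        if required not in lower_map:
            raise ValueError(f"MAF file {path} is missing required column '{required}'")
    df = pd.DataFrame({canon: raw[lower_map[req]] for req, canon in _MAF_COLUMNS.items()})

    n0 = len(df)
    df = df.dropna(subset=["gene", "case_id"])
    df = df[(df["gene"].str.strip() != "") & (df["case_id"].str.strip() != "")]
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with missing gene or sample barcode", path.name, dropped)

    df["case_id"] = df["case_id"].map(normalize_case_id)
    df["impact"] = df["impact"].str.strip().str.upper()
    unknown = ~df["impact"].isin(IMPACT_LEVELS)
    if unknown.any():
        logger.warning(
            "%s: dropped %d rows with impact outside %s", path.name, int(unknown.sum()), IMPACT_LEVELS
        )
        df = df[~unknown]
    df["start"] = df["start"].astype(int)
    df["pipeline"] = pipeline_name
    return df.reset_index(drop=True)[RECORD_COLUMNS]


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical TSV (case_id, histology, stage) with normalisation."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    lower_map = {c.lower(): c for c in raw.columns}
    for required in CLINICAL_COLUMNS:
        if required not in lower_map:
            raise ValueError(f"clinical file {path} is missing required column '{required}'")
    df = pd.DataFrame({c: raw[lower_map[c]] for c in CLINICAL_COLUMNS})
    df["case_id"] = df["case_id"].map(normalize_case_id)
    df["stage"] = df["stage"].map(normalize_stage)
    df["histology"] = df["histology"].str.strip()
    if df["case_id"].duplicated().any():
        dup = df.loc[df["case_id"].duplicated(), "case_id"].unique()
        raise ValueError(f"clinical table has duplicate case ids: {list(dup)[:5]}")
    return df


def filter_cohort(
    records: pd.DataFrame,
    clinical: pd.DataFrame,
    histology: str = DEFAULT_HISTOLOGY,
) -> pd.DataFrame:
    """Keep records of cases with the given histology and stage in {ii, iii, iv}.

    Cases absent from the clinical table are dropped, as are cases whose
    clinical row fails the histology or stage criterion.
    """
    clin = clinical.copy()
    clin["stage"] = clin["stage"].map(normalize_stage)
    eligible = set(
        clin.loc[
            (clin["histology"].str.strip().str.lower() == histology.strip().lower())
            & clin["stage"].isin(ELIGIBLE_STAGES),
            "case_id",
        ]
    )
    kept = records[records["case_id"].isin(eligible)].reset_index(drop=True)
    if len(records) and not len(kept):
        logger.warning("cohort filter removed every record")
    n_dropped_cases = records.loc[~records["case_id"].isin(eligible), "case_id"].nunique()
    if n_dropped_cases:
        logger.info("cohort filter excluded %d cases", n_dropped_cases)
    return kept


def filter_impact(records: pd.DataFrame, allowed: set[str]) -> pd.DataFrame:
    """Keep records whose predicted impact is in ``allowed``; order preserved."""
    allowed = {str(a).upper() for a in allowed}
    if not allowed:
        raise ValueError("allowed impact set may not be empty")
    bad = allowed - set(IMPACT_LEVELS)
    if bad:
        raise ValueError(f"unknown impact levels in allowed set: {sorted(bad)}")
    return records[records["impact"].isin(allowed)].reset_index(drop=True)


def read_gene_list(path) -> dict[str, str]:
    """Read a gene list: one symbol per line, optional tab-separated class.

    Returns a mapping symbol -> functional class ("DDR", "CM", "both", or ""
    when the file carries bare symbols).  Lines starting with '#' are skipped.
    """
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        mapping[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else ""
    return mapping
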