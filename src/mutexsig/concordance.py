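"""Inter-pipeline concordance: per-case dispersion and k-way overlap.

Quantifies how much the calling pipelines disagree on a case: per-pipeline
mutation counts, their coefficient of variation (CV = SD/mean, sample SD by
default), and the partition of the case's distinct variants by the exact set
of pipelines supporting each.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from mutexsig.records import VARIANT_KEY_FIELDS


@dataclass
class CaseDispersion:
    case_id: str
    per_pipeline_counts: dict[str, int]
    mean: float
    sd: float
    cv: float  # NaN when mean == 0 (flagged undefined)
    total_unique: int


def _as_dict(per_pipeline_records) -> dict[str, pd.DataFrame]:
    if isinstance(per_pipeline_records, dict):
        return per_pipeline_records
    return {str(i): t for i, t in enumerate(per_pipeline_records)}


def case_dispersion(per_pipeline_records, case_id: str, ddof: int = 1) -> CaseDispersion:
    """Per-pipeline call counts and their CV for one case.

    Pipelines with no calls for the case count 0.  ``ddof=1`` (sample SD) by
    default; pass 0 for the population convention.
    """
    tables = _as_dict(per_pipeline_records)
    counts = {name: int((t["case_id"] == case_id).sum()) for name, t in tables.items()}
    if all(case_id not in set(t["case_id"]) for t in tables.values()):
        raise ValueError(f"case {case_id!r} appears in no pipeline table")
    values = np.array(list(counts.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=ddof)) if len(values) > ddof else 0.0
    cv = sd / mean if mean > 0 else float("nan")
    keys = pd.concat(
        [t.loc[t["case_id"] == case_id, VARIANT_KEY_FIELDS] for t in tables.values()],
        ignore_index=True,
    ).drop_duplicates()
    return CaseDispersion(
        case_id=case_id,
        per_pipeline_counts=counts,
        mean=mean,
        sd=sd,
        cv=cv,
        total_unique=len(keys),
    )


def dispersion_table(per_pipeline_records, ddof: int = 1) -> pd.DataFrame:
    """CaseDispersion over every case appearing in any pipeline table."""
    tables = _as_dict(per_pipeline_records)
    cases = sorted(set().union(*(set(t["case_id"]) for t in tables.values())))
    rows = []
    for case in cases:
        d = case_dispersion(tables, case, ddof=ddof)
        row = {"case_id": case, "mean": d.mean, "sd": d.sd, "cv": d.cv, "total_unique": d.total_unique}
        row.update({f"n_{k}": v for k, v in d.per_pipeline_counts.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def pipeline_summary(per_pipeline_records) -> pd.DataFrame:
    """Per-pipeline profile: cases, mutations, mean per case, count quartiles.

    Quartile boundaries are computed on the per-case mutation counts with
    linear interpolation and reported both numerically and as the four
    min-Q1 / Q1-Q2 / Q2-Q3 / Q3-max ranges.
    """
    tables = _as_dict(per_pipeline_records)
    rows = []
    for name, t in tables.items():
        if not len(t):
            rows.append(
                {
                    "pipeline": name, "total_cases": 0, "total_mutations": 0,
                    "mean_per_case": 0.0, "q_min": 0.0, "q1": 0.0, "q2": 0.0,
                    "q3": 0.0, "q_max": 0.0, "quartile_ranges": ["0-0"] * 4,
                }
            )
            continue
        counts = t.groupby("case_id").size().to_numpy(dtype=float)
        qs = np.percentile(counts, [0, 25, 50, 75, 100])
        rows.append(
            {
                "pipeline": name,
                "total_cases": int(t["case_id"].nunique()),
                "total_mutations": int(len(t)),
                "mean_per_case": float(counts.mean()),
                "q_min": qs[0], "q1": qs[1], "q2": qs[2], "q3": qs[3], "q_max": qs[4],
                "quartile_ranges": [f"{qs[i]:g}-{qs[i + 1]:g}" for i in range(4)],
            }
        )
    return pd.DataFrame(rows)


def overlap_counts(per_pipeline_records, case_id: str) -> dict[frozenset, int]:
    """Partition a case's distinct variants by exact supporting-pipeline set.

    Returns a count for every nonempty pipeline subset (2^k - 1 cells); cells
    sum to the case's total distinct variant count.
    """
    tables = _as_dict(per_pipeline_records)
    names = list(tables)
    support: dict[tuple, set[str]] = {}
    for name, t in tables.items():
        sub = t.loc[t["case_id"] == case_id, VARIANT_KEY_FIELDS].drop_duplicates()
        for key in sub.itertuples(index=False, name=None):
            support.setdefault(key, set()).add(name)
    counts = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in combinations(names, r)
    }
    for callers in support.values():
        counts[frozenset(callers)] += 1
    return counts
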