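"""Multi-pipeline consensus tiers and the binary mutation matrix.

A variant is identified across calling pipelines by the exact
(case, chromosome, start, ref, alt) tuple.  The "least conservative" subset
keeps variants called by any pipeline (min_callers=1), "mid" those called by
at least two, and "most" those called by every pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mutexsig.records import IMPACT_SEVERITY, RECORD_COLUMNS, VARIANT_KEY_FIELDS


@dataclass(frozen=True)
class VariantKey:
    """Identity of a called variant; equal keys mean the same variant."""

    case_id: str
    chromosome: str
    start: int
    ref_allele: str
    alt_allele: str


@dataclass
class MutationMatrix:
    """Binary case x gene incidence over a fixed case universe.

    Cases with zero qualifying mutations stay as all-zero rows: conditional
    probabilities downstream are over all cohort cases, not just mutated ones.
    """

    incidence: pd.DataFrame  # cases (rows) x genes (columns), values {0, 1}

    def __post_init__(self) -> None:
        if len(self.incidence.index) < 1:
            raise ValueError("mutation matrix needs at least one case")
        vals = self.incidence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        self.incidence = self.incidence.astype(np.int8)

    @property
    def case_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def n(self) -> int:
        """Cohort size (number of cases, including unmutated ones)."""
        return len(self.incidence.index)

    @property
    def per_gene_counts(self) -> pd.Series:
        """Number of mutated cases per gene (a_g)."""
        return self.incidence.sum(axis=0)

    def column(self, gene: str) -> np.ndarray:
        return self.incidence[gene].to_numpy(dtype=bool)

    def restrict_genes(self, genes: list[str]) -> "MutationMatrix":
        return MutationMatrix(self.incidence[genes].copy())


def _concat_pipelines(per_pipeline_records) -> pd.DataFrame:
    if isinstance(per_pipeline_records, dict):
        frames = list(per_pipeline_records.values())
    else:
        frames = list(per_pipeline_records)
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def consensus_subset(
    per_pipeline_records,
    min_callers: int,
    total_callers: int | None = None,
) -> pd.DataFrame:
    """Variants supported by at least ``min_callers`` distinct pipelines.

    Duplicate rows within one pipeline count as support 1.  Each retained
    variant contributes a single deduplicated record whose impact is the modal
    impact across supporting callers, ties broken toward the more severe
    class; the record's ``pipeline`` field is ``consensus>=k``.
    """
    if isinstance(per_pipeline_records, dict):
        n_pipelines = len(per_pipeline_records)
    else:
        n_pipelines = len(list(per_pipeline_records))
    if total_callers is None:
        total_callers = n_pipelines
    if not 1 <= min_callers <= total_callers:
        raise ValueError(f"min_callers must be in [1, {total_callers}], got {min_callers}")
    if min_callers > n_pipelines:
        raise ValueError(
            f"min_callers={min_callers} exceeds the {n_pipelines} supplied pipeline tables"
        )

    records = _concat_pipelines(per_pipeline_records)
    if not len(records):
        return records.copy()

    # one vote per (variant, pipeline), regardless of duplicate rows
    votes = records.drop_duplicates(VARIANT_KEY_FIELDS + ["pipeline"])
    support = votes.groupby(VARIANT_KEY_FIELDS, sort=False)["pipeline"].nunique()
    kept_keys = support[support >= min_callers].index

    # modal impact over supporting callers, severity breaking ties
    impact_votes = (
        votes.groupby(VARIANT_KEY_FIELDS + ["impact"], sort=False, as_index=False)
        .size()
        .assign(severity=lambda d: d["impact"].map(IMPACT_SEVERITY))
        .sort_values(["size", "severity"], ascending=False, kind="mergesort")
        .drop_duplicates(VARIANT_KEY_FIELDS)
        .set_index(VARIANT_KEY_FIELDS)
    )

    dedup = (
        votes.drop_duplicates(VARIANT_KEY_FIELDS)
        .set_index(VARIANT_KEY_FIELDS)
        .loc[list(kept_keys)]
        .reset_index()
    )
    dedup["impact"] = impact_votes.loc[list(kept_keys), "impact"].to_numpy()
    dedup["pipeline"] = f"consensus>={min_callers}"
    return dedup.reset_index(drop=True)[RECORD_COLUMNS]


def build_matrix(records: pd.DataFrame, case_universe: list[str]) -> MutationMatrix:
    """Binarised case x gene incidence over ``case_universe``.

    ``incidence[i, j] = 1`` iff case i carries >= 1 record in gene j; cases in
    the universe without records remain all-zero rows and still count in n.
    """
    universe = list(dict.fromkeys(case_universe))
    if not universe:
        raise ValueError("case_universe may not be empty")
    extra = set(records["case_id"]) - set(universe)
    if extra:
        raise ValueError(f"records contain cases outside the universe: {sorted(extra)[:5]}")
    genes = sorted(records["gene"].unique())
    arr = np.zeros((len(universe), len(genes)), dtype=np.int8)
    if len(records):
        case_pos = {c: i for i, c in enumerate(universe)}
        gene_pos = {g: j for j, g in enumerate(genes)}
        flat = records[["case_id", "gene"]].drop_duplicates()
        arr[flat["case_id"].map(case_pos).to_numpy(), flat["gene"].map(gene_pos).to_numpy()] = 1
    return MutationMatrix(pd.DataFrame(arr, index=universe, columns=genes))
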