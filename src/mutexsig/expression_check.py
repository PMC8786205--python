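"""Expression corroboration of epistasis between two driver genes.

If two mutually exclusive drivers act through a shared complex, their
mutations should move the same downstream targets in the same direction.
This module compares each candidate target's mean expression in driver-A
mutants and driver-B mutants against wild-type (mutant in neither) cases,
expresses the changes as signed fractions of the wild-type mean, and bins
them:

* ``little`` — both |change| below the little threshold (default 20%);
* ``modest`` — one change between the little and modest thresholds (default
  40%) and the other below little;
* ``coordinate_decrease`` — both changes negative and beyond the bins above:
  the signature of shared downregulation;
* ``other`` — anything else (e.g. coordinate increase, opposite directions).

Control genes are expected to sit in ``little``; each gets a pass flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mutexsig.consensus import MutationMatrix

logger = logging.getLogger(__name__)

T_LITTLE = 0.20
T_MODEST = 0.40


@dataclass
class ExpressionComparison:
    gene: str
    pct_change_a: float  # (mutA mean - WT mean) / WT mean, signed
    pct_change_b: float
    label: str  # little | modest | coordinate_decrease | other


@dataclass
class ClassificationReport:
    targets: pd.DataFrame  # gene, pct_change_a, pct_change_b, label
    controls: pd.DataFrame  # gene, pct_change_a, pct_change_b, label, control_pass
    mean_coordinate_decrease: float  # mean per-gene decrease over coordinate genes, NaN if none
    median_coordinate_decrease: float
    skipped: list[str]


def group_means(
    expression: pd.DataFrame,
    matrix: MutationMatrix,
    driver_a: str,
    driver_b: str,
    drop_double_mutants: bool = False,
) -> pd.DataFrame:
    """Per-gene expression means for the A-mutant, B-mutant and WT groups.

    ``expression`` is genes (rows) x cases (columns); its case set must cover
    the matrix's cases.  WT = cases mutant in neither driver.  Cases mutant in
    both drivers join both mutant groups unless ``drop_double_mutants``
    (exclusivity makes such cases rare by construction).
    """
    cases = [c for c in matrix.case_ids if c in expression.columns]
    missing = set(matrix.case_ids) - set(cases)
    if missing:
        logger.warning("expression matrix lacks %d matrix cases", len(missing))
    if not cases:
        raise ValueError("no shared cases between expression and mutation matrices")
    sub = expression[cases]
    in_a = matrix.incidence.loc[cases, driver_a].to_numpy(bool)
    in_b = matrix.incidence.loc[cases, driver_b].to_numpy(bool)
    if drop_double_mutants:
        both = in_a & in_b
        in_a = in_a & ~both
        in_b = in_b & ~both
    wt = ~in_a & ~in_b
    for name, mask in ((f"{driver_a}-mutant", in_a), (f"{driver_b}-mutant", in_b), ("WT", wt)):
        if not mask.any():
            raise ValueError(f"group '{name}' is empty")
    return pd.DataFrame(
        {
            "mut_a": sub.loc[:, in_a].mean(axis=1),
            "mut_b": sub.loc[:, in_b].mean(axis=1),
            "wt": sub.loc[:, wt].mean(axis=1),
        }
    )


def classify_change(delta_a: float, delta_b: float, t_little: float = T_LITTLE, t_modest: float = T_MODEST) -> str:
    """Bin a pair of signed fractional expression changes."""
    if not 0 < t_little < t_modest:
        raise ValueError("thresholds must satisfy 0 < t_little < t_modest")
    mags = sorted((abs(delta_a), abs(delta_b)))
    if mags[1] < t_little:
        return "little"
    if mags[0] < t_little and mags[1] < t_modest:
        return "modest"
    if delta_a < 0 and delta_b < 0:
        return "coordinate_decrease"
    return "other"


def classify_targets(
    expression: pd.DataFrame,
    matrix: MutationMatrix,
    driver_a: str,
    driver_b: str,
    target_genes: list[str],
    control_genes: list[str],
    t_little: float = T_LITTLE,
    t_modest: float = T_MODEST,
    drop_double_mutants: bool = False,
) -> ClassificationReport:
    """Classify target/control genes by driver-mutant expression change.

    Per-gene change = (mutant-group mean - WT mean) / WT mean.  Genes absent
    from the expression matrix or with non-positive WT mean are skipped with a
    log entry.  The report's decrease summaries average each coordinate gene's
    mean of |change_A| and |change_B|, as positive fractions.
    """
    means = group_means(expression, matrix, driver_a, driver_b, drop_double_mutants)
    skipped: list[str] = []

    def compare(genes: list[str]) -> pd.DataFrame:
        rows = []
        for g in genes:
            if g not in means.index:
                skipped.append(g)
                logger.warning("gene %s absent from expression matrix; skipped", g)
                continue
            wt = means.at[g, "wt"]
            if wt <= 0:
                skipped.append(g)
                logger.warning("gene %s has non-positive WT mean (%.3g); skipped", g, wt)
                continue
            da = (means.at[g, "mut_a"] - wt) / wt
            db = (means.at[g, "mut_b"] - wt) / wt
            rows.append(
                {
                    "gene": g, "pct_change_a": da, "pct_change_b": db,
                    "label": classify_change(da, db, t_little, t_modest),
                }
            )
        return pd.DataFrame(rows, columns=["gene", "pct_change_a", "pct_change_b", "label"])

    targets = compare(list(target_genes))
    controls = compare(list(control_genes))
    if len(controls):
        controls["control_pass"] = controls["label"] == "little"

    coord = targets[targets["label"] == "coordinate_decrease"] if len(targets) else targets
    if len(coord):
        per_gene = (coord["pct_change_a"].abs() + coord["pct_change_b"].abs()) / 2.0
        mean_dec, median_dec = float(per_gene.mean()), float(per_gene.median())
    else:
        mean_dec = median_dec = float("nan")
    return ClassificationReport(
        targets=targets,
        controls=controls,
        mean_coordinate_decrease=mean_dec,
        median_coordinate_decrease=median_dec,
        skipped=skipped,
    )


def read_expression(path) -> pd.DataFrame:
    """Read a genes (rows) x cases (columns) expression TSV."""
    return pd.read_csv(path, sep="\t", index_col=0)
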