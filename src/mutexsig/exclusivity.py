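"""Conditional-probability exclusivity statistic and its permutation null.

For an ordered gene pair (A, B) over a binary case x gene matrix the observed
statistic is the conditional probability

    CP(A, B) = P(not A | B) = #(B and not A) / #B.

Its null distribution — the randomised-gene conditional probability (RGCP)
distribution — re-assigns, independently per gene, that gene's mutated cases
to a uniformly random case subset of the same size, and recomputes CP.  Under
this null the number of B-carriers that also carry A is hypergeometric
(population n, a_A marked, b drawn), so CP = (b - K)/b with
K ~ Hypergeometric(n, a_A, b); the sampler draws K directly.  Its mean is
(n - a_A)/n, independent of B.

The observed CP is scored as sigma = (CP - null mean)/null SD; elevated CP
(positive sigma) means B-carriers avoid A more than chance allows — the
exclusivity direction.  p-values are two-sided normal tails at |sigma|
(2 sigma ~ 0.05, 3 sigma ~ 0.003), extrapolated from the fitted normal rather
than from empirical rank so that p-values far below 1/n_permutations remain
expressible; normality of the null is checked per pair with a Shapiro-Wilk
test, and the empirical percentile is kept alongside for flagged pairs.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mutexsig.consensus import MutationMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_PERMUTATIONS = 2000
SHAPIRO_ALPHA = 0.05


class UndefinedPairError(ValueError):
    """CP(A, B) is undefined because gene B has no mutated cases."""


@dataclass
class NullSummary:
    """RGCP null distribution for one ordered pair."""

    pair: tuple[str, str]
    mean: float
    sd: float
    max_value: float
    shapiro_p: float
    n_permutations: int
    values: np.ndarray | None = field(default=None, repr=False)
    degenerate: bool = False  # a_g in {0, n} for a member gene: sd is 0 by construction


@dataclass
class PairExclusivity:
    """Observed CP for an ordered pair scored against its RGCP null."""

    pair: tuple[str, str]
    cp_observed: float
    null: NullSummary
    sigma: float
    p_value: float
    outside_null: bool
    non_normal: bool = False
    empirical_percentile: float = float("nan")
    excluded: bool = False  # degenerate null (sd == 0); sigma/p are NaN


def conditional_probability(matrix: MutationMatrix, geneA: str, geneB: str) -> float:
    """Observed CP(A, B) = #(B and not A) / #B.  Ordered: CP(A,B) != CP(B,A)."""
    a_col = matrix.column(geneA)
    b_col = matrix.column(geneB)
    b = int(b_col.sum())
    if b == 0:
        raise UndefinedPairError(f"gene {geneB} has no mutated cases; CP({geneA}|{geneB}) undefined")
    return float((b_col & ~a_col).sum() / b)


def _shapiro_p(values: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def rgcp_null(
    matrix: MutationMatrix,
    geneA: str,
    geneB: str,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    keep_values: bool = True,
    compute_shapiro: bool = True,
) -> NullSummary:
    """RGCP null for the ordered pair (A, B) by per-gene re-assignment.

    Each of the ``n_permutations`` draws places gene A's a mutated cases and
    gene B's b mutated cases on independent uniform subsets of the n cases
    (per-gene counts preserved exactly) and recomputes CP; equivalently the
    A-carrier count among B's cases is drawn hypergeometrically.
    Deterministic under ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    a = int(matrix.column(geneA).sum())
    b = int(matrix.column(geneB).sum())
    n = matrix.n
    if b == 0:
        raise UndefinedPairError(f"gene {geneB} has no mutated cases")
    if a in (0, n):
        value = 1.0 if a == 0 else 0.0
        values = np.full(n_permutations, value)
        return NullSummary(
            pair=(geneA, geneB), mean=value, sd=0.0, max_value=value,
            shapiro_p=float("nan"), n_permutations=n_permutations,
            values=values if keep_values else None, degenerate=True,
        )
    overlap = rng.hypergeometric(ngood=a, nbad=n - a, nsample=b, size=n_permutations)
    values = (b - overlap) / b
    sd = float(values.std(ddof=1))
    return NullSummary(
        pair=(geneA, geneB),
        mean=float(values.mean()),
        sd=sd,
        max_value=float(values.max()),
        shapiro_p=_shapiro_p(values) if compute_shapiro else float("nan"),
        n_permutations=n_permutations,
        values=values if keep_values else None,
        degenerate=sd == 0.0,
    )


def sigma_and_p(cp_observed: float, null: NullSummary) -> PairExclusivity:
    """Score an observed CP against its null: signed sigma and two-sided p.

    Positive sigma is the exclusivity direction (observed CP above the RGCP
    expected value).  A degenerate null (sd == 0) yields an excluded marker
    rather than an error: such pairs carry no usable signal.
    """
    if null.sd == 0.0:
        return PairExclusivity(
            pair=null.pair, cp_observed=cp_observed, null=null,
            sigma=float("nan"), p_value=float("nan"),
            outside_null=False, excluded=True,
        )
    sigma = (cp_observed - null.mean) / null.sd
    p = float(2.0 * stats.norm.sf(abs(sigma)))
    p = min(p, 1.0)
    non_normal = bool(np.isfinite(null.shapiro_p) and null.shapiro_p < SHAPIRO_ALPHA)
    if null.values is not None:
        percentile = float(np.mean(null.values <= cp_observed))
    else:
        percentile = float("nan")
    return PairExclusivity(
        pair=null.pair,
        cp_observed=cp_observed,
        null=null,
        sigma=float(sigma),
        p_value=p,
        outside_null=bool(cp_observed > null.max_value),
        non_normal=non_normal,
        empirical_percentile=percentile,
    )


def pair_seed(master_seed: int, geneA: str, geneB: str) -> int:
    """Per-pair seed from the master seed and the unordered pair symbols.

    Stable across runs and across the two orderings of the pair.
    """
    lo, hi = sorted((geneA, geneB))
    digest = hashlib.sha256(f"{master_seed}:{lo}:{hi}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _curveball_trade(sets: list[set], rng: np.random.Generator, n_trades: int) -> None:
    """In-place curveball trades between gene case-sets.

    Each trade picks two genes and re-deals the cases unique to either
    between them, preserving both per-gene counts and per-case burdens.
    """
    n_genes = len(sets)
    for _ in range(n_trades):
        i, j = rng.choice(n_genes, size=2, replace=False)
        only_i = sets[i] - sets[j]
        only_j = sets[j] - sets[i]
        tradeable = list(only_i | only_j)
        if not tradeable:
            continue
        rng.shuffle(tradeable)
        new_i = set(tradeable[: len(only_i)])
        sets[i] = (sets[i] - only_i) | new_i
        sets[j] = (sets[j] - only_j) | (set(tradeable) - new_i)


def curveball_null_values(
    matrix: MutationMatrix,
    n_permutations: int,
    seed: int,
    trades_per_sample: int | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """Margins-preserving alternative null: CP draws for every ordered pair.

    Randomises the whole incidence matrix with curveball trades (per-gene
    counts and per-case mutation burdens both preserved) and records each
    ordered pair's CP per randomised matrix.  Heavier than the per-gene null;
    offered as a sensitivity check, not the default.
    """
    rng = np.random.default_rng(seed)
    genes = matrix.genes
    sets = [set(np.flatnonzero(matrix.column(g))) for g in genes]
    if trades_per_sample is None:
        trades_per_sample = max(5 * len(genes), 20)
    # burn-in
    _curveball_trade(sets, rng, 10 * trades_per_sample)
    out = {
        (a, b): np.empty(n_permutations)
        for a in genes
        for b in genes
        if a != b and len(sets[genes.index(b)]) > 0
    }
    for t in range(n_permutations):
        _curveball_trade(sets, rng, trades_per_sample)
        for (a, b), arr in out.items():
            sb = sets[genes.index(b)]
            arr[t] = len(sb - sets[genes.index(a)]) / len(sb)
    return out


def evaluate_all_pairs(
    matrix: MutationMatrix,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    null: str = "pergene",
    compute_shapiro: bool = True,
    keep_values: bool = False,
) -> list[PairExclusivity]:
    """Score every ordered gene pair with a defined CP.

    Both orderings of each unordered pair are evaluated; per-pair permutation
    seeds derive from the master seed and the unordered pair symbols, so the
    result is independent of gene order in the matrix.  Degenerate pairs
    (a_g in {0, n}) are returned with ``excluded=True`` and logged.
    """
    if len(matrix.genes) < 2:
        raise ValueError("need at least two genes to evaluate pairs")
    if null not in ("pergene", "curveball"):
        raise ValueError(f"unknown null scheme {null!r}")
    counts = matrix.per_gene_counts
    results: list[PairExclusivity] = []

    curve_values: dict[tuple[str, str], np.ndarray] | None = None
    if null == "curveball":
        curve_values = curveball_null_values(matrix, n_permutations, seed)

    # unordered pairs in sorted-symbol order so the per-pair RNG stream (and
    # hence every sigma) is independent of the matrix's column order
    genes = sorted(matrix.genes)
    for i, gene_a in enumerate(genes):
        for gene_b in genes[i + 1 :]:
            rng = np.random.default_rng(pair_seed(seed, gene_a, gene_b))
            for a, b in ((gene_a, gene_b), (gene_b, gene_a)):
                if counts[b] == 0:
                    logger.info("skipping (%s, %s): %s has no mutated cases", a, b, b)
                    continue
                cp = conditional_probability(matrix, a, b)
                if curve_values is not None:
                    vals = curve_values[(a, b)]
                    sd = float(vals.std(ddof=1))
                    summary = NullSummary(
                        pair=(a, b), mean=float(vals.mean()), sd=sd,
                        max_value=float(vals.max()),
                        shapiro_p=_shapiro_p(vals) if compute_shapiro else float("nan"),
                        n_permutations=n_permutations,
                        values=vals if keep_values else None,
                        degenerate=sd == 0.0,
                    )
                else:
                    summary = rgcp_null(
                        matrix, a, b, n_permutations=n_permutations, rng=rng,
                        keep_values=True, compute_shapiro=compute_shapiro,
                    )
                result = sigma_and_p(cp, summary)
                if not keep_values:
                    summary.values = None
                results.append(result)
    return results


def pairs_table(results: list[PairExclusivity]) -> pd.DataFrame:
    """Flatten pair results to a table (one row per ordered pair)."""
    rows = [
        {
            "geneA": r.pair[0],
            "geneB": r.pair[1],
            "cp": r.cp_observed,
            "null_mean": r.null.mean,
            "null_sd": r.null.sd,
            "sigma": r.sigma,
            "p": r.p_value,
            "shapiro_p": r.null.shapiro_p,
            "outside_null": r.outside_null,
            "non_normal": r.non_normal,
            "excluded": r.excluded,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
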