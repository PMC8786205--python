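"""Synthetic multi-caller cohorts with known ground truth.

Generates binary case x gene mutation incidence with planted pairwise
exclusivity, derives noisy per-pipeline call tables from it, and produces
matching clinical and expression tables, so every downstream stage can be
tested against a known answer.

Exclusivity of strength ``e`` for a pair (A, B) with marginal case-mutation
probabilities p and q is planted by drawing each case's joint status from the
2x2 distribution with P(A and B) = (1 - e) * p * q and both margins preserved:
e = 0 gives independence, e = 1 forbids co-occurrence, and the per-gene
frequencies stay at their configured values — which is exactly what the
downstream permutation null conditions on.

Caller noise: each pipeline drops a true call with probability
(1 - sensitivity) and, per case, emits a spurious call with probability equal
to its false-call rate.  Spurious calls receive fresh unique coordinates so
they can never accidentally gain cross-pipeline consensus support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mutexsig.records import RECORD_COLUMNS, IMPACT_LEVELS

logger = logging.getLogger(__name__)

DEFAULT_HISTOLOGY = "muscle invasive urothelial carcinoma"

#: Coordinate offset for spurious calls; keeps them clear of true-variant loci.
_FALSE_CALL_BASE = 900_000_000


@dataclass(frozen=True)
class PipelineSpec:
    """One calling pipeline: name, true-call sensitivity, per-case false-call rate."""

    name: str
    sensitivity: float = 1.0
    false_call_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in (0, 1], got {self.sensitivity}")
        if not 0.0 <= self.false_call_rate < 1.0:
            raise ValueError(f"false_call_rate must be in [0, 1), got {self.false_call_rate}")


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort.

    Parameters
    ----------
    n_cases
        Cohort size.
    gene_specs
        ``(gene symbol, marginal case-mutation probability)`` per gene.
    exclusive_pairs
        ``(geneA, geneB, strength e)`` with e in [0, 1]; each gene may appear
        in at most one pair so the planted joint distributions are well defined.
    pipeline_specs
        Calling pipelines deriving noisy call tables from the true incidence.
    impact_probs
        Probabilities over the four impact classes; applied per variant.
    stage_probs
        Probabilities over tumour stages ``{"ii", "iii", "iv"}``.
    seed
        Master seed; all outputs are deterministic under it.
    """

    n_cases: int
    gene_specs: list[tuple[str, float]]
    exclusive_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    pipeline_specs: list[PipelineSpec] = field(default_factory=lambda: [PipelineSpec("caller1")])
    impact_probs: dict[str, float] = field(
        default_factory=lambda: {"HIGH": 0.25, "MODERATE": 0.45, "LOW": 0.15, "MODIFIER": 0.15}
    )
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"ii": 130 / 407, "iii": 141 / 407, "iv": 136 / 407}
    )
    seed: int = 0
    histology: str = DEFAULT_HISTOLOGY

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError(f"n_cases must be positive, got {self.n_cases}")
        genes = [g for g, _ in self.gene_specs]
        if len(set(genes)) != len(genes):
            raise ValueError("gene symbols must be unique")
        for g, p in self.gene_specs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal probability for {g} outside [0, 1]: {p}")
        known = set(genes)
        seen_in_pair: set[str] = set()
        for a, b, e in self.exclusive_pairs:
            if a not in known or b not in known:
                raise ValueError(f"exclusive pair ({a}, {b}) references unknown gene")
            if a == b:
                raise ValueError(f"exclusive pair may not repeat a gene: {a}")
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"exclusivity strength outside [0, 1]: {e}")
            if a in seen_in_pair or b in seen_in_pair:
                raise ValueError("a gene may appear in at most one exclusive pair")
            seen_in_pair.update((a, b))
        for name, probs in (("impact_probs", self.impact_probs), ("stage_probs", self.stage_probs)):
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains a negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs.values())}")
        bad = set(self.impact_probs) - set(IMPACT_LEVELS)
        if bad:
            raise ValueError(f"impact_probs has unknown levels: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.gene_specs]


@dataclass
class GroundTruth:
    """True mutation incidence before caller noise, plus the planted pairs."""

    incidence: pd.DataFrame  # cases x genes, values in {0, 1}
    planted_pairs: list[tuple[str, str, float]]

    @property
    def case_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.incidence.columns)


def _case_barcode(i: int) -> str:
    # 12-character TCGA-style case barcode.
    return f"TCGA-SY-{i:04d}"


def _draw_incidence(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cases
    marg = dict(cfg.gene_specs)
    inc = pd.DataFrame(0, index=[_case_barcode(i) for i in range(n)], columns=cfg.genes, dtype=np.int8)
    paired = {g for a, b, _ in cfg.exclusive_pairs for g in (a, b)}
    for a, b, e in cfg.exclusive_pairs:
        p, q = marg[a], marg[b]
        p_both = (1.0 - e) * p * q
        cell = np.array([1.0 - p - q + p_both, p - p_both, q - p_both, p_both])
        if (cell < -1e-12).any():
            raise ValueError(
                f"pair ({a}, {b}, e={e}) with margins ({p}, {q}) has no valid joint distribution"
            )
        cell = np.clip(cell, 0.0, None)
        cell /= cell.sum()
        status = rng.choice(4, size=n, p=cell)
        inc[a] = ((status == 1) | (status == 3)).astype(np.int8)
        inc[b] = ((status == 2) | (status == 3)).astype(np.int8)
    for g in cfg.genes:
        if g not in paired:
            inc[g] = (rng.random(n) < marg[g]).astype(np.int8)
    return inc


def _true_variants(cfg: SimulationConfig, incidence: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One variant per true (case, gene) event, identical across pipelines.

    Each gene gets its own locus block; the variant position within the block
    is the case index, so the (case, chrom, start, ref, alt) key is unique per
    event and shared by every pipeline that detects it.
    """
    alts = np.array(["C", "G", "T"])
    rows = []
    case_index = {c: i for i, c in enumerate(incidence.index)}
    for j, gene in enumerate(incidence.columns):
        carriers = incidence.index[incidence[gene].to_numpy(bool)]
        base = 1_000_000 * (j + 1)
        for case in carriers:
            rows.append((case, gene, f"chr{j % 22 + 1}", base + case_index[case]))
    variants = pd.DataFrame(rows, columns=["case_id", "gene", "chromosome", "start"])
    m = len(variants)
    variants["ref_allele"] = "A"
    variants["alt_allele"] = alts[rng.integers(0, 3, size=m)]
    impacts = list(cfg.impact_probs)
    probs = np.array([cfg.impact_probs[k] for k in impacts])
    variants["impact"] = np.array(impacts, dtype=object)[rng.choice(len(impacts), size=m, p=probs)]
    return variants


def _pipeline_calls(
    cfg: SimulationConfig,
    variants: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    impacts = list(cfg.impact_probs)
    probs = np.array([cfg.impact_probs[k] for k in impacts])
    false_counter = 0
    case_ids = [_case_barcode(i) for i in range(cfg.n_cases)]
    for spec in cfg.pipeline_specs:
        kept = variants[rng.random(len(variants)) < spec.sensitivity].copy()
        kept["pipeline"] = spec.name
        false_rows = []
        if spec.false_call_rate > 0:
            hit = rng.random(cfg.n_cases) < spec.false_call_rate
            for case in np.asarray(case_ids, dtype=object)[hit]:
                gene = cfg.genes[rng.integers(0, len(cfg.genes))]
                false_counter += 1
                false_rows.append(
                    {
                        "case_id": case,
                        "gene": gene,
                        "chromosome": "chrX",
                        "start": _FALSE_CALL_BASE + false_counter,
                        "ref_allele": "A",
                        "alt_allele": "C",
                        "impact": impacts[rng.choice(len(impacts), p=probs)],
                        "pipeline": spec.name,
                    }
                )
        table = pd.concat([kept, pd.DataFrame(false_rows)], ignore_index=True) if false_rows else kept
        tables[spec.name] = table.reset_index(drop=True)[RECORD_COLUMNS]
    return tables


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GroundTruth, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a cohort: ground truth, per-pipeline call tables, clinical table.

    Returns
    -------
    truth : GroundTruth
    pipeline_tables : dict mapping pipeline name to a mutation-record table
    clinical : DataFrame with columns case_id, histology, stage
    """
    rng = np.random.default_rng(config.seed)
    incidence = _draw_incidence(config, rng)
    variants = _true_variants(config, incidence, rng)
    tables = _pipeline_calls(config, variants, rng)
    stages = list(config.stage_probs)
    stage_p = np.array([config.stage_probs[s] for s in stages])
    clinical = pd.DataFrame(
        {
            "case_id": incidence.index,
            "histology": config.histology,
            "stage": np.array(stages, dtype=object)[rng.choice(len(stages), size=config.n_cases, p=stage_p)],
        }
    )
    truth = GroundTruth(incidence=incidence, planted_pairs=list(config.exclusive_pairs))
    return truth, tables, clinical


def simulate_expression(
    truth: GroundTruth,
    target_genes: list[str],
    control_genes: list[str],
    effect: float,
    noise_sd: float,
    seed: int,
    drivers: tuple[str, str] | None = None,
    baseline: float = 10.0,
) -> pd.DataFrame:
    """Expression matrix (genes x cases) with planted coordinate downregulation.

    Target genes are scaled by ``(1 - effect)`` in cases carrying a true
    mutation in either driver (default: the first planted exclusive pair)
    before Gaussian noise of SD ``noise_sd`` is added; control genes keep the
    baseline in every case.
    """
    if set(target_genes) & set(control_genes):
        raise ValueError("target and control gene lists must be disjoint")
    if not 0.0 <= effect < 1.0:
        raise ValueError(f"effect must be in [0, 1), got {effect}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if drivers is None:
        if not truth.planted_pairs:
            raise ValueError("no planted pairs to use as drivers; pass drivers explicitly")
        drivers = (truth.planted_pairs[0][0], truth.planted_pairs[0][1])
    a, b = drivers
    carrier = (truth.incidence[a].to_numpy(bool)) | (truth.incidence[b].to_numpy(bool))
    rng = np.random.default_rng(seed)
    genes = list(target_genes) + list(control_genes)
    values = np.full((len(genes), len(truth.case_ids)), baseline, dtype=float)
    values[: len(target_genes), carrier] *= 1.0 - effect
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    return pd.DataFrame(values, index=genes, columns=truth.case_ids)


def write_cohort(
    tables: dict[str, pd.DataFrame],
    clinical: pd.DataFrame,
    outdir,
    sample_suffix: str = "-01A",
) -> dict[str, str]:
    """Write per-pipeline MAF-dialect TSVs and the clinical TSV.

    MAF files carry sample-level barcodes (case barcode + ``sample_suffix``),
    mirroring the convention of real mutation annotation files; readers
    truncate back to the case level.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for name, table in tables.items():
        maf = pd.DataFrame(
            {
                "Hugo_Symbol": table["gene"],
                "Tumor_Sample_Barcode": table["case_id"] + sample_suffix,
                "Chromosome": table["chromosome"],
                "Start_Position": table["start"],
                "Reference_Allele": table["ref_allele"],
                "Tumor_Seq_Allele2": table["alt_allele"],
                "IMPACT": table["impact"],
            }
        )
        path = outdir / f"{name}.maf.tsv"
        maf.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)
    clin_path = outdir / "clinical.tsv"
    clinical.to_csv(clin_path, sep="\t", index=False)
    paths["clinical"] = str(clin_path)
    return paths
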