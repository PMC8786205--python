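"""MAF ingestion, barcode/stage normalisation, cohort and impact filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutexsig.maf_io import (
    filter_cohort,
    filter_impact,
    normalize_case_id,
    normalize_stage,
    read_clinical,
    read_gene_list,
    read_maf,
)
from conftest import make_records

MAF_HEADER = [
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "IMPACT",
]


def write_maf(tmp_path, rows, header=MAF_HEADER, name="calls.maf.tsv"):
    path = tmp_path / name
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)
    return path


class TestReadMaf:
    def test_reads_one_record_per_valid_row(self, tmp_path):
        rows = [
            ["TP53", "TCGA-AA-0001-01A", "chr17", 7577, "C", "T", "HIGH"],
            ["RB1", "TCGA-AA-0002-01A", "chr13", 48878, "G", "A", "MODERATE"],
            ["KDM6A", "TCGA-AA-0001-01A", "chrX", 44873, "A", "G", "HIGH"],
        ]
        records = read_maf(write_maf(tmp_path, rows), "mutect2")
        assert len(records) == 3
        assert set(records["pipeline"]) == {"mutect2"}

    def test_missing_required_column_is_named(self, tmp_path):
        header = [c for c in MAF_HEADER if c != "Tumor_Sample_Barcode"]
        path = write_maf(tmp_path, [["TP53", "chr17", 7577, "C", "T", "HIGH"]], header=header)
        with pytest.raises(ValueError, match="tumor_sample_barcode"):
            read_maf(path, "mutect2")

    def test_impact_vocabulary_is_case_insensitive(self, tmp_path):
        rows = [["TP53", "TCGA-AA-0001-01A", "chr17", 7577, "C", "T", "modifier"]]
        records = read_maf(write_maf(tmp_path, rows), "muse")
        assert records.loc[0, "impact"] == "MODIFIER"

    def test_header_match_is_case_insensitive(self, tmp_path):
        header = [c.upper() for c in MAF_HEADER]
        rows = [["TP53", "TCGA-AA-0001-01A", "chr17", 7577, "C", "T", "HIGH"]]
        records = read_maf(write_maf(tmp_path, rows, header=header), "muse")
        assert len(records) == 1

    def test_rows_missing_gene_or_case_are_dropped(self, tmp_path):
        rows = [
            ["TP53", "TCGA-AA-0001-01A", "chr17", 7577, "C", "T", "HIGH"],
            ["", "TCGA-AA-0002-01A", "chr13", 48878, "G", "A", "HIGH"],
            ["RB1", "", "chr13", 48878, "G", "A", "HIGH"],
        ]
        records = read_maf(write_maf(tmp_path, rows), "muse")
        assert len(records) == 1

    def test_sample_barcodes_truncate_to_case_level(self, tmp_path):
        rows = [["KDM6A", "TCGA-XF-A9SL-01A-11D-A391-08", "chrX", 44873, "A", "G", "HIGH"]]
        records = read_maf(write_maf(tmp_path, rows), "muse")
        assert records.loc[0, "case_id"] == "TCGA-XF-A9SL"


@pytest.mark.parametrize(
    "barcode, expected",
    [
        ("TCGA-XF-A9SL-01A-11D-A391-08", "TCGA-XF-A9SL"),
        ("TCGA-XF-A9SL", "TCGA-XF-A9SL"),
        ("SAMPLE-123-LONG-IDENTIFIER", "SAMPLE-123-LONG-IDENTIFIER"),
    ],
)
def test_case_id_normalisation(barcode, expected):
    assert normalize_case_id(barcode) == expected


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Stage II", "ii"), ("stage ii", "ii"), ("2", "ii"), ("III", "iii"),
        ("stage 4", "iv"), ("iv", "iv"), ("Stage I", "other"), ("x", "other"),
    ],
)
def test_stage_normalisation(raw, expected):
    assert normalize_stage(raw) == expected


@pytest.fixture
def clinical():
    return pd.DataFrame(
        {
            "case_id": ["TCGA-AA-0001", "TCGA-AA-0002", "TCGA-AA-0003"],
            "histology": ["muscle invasive urothelial carcinoma"] * 3,
            "stage": ["ii", "iii", "i"],
        }
    )


@pytest.fixture
def mixed_records():
    # cases: 0001 (stage ii, eligible), 0002 (stage iii, eligible),
    # 0003 (stage i), 0004 (absent from the clinical table)
    return make_records(
        [
            ("TCGA-AA-0001", "TP53", "chr17", 1, "C", "T", "HIGH"),
            ("TCGA-AA-0002", "RB1", "chr13", 2, "G", "A", "HIGH"),
            ("TCGA-AA-0002", "KDM6A", "chrX", 3, "A", "G", "MODERATE"),
            ("TCGA-AA-0003", "TP53", "chr17", 4, "C", "T", "HIGH"),
            ("TCGA-AA-0004", "TP53", "chr17", 5, "C", "T", "HIGH"),
        ]
    )


class TestFilterCohort:
    def test_stage_i_case_removed(self, mixed_records, clinical):
        kept = filter_cohort(mixed_records, clinical)
        assert "TCGA-AA-0003" not in set(kept["case_id"])

    def test_case_absent_from_clinical_removed(self, mixed_records, clinical):
        kept = filter_cohort(mixed_records, clinical)
        assert "TCGA-AA-0004" not in set(kept["case_id"])

    def test_only_eligible_cases_remain(self, mixed_records, clinical):
        kept = filter_cohort(mixed_records, clinical)
        assert set(kept["case_id"]) == {"TCGA-AA-0001", "TCGA-AA-0002"}
        assert len(kept) == 3

    def test_histology_mismatch_removes_case(self, mixed_records, clinical):
        clinical = clinical.copy()
        clinical.loc[0, "histology"] = "papillary"
        kept = filter_cohort(mixed_records, clinical)
        assert "TCGA-AA-0001" not in set(kept["case_id"])


class TestFilterImpact:
    def test_low_removed_when_only_high_moderate_allowed(self):
        records = make_records([("c1", "G", "chr1", 1, "A", "T", "LOW")])
        assert len(filter_impact(records, {"HIGH", "MODERATE"})) == 0

    def test_all_levels_allowed_is_identity(self, mixed_records):
        out = filter_impact(mixed_records, {"HIGH", "MODERATE", "LOW", "MODIFIER"})
        pd.testing.assert_frame_equal(out, mixed_records)

    def test_counts_by_hand(self):
        records = make_records(
            [
                ("c1", "G1", "chr1", 1, "A", "T", "HIGH"),
                ("c2", "G1", "chr1", 1, "A", "T", "HIGH"),
                ("c3", "G2", "chr2", 2, "A", "T", "MODERATE"),
                ("c4", "G2", "chr2", 2, "A", "T", "MODIFIER"),
            ]
        )
        assert len(filter_impact(records, {"HIGH"})) == 2

    def test_empty_allowed_set_rejected(self, mixed_records):
        with pytest.raises(ValueError, match="empty"):
            filter_impact(mixed_records, set())


@st.composite
def record_tables(draw):
    n = draw(st.integers(0, 20))
    rows = []
    for i in range(n):
        case = draw(st.sampled_from(["TCGA-AA-0001", "TCGA-AA-0002", "TCGA-AA-0003", "TCGA-AA-0009"]))
        impact = draw(st.sampled_from(["HIGH", "MODERATE", "LOW", "MODIFIER"]))
        rows.append((case, f"G{i % 4}", "chr1", i + 1, "A", "T", impact))
    return make_records(rows)


@given(records=record_tables(), allowed=st.sets(st.sampled_from(["HIGH", "MODERATE", "LOW"]), min_size=1))
@settings(max_examples=50, deadline=None)
def test_filters_commute_and_are_idempotent(records, allowed):
    clinical = pd.DataFrame(
        {
            "case_id": ["TCGA-AA-0001", "TCGA-AA-0002", "TCGA-AA-0003"],
            "histology": ["muscle invasive urothelial carcinoma"] * 3,
            "stage": ["ii", "iii", "i"],
        }
    )
    a = filter_impact(filter_cohort(records, clinical), allowed)
    b = filter_cohort(filter_impact(records, allowed), clinical)
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))
    pd.testing.assert_frame_equal(filter_impact(a, allowed), a)
    pd.testing.assert_frame_equal(filter_cohort(a, clinical), a)


def test_read_clinical_normalises_and_rejects_duplicates(tmp_path):
    path = tmp_path / "clinical.tsv"
    pd.DataFrame(
        {
            "Case_ID": ["TCGA-AA-0001-01A", "TCGA-AA-0002"],
            "Histology": ["muscle invasive urothelial carcinoma"] * 2,
            "Stage": ["Stage II", "4"],
        }
    ).to_csv(path, sep="\t", index=False)
    clin = read_clinical(path)
    assert list(clin["case_id"]) == ["TCGA-AA-0001", "TCGA-AA-0002"]
    assert list(clin["stage"]) == ["ii", "iv"]

    dup = tmp_path / "dup.tsv"
    pd.DataFrame(
        {"case_id": ["TCGA-AA-0001"] * 2, "histology": ["x"] * 2, "stage": ["ii"] * 2}
    ).to_csv(dup, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_clinical(dup)


def test_read_gene_list_supports_classes_and_bare_symbols(tmp_path):
    path = tmp_path / "genes.txt"
    path.write_text("# panel\nTP53\tboth\nKDM6A\tCM\nRB1\n")
    assert read_gene_list(path) == {"TP53": "both", "KDM6A": "CM", "RB1": ""}
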