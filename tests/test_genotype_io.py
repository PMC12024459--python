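"""PLINK/VCF reading, writing and quality-control filtering."""

import numpy as np
import pytest

from condiv import (
    MISSING,
    GenotypePanel,
    SampleRecord,
    VariantRecord,
    apply_qc,
    make_toy_panel,
    read_plink,
    reader_oriented,
    simulate_panel,
    write_plink,
)
from condiv.genotype_io import FormatError, read_breed_table, read_vcf_with_stats
from condiv.synthetic_data import SimulationConfig


def write_toy_vcf(panel, path, extra_records=()):
    gtmap = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted({v.chromosome for v in panel.variants}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(s.sample_id for s in panel.samples)
            + "\n"
        )
        for j, v in enumerate(panel.variants):
            gts = "\t".join(gtmap[int(g)] for g in panel.calls[:, j])
            fh.write(
                f"{v.chromosome}\t{v.position_bp}\t{v.snp_id}\t{v.allele_a}\t"
                f"{v.allele_b}\t.\tPASS\t.\tGT\t{gts}\n"
            )
        for rec in extra_records:
            fh.write(rec + "\n")


# ----------------------------------------------------------------------
# PLINK round trips
# ----------------------------------------------------------------------

def test_plink_round_trip_toy(tmp_path, toy_panel):
    oriented = reader_oriented(toy_panel)
    write_plink(oriented, tmp_path / "p.ped", tmp_path / "p.map")
    # PED stores no FAO class/origin; supply them through the breed table
    back = read_plink(
        tmp_path / "p.ped",
        tmp_path / "p.map",
        {s.sample_id: s for s in oriented.samples},
    )
    assert back == oriented


def test_plink_round_trip_simulated(tmp_path):
    panel, _ = simulate_panel(
        SimulationConfig(n_breeds=3, samples_per_breed=5, n_snps=40, seed=5, missing_rate=0.1)
    )
    oriented = reader_oriented(panel)
    write_plink(oriented, tmp_path / "p.ped", tmp_path / "p.map")
    back = read_plink(tmp_path / "p.ped", tmp_path / "p.map")
    assert np.array_equal(back.calls, oriented.calls)
    assert [s.breed_code for s in back.samples] == [s.breed_code for s in oriented.samples]


def test_missing_genotype_round_trips_as_missing(tmp_path, toy_panel):
    write_plink(toy_panel, tmp_path / "p.ped", tmp_path / "p.map")
    line = (tmp_path / "p.ped").read_text().splitlines()[3]  # RED_4 has a missing call
    assert line.split()[-2:] == ["0", "0"]
    back = read_plink(tmp_path / "p.ped", tmp_path / "p.map")
    assert back.calls[3, 5] == MISSING


def test_read_plink_codes_against_first_observed_allele(tmp_path):
    (tmp_path / "t.map").write_text("1 v1 0 100\n1 v2 0 200\n")
    (tmp_path / "t.ped").write_text(
        "F1 s1 0 0 0 -9 G G A C\n"
        "F1 s2 0 0 0 -9 G T C C\n"
    )
    panel = read_plink(tmp_path / "t.ped", tmp_path / "t.map")
    v1, v2 = panel.variants
    assert (v1.allele_a, v1.allele_b) == ("G", "T")
    assert (v2.allele_a, v2.allele_b) == ("A", "C")
    assert panel.calls.tolist() == [[0, 1], [1, 2]]


def test_one_sample_one_variant_ped_has_eight_fields(tmp_path):
    panel = GenotypePanel(
        [SampleRecord("s1", "X")],
        [VariantRecord("v1", "1", 10, "A", "G")],
        np.array([[1]], dtype=np.int8),
    )
    write_plink(panel, tmp_path / "p.ped", tmp_path / "p.map")
    fields = (tmp_path / "p.ped").read_text().split()
    assert len(fields) == 8


def test_write_empty_panel_raises(tmp_path):
    panel = GenotypePanel([SampleRecord("s1", "X")], [], np.empty((1, 0), dtype=np.int8))
    with pytest.raises(ValueError):
        write_plink(panel, tmp_path / "p.ped", tmp_path / "p.map")


@pytest.mark.parametrize(
    "ped_text",
    [
        "F1 s1 0 0 0 -9 A Z\n",  # bad allele character
        "F1 s1 0 0 0 -9 A\n",  # row length inconsistent with MAP
        "F1 s1 0 0 0 -9 A 0\n",  # half-missing genotype
    ],
)
def test_malformed_ped_raises(tmp_path, ped_text):
    (tmp_path / "t.map").write_text("1 v1 0 100\n")
    (tmp_path / "t.ped").write_text(ped_text)
    with pytest.raises(FormatError):
        read_plink(tmp_path / "t.ped", tmp_path / "t.map")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def test_vcf_matches_plink_encoding(tmp_path, toy_panel):
    """The same cohort read from VCF and from PED/MAP yields identical calls."""
    write_toy_vcf(toy_panel, tmp_path / "t.vcf")
    table = {s.sample_id: s for s in toy_panel.samples}
    vcf_panel, stats = read_vcf_with_stats(tmp_path / "t.vcf", table)
    assert np.array_equal(vcf_panel.calls, toy_panel.calls)
    assert stats.n_multiallelic == 0

    oriented = reader_oriented(toy_panel)
    write_plink(oriented, tmp_path / "t.ped", tmp_path / "t.map")
    plink_panel = read_plink(tmp_path / "t.ped", tmp_path / "t.map")
    assert np.array_equal(reader_oriented(vcf_panel).calls, plink_panel.calls)


def test_vcf_multiallelic_skipped_and_counted(tmp_path, toy_panel):
    n = toy_panel.n_samples
    rec = "2\t400\tmulti\tA\tC,G\t.\tPASS\t.\tGT\t" + "\t".join(["0/1"] * n)
    write_toy_vcf(toy_panel, tmp_path / "t.vcf", extra_records=[rec])
    table = {s.sample_id: s for s in toy_panel.samples}
    panel, stats = read_vcf_with_stats(tmp_path / "t.vcf", table)
    assert stats.n_multiallelic == 1
    assert panel.n_variants == toy_panel.n_variants


def test_vcf_unknown_sample_raises(tmp_path, toy_panel):
    write_toy_vcf(toy_panel, tmp_path / "t.vcf")
    table = {s.sample_id: s for s in toy_panel.samples if s.sample_id != "GRN_4"}
    with pytest.raises(ValueError, match="GRN_4"):
        read_vcf_with_stats(tmp_path / "t.vcf", table)


def test_breed_table_parsing(tmp_path):
    (tmp_path / "b.tsv").write_text(
        "sample_id\tbreed_code\tfao_class\torigin\n"
        "s1\tRED\tnative\tgovernment\n"
        "s2\tBLU\tNA\tNA\n"
    )
    table = read_breed_table(tmp_path / "b.tsv")
    assert table["s1"].fao_class == "native"
    assert table["s2"].fao_class is None and table["s2"].origin is None


# ----------------------------------------------------------------------
# quality control
# ----------------------------------------------------------------------

def _panel_with_column(cols, chroms=None):
    """Panel with one breed and explicit genotype columns (lists over samples)."""
    n = len(cols[0])
    chroms = chroms or ["1"] * len(cols)
    pos = {}
    variants = []
    for j, c in enumerate(chroms):
        pos[c] = pos.get(c, 0) + 100
        variants.append(VariantRecord(f"v{j}", c, pos[c], "A", "G"))
    samples = [SampleRecord(f"s{i}", "X") for i in range(n)]
    return GenotypePanel(samples, variants, np.array(cols, dtype=np.int8).T)


def test_qc_missingness_boundary_is_strict():
    """With 20 samples, 2 missing calls (10%) is removed, 1 (5%) is kept."""
    col_keep = [1] * 19 + [MISSING]
    col_drop = [1] * 18 + [MISSING, MISSING]
    panel = _panel_with_column([col_keep, col_drop])
    filtered, report = apply_qc(panel)
    assert [v.snp_id for v in filtered.variants] == ["v0"]
    assert report.n_removed_missingness == 1


def test_qc_maf_boundary_is_strict():
    """Pooled MAF exactly at the threshold is removed; above it is kept."""
    col_at = [1] + [0] * 9  # 10 samples, 20 copies: p = 1/20 = 0.05, removed
    col_ok = [1, 1] + [0] * 8  # p = 2/20 = 0.10, kept
    panel = _panel_with_column([col_at, col_ok])
    filtered, report = apply_qc(panel)
    assert [v.snp_id for v in filtered.variants] == ["v1"]
    assert report.n_removed_maf == 1


def test_qc_excludes_sex_chromosomes():
    cols = [[0, 1, 1, 2]] * 7
    panel = _panel_with_column(cols, chroms=["1", "2", "3", "4", "5", "Z", "W"])
    filtered, report = apply_qc(panel)
    assert report.n_removed_nonautosomal == 2
    assert report.n_retained == 5
    assert {v.chromosome for v in filtered.variants} <= {"1", "2", "3", "4", "5"}


def test_qc_counts_conserved_and_idempotent():
    panel, _ = simulate_panel(
        SimulationConfig(
            n_breeds=4, samples_per_breed=10, n_snps=200, seed=9,
            missing_rate=0.08, ancestral_freq_law=("uniform", 0.01, 0.99),
        )
    )
    filtered, report = apply_qc(panel)
    assert (
        report.n_retained
        + report.n_removed_nonautosomal
        + report.n_removed_missingness
        + report.n_removed_maf
        == report.n_input_variants
    )
    again, report2 = apply_qc(filtered)
    assert again == filtered
    assert report2.n_retained == report2.n_input_variants


def test_qc_all_removed_raises(toy_panel):
    with pytest.raises(ValueError, match="threshold"):
        apply_qc(toy_panel, min_maf=0.5, autosome_labels={"1", "2"})
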