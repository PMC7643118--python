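"""I/O layer: VCF round trips, breakend typing, TSV tables, the pipeline
manifest contract, and CLI smoke tests."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from hrdscar import (
    CopyNumberSegment,
    FastaReferenceStore,
    SampleInput,
    SmallVariant,
    StructuralVariant,
    extract_profile,
    make_fixture_genome,
    plant_variants,
    read_copynumber_tsv,
    read_profile_tsv,
    read_small_variant_vcf,
    read_sv_vcf,
    run_pipeline,
    simulate_cohort,
    write_copynumber_tsv,
    write_genome_fasta,
    write_profile_tsv,
    write_small_variant_vcf,
    write_sv_vcf,
)
from hrdscar.cli import main as cli_main

CONTIGS = {"chr1": 10_000}


@pytest.fixture(scope="module")
def fasta_path(tmp_path_factory):
    genome = make_fixture_genome(10_000, gc=0.41, seed=42)
    return write_genome_fasta(genome, tmp_path_factory.mktemp("ref") / "ref.fa")


# ---------------------------------------------------------------------------
# Small-variant VCF
# ---------------------------------------------------------------------------


def test_small_variant_vcf_round_trip(tmp_path):
    variants = [
        SmallVariant("chr1", 100, "A", "T"),
        SmallVariant("chr1", 200, "CTT", "C"),
        SmallVariant("chr1", 300, "G", "GACA"),
    ]
    path = tmp_path / "x.vcf"
    write_small_variant_vcf(variants, path, CONTIGS)
    back, n_skipped = read_small_variant_vcf(path)
    assert n_skipped == 0
    assert [(v.chrom, v.pos, v.ref, v.alt) for v in back] == [
        (v.chrom, v.pos, v.ref, v.alt) for v in variants
    ]


def test_multiallelic_record_decomposed(tmp_path):
    path = tmp_path / "ma.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=10000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t500\t.\tA\tT,G\t.\t.\t.\n"
    )
    back, n_skipped = read_small_variant_vcf(path)
    assert n_skipped == 0
    assert [(v.pos, v.alt) for v in back] == [(500, "T"), (500, "G")]


def test_malformed_allele_skipped_not_fatal(tmp_path):
    path = tmp_path / "bad.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=10000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t500\t.\tA\t<INS>\t.\t.\t.\n"
        "chr1\t600\t.\tA\tT\t.\t.\t.\n"
    )
    back, n_skipped = read_small_variant_vcf(path)
    assert n_skipped == 1
    assert [(v.pos, v.alt) for v in back] == [(600, "T")]


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------


def test_symbolic_sv_round_trip(tmp_path):
    svs = [
        StructuralVariant("DEL", 5_000),
        StructuralVariant("DUP", 50_000),
        StructuralVariant("INV", 2_000_000),
        StructuralVariant("TRA"),
    ]
    path = tmp_path / "sv.vcf"
    write_sv_vcf(svs, path)
    back, n_skipped = read_sv_vcf(path)
    assert n_skipped == 0
    assert sorted((s.sv_type, s.length) for s in back) == sorted(
        (s.sv_type, s.length) for s in svs
    )


def _bnd_vcf(tmp_path, records):
    path = tmp_path / "bnd.vcf"
    body = "".join(
        f"chr{c}\t{p}\t{i}\tN\t{alt}\t.\t.\tSVTYPE=BND\n"
        for c, p, i, alt in records
    )
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=300000000>\n'
        '##contig=<ID=chr2,length=300000000>\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n" + body
    )
    return path


@pytest.mark.parametrize(
    "alt_low, alt_high, expected",
    [
        ("N[chr1:15000[", "]chr1:10000]N", "DEL"),  # rightward join
        ("]chr1:15000]N", "N[chr1:10000[", "DUP"),  # leftward join
        ("N]chr1:15000]", "N]chr1:10000]", "INV"),  # mixed orientation
    ],
)
def test_bnd_pair_typed_by_orientation(tmp_path, alt_low, alt_high, expected):
    path = _bnd_vcf(
        tmp_path,
        [(1, 10_000, "a", alt_low), (1, 15_000, "b", alt_high)],
    )
    back, n_skipped = read_sv_vcf(path)
    assert n_skipped == 0
    assert len(back) == 1
    assert back[0].sv_type == expected
    assert back[0].length == 5_000


def test_interchromosomal_bnd_is_translocation(tmp_path):
    path = _bnd_vcf(
        tmp_path,
        [(1, 10_000, "a", "N[chr2:20000["), (2, 20_000, "b", "]chr1:10000]N")],
    )
    back, n_skipped = read_sv_vcf(path)
    assert n_skipped == 0
    assert [s.sv_type for s in back] == ["TRA"]


def test_sv_without_length_info_skipped(tmp_path):
    path = tmp_path / "nolen.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=300000000>\n'
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t10000\t.\tN\t<DEL>\t.\t.\tSVTYPE=DEL\n"
    )
    back, n_skipped = read_sv_vcf(path)
    assert back == [] and n_skipped == 1


# ---------------------------------------------------------------------------
# FASTA store and TSV tables
# ---------------------------------------------------------------------------


def test_fasta_store_matches_in_memory_genome(fasta_path):
    genome = make_fixture_genome(10_000, gc=0.41, seed=42)
    store = FastaReferenceStore(fasta_path)
    for start, end in [(0, 10), (995, 1005), (9_990, 10_000)]:
        assert store.substring("chr1", start, end) == genome.substring(
            "chr1", start, end
        )
    assert store.substring("chr1", -5, 3) == genome.substring("chr1", -5, 3)


def test_copynumber_tsv_round_trip(tmp_path):
    segs = [
        CopyNumberSegment("chr13", 0, 1_000, 2.0, 1.0),
        CopyNumberSegment("chr13", 1_000, 2_000, 0.1, 0.0),
    ]
    path = tmp_path / "cn.tsv"
    write_copynumber_tsv(segs, path)
    assert read_copynumber_tsv(path) == segs


def test_copynumber_tsv_missing_column_errors(tmp_path):
    path = tmp_path / "cn.tsv"
    path.write_text("chrom\tstart\tend\ttotal_cn\nchr1\t0\t10\t2.0\n")
    with pytest.raises(ValueError, match="minor_cn"):
        read_copynumber_tsv(path)


def test_profile_tsv_round_trip(tmp_path):
    _, _, profiles = simulate_cohort(1, 1, 1, seed=2, return_profiles=True)
    path = tmp_path / "profiles.tsv"
    write_profile_tsv(profiles, path)
    back = read_profile_tsv(path)
    assert set(back) == set(profiles)
    for name in profiles:
        assert back[name].counts == profiles[name].counts


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _write_sample(tmp_path, fasta_path, name, seed):
    genome = make_fixture_genome(10_000, gc=0.41, seed=42)
    spec = {"A[C>T]G": 3, "del.mh.bimh.2": 2, "DEL_1e03_1e04_bp": 2, "TRA": 1}
    small, svs, _ = plant_variants(genome, spec, seed=seed)
    vcf = tmp_path / f"{name}.vcf"
    sv_vcf = tmp_path / f"{name}.sv.vcf"
    write_small_variant_vcf(small, vcf, CONTIGS)
    write_sv_vcf(svs, sv_vcf)
    return SampleInput(name, str(vcf), str(sv_vcf)), spec


def test_pipeline_outputs_and_manifest(tmp_path, fasta_path):
    sample, spec = _write_sample(tmp_path, fasta_path, "s1", seed=1)
    out = tmp_path / "run"
    manifest = run_pipeline([sample], fasta_path, out, seed=7)
    assert (out / "profiles.tsv").exists() and (out / "features.tsv").exists()
    assert manifest["seed"] == 7
    assert manifest["skipped_records"] == {"s1": 0}
    assert json.loads((out / "manifest.json").read_text()) == manifest
    profile = read_profile_tsv(out / "profiles.tsv")["s1"]
    for key, want in spec.items():
        assert profile.counts[key] == want
    features = pd.read_csv(out / "features.tsv", sep="\t", index_col=0)
    assert features.shape == (1, 29)


def test_pipeline_rerun_is_byte_identical(tmp_path, fasta_path):
    sample, _ = _write_sample(tmp_path, fasta_path, "s1", seed=3)
    out1, out2 = tmp_path / "run1", tmp_path / "run2"
    run_pipeline([sample], fasta_path, out1, seed=0)
    run_pipeline([sample], fasta_path, out2, seed=0)
    for fname in ["profiles.tsv", "features.tsv", "manifest.json"]:
        assert (out1 / fname).read_bytes() == (out2 / fname).read_bytes()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def test_cli_extract_and_features(tmp_path, fasta_path):
    sample, _ = _write_sample(tmp_path, fasta_path, "s1", seed=5)
    runner = CliRunner()
    prof_out = tmp_path / "p.tsv"
    res = runner.invoke(
        cli_main,
        ["extract", "--vcf", sample.vcf, "--sv-vcf", sample.sv_vcf,
         "--ref", str(fasta_path), "--sample", "s1", "--out", str(prof_out)],
    )
    assert res.exit_code == 0, res.output
    feat_out = tmp_path / "f.tsv"
    res = runner.invoke(
        cli_main,
        ["features", "--profiles", str(prof_out), "--out", str(feat_out)],
    )
    assert res.exit_code == 0, res.output
    assert pd.read_csv(feat_out, sep="\t", index_col=0).shape == (1, 29)


def test_cli_simulate_train_predict(tmp_path):
    runner = CliRunner()
    prefix = str(tmp_path / "cohort")
    res = runner.invoke(
        cli_main,
        ["simulate", "--n-b1", "8", "--n-b2", "8", "--n-none", "30",
         "--seed", "4", "--out-prefix", prefix],
    )
    assert res.exit_code == 0, res.output
    model_path = str(tmp_path / "model.joblib")
    res = runner.invoke(
        cli_main,
        ["train", "--features", f"{prefix}.features.tsv",
         "--labels", f"{prefix}.labels.tsv", "--seed", "4", "--core",
         "--out", model_path],
    )
    assert res.exit_code == 0, res.output
    pred_path = str(tmp_path / "pred.tsv")
    res = runner.invoke(
        cli_main,
        ["predict", "--model", model_path,
         "--features", f"{prefix}.features.tsv", "--out", pred_path],
    )
    assert res.exit_code == 0, res.output
    preds = pd.read_csv(pred_path, sep="\t", index_col=0)
    assert {"p_hrd", "hr_status", "hrd_type"} <= set(preds.columns)
    assert len(preds) == 46


def test_cli_biallelic_enrich_cluster(tmp_path):
    runner = CliRunner()
    genes = tmp_path / "genes.tsv"
    genes.write_text(
        "chrom\tstart\tend\tgene\n"
        "chr13\t32315000\t32400000\tBRCA2\n"
        "chr17\t43044000\t43170000\tBRCA1\n"
    )
    cn = tmp_path / "cn.tsv"
    write_copynumber_tsv(
        [
            CopyNumberSegment("chr13", 32_000_000, 33_000_000, 0.1, 0.0),
            CopyNumberSegment("chr17", 43_000_000, 44_000_000, 2.0, 1.0),
        ],
        cn,
    )
    bi_out = tmp_path / "bi.tsv"
    res = runner.invoke(
        cli_main,
        ["biallelic", "--genes", str(genes), "--copynumber", str(cn),
         "--sample", "s0", "--out", str(bi_out)],
    )
    assert res.exit_code == 0, res.output
    bi = pd.read_csv(bi_out, sep="\t").set_index("gene")
    assert bool(bi.loc["BRCA2", "deficient"]) is True
    assert bool(bi.loc["BRCA1", "deficient"]) is False

    defic = tmp_path / "defic.tsv"
    pd.DataFrame(
        {"BRCA2": [1, 1, 0, 0]}, index=[f"s{i}" for i in range(4)]
    ).rename_axis("sample").to_csv(defic, sep="\t")
    calls = tmp_path / "calls.tsv"
    pd.Series(
        ["HRD", "HRD", "HRP", "HRP"],
        index=[f"s{i}" for i in range(4)], name="hr_status",
    ).rename_axis("sample").to_csv(calls, sep="\t")
    enrich_out = tmp_path / "enrich.tsv"
    res = runner.invoke(
        cli_main,
        ["enrich", "--deficiency", str(defic), "--hrd-calls", str(calls),
         "--out", str(enrich_out)],
    )
    assert res.exit_code == 0, res.output
    enr = pd.read_csv(enrich_out, sep="\t", index_col=0)
    assert enr.loc["BRCA2", "n_hrd_deficient"] == 2

    preds = tmp_path / "preds.tsv"
    pd.DataFrame(
        {
            "hr_status": ["HRD", "HRD", "HRP"],
            "hrd_type": ["BRCA2-type", "BRCA1-type", "none"],
        },
        index=["s0", "s1", "s2"],
    ).rename_axis("sample").to_csv(preds, sep="\t")
    gc = tmp_path / "gene_calls.tsv"
    pd.DataFrame(
        [
            {"sample": "s0", "gene": "BRCA2", "bp_score": 10, "p_a": 5,
             "p_b": 5, "deep_deletion": True, "loh": False,
             "frameshift": False, "max_variant_p": 0},
            {"sample": "s1", "gene": "BRCA1", "bp_score": 10, "p_a": 5,
             "p_b": 5, "deep_deletion": False, "loh": True,
             "frameshift": True, "max_variant_p": 5},
        ]
    ).to_csv(gc, sep="\t", index=False)
    cl_out = tmp_path / "clusters.tsv"
    res = runner.invoke(
        cli_main,
        ["cluster", "--predictions", str(preds), "--gene-calls", str(gc),
         "--out", str(cl_out)],
    )
    assert res.exit_code == 0, res.output
    cl = pd.read_csv(cl_out, sep="\t")
    assert list(cl["sample"]) == ["s0", "s1"]  # BRCA2-type first
    assert list(cl["gene"]) == ["BRCA2", "BRCA1"]
    assert list(cl["cluster_id"]) == [1, 2]
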