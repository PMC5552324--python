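"""Unit and property tests for variant normalization, matching and readers."""

from __future__ import annotations

import numpy as np
import pytest

from deepintron.errors import (
    ContractViolationError,
    ReferenceMismatchError,
    StructuralError,
    VcfParseError,
)
from deepintron.variant_model import (
    CallerObservation,
    GenomicVariant,
    Genotype,
    ReferenceContext,
    is_normalized,
    normalize_chrom,
    normalize_variant,
    read_caller_vcf,
    read_pedigree,
    same_variant,
    write_observations_vcf,
)
from conftest import random_indel_in_context
from oracles import enumerate_equivalent_spellings, oracle_normalize


class TestGenomicVariant:
    def test_valid_construction(self):
        v = GenomicVariant("1", 100, "A", "G", id="rs1")
        assert v.key == ("1", 100, "A", "G")
        assert v.is_snv

    @pytest.mark.parametrize(
        "ref,alt",
        [("A", "A"), ("", "G"), ("A", ""), ("N", "G"), ("A", "g"), ("A-", "G")],
    )
    def test_invalid_alleles_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            GenomicVariant("1", 100, ref, alt)

    def test_position_must_be_positive(self):
        with pytest.raises(ValueError):
            GenomicVariant("1", 0, "A", "G")

    def test_id_and_hgvs_do_not_affect_identity(self):
        a = GenomicVariant("1", 5, "A", "G", id="rs1", hgvs="c.1A>G")
        b = GenomicVariant("1", 5, "A", "G")
        assert a == b


class TestNormalization:
    def test_snv_unchanged(self, context_factory):
        ctx = context_factory("GGATG")
        v = GenomicVariant("ctg", 3, "A", "G")
        assert normalize_variant(v, ctx) == v

    def test_ref_mismatch_raises(self, context_factory):
        ctx = context_factory("GGATG")
        with pytest.raises(ReferenceMismatchError):
            normalize_variant(GenomicVariant("ctg", 3, "C", "G"), ctx)

    def test_chrom_mismatch_raises(self, context_factory):
        ctx = context_factory("GGATG", chrom="other")
        with pytest.raises(ReferenceMismatchError):
            normalize_variant(GenomicVariant("ctg", 3, "A", "G"), ctx)

    def test_homopolymer_deletion_left_aligned(self, context_factory):
        # deletion of one T placed mid-run in GTTTTC: canonical spelling
        # anchors at the G preceding the run
        seq = "GTTTTC"
        ctx = context_factory(seq)
        mid = GenomicVariant("ctg", 3, "TT", "T")
        result = normalize_variant(mid, ctx)
        expected_pos, expected_ref, expected_alt = oracle_normalize(seq, 3, "TT", "T")
        assert (result.pos, result.ref, result.alt) == (expected_pos, expected_ref, expected_alt)
        assert result.pos == 1  # leftmost anchor of the T run

    def test_trailing_base_trimmed(self, context_factory):
        ctx = context_factory("GACTG")
        v = GenomicVariant("ctg", 2, "ACT", "AT")
        result = normalize_variant(v, ctx)
        assert (result.pos, result.ref, result.alt) == oracle_normalize("GACTG", 2, "ACT", "AT")

    def test_equivalence_classes_collapse(self, rng):
        """All enumerable equivalent spellings of a random indel normalize
        to one identical tuple (exhaustive-equivalence oracle)."""
        for _ in range(150):
            seq, v = random_indel_in_context(rng)
            ctx = ReferenceContext("ctg", 1, seq)
            spellings = enumerate_equivalent_spellings(seq, v.pos, v.ref, v.alt)
            normalized = {
                normalize_variant(GenomicVariant("ctg", p, r, a), ctx).key
                for p, r, a in spellings
            }
            assert len(normalized) == 1
            expected = oracle_normalize(seq, v.pos, v.ref, v.alt)
            assert normalized == {("ctg", *expected)}

    def test_idempotence_on_random_indels(self, rng):
        for _ in range(1000):
            seq, v = random_indel_in_context(rng)
            ctx = ReferenceContext("ctg", 1, seq)
            once = normalize_variant(v, ctx)
            twice = normalize_variant(once, ctx)
            assert once == twice


class TestSameVariant:
    def test_identical_tuples(self):
        a = GenomicVariant("1", 10, "A", "G")
        assert same_variant(a, GenomicVariant("1", 10, "A", "G"))

    def test_different_alt(self):
        assert not same_variant(GenomicVariant("1", 10, "A", "G"), GenomicVariant("1", 10, "A", "T"))

    def test_unnormalized_input_rejected(self):
        dirty = GenomicVariant("1", 10, "ATT", "GTT")  # shared trailing base
        with pytest.raises(ContractViolationError):
            same_variant(dirty, GenomicVariant("1", 10, "A", "G"))

    def test_equivalent_spellings_match_after_normalization(self, context_factory):
        seq = "GATTTTC"
        ctx = context_factory(seq)
        a = normalize_variant(GenomicVariant("ctg", 2, "AT", "A"), ctx)
        b = normalize_variant(GenomicVariant("ctg", 4, "TT", "T"), ctx)
        assert same_variant(a, b)


class TestChromNormalization:
    @pytest.mark.parametrize("raw,expected", [("chr10", "10"), ("10", "10"), ("chrX", "X"), ("chr", "chr")])
    def test_prefix_stripping(self, raw, expected):
        assert normalize_chrom(raw) == expected


def _write_vcf(path, body: str, samples=("S1",)) -> None:
    sample_cols = "\t".join(samples)
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=1,length=10000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_cols}\n"
    )
    path.write_text(header + body)


class TestVcfReading:
    def test_biallelic_het_with_depth(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_vcf(p, "1\t100\trs9\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:35\n")
        obs = read_caller_vcf(p, "callerX")
        assert len(obs) == 1
        o = obs[0]
        assert (o.caller, o.sample, o.genotype, o.depth) == ("callerX", "S1", Genotype.HET, 35)
        assert o.variant.key == ("1", 100, "A", "G")
        assert o.variant.id == "rs9"

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "m.vcf"
        _write_vcf(p, "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t1/2:40\n")
        obs = read_caller_vcf(p, "c")
        assert len(obs) == 2
        assert {o.variant.alt for o in obs} == {"G", "T"}
        assert all(o.variant.pos == 100 for o in obs)
        assert all(o.genotype is Genotype.HET for o in obs)

    def test_missing_dp_is_zero(self, tmp_path):
        p = tmp_path / "d.vcf"
        _write_vcf(p, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        obs = read_caller_vcf(p, "c")
        assert obs[0].depth == 0

    def test_missing_genotype_skipped(self, tmp_path):
        p = tmp_path / "g.vcf"
        _write_vcf(p, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t./.:10\n")
        assert read_caller_vcf(p, "c") == []

    def test_haploid_alt_is_hemi(self, tmp_path):
        p = tmp_path / "h.vcf"
        _write_vcf(p, "X\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t1:30\n")
        header_fix = p.read_text().replace("ID=1,length=10000", "ID=X,length=10000")
        p.write_text(header_fix)
        obs = read_caller_vcf(p, "c")
        assert obs[0].genotype is Genotype.HEMI

    def test_non_acgt_allele_raises_with_line(self, tmp_path):
        p = tmp_path / "bad.vcf"
        _write_vcf(p, "1\t100\t.\tA\t<DEL>\t.\tPASS\t.\tGT:DP\t0/1:30\n")
        with pytest.raises(VcfParseError, match="line"):
            read_caller_vcf(p, "c")

    def test_indels_normalized_on_load(self, tmp_path):
        reference = {"1": "GATTTTCAAA"}
        p = tmp_path / "i.vcf"
        _write_vcf(p, "1\t4\t.\tTT\tT\t.\tPASS\t.\tGT:DP\t0/1:30\n")
        obs = read_caller_vcf(p, "c", reference=reference)
        assert (obs[0].variant.pos, obs[0].variant.ref, obs[0].variant.alt) == (2, "AT", "A")

    def test_round_trip(self, tmp_path, rng):
        observations = []
        for i in range(30):
            v = GenomicVariant("1", int(rng.integers(10, 5000)) * 2 + i, "A" if i % 2 else "C", "G")
            observations.append(
                CallerObservation(
                    "c", v, f"S{i % 4}", Genotype.HET if i % 3 else Genotype.HOM_ALT,
                    int(rng.integers(0, 100)),
                )
            )
        # unique (sample, variant) keys required for exact round trip
        unique = {(o.sample, o.variant.key): o for o in observations}
        observations = list(unique.values())
        out = tmp_path / "rt.vcf"
        write_observations_vcf(observations, out)
        back = read_caller_vcf(out, "c")
        assert {(o.sample, o.variant.key, o.genotype, o.depth) for o in back} == {
            (o.sample, o.variant.key, o.genotype, o.depth) for o in observations
        }


class TestPedigreeReader:
    def test_family6_fixture(self):
        from deepintron.fixtures import load_family

        ped = load_family(6)
        assert len(ped.members) == 6
        assert len(ped.affected) == 2
        assert ped.variant_labels == ["rs397515893", "rs113195070"]

    def test_family15_fixture(self):
        from deepintron.fixtures import load_family

        ped = load_family(15)
        assert len(ped.members) == 3
        assert len(ped.affected) == 3

    def test_empty_file_is_structural_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(StructuralError):
            read_pedigree(p)

    def test_dangling_parent_raises(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "family\tindividual\tfather\tmother\tsex\tphenotype\tv1\n"
            "1\tkid\tGHOST\t0\t1\t2\thet\n"
        )
        with pytest.raises(StructuralError, match="GHOST"):
            read_pedigree(p)
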