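"""Alignment reading, diploid decoding, carrier-rule SNP calling,
region/effect classification and allele frequencies."""

import numpy as np
import pytest

from conftest import make_alignment, make_annotation
from oracles import CODON_TABLE, naive_snp_columns, substitution_is_synonymous
from photocline import variants
from photocline.types import (
    Effect,
    FormatError,
    FragmentAnnotation,
    InputError,
    Lineage,
    Locality,
    Region,
)


def _write_fasta(tmp_path, records):
    p = tmp_path / "aln.fasta"
    p.write_text("".join(f">{h}\n{s}\n" for h, s in records))
    return p


class TestReadAlignment:
    def test_reads_equal_length_records(self, tmp_path):
        p = _write_fasta(tmp_path, [("s1|P1", "ACGTACGTAC"),
                                    ("s2|P1", "ACRTACGTAC"),
                                    ("s3|P2", "ACGTNCGTAC")])
        aln = variants.read_alignment(p)
        assert [a.specimen_id for a in aln] == ["s1", "s2", "s3"]
        assert aln[1].locality_id == "P1"

    def test_invalid_symbol(self, tmp_path):
        p = _write_fasta(tmp_path, [("s1|P1", "ACBT")])
        with pytest.raises(FormatError, match="s1"):
            variants.read_alignment(p)

    def test_ragged_alignment(self, tmp_path):
        p = _write_fasta(tmp_path, [("s1|P1", "ACGTACGTAC"),
                                    ("s2|P1", "ACGTACGTACG")])
        with pytest.raises(FormatError, match="ragged"):
            variants.read_alignment(p)

    def test_header_without_locality(self, tmp_path):
        p = _write_fasta(tmp_path, [("s1", "ACGT")])
        with pytest.raises(FormatError):
            variants.read_alignment(p)


class TestGenotypeColumn:
    @pytest.mark.parametrize("sym,expected", [
        ("R", ("A", "G")), ("Y", ("C", "T")), ("S", ("C", "G")),
        ("W", ("A", "T")), ("K", ("G", "T")), ("M", ("A", "C")),
        ("T", ("T", "T")),
    ])
    def test_decoding(self, sym, expected):
        genotypes, multi = variants.genotype_column([sym])
        assert genotypes[0] == expected
        assert not multi

    def test_missing(self):
        genotypes, _ = variants.genotype_column(["N", "A"])
        assert genotypes[0] is None

    def test_multiallelic_flag(self):
        column = list("AAAAAGGC")
        _, multi = variants.genotype_column(column)
        assert multi


class TestCarrierRule:
    def _call(self, symbols, ref_base="A"):
        n = len(symbols)
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({4: symbols}, ["P1"] * n, ann)
        return variants.call_snps(aln, ann)

    def test_three_carriers_not_called(self):
        assert self._call("GRWAAAAA".replace("W", "R")) == []
        # het or hom both count one carrier: 3 carriers -> below threshold
        assert self._call("GGRAAAAA") == []

    def test_four_carriers_called(self):
        snps = self._call("GGRRAAAA")
        assert len(snps) == 1
        assert snps[0].carriers == 4
        assert (snps[0].ref_allele, snps[0].alt_allele) == ("A", "G")

    def test_boundary_flip(self):
        # removing one carrier from a 4-carrier SNP removes the call
        assert len(self._call("GGRRAAAA")) == 1
        assert self._call("GGRAAAAA") == []

    def test_monomorphic_alignment(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="ACACAC")
        aln = make_alignment({}, ["P1"] * 5, ann)
        assert variants.call_snps(aln, ann) == []

    def test_multiallelic_column_excluded(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({1: "GGGGCCAA"}, ["P1"] * 8, ann)
        assert variants.call_snps(aln, ann) == []

    def test_order_and_case_invariance(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({4: "GGRRAAAA"}, ["P1"] * 8, ann)
        rev = list(reversed(aln))
        a = variants.call_snps(aln, ann)
        b = variants.call_snps(rev, ann)
        assert [(s.column_index, s.carriers) for s in a] == \
               [(s.column_index, s.carriers) for s in b]

    def test_matches_naive_oracle_on_random_alignments(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            length = 30
            n_spec = 12
            ref = "".join(rng.choice(list("ACGT"), size=length))
            ann = make_annotation(intron_len=14, exon_len=16, seq=ref)
            rows = []
            for _ in range(n_spec):
                row = list(ref)
                for col in rng.choice(length, size=8, replace=False):
                    row[col] = rng.choice(list("ACGTNRYSWKM"))
                rows.append("".join(row))
            aln = make_alignment(
                {c: "".join(r[c] for r in rows) for c in range(length)},
                ["P1"] * n_spec, ann)
            called = {s.column_index for s in variants.call_snps(aln, ann)}
            expected = naive_snp_columns(rows, ref)
            assert called == expected


class TestRegionClassification:
    def test_boundary_labels(self):
        ann = make_annotation(intron_len=829, exon_len=849,
                              seq="A" * (829 + 849))
        assert variants.classify_region(828, ann) == (Region.INTRONIC, -1)
        assert variants.classify_region(829, ann) == (Region.EXONIC, 1)
        # the paper-style label SNP-158 maps to column 671
        assert variants.classify_region(671, ann) == (Region.INTRONIC, -158)

    def test_out_of_range(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        with pytest.raises(InputError):
            variants.classify_region(6, ann)

    def test_labels_partition_and_increase(self):
        ann = make_annotation(intron_len=20, exon_len=25, seq="A" * 45)
        labels = [variants.classify_region(c, ann) for c in range(45)]
        intronic = [l for r, l in labels if r is Region.INTRONIC]
        exonic = [l for r, l in labels if r is Region.EXONIC]
        assert len(intronic) == 20 and len(exonic) == 25
        assert intronic == sorted(intronic) and exonic == sorted(exonic)
        assert len(set(l for _, l in labels)) == 45
        # round trip
        for col in range(45):
            _, lab = variants.classify_region(col, ann)
            assert variants.label_to_column(lab, ann) == col


class TestCodingEffect:
    def test_synonymous_third_position(self):
        ann = make_annotation(intron_len=0, exon_len=6, seq="GGAGGA")
        assert variants.coding_effect(2, "A", "G", ann) is Effect.SYNONYMOUS

    def test_nonsynonymous(self):
        ann = make_annotation(intron_len=0, exon_len=6, seq="ATGGGA")
        assert variants.coding_effect(2, "G", "A", ann) is Effect.NONSYNONYMOUS

    def test_frame_offset_shifts_codons(self):
        # with offset 1 the first exonic base completes a truncated codon,
        # so column 0 has no complete codon -> NA
        ann = make_annotation(intron_len=0, exon_len=7, seq="GGGAGGA")
        with pytest.warns(UserWarning):
            eff = variants.coding_effect(0, "G", "A",
                                         make_annotation(intron_len=0,
                                                         exon_len=7,
                                                         frame=1,
                                                         seq="GGGAGGA"))
        assert eff is Effect.NA

    def test_codon_with_n_gives_na(self):
        ann = make_annotation(intron_len=0, exon_len=3, seq="GNA")
        with pytest.warns(UserWarning):
            assert variants.coding_effect(0, "G", "A", ann) is Effect.NA

    def test_matches_translation_oracle_on_all_substitutions(self):
        bases = "ACGT"
        for codon in CODON_TABLE:
            ann = make_annotation(intron_len=0, exon_len=3, seq=codon)
            for pos in range(3):
                for alt in bases:
                    if alt == codon[pos]:
                        continue
                    eff = variants.coding_effect(pos, codon[pos], alt, ann)
                    expected = (Effect.SYNONYMOUS
                                if substitution_is_synonymous(codon, pos, alt)
                                else Effect.NONSYNONYMOUS)
                    assert eff is expected, (codon, pos, alt)


class TestAlleleFrequencies:
    def _localities(self, ids):
        return [Locality(id=i, name=i, latitude=50.0, longitude=0.0,
                         altitude=0.0, lineage=Lineage.WEST, n_specimens=4)
                for i in ids]

    def test_half_frequency(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        # genotypes A/A, A/G, A/G, G/G plus 4 hom-alt carriers elsewhere to
        # pass the carrier rule
        aln = make_alignment({1: "ARRGGGGG"},
                             ["P1"] * 4 + ["P2"] * 4, ann)
        snps = variants.call_snps(aln, ann)
        fm = variants.allele_frequency_matrix(snps, self._localities(["P1", "P2"]))
        assert fm.freq.loc["P1", snps[0].position_label] == pytest.approx(0.5)
        assert fm.freq.loc["P2", snps[0].position_label] == pytest.approx(1.0)

    def test_heterozygote_quarter_frequency(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({1: "RRAAGGGG"},
                             ["P1"] * 4 + ["P2"] * 4, ann)
        snps = variants.call_snps(aln, ann)
        assert fmfreq(snps, self._localities(["P1", "P2"]))["P1"] == \
            pytest.approx(0.25)

    def test_missing_data_excluded(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({1: "RNNAGGGG"},
                             ["P1"] * 4 + ["P2"] * 4, ann)
        snps = variants.call_snps(aln, ann)
        fm = variants.allele_frequency_matrix(snps, self._localities(["P1", "P2"]))
        lab = snps[0].position_label
        assert fm.sample_n.loc["P1", lab] == 2
        assert fm.freq.loc["P1", lab] == pytest.approx(0.25)

    def test_unknown_locality_rejected(self):
        ann = make_annotation(intron_len=3, exon_len=3, seq="AAAAAA")
        aln = make_alignment({1: "GGGGAAAA"},
                             ["P1"] * 4 + ["PX"] * 4, ann)
        snps = variants.call_snps(aln, ann)
        with pytest.raises(InputError, match="PX"):
            variants.allele_frequency_matrix(snps, self._localities(["P1"]))

    def test_counts_sum_to_carrier_alleles(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=20))
        ann = make_annotation(intron_len=10, exon_len=10, seq=ref)
        pops = ["P1"] * 6 + ["P2"] * 6
        col = "".join(rng.choice(list("AGR"), size=12))
        aln = make_alignment({int(np.flatnonzero([ref[i] == "A" for i in range(20)])[0]): col},
                             pops, ann)
        for snp in variants.call_snps(aln, ann):
            total_alt = sum(a for a, _ in snp.per_population_counts.values())
            genotypes, _ = variants.genotype_column(
                [s.seq[snp.column_index] for s in aln])
            direct = sum(g.count(snp.alt_allele) for g in genotypes if g)
            assert total_alt == direct


def fmfreq(snps, locs):
    fm = variants.allele_frequency_matrix(snps, locs)
    return fm.freq[snps[0].position_label]
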