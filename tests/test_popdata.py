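"""Data model, file formats, site classification and SNP extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivypop.popdata import (
    CodingAnnotation,
    HaplotypeAlignment,
    MalformedInputError,
    SITE_EXCLUDED,
    SITE_NONCODING,
    SITE_NONSYNONYMOUS,
    SITE_SYNONYMOUS,
    classify_sites,
    extract_snps,
    read_haplotype_fasta,
    write_haplotype_fasta,
    read_population_table,
    assign_regions,
    read_coding_annotation,
    write_coding_annotation,
)


def _write_fasta(path, records):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))


class TestFastaIO:
    def test_reads_two_haplotypes_per_individual(self, tmp_path):
        f = tmp_path / "L1.fasta"
        _write_fasta(f, [("A|hap1", "ACGTACGTAC"), ("A|hap2", "ACGTACGTAC"),
                         ("B|hap1", "ACGAACGTAC"), ("B|hap2", "ACGTACGTAC")])
        aln = read_haplotype_fasta(f)
        assert aln.n_haplotypes == 4
        assert aln.individual_ids() == ["A", "B"]
        assert aln.length_bp == 10
        assert aln.locus_id == "L1"

    def test_three_haplotypes_is_an_error_naming_the_individual(self, tmp_path):
        f = tmp_path / "bad.fasta"
        _write_fasta(f, [("A|hap1", "ACGT"), ("A|hap2", "ACGT"),
                         ("A|hap3", "ACGT"), ("B|hap1", "ACGT")])
        with pytest.raises(MalformedInputError, match="A"):
            read_haplotype_fasta(f)

    def test_ragged_alignment_rejected(self, tmp_path):
        f = tmp_path / "ragged.fasta"
        _write_fasta(f, [("A|hap1", "ACGT"), ("A|hap2", "ACG")])
        with pytest.raises(MalformedInputError, match="ragged"):
            read_haplotype_fasta(f)

    def test_round_trip_is_byte_stable(self, tmp_path):
        f = tmp_path / "L2.fasta"
        _write_fasta(f, [("A|hap1", "ACGTTT"), ("A|hap2", "AAGTTT"),
                         ("B|hap1", "ACGTTA"), ("B|hap2", "ACGTTT")])
        aln = read_haplotype_fasta(f)
        g = tmp_path / "out.fasta"
        write_haplotype_fasta(aln, g)
        aln2 = read_haplotype_fasta(g, locus_id="L2")
        assert np.array_equal(aln.sequences, aln2.sequences)
        assert aln.individuals == aln2.individuals
        write_haplotype_fasta(aln2, tmp_path / "out2.fasta")
        assert g.read_bytes() == (tmp_path / "out2.fasta").read_bytes()

    def test_metadata_check(self, tmp_path):
        f = tmp_path / "L1.fasta"
        _write_fasta(f, [("A|hap1", "ACGT"), ("A|hap2", "ACGT")])
        meta = pd.DataFrame({"individual_id": ["Z"]})
        with pytest.raises(MalformedInputError, match="absent"):
            read_haplotype_fasta(f, metadata=meta)


class TestPopulationTable:
    def test_reads_and_validates(self, tmp_path):
        f = tmp_path / "pops.csv"
        f.write_text(
            "individual_id,population_id,latitude,longitude,leaf_genotype\n"
            "A,P1,30.0,-85.0,LL\nB,P1,30.0,-85.0,\nC,P2,39.0,-77.0,ll\n"
        )
        meta = read_population_table(f)
        assert list(meta["leaf_genotype"]) == ["LL", "unknown", "ll"]
        meta = assign_regions(meta, boundary_latitude=36.0)
        assert list(meta["region"]) == ["south", "south", "north"]

    def test_duplicate_individuals_rejected(self, tmp_path):
        f = tmp_path / "pops.csv"
        f.write_text(
            "individual_id,population_id,latitude,longitude,leaf_genotype\n"
            "A,P1,30,-85,LL\nA,P1,30,-85,LL\n"
        )
        with pytest.raises(MalformedInputError, match="duplicate"):
            read_population_table(f)


class TestAnnotation:
    def test_round_trip(self, tmp_path):
        anns = {"L1": CodingAnnotation("L1", [(10, 40), (60, 90)], frame=1)}
        f = tmp_path / "ann.bed"
        write_coding_annotation(anns, f)
        back = read_coding_annotation(f)
        assert back["L1"].cds_intervals == [(10, 40), (60, 90)]
        assert back["L1"].frame == 1

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(MalformedInputError, match="overlap"):
            CodingAnnotation("L1", [(0, 10), (5, 20)])


class TestClassifySites:
    def test_no_cds_means_all_noncoding(self, four_hap_alignment):
        out = classify_sites(four_hap_alignment, None)
        assert set(out.site_classes) == {SITE_NONCODING}
        assert np.allclose(out.silent_weights, 1.0)

    def test_fourfold_third_position_is_synonymous(self):
        # GGG/GGA glycine codon: polymorphic third position stays glycine
        seqs = np.array([list("GGG"), list("GGA"), list("GGG"), list("GGA")])
        aln = HaplotypeAlignment("g", seqs, ["a", "a", "b", "b"])
        out = classify_sites(aln, CodingAnnotation("g", [(0, 3)], 0))
        assert out.site_classes[2] == SITE_SYNONYMOUS
        assert out.silent_weights[2] == 1.0  # fourfold degenerate

    def test_first_position_met_leu_is_nonsynonymous(self):
        seqs = np.array([list("ATG"), list("TTG"), list("ATG"), list("TTG")])
        aln = HaplotypeAlignment("m", seqs, ["a", "a", "b", "b"])
        out = classify_sites(aln, CodingAnnotation("m", [(0, 3)], 0))
        assert out.site_classes[0] == SITE_NONSYNONYMOUS

    def test_cds_past_alignment_end_rejected(self, four_hap_alignment):
        with pytest.raises(MalformedInputError, match="past"):
            classify_sites(four_hap_alignment,
                           CodingAnnotation("toy", [(0, 99)], 0))

    def test_gap_columns_excluded(self):
        seqs = np.array([list("A-GT"), list("A-GT"), list("ANGT"), list("AAGT")])
        aln = HaplotypeAlignment("x", seqs, ["a", "a", "b", "b"])
        out = classify_sites(aln, None)
        assert out.site_classes[1] == SITE_EXCLUDED
        assert out.silent_weights[1] == 0.0


class TestExtractSnps:
    def _meta(self, inds):
        return pd.DataFrame({"individual_id": inds})

    def test_biallelic_columns_become_snps(self, four_hap_alignment):
        snps = extract_snps([four_hap_alignment], self._meta(["i1", "i2"]))
        assert snps.n_snps == 2
        assert snps.n_individuals == 2
        # dosage = count of minor allele over the individual's two rows
        assert snps.genotypes.sum() == 4  # each column has 2 minor copies

    def test_monomorphic_locus_contributes_nothing(self):
        seqs = np.tile(np.array(list("ACGT")), (4, 1))
        aln = HaplotypeAlignment("m", seqs, ["a", "a", "b", "b"])
        snps = extract_snps([aln], self._meta(["a", "b"]))
        assert snps.n_snps == 0

    def test_triallelic_column_dropped(self):
        seqs = np.array([list("A"), list("C"), list("G"), list("A")])
        aln = HaplotypeAlignment("t", seqs, ["a", "a", "b", "b"])
        snps = extract_snps([aln], self._meta(["a", "b"]))
        assert snps.n_snps == 0

    def test_empty_list_rejected(self):
        with pytest.raises(MalformedInputError):
            extract_snps([], self._meta(["a"]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(2, 5), st.integers(4, 16), st.integers(0, 10_000))
def test_dosage_matches_haplotype_counts(n_ind, length, seed):
    """Genotype dosage equals the per-individual haplotype allele count."""
    r = np.random.default_rng(seed)
    seqs = r.choice(list("ACT"), size=(2 * n_ind, length))
    inds = [f"I{i}" for i in range(n_ind) for _ in range(2)]
    aln = HaplotypeAlignment("h", seqs, inds)
    snps = extract_snps([aln], pd.DataFrame({"individual_id": [f"I{i}" for i in range(n_ind)]}))
    for j, (locus, col) in enumerate(snps.snp_ids):
        minor = snps.allele_labels[j][1]
        for i in range(n_ind):
            rows = [k for k, ind in enumerate(inds) if ind == f"I{i}"]
            assert snps.genotypes[i, j] == np.sum(seqs[rows, col] == minor)


def test_silent_count_invariant_to_row_order(rng):
    from ivypop.diversity import site_summary

    seqs = rng.choice(list("ACGT"), size=(8, 40))
    inds = [f"I{i}" for i in range(4) for _ in range(2)]
    aln = HaplotypeAlignment("x", seqs, inds)
    perm = rng.permutation(8)
    # permute pairs of rows jointly to keep the 2-per-individual invariant
    aln2 = HaplotypeAlignment("x", seqs[perm], [inds[i] for i in perm])
    assert site_summary(aln).s == site_summary(aln2).s
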