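"""Pedigree, VCF and annotation loading."""

import io

import pytest

from famprio import (
    AnnotatedVariant,
    Consequence,
    GenotypeCall,
    PedigreeError,
    VariantSite,
    load_pedigree,
    load_variants,
    merge_annotations,
    write_vcf,
)
from famprio.family import PedigreeError


class TestPedigree:
    def test_quad_roles(self, quad_ped_text):
        ped = load_pedigree(quad_ped_text)
        assert {e.sample_id for e in ped.affected_sibs()} == {"sibA", "sibB"}
        father, mother = ped.shared_parents()
        assert (father.sample_id, mother.sample_id) == ("father", "mother")

    def test_empty_input_rejected(self):
        with pytest.raises(PedigreeError, match="no samples"):
            load_pedigree("")

    def test_self_ancestor_rejected(self):
        text = "F1 father father 0 1 1\nF1 mother 0 0 2 1\n"
        with pytest.raises(PedigreeError, match="ancestor"):
            load_pedigree(text)

    def test_duplicate_and_dangling_ids_rejected(self, quad_ped_text):
        with pytest.raises(PedigreeError, match="duplicate"):
            load_pedigree(quad_ped_text + "FAM1 sibA 0 0 1 2\n")
        with pytest.raises(PedigreeError, match="ghost"):
            load_pedigree("F1 kid ghost 0 1 2\n")


def _vcf(records, samples=("sibA", "sibB", "father", "mother"), fmt="GT"):
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        "##contig=<ID=16>\n##contig=<ID=1>\n##contig=<ID=X>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    lines = []
    for chrom, pos, rsid, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
            + "\t".join(gts)
        )
    return header + "\n".join(lines) + "\n"


class TestLoadVariants:
    def test_quad_het_record(self, quad_pedigree):
        # the compound-het paternal allele: sibs and father het, mother hom-ref
        text = _vcf([("16", 3656625, "rs79842542", "G", "A",
                      ["0/1", "0/1", "0/1", "0/0"])])
        fam = load_variants(text, quad_pedigree)
        (site,) = fam.sites
        assert (site.chrom, site.pos, site.ref, site.alt) == ("16", 3656625, "G", "A")
        assert site.rsid == "rs79842542"
        assert fam.call(site, "sibA").is_het
        assert fam.call(site, "sibB").is_het
        assert fam.call(site, "father").is_het
        assert fam.call(site, "mother").is_hom_ref

    def test_missing_gt_flagged(self, quad_pedigree):
        text = _vcf([("1", 100, ".", "A", "G", ["0/1", "0/1", "0/1", "./."])])
        fam = load_variants(text, quad_pedigree)
        assert fam.call(fam.sites[0], "mother").missing

    def test_sample_absent_from_header_is_error(self, quad_pedigree):
        text = _vcf([("1", 100, ".", "A", "G", ["0/1", "0/1", "0/1"])],
                    samples=("sibA", "sibB", "father"))
        with pytest.raises(ValueError, match="mother"):
            load_variants(text, quad_pedigree)

    # oracle: hand-enumerated allele-index remapping for a triallelic
    # record A -> G,T split into (A,G) and (A,T) biallelic sites
    TRIALLELIC_REMAP = {
        "0/0": ((0, 0), (0, 0)),
        "0/1": ((0, 1), (0, 0)),
        "0/2": ((0, 0), (0, 1)),
        "1/1": ((1, 1), (0, 0)),
        "1/2": ((0, 1), (0, 1)),
        "2/2": ((0, 0), (1, 1)),
    }

    @pytest.mark.parametrize("gt,expected", sorted(TRIALLELIC_REMAP.items()))
    def test_multiallelic_split_matches_enumeration(self, quad_pedigree, gt, expected):
        text = _vcf([("1", 500, ".", "A", "G,T", [gt, "0/0", "0/0", "0/0"])])
        fam = load_variants(text, quad_pedigree)
        assert [s.alt for s in fam.sites] == ["G", "T"]
        got = tuple(fam.call(s, "sibA").alleles for s in fam.sites)
        assert got == expected

    def test_multiallelic_split_conserves_alt_dose(self, quad_pedigree):
        # summed per-site alt dose equals the original non-ref dose
        for gt, expected in self.TRIALLELIC_REMAP.items():
            orig_dose = sum(a != "0" for a in gt.split("/"))
            split_dose = sum(sum(g) for g in expected)
            assert split_dose == orig_dose

    def test_male_x_normalized_to_hemizygous(self, quad_pedigree):
        text = _vcf([("X", 1000, ".", "G", "T", ["1/1", "0/0", "0/0", "0/1"])])
        fam = load_variants(text, quad_pedigree)
        site = fam.sites[0]
        assert fam.call(site, "sibA").is_hemizygous
        assert fam.call(site, "sibA").alleles == (1,)
        assert fam.call(site, "father").is_hemizygous
        assert not fam.call(site, "mother").is_hemizygous

    def test_ad_dp_parsed(self, quad_pedigree):
        text = _vcf(
            [("1", 7, ".", "A", "G", ["0/1:5,6:11", "0/1:4,4:8",
                                      "0/0:9,0:9", "0/0:12,0:12"])],
            fmt="GT:AD:DP",
        )
        fam = load_variants(text, quad_pedigree)
        call = fam.call(fam.sites[0], "sibA")
        assert (call.depth, call.alt_depth) == (11, 6)

    def test_round_trip_preserves_genotype_matrix(self, quad_pedigree):
        text = _vcf(
            [
                ("16", 3656625, "rs79842542", "G", "A", ["0/1", "0/1", "0/1", "0/0"]),
                ("1", 100, ".", "A", "G", ["1/1", "1/1", "0/1", "0/1"]),
                ("X", 1000, ".", "G", "T", ["1", "1", "0", "0/1"]),
            ]
        )
        fam = load_variants(text, quad_pedigree)
        buf = io.StringIO()
        write_vcf(fam, quad_pedigree, buf)
        fam2 = load_variants(buf.getvalue(), quad_pedigree)
        assert [s.key for s in fam2.sites] == [s.key for s in fam.sites]
        assert fam2.calls == fam.calls

    def test_every_site_fully_called(self, quad_pedigree):
        text = _vcf([("1", 100, ".", "A", "G", ["0/1", "./.", "0/1", "0/0"])])
        fam = load_variants(text, quad_pedigree)
        fam.validate_complete()  # missing-flagged entries still present


class TestGenotypeCall:
    def test_alt_depth_bounded_by_depth(self):
        with pytest.raises(ValueError):
            GenotypeCall(alleles=(0, 1), depth=5, alt_depth=9)

    def test_missing_has_no_alleles(self):
        assert GenotypeCall(missing=True).alleles == ()


ANNOTATION_TSV = """\
chrom\tpos\tref\talt\trsid\tgene\tconsequence\taa_change\tmaf_1000g\tmaf_esp\tq2_esp\tsift\tpolyphen2\tfathmm\tsiphy
2\t17946243\tA\tG\trs16981869\tGEN1\tmissense\tN143S\t0.13\t0.145394\t0.025\t0.03\t0.81\t-0.45\t8.03
1\t144916676\tC\tT\trs1698683\tPDE4DIP\t-\tW626*\t-\t0.321203\t-\t0.16\t-\t3.81\t18.03
"""


class TestMergeAnnotations:
    @pytest.fixture
    def fam(self, quad_pedigree):
        text = _vcf(
            [
                ("2", 17946243, "rs16981869", "A", "G", ["1/1", "1/1", "0/1", "0/1"]),
                ("1", 144916676, "rs1698683", "C", "T", ["0/1", "0/1", "0/0", "0/1"]),
                ("1", 999, ".", "A", "C", ["0/1", "0/1", "0/0", "0/1"]),
            ]
        )
        return load_variants(text, quad_pedigree)

    def test_homozygous_row_values(self, fam):
        ann = merge_annotations(fam, ANNOTATION_TSV)
        v = ann[0]
        assert v.gene == "GEN1"
        assert v.maf_esp == 0.145394
        assert v.q2_esp == 0.025
        assert (v.sift, v.polyphen2, v.fathmm, v.siphy) == (0.03, 0.81, -0.45, 8.03)

    def test_stop_gain_inferred_from_aa_change(self, fam):
        ann = merge_annotations(fam, ANNOTATION_TSV)
        v = ann[1]
        assert v.consequence is Consequence.STOP_GAIN
        assert v.polyphen2 is None  # "-" means missing

    def test_unannotated_site_all_none(self, fam):
        ann = merge_annotations(fam, ANNOTATION_TSV)
        v = ann[2]
        assert v.gene is None
        assert v.maf_1000g is None and v.sift is None

    def test_duplicate_keys_rejected(self, fam):
        dup = ANNOTATION_TSV + "2\t17946243\tA\tG\trs16981869\tGEN1\tmissense\tN143S\t-\t-\t-\t-\t-\t-\t-\n"
        with pytest.raises(ValueError, match="duplicate"):
            merge_annotations(fam, dup)


class TestAnnotatedVariant:
    def test_frequencies_must_be_fractions(self):
        site = VariantSite(chrom="1", pos=1, ref="A", alt="G")
        with pytest.raises(ValueError):
            AnnotatedVariant(site=site, maf_1000g=1.5)

    def test_maf_max_over_available_databases(self):
        site = VariantSite(chrom="1", pos=1, ref="A", alt="G")
        assert AnnotatedVariant(site=site, maf_1000g=0.06, maf_esp=0.071).maf_max == 0.071
        assert AnnotatedVariant(site=site).maf_max is None
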