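"""Mendelian filtering, sharing, origin phasing and classification."""

import itertools

import pytest

from famprio import (
    GenotypeCall,
    InheritanceClass,
    Origin,
    PipelineConfig,
    Sex,
    VariantSite,
    classify_gene,
    denovo_screen,
    mendelian_consistent,
    parental_origin,
    run_reduction,
    shared_by_affected,
    x_linked_screen,
)
from famprio.family import AnnotatedVariant, Consequence, FamilyGenotypes
from famprio.segregation import FilterTrace, UnsupportedChromosomeError

DIPLOID = [(0, 0), (0, 1), (1, 1)]


def _call(alleles, **kw):
    return GenotypeCall(alleles=alleles, **kw)


# --- independent oracle: enumerate one gamete from each parent -------------

def gamete_oracle_autosomal(child, father, mother):
    return any(
        tuple(sorted((p, m))) == tuple(sorted(child))
        for p in father
        for m in mother
    )


def gamete_oracle_male_x(child_allele, mother):
    return child_allele in mother


class TestMendelianConsistency:
    def test_het_child_from_carrier_mother(self):
        # sibs het, father hom-ref, mother het: a maternal transmission
        assert mendelian_consistent(
            _call((0, 1)), _call((0, 0)), _call((0, 1)), "16", Sex.MALE
        )

    def test_alt_absent_from_both_parents_is_inconsistent(self):
        assert not mendelian_consistent(
            _call((1, 1)), _call((0, 0)), _call((0, 0)), "1", Sex.MALE
        )

    @pytest.mark.parametrize(
        "child,father,mother", list(itertools.product(DIPLOID, repeat=3))
    )
    def test_all_27_autosomal_combinations_match_oracle(self, child, father, mother):
        got = mendelian_consistent(
            _call(child), _call(father), _call(mother), "7", Sex.FEMALE
        )
        assert got == gamete_oracle_autosomal(child, father, mother)

    @pytest.mark.parametrize(
        "child,father,mother",
        list(itertools.product([0, 1], DIPLOID, DIPLOID)),
    )
    def test_all_18_male_x_combinations_match_oracle(self, child, father, mother):
        got = mendelian_consistent(
            _call((child,)), _call((father[0],)), _call(mother), "X", Sex.MALE
        )
        assert got == gamete_oracle_male_x(child, mother)

    def test_unsupported_chromosomes_rejected(self):
        for chrom in ("Y", "MT"):
            with pytest.raises(UnsupportedChromosomeError):
                mendelian_consistent(
                    _call((0, 1)), _call((0, 1)), _call((0, 1)), chrom, Sex.MALE
                )


def _family(genotypes, chrom="1", pos=100, ref="A", alt="G"):
    """Build a one-site FamilyGenotypes from {sample: alleles-or-None}."""
    site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt)
    calls = {
        (site.key, s): (
            GenotypeCall(missing=True) if g is None else GenotypeCall(alleles=g)
        )
        for s, g in genotypes.items()
    }
    return site, FamilyGenotypes(
        sites=[site], calls=calls, sample_ids=list(genotypes)
    )


class TestSharedByAffected:
    @pytest.mark.parametrize("a", DIPLOID)
    @pytest.mark.parametrize("b", DIPLOID)
    def test_truth_table_matches_oracle_for_both_rules(self, quad_pedigree, a, b):
        site, fam = _family(
            {"sibA": a, "sibB": b, "father": (0, 1), "mother": (0, 1)}
        )
        # identity rule: same unordered non-ref pair in every sib
        identity = a == b and any(x != 0 for x in a)
        carrier = all(any(x != 0 for x in g) for g in (a, b))
        assert shared_by_affected(site, fam, quad_pedigree, "identity") == identity
        assert shared_by_affected(site, fam, quad_pedigree, "carrier") == carrier

    def test_missing_sib_call_fails(self, quad_pedigree):
        site, fam = _family(
            {"sibA": (0, 1), "sibB": None, "father": (0, 1), "mother": (0, 0)}
        )
        assert not shared_by_affected(site, fam, quad_pedigree)


class TestParentalOrigin:
    @pytest.mark.parametrize(
        "father,mother,expected",
        [
            ((0, 1), (0, 0), Origin.PATERNAL),
            ((0, 0), (0, 1), Origin.MATERNAL),
            ((0, 1), (0, 1), Origin.AMBIGUOUS),
            ((0, 0), (0, 0), Origin.INCONSISTENT),
        ],
    )
    def test_carrier_rule(self, quad_pedigree, father, mother, expected):
        site, fam = _family(
            {"sibA": (0, 1), "sibB": (0, 1), "father": father, "mother": mother}
        )
        assert parental_origin(site, fam, quad_pedigree) == expected

    def test_non_het_sibs_rejected(self, quad_pedigree):
        site, fam = _family(
            {"sibA": (1, 1), "sibB": (1, 1), "father": (0, 1), "mother": (0, 1)}
        )
        with pytest.raises(ValueError, match="het"):
            parental_origin(site, fam, quad_pedigree)


def _gene_fixture(quad, patterns, chrom="1"):
    """patterns: list of (sibs, father, mother) allele tuples, one per site."""
    sites, calls = [], {}
    for i, (sibs, father, mother) in enumerate(patterns):
        site = VariantSite(chrom=chrom, pos=1000 + i, ref="A", alt="G")
        sites.append(site)
        for s, g in (("sibA", sibs), ("sibB", sibs), ("father", father), ("mother", mother)):
            calls[(site.key, s)] = GenotypeCall(alleles=g)
    fam = FamilyGenotypes(sites=sites, calls=calls, sample_ids=quad.sample_ids)
    variants = [
        AnnotatedVariant(site=s, gene="GENE", consequence=Consequence.MISSENSE)
        for s in sites
    ]
    return fam, variants


class TestClassifyGene:
    def test_trans_pair_is_compound_het(self, quad_pedigree):
        fam, variants = _gene_fixture(
            quad_pedigree,
            [((0, 1), (0, 1), (0, 0)),  # paternal
             ((0, 1), (0, 0), (0, 1))],  # maternal
        )
        cand = classify_gene("GENE", variants, fam, quad_pedigree)
        assert cand.klass is InheritanceClass.COMPOUND_HET
        assert sorted(o.value for o in cand.origins.values()) == ["maternal", "paternal"]

    def test_hom_alt_sibs_with_carrier_parents_is_homozygous(self, quad_pedigree):
        fam, variants = _gene_fixture(
            quad_pedigree, [((1, 1), (0, 1), (0, 1))]
        )
        cand = classify_gene("GENE", variants, fam, quad_pedigree)
        assert cand.klass is InheritanceClass.HOMOZYGOUS_RECESSIVE

    def test_single_het_site_is_not_a_candidate(self, quad_pedigree):
        fam, variants = _gene_fixture(
            quad_pedigree, [((0, 1), (0, 1), (0, 0))]
        )
        cand = classify_gene("GENE", variants, fam, quad_pedigree)
        assert cand.klass is InheritanceClass.NONE

    def test_same_resolved_origin_never_compound_het(self, quad_pedigree):
        fam, variants = _gene_fixture(
            quad_pedigree,
            [((0, 1), (0, 1), (0, 0)), ((0, 1), (0, 1), (0, 0))],  # both paternal
        )
        cand = classify_gene("GENE", variants, fam, quad_pedigree)
        assert cand.klass is InheritanceClass.NONE

    def test_unresolvable_origins_flagged_ambiguous(self, quad_pedigree):
        fam, variants = _gene_fixture(
            quad_pedigree,
            [((0, 1), (0, 1), (0, 1)), ((0, 1), (0, 1), (0, 1))],
        )
        cand = classify_gene("GENE", variants, fam, quad_pedigree)
        assert cand.klass is InheritanceClass.COMPOUND_HET_AMBIGUOUS

    def test_empty_variant_list_rejected(self, quad_pedigree):
        fam, _ = _gene_fixture(quad_pedigree, [((0, 1), (0, 1), (0, 0))])
        with pytest.raises(ValueError):
            classify_gene("GENE", [], fam, quad_pedigree)


def _denovo_family(quad, parent_depths=(10, 12), parent_alt=(0, 0), sib=(0, 1)):
    site = VariantSite(chrom="5", pos=777, ref="T", alt="C")
    fd, md = parent_depths
    fa, ma = parent_alt
    calls = {
        (site.key, "sibA"): GenotypeCall(alleles=sib, depth=30, alt_depth=14),
        (site.key, "sibB"): GenotypeCall(alleles=sib, depth=28, alt_depth=15),
        (site.key, "father"): GenotypeCall(alleles=(0, 0), depth=fd, alt_depth=fa),
        (site.key, "mother"): GenotypeCall(alleles=(0, 0), depth=md, alt_depth=ma),
    }
    fam = FamilyGenotypes(sites=[site], calls=calls, sample_ids=quad.sample_ids)
    return site, fam


class TestDenovoScreen:
    def test_private_shared_site_with_clean_covered_parents_retained(self, quad_pedigree):
        site, fam = _denovo_family(quad_pedigree)
        assert denovo_screen(fam, quad_pedigree, []) == [site]

    def test_parent_below_minimum_coverage_excluded(self, quad_pedigree):
        _, fam = _denovo_family(quad_pedigree, parent_depths=(5, 12))
        assert denovo_screen(fam, quad_pedigree, []) == []

    def test_parent_with_alt_reads_excluded(self, quad_pedigree):
        _, fam = _denovo_family(quad_pedigree, parent_alt=(1, 0))
        assert denovo_screen(fam, quad_pedigree, []) == []

    def test_database_recorded_site_is_not_private(self, quad_pedigree):
        site, fam = _denovo_family(quad_pedigree)
        ann = [AnnotatedVariant(site=site, gene="G", maf_1000g=0.001)]
        assert denovo_screen(fam, quad_pedigree, ann) == []

    def test_parents_without_depth_info_excluded(self, quad_pedigree):
        site = VariantSite(chrom="5", pos=777, ref="T", alt="C")
        calls = {
            (site.key, "sibA"): GenotypeCall(alleles=(0, 1)),
            (site.key, "sibB"): GenotypeCall(alleles=(0, 1)),
            (site.key, "father"): GenotypeCall(alleles=(0, 0)),
            (site.key, "mother"): GenotypeCall(alleles=(0, 0)),
        }
        fam = FamilyGenotypes(sites=[site], calls=calls, sample_ids=quad_pedigree.sample_ids)
        trace = FilterTrace()
        assert denovo_screen(fam, quad_pedigree, [], trace=trace) == []
        assert dict((n, i) for n, i, _ in trace.stages)[
            "insufficient_parental_coverage"
        ] == 1


class TestXLinkedScreen:
    def _x_family(self, quad, sib=(1,), mother=(0, 1)):
        site = VariantSite(chrom="X", pos=5000, ref="G", alt="T")
        calls = {
            (site.key, "sibA"): GenotypeCall(alleles=sib),
            (site.key, "sibB"): GenotypeCall(alleles=sib),
            (site.key, "father"): GenotypeCall(alleles=(0,)),
            (site.key, "mother"): GenotypeCall(alleles=mother),
        }
        fam = FamilyGenotypes(sites=[site], calls=calls, sample_ids=quad.sample_ids)
        return site, fam

    def test_hemizygous_sibs_with_carrier_mother_is_candidate(self, quad_pedigree):
        site, fam = self._x_family(quad_pedigree)
        ann = [AnnotatedVariant(site=site, gene="XG")]
        (cand,) = x_linked_screen(fam, quad_pedigree, ann)
        assert cand.gene == "XG"
        assert cand.klass is InheritanceClass.X_HEMIZYGOUS
        assert list(cand.origins.values()) == [Origin.MATERNAL]

    def test_non_carrier_mother_excluded_as_inconsistent(self, quad_pedigree):
        _, fam = self._x_family(quad_pedigree, mother=(0, 0))
        assert x_linked_screen(fam, quad_pedigree) == []

    def test_no_x_sites_yields_empty_list(self, quad_pedigree):
        site = VariantSite(chrom="2", pos=1, ref="A", alt="G")
        calls = {
            (site.key, s): GenotypeCall(alleles=(0, 1))
            for s in quad_pedigree.sample_ids
        }
        fam = FamilyGenotypes(sites=[site], calls=calls, sample_ids=quad_pedigree.sample_ids)
        assert x_linked_screen(fam, quad_pedigree) == []


class TestRunReduction:
    def test_empty_input_yields_empty_trace_and_candidates(self, quad_pedigree):
        fam = FamilyGenotypes(sites=[], calls={}, sample_ids=quad_pedigree.sample_ids)
        cands, trace = run_reduction(fam, quad_pedigree, [])
        assert cands == []
        assert all(i == 0 and o == 0 for _, i, o in trace.stages[:4])

    def test_trace_is_monotone(self, table_family):
        fam, ped, ann = table_family
        _, trace = run_reduction(fam, ped, ann)
        assert all(o <= i for _, i, o in trace.stages)

    def test_mendelian_and_shared_stages_commute(self, table_family):
        """Pure set filters: applying them in either order keeps the same sites."""
        from famprio.segregation import shared_by_affected as shared

        fam, ped, ann = table_family
        father, mother = ped.shared_parents()
        sexes = {e.sample_id: e.sex for e in ped.entries}

        def mendel_ok(site):
            return all(
                mendelian_consistent(
                    fam.call(site, s.sample_id),
                    fam.call(site, father.sample_id),
                    fam.call(site, mother.sample_id),
                    site.chrom,
                    sexes[s.sample_id],
                )
                for s in ped.affected_sibs()
            )

        order1 = [s for s in fam.sites if mendel_ok(s) and shared(s, fam, ped)]
        order2 = [s for s in fam.sites if shared(s, fam, ped) and mendel_ok(s)]
        assert order1 == order2
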