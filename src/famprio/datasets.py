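"""Worked-example data: a familial childhood-ALL quad.

This module ships, as plain Python literals, the published findings of a
nonsyndromic childhood pre-B ALL family (two affected brothers and both
parents): the gene-level table of shared non-synonymous variants that
were compound heterozygous or homozygous in the sibship, the separately
reported rare heterozygous FANCA variant, both sibs' hyperdiploid
karyotypes, the reference-cohort composition used for carrier lookups,
and the list of common ALL susceptibility loci genotyped in the sibs.

These data exercise every stage of the pipeline on real printed values.
Genomic coordinates for the susceptibility loci and the FANCA variant
were not part of the printed tables; they carry synthetic placeholder
positions (only the rsid is used to address them).
"""

from __future__ import annotations

import pandas as pd

from .family import (
    Affection,
    AnnotatedVariant,
    Consequence,
    FamilyGenotypes,
    GenotypeCall,
    Pedigree,
    PedigreeEntry,
    Sex,
    VariantSite,
)

__all__ = [
    "SIB_A",
    "SIB_B",
    "FATHER",
    "MOTHER",
    "N_COHORT_TRIOS",
    "N_COHORT_SINGLETONS",
    "KARYOTYPE_SIB_A",
    "KARYOTYPE_SIB_B",
    "quad_pedigree",
    "variant_table",
    "quad_genotypes",
    "quad_annotations",
    "fanca_variant",
    "susceptibility_loci",
    "susceptibility_family",
]

SIB_A = "sibA"
SIB_B = "sibB"
FATHER = "father"
MOTHER = "mother"

N_COHORT_TRIOS = 103
N_COHORT_SINGLETONS = 60

KARYOTYPE_SIB_A = "53,XY,+4,+6,+12,+15,+17,+18,+21"
KARYOTYPE_SIB_B = "54,XY,+X,+5,+8,+10,+14,+17,+18,+21"


def quad_pedigree() -> Pedigree:
    """Two affected brothers plus their unaffected parents."""
    return Pedigree(
        [
            PedigreeEntry(SIB_A, FATHER, MOTHER, Sex.MALE, Affection.AFFECTED),
            PedigreeEntry(SIB_B, FATHER, MOTHER, Sex.MALE, Affection.AFFECTED),
            PedigreeEntry(FATHER, None, None, Sex.MALE, Affection.UNAFFECTED),
            PedigreeEntry(MOTHER, None, None, Sex.FEMALE, Affection.UNAFFECTED),
        ]
    )


# gene, rsid, chrom, pos, ref, alt, sibs, father, mother, aa_change,
# maf_1000g, maf_esp, q2_esp, sift, polyphen2, fathmm, siphy, section
#
# Genotypes are allele-letter pairs (both sibs carry the same genotype).
# The CA9 row's alleles are normalized so that the sibs' homozygous
# allele is the alternate (ref/alt orientation as in the VCF sense).
_VARIANT_ROWS = [
    ("FANCP/SLX4", "rs79842542", "16", 3656625, "G", "A", "GA", "GA", "GG",
     "R204C", 0.06, 0.071264, None, 0.0, 1.0, 3.49, 12.9, "compound_het"),
    ("FANCP/SLX4", "rs137976282", "16", 3658545, "C", "A", "CA", "CC", "CA",
     "G141W", 0.0, 0.00077, None, 0.0, 0.964, 5.2, 7.27, "compound_het"),
    ("CEP55", "rs75139274", "10", 95278683, "G", "A", "GA", "GA", "GG",
     "R348K", 0.03, 0.074581, None, 0.19, 0.21, 2.05, 11.44, "compound_het"),
    ("CEP55", "rs2293277", "10", 95279506, "A", "T", "AT", "AA", "AT",
     "H378L", 0.56, 0.610257, None, 0.13, 0.48, 2.21, 14.69, "compound_het"),
    ("DNAH2", "rs140035206", "17", 7673930, "A", "G", "AG", "AG", "AA",
     "Y1385C", 0.0, 0.004075, None, 0.0, 1.0, -0.15, 15.1, "compound_het"),
    ("DNAH2", "rs79350244", "17", 7734114, "A", "C", "AC", "AA", "AC",
     "I4023L", 0.01, 0.021913, None, 1.0, 0.52, 3.81, 15.2, "compound_het"),
    ("DNAH2", "rs117465420", "17", 7734476, "A", "T", "AT", "AA", "AT",
     "L4062F", 0.01, 0.021759, None, 0.02, 0.41, 3.06, 8.22, "compound_het"),
    ("DNAH2", "rs78354379", "17", 7736480, "T", "A", "TA", "TA", "TT",
     "V4357D", 0.05, 0.008073, None, 0.03, 0.99, 2.95, 12.12, "compound_het"),
    ("PDE4DIP", "rs1778120", "1", 144879090, "C", "T", "CT", "CT", "TT",
     "K1410E", None, 0.124712, None, 0.11, 1.0, 4.64, 11.54, "compound_het"),
    ("PDE4DIP", "rs1698683", "1", 144916676, "C", "T", "CT", "CC", "CT",
     "W626*", None, 0.321203, None, 0.16, None, 3.81, 18.03, "compound_het"),
    ("GEN1", "rs16981869", "2", 17946243, "A", "G", "GG", "AG", "AG",
     "N143S", 0.13, 0.145394, 0.025, 0.03, 0.81, -0.45, 8.03, "homozygous"),
    ("B3GALTL", "rs1041073", "13", 31891746, "G", "A", "AA", "GA", "GA",
     "E370K", 0.67, 0.65539, 0.442, 0.28, 0.96, -1.92, 7.09, "homozygous"),
    ("CA9", "rs2071676", "9", 35674053, "G", "A", "AA", "AG", "AG",
     "V33L", 0.32, 0.269107, 0.56, 0.0, 0.82, -0.66, 8.01, "homozygous"),
    ("CHIT1", "rs2297950", "1", 203194186, "C", "T", "TT", "TC", "TC",
     "G102S", 0.29, 0.285253, 0.065, 0.0, 1.0, 3.81, 7.76, "homozygous"),
    ("CHRNB1", "rs17856697", "17", 7348625, "A", "G", "GG", "GA", "GA",
     "E32G", 0.12, 0.25585, 0.052, 0.08, 0.77, -1.16, 8.74, "homozygous"),
    ("ERBB2", "rs1058808", "17", 37884037, "C", "G", "GG", "GC", "GC",
     "P1170A", 0.45, 0.513532, 0.278, 0.03, 0.95, -0.81, 18.01, "homozygous"),
    ("ZNF207", "rs3795244", "17", 30692396, "G", "T", "TT", "TG", "TG",
     "A240S", 0.05, 0.045748, 0.001, 0.41, 0.75, 0.85, 20.21, "homozygous"),
]

COMPOUND_HET_GENES = ["FANCP/SLX4", "CEP55", "DNAH2", "PDE4DIP"]
HOMOZYGOUS_GENES = ["GEN1", "B3GALTL", "CA9", "CHIT1", "CHRNB1", "ERBB2", "ZNF207"]


def variant_table() -> pd.DataFrame:
    """The shared-variant table in annotation-TSV column layout."""
    rows = []
    for (gene, rsid, chrom, pos, ref, alt, _s, _f, _m, aa, m1k, mesp, q2,
         sift, pp2, fathmm, siphy, _section) in _VARIANT_ROWS:
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "rsid": rsid,
                "gene": gene,
                "consequence": "stop_gain" if aa.endswith("*") else "missense",
                "aa_change": aa,
                "maf_1000g": "-" if m1k is None else m1k,
                "maf_esp": "-" if mesp is None else mesp,
                "q2_esp": "-" if q2 is None else q2,
                "sift": "-" if sift is None else sift,
                "polyphen2": "-" if pp2 is None else pp2,
                "fathmm": "-" if fathmm is None else fathmm,
                "siphy": "-" if siphy is None else siphy,
            }
        )
    return pd.DataFrame(rows)


def _letters_to_call(gt: str, ref: str, alt: str) -> GenotypeCall:
    idx = {ref: 0, alt: 1}
    return GenotypeCall(alleles=tuple(idx[ch] for ch in gt))


def quad_genotypes() -> FamilyGenotypes:
    """Family genotype matrix for the shared-variant table sites."""
    ped = quad_pedigree()
    sites: list[VariantSite] = []
    calls = {}
    for (_gene, rsid, chrom, pos, ref, alt, sibs_gt, f_gt, m_gt,
         *_rest) in _VARIANT_ROWS:
        site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid)
        sites.append(site)
        calls[(site.key, SIB_A)] = _letters_to_call(sibs_gt, ref, alt)
        calls[(site.key, SIB_B)] = _letters_to_call(sibs_gt, ref, alt)
        calls[(site.key, FATHER)] = _letters_to_call(f_gt, ref, alt)
        calls[(site.key, MOTHER)] = _letters_to_call(m_gt, ref, alt)
    return FamilyGenotypes(sites=sites, calls=calls, sample_ids=ped.sample_ids)


def quad_annotations() -> list[AnnotatedVariant]:
    """AnnotatedVariant objects for the shared-variant table."""
    out = []
    for (gene, rsid, chrom, pos, ref, alt, _s, _f, _m, aa, m1k, mesp, q2,
         sift, pp2, fathmm, siphy, _section) in _VARIANT_ROWS:
        out.append(
            AnnotatedVariant(
                site=VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid),
                gene=gene,
                consequence=(
                    Consequence.STOP_GAIN if aa.endswith("*") else Consequence.MISSENSE
                ),
                aa_change=aa,
                maf_1000g=m1k,
                maf_esp=mesp,
                q2_esp=q2,
                sift=sift,
                polyphen2=pp2,
                fathmm=fathmm,
                siphy=siphy,
            )
        )
    return out


def fanca_variant() -> AnnotatedVariant:
    """The rare shared heterozygous FANCA variant (rs61753269).

    Only Fathmm scores it damaging (-1.78); the SiPhy score (12.742)
    marks a strongly conserved position.  Both population MAFs were
    below 1e-3; the databases' exact values were not printed, so the
    frequency fields are left unset here.  The position is a synthetic
    placeholder; the variant is addressed by rsid.
    """
    return AnnotatedVariant(
        site=VariantSite(chrom="16", pos=89_800_000, ref="G", alt="A",
                         rsid="rs61753269"),
        gene="FANCA",
        consequence=Consequence.MISSENSE,
        fathmm=-1.78,
        siphy=12.742,
    )


# gene, rsid, ref allele, sib A genotype, sib B genotype ("-" = missing)
_RISK_LOCI = [
    ("ARID5B", "rs7073837", "C", "-", "AA"),
    ("ARID5B", "rs10994982", "G", "GG", "GA"),
    ("ARID5B", "rs10740055", "A", "-", "CC"),
    ("ARID5B", "rs10821936", "T", "-", "CC"),
    ("ARID5B", "rs7089424", "T", "-", "GG"),
    ("CEBPE", "rs2239633", "C", "CT", "TT"),
    ("DDC", "rs7809758", "A", "AG", "AG"),
    ("DDC", "rs880028", "T", "TC", "TC"),
    ("DDC", "rs3779084", "T", "TC", "TC"),
    ("DDC", "rs2242041", "C", "GG", "CG"),
    ("IKZF1", "rs6964823", "G", "GA", "GA"),
    ("IKZF1", "rs11978267", "A", "-", "AG"),
    ("IKZF1", "rs4132601", "T", "-", "TG"),
    ("IKZF1", "rs6944602", "G", "GG", "GG"),
    ("OR2C3", "rs1881797", "T", "TT", "-"),
    ("CDKN2A", "rs36228834", "T", "TT", "TT"),
]

_RISK_GENE_CHROM = {
    "ARID5B": "10",
    "CEBPE": "14",
    "DDC": "7",
    "IKZF1": "7",
    "OR2C3": "1",
    "CDKN2A": "9",
}


def susceptibility_loci() -> pd.DataFrame:
    """The common ALL susceptibility loci genotyped in the sibs."""
    return pd.DataFrame(
        [{"gene": g, "rsid": r, "ref": ref} for g, r, ref, _a, _b in _RISK_LOCI]
    )


def susceptibility_family() -> FamilyGenotypes:
    """Sib genotypes at the susceptibility loci (parents untyped).

    Positions are synthetic placeholders (per-gene chromosome, rsid is
    the key); loci the report marked "-" become missing-flagged calls.
    """
    ped = quad_pedigree()
    sites: list[VariantSite] = []
    calls = {}
    for i, (gene, rsid, ref, a_gt, b_gt) in enumerate(_RISK_LOCI):
        letters = {ch for gt in (a_gt, b_gt) if gt != "-" for ch in gt}
        alts = sorted(letters - {ref})
        alt = alts[0] if alts else ("A" if ref != "A" else "G")
        site = VariantSite(
            chrom=_RISK_GENE_CHROM[gene],
            pos=900_000_001 + i,
            ref=ref,
            alt=alt,
            rsid=rsid,
        )
        sites.append(site)
        for sample, gt in ((SIB_A, a_gt), (SIB_B, b_gt)):
            if gt == "-":
                calls[(site.key, sample)] = GenotypeCall(missing=True)
            else:
                calls[(site.key, sample)] = _letters_to_call(gt, ref, alt)
        calls[(site.key, FATHER)] = GenotypeCall(missing=True)
        calls[(site.key, MOTHER)] = GenotypeCall(missing=True)
    return FamilyGenotypes(sites=sites, calls=calls, sample_ids=ped.sample_ids)
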