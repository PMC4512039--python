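"""The data-reduction cascade for a sequenced sibship.

Given called genotypes for an affected sibship and both parents, the
cascade removes Mendelian-inconsistent sites (a sequencing-error filter:
a child genotype that cannot be formed from one gamete of each parent is
far more likely a miscall than a true event), keeps sites shared by every
affected sib, restricts to protein-altering consequences, and classifies
the surviving genes under a recessive disease model:

* ``homozygous_recessive`` - every affected sib homozygous for the
  alternate allele, both parents carriers;
* ``compound_het`` - two or more shared heterozygous variants in one gene
  with at least one resolved paternal and one resolved maternal origin
  (trans configuration inferred from transmission, not read phasing);
* ``compound_het_ambiguous`` - two or more shared het variants whose
  parental origins cannot be resolved to opposite parents;
* ``x_hemizygous`` - male sibs hemizygous for the alternate allele on X
  with a carrier mother.

Separate screens cover de novo candidates (private to the sibship, zero
supporting reads in either parent at adequate coverage) and the X
chromosome.  Every stage logs its input/output counts to a
:class:`FilterTrace`, which is the audit artifact of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .consensus import (
    ConsensusVerdict,
    RarityVerdict,
    Thresholds,
    consequence_filter,
    damaging_calls,
    is_rare,
    pair_is_rare,
)
from .family import (
    AnnotatedVariant,
    Affection,
    FamilyGenotypes,
    GenotypeCall,
    Pedigree,
    Sex,
    SiteKey,
    VariantSite,
    is_autosome,
    is_x_chromosome,
)

__all__ = [
    "Origin",
    "InheritanceClass",
    "CandidateGene",
    "FilterTrace",
    "PipelineConfig",
    "UnsupportedChromosomeError",
    "mendelian_consistent",
    "shared_by_affected",
    "parental_origin",
    "classify_gene",
    "denovo_screen",
    "x_linked_screen",
    "run_reduction",
]


class UnsupportedChromosomeError(ValueError):
    """Raised for chromosomes outside the autosomes and X."""


class Origin(Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    AMBIGUOUS = "ambiguous"
    INCONSISTENT = "inconsistent"


class InheritanceClass(Enum):
    HOMOZYGOUS_RECESSIVE = "homozygous_recessive"
    COMPOUND_HET = "compound_het"
    COMPOUND_HET_AMBIGUOUS = "compound_het_ambiguous"
    X_HEMIZYGOUS = "x_hemizygous"
    DE_NOVO = "de_novo"
    NONE = "none"


@dataclass
class CandidateGene:
    """A gene-level recessive candidate with its defining variants."""

    gene: str
    variants: list[AnnotatedVariant]
    klass: InheritanceClass
    origins: dict[SiteKey, Origin] = field(default_factory=dict)
    rarity: RarityVerdict | None = None
    consensus: dict[SiteKey, ConsensusVerdict] = field(default_factory=dict)
    prioritized: bool = False

    @property
    def in_compound_het_section(self) -> bool:
        return self.klass in (
            InheritanceClass.COMPOUND_HET,
            InheritanceClass.COMPOUND_HET_AMBIGUOUS,
        )


@dataclass
class FilterTrace:
    """Ordered per-stage input/output counts for the reduction cascade."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name!r}: n_out {n_out} > n_in {n_in}")
        if min(n_in, n_out) < 0:
            raise ValueError("negative stage counts")
        self.stages.append((name, n_in, n_out))

    def as_dict(self) -> dict[str, dict[str, int]]:
        return {name: {"n_in": i, "n_out": o} for name, i, o in self.stages}


@dataclass(frozen=True)
class PipelineConfig:
    """Behavioural switches and thresholds for the cascade.

    shared_mode
        ``identity`` (default): every affected sib must carry the same
        non-reference genotype; ``carrier``: every sib carries at least
        one alternate allele.
    missing_policy
        ``strict`` (default): a missing call in any required family
        member fails the site at QC; ``lenient``: missing calls pass QC
        and Mendelian checks as unknown.
    min_parent_depth
        De novo screen: minimum parental coverage (reads) required to
        accept zero alternate reads as evidence of absence.
    """

    thresholds: Thresholds = field(default_factory=Thresholds)
    shared_mode: str = "identity"
    missing_policy: str = "strict"
    min_parent_depth: int = 8

    def __post_init__(self) -> None:
        if self.shared_mode not in ("identity", "carrier"):
            raise ValueError("shared_mode must be 'identity' or 'carrier'")
        if self.missing_policy not in ("strict", "lenient"):
            raise ValueError("missing_policy must be 'strict' or 'lenient'")


# ---------------------------------------------------------------------------
# Per-site checks


def mendelian_consistent(
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    chrom: str = "1",
    child_sex: Sex = Sex.UNKNOWN,
) -> bool:
    """Can the child genotype arise from one gamete of each parent?

    Autosomes: one allele from each parent.  Male X: the single
    hemizygous allele must be transmissible by the mother.  Female X: the
    father contributes his hemizygous allele.  Y and mitochondrial sites
    are unsupported.
    """
    if not (is_autosome(chrom) or is_x_chromosome(chrom)):
        raise UnsupportedChromosomeError(
            f"Mendelian check unsupported on chromosome {chrom!r}"
        )
    if child.missing or father.missing or mother.missing:
        raise ValueError("Mendelian check requires non-missing calls")
    if is_x_chromosome(chrom) and child_sex is Sex.MALE:
        if len(child.alleles) == 2:
            # diploid-encoded male X: a het call is impossible
            if child.alleles[0] != child.alleles[1]:
                return False
            allele = child.alleles[0]
        else:
            allele = child.alleles[0]
        return allele in mother.alleles
    child_pair = tuple(sorted(child.alleles))
    if len(child_pair) != 2:
        return False  # hemizygous call at a site needing two gametes
    for p in set(father.alleles):
        for m in set(mother.alleles):
            if tuple(sorted((p, m))) == child_pair:
                return True
    return False


def shared_by_affected(
    site: VariantSite,
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    mode: str = "identity",
) -> bool:
    """Do all affected sibs share the variant at this site?

    ``identity`` requires the same non-reference unordered genotype in
    every affected sib; ``carrier`` only requires each sib to carry at
    least one alternate allele.  A missing call in any affected sib fails.
    """
    sibs = pedigree.affected_sibs()
    if not sibs:
        raise ValueError("no affected sibs in pedigree")
    calls = [fam.call(site, s.sample_id) for s in sibs]
    if any(c.missing for c in calls):
        return False
    if not all(c.carries_alt for c in calls):
        return False
    if mode == "carrier":
        return True
    first = calls[0].alleles
    return all(c.alleles == first for c in calls[1:])


def parental_origin(
    site: VariantSite, fam: FamilyGenotypes, pedigree: Pedigree
) -> Origin:
    """Which parent transmitted the alternate allele the het sibs carry?

    Resolution is by carrier status: paternal when only the father
    carries the allele, maternal when only the mother does, ambiguous
    when both do, inconsistent when neither does (transmission would be
    impossible under Mendelian rules).
    """
    father, mother = pedigree.shared_parents()
    for sib in pedigree.affected_sibs():
        call = fam.call(site, sib.sample_id)
        if not call.is_het:
            raise ValueError(
                f"parental origin requires het sibs at {site.chrom}:{site.pos}"
            )
    f_call = fam.call(site, father.sample_id)
    m_call = fam.call(site, mother.sample_id)
    if f_call.missing or m_call.missing:
        raise ValueError("parental origin requires non-missing parental calls")
    f_has, m_has = f_call.carries_alt, m_call.carries_alt
    if f_has and not m_has:
        return Origin.PATERNAL
    if m_has and not f_has:
        return Origin.MATERNAL
    if f_has and m_has:
        return Origin.AMBIGUOUS
    return Origin.INCONSISTENT


# ---------------------------------------------------------------------------
# Gene-level classification


def _required_members(pedigree: Pedigree) -> list[str]:
    father, mother = pedigree.shared_parents()
    return [s.sample_id for s in pedigree.affected_sibs()] + [
        father.sample_id,
        mother.sample_id,
    ]


def _usable(fam: FamilyGenotypes, site: VariantSite, members: Sequence[str]) -> bool:
    return all(not fam.call(site, m).missing for m in members)


def classify_gene(
    gene: str,
    variants: Sequence[AnnotatedVariant],
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    config: PipelineConfig | None = None,
) -> CandidateGene:
    """Assign one recessive-model inheritance class to a gene.

    Precedence: X-hemizygous (male sibs, X sites) > homozygous recessive
    > compound het (resolved trans) > compound het with ambiguous phase >
    none.  Variants are assumed to have passed the upstream site filters.
    """
    if not variants:
        raise ValueError("classify_gene requires a non-empty variant list")
    cfg = config or PipelineConfig()
    sibs = pedigree.affected_sibs()
    father, mother = pedigree.shared_parents()
    members = _required_members(pedigree)

    usable = [v for v in variants if _usable(fam, v.site, members)]

    # X-linked hemizygous pattern for an all-male affected sibship
    male_sibs = [s for s in sibs if s.sex is Sex.MALE]
    x_variants = [v for v in usable if is_x_chromosome(v.site.chrom)]
    if x_variants and male_sibs and len(male_sibs) == len(sibs):
        hits = []
        for v in x_variants:
            sib_calls = [fam.call(v.site, s.sample_id) for s in male_sibs]
            m_call = fam.call(v.site, mother.sample_id)
            if all(c.is_hemizygous and c.carries_alt for c in sib_calls) and m_call.carries_alt:
                hits.append(v)
        if hits:
            return CandidateGene(
                gene=gene,
                variants=hits,
                klass=InheritanceClass.X_HEMIZYGOUS,
                origins={v.site.key: Origin.MATERNAL for v in hits},
            )

    autosomal = [v for v in usable if is_autosome(v.site.chrom)]

    hom_hits = []
    for v in autosomal:
        sib_calls = [fam.call(v.site, s.sample_id) for s in sibs]
        f_call = fam.call(v.site, father.sample_id)
        m_call = fam.call(v.site, mother.sample_id)
        if (
            all(c.is_hom_alt and not c.is_hemizygous for c in sib_calls)
            and f_call.carries_alt
            and m_call.carries_alt
        ):
            hom_hits.append(v)
    if hom_hits:
        return CandidateGene(
            gene=gene, variants=hom_hits, klass=InheritanceClass.HOMOZYGOUS_RECESSIVE
        )

    het_hits = []
    origins: dict[SiteKey, Origin] = {}
    for v in autosomal:
        sib_calls = [fam.call(v.site, s.sample_id) for s in sibs]
        if all(c.is_het for c in sib_calls):
            het_hits.append(v)
            origins[v.site.key] = parental_origin(v.site, fam, pedigree)
    if len(het_hits) >= 2:
        vals = set(origins[v.site.key] for v in het_hits)
        if Origin.PATERNAL in vals and Origin.MATERNAL in vals:
            return CandidateGene(
                gene=gene,
                variants=het_hits,
                klass=InheritanceClass.COMPOUND_HET,
                origins=origins,
            )
        if Origin.AMBIGUOUS in vals:
            return CandidateGene(
                gene=gene,
                variants=het_hits,
                klass=InheritanceClass.COMPOUND_HET_AMBIGUOUS,
                origins=origins,
            )
    return CandidateGene(
        gene=gene,
        variants=list(variants),
        klass=InheritanceClass.NONE,
        origins=origins,
    )


# ---------------------------------------------------------------------------
# Screens


def denovo_screen(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    freqs: Mapping[SiteKey, AnnotatedVariant] | Iterable[AnnotatedVariant] | None = None,
    min_parent_depth: int = 8,
    trace: FilterTrace | None = None,
) -> list[VariantSite]:
    """Putative de novo events: private mutations shared by the sibship.

    A site is retained when (a) every affected sib carries the alternate
    allele, (b) the site has no recorded frequency in any supplied
    population table (absence = privacy), (c) both parents show zero
    alternate-supporting reads, and (d) both parents are covered at
    ``min_parent_depth`` or more reads.  Parents lacking depth
    information exclude the site ("insufficient parental coverage").
    """
    ann = _freqs_to_map(freqs)
    father, mother = pedigree.shared_parents()
    sibs = pedigree.affected_sibs()
    out: list[VariantSite] = []
    n_insufficient = 0
    for site in fam.sites:
        sib_calls = [fam.call(site, s.sample_id) for s in sibs]
        if any(c.missing or not c.carries_alt for c in sib_calls):
            continue
        a = ann.get(site.key)
        if a is not None and any(
            x is not None for x in (a.maf_1000g, a.maf_esp, a.q2_esp)
        ):
            continue  # known to the databases: not private
        ok = True
        for parent in (father, mother):
            c = fam.call(site, parent.sample_id)
            if c.missing or c.depth is None or c.alt_depth is None:
                n_insufficient += 1
                ok = False
                break
            if c.alt_depth != 0 or c.depth < min_parent_depth:
                ok = False
                break
        if ok:
            out.append(site)
    if trace is not None:
        trace.add("de_novo_screen", len(fam.sites), len(out))
        trace.add(
            "insufficient_parental_coverage",
            n_insufficient,
            0,
        )
    return out


def _freqs_to_map(freqs) -> dict[SiteKey, AnnotatedVariant]:
    if freqs is None:
        return {}
    if isinstance(freqs, Mapping):
        return dict(freqs)
    return {v.site.key: v for v in freqs}


def x_linked_screen(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    annotations: Mapping[SiteKey, AnnotatedVariant] | Iterable[AnnotatedVariant] | None = None,
) -> list[CandidateGene]:
    """X-chromosome screen for an all-male affected sibship.

    Returns gene-level candidates where every affected male sib is
    hemizygous for the alternate allele and the mother is a carrier.
    Sites with hemizygous-alt sibs but a non-carrier mother are
    transmission-inconsistent and excluded.
    """
    ann = _freqs_to_map(annotations)
    sibs = [s for s in pedigree.affected_sibs() if s.sex is Sex.MALE]
    if not sibs:
        return []
    _, mother = pedigree.shared_parents()
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for site in fam.sites:
        if not is_x_chromosome(site.chrom):
            continue
        sib_calls = [fam.call(site, s.sample_id) for s in sibs]
        if any(c.missing for c in sib_calls):
            continue
        if not all(c.is_hemizygous and c.carries_alt for c in sib_calls):
            continue
        m_call = fam.call(site, mother.sample_id)
        if m_call.missing or not m_call.carries_alt:
            continue  # maternal transmission impossible: flagged out
        v = ann.get(site.key) or AnnotatedVariant(site=site)
        gene = v.gene or f"{site.chrom}:{site.pos}"
        by_gene.setdefault(gene, []).append(v)
    return [
        CandidateGene(
            gene=g,
            variants=vs,
            klass=InheritanceClass.X_HEMIZYGOUS,
            origins={v.site.key: Origin.MATERNAL for v in vs},
        )
        for g, vs in by_gene.items()
    ]


# ---------------------------------------------------------------------------
# The full cascade


def _prioritize(cand: CandidateGene, t: Thresholds) -> tuple[RarityVerdict, bool]:
    """Gene-level rarity + damaging-consensus decision.

    Homozygous/X candidates need one defining variant that is rare (class
    rule) and putatively damaging.  Compound-het candidates need a trans
    pair (one paternal- or ambiguous-, one maternal- or ambiguous-origin
    variant from opposite parents when resolved) that passes the pair
    rarity rule with both members putatively damaging.
    """
    verdicts = {v.site.key: damaging_calls(v, t) for v in cand.variants}
    cand.consensus = verdicts
    if cand.klass in (
        InheritanceClass.HOMOZYGOUS_RECESSIVE,
        InheritanceClass.X_HEMIZYGOUS,
    ):
        best: RarityVerdict | None = None
        ok = False
        for v in cand.variants:
            r = is_rare(v, cand.klass, t)
            if best is None or (r.is_rare and not best.is_rare):
                best = r
            if r.is_rare and verdicts[v.site.key].putatively_damaging:
                ok = True
        return best, ok
    if cand.in_compound_het_section:
        paternal_side = [
            v
            for v in cand.variants
            if cand.origins.get(v.site.key) in (Origin.PATERNAL, Origin.AMBIGUOUS)
        ]
        maternal_side = [
            v
            for v in cand.variants
            if cand.origins.get(v.site.key) in (Origin.MATERNAL, Origin.AMBIGUOUS)
        ]
        best = None
        ok = False
        for p in paternal_side:
            for m in maternal_side:
                if p.site.key == m.site.key:
                    continue
                r = pair_is_rare([p, m], t)
                if best is None or (r.is_rare and not best.is_rare):
                    best = r
                if (
                    r.is_rare
                    and verdicts[p.site.key].putatively_damaging
                    and verdicts[m.site.key].putatively_damaging
                ):
                    ok = True
        if best is None:
            best = pair_is_rare(cand.variants, t)
        return best, ok
    return pair_is_rare(cand.variants, t), False


def run_reduction(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    annotations: Iterable[AnnotatedVariant],
    config: PipelineConfig | None = None,
) -> tuple[list[CandidateGene], FilterTrace]:
    """Run the full site-level cascade and gene-level classification.

    Stage order: QC/missingness -> Mendelian filter -> shared-by-affected
    -> consequence filter -> recessive classification -> rarity and
    consensus annotation (prioritization).  Returns every classified
    candidate gene (``prioritized`` marks those passing rarity and the
    damaging consensus) plus the per-stage :class:`FilterTrace`.
    """
    cfg = config or PipelineConfig()
    ann_map = _freqs_to_map(annotations)
    trace = FilterTrace()
    sibs = pedigree.affected_sibs()
    if not sibs:
        raise ValueError("pipeline requires at least one affected sib")
    father, mother = pedigree.shared_parents()
    members = _required_members(pedigree)
    sex_by_id = {e.sample_id: e.sex for e in pedigree.entries}

    # QC: unsupported chromosomes and (strict mode) missing calls
    sites = list(fam.sites)
    kept: list[VariantSite] = []
    for site in sites:
        if not (is_autosome(site.chrom) or is_x_chromosome(site.chrom)):
            continue
        if cfg.missing_policy == "strict" and not _usable(fam, site, members):
            continue
        kept.append(site)
    trace.add("qc_missingness", len(sites), len(kept))

    # Mendelian filter: every affected-sib trio must be consistent
    mendel_kept: list[VariantSite] = []
    for site in kept:
        f_call = fam.call(site, father.sample_id)
        m_call = fam.call(site, mother.sample_id)
        ok = True
        for sib in sibs:
            c = fam.call(site, sib.sample_id)
            if c.missing or f_call.missing or m_call.missing:
                if cfg.missing_policy == "lenient":
                    continue  # unknown passes
                ok = False
                break
            if not mendelian_consistent(
                c, f_call, m_call, site.chrom, sex_by_id[sib.sample_id]
            ):
                ok = False
                break
        if ok:
            mendel_kept.append(site)
    trace.add("mendelian_filter", len(kept), len(mendel_kept))

    # Shared by both (all) affected sibs
    shared_kept = [
        s
        for s in mendel_kept
        if shared_by_affected(s, fam, pedigree, mode=cfg.shared_mode)
    ]
    trace.add("shared_by_affected", len(mendel_kept), len(shared_kept))

    # Protein-altering consequence
    cons_kept = [
        s
        for s in shared_kept
        if s.key in ann_map and consequence_filter(ann_map[s.key])
    ]
    trace.add("consequence_filter", len(shared_kept), len(cons_kept))

    # Gene-level recessive classification
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for s in cons_kept:
        v = ann_map[s.key]
        gene = v.gene or f"{s.chrom}:{s.pos}"
        by_gene.setdefault(gene, []).append(v)
    candidates = []
    for gene, variants in by_gene.items():
        cand = classify_gene(gene, variants, fam, pedigree, cfg)
        if cand.klass is not InheritanceClass.NONE:
            candidates.append(cand)
    n_classified_sites = sum(len(c.variants) for c in candidates)
    trace.add("classification", len(cons_kept), min(n_classified_sites, len(cons_kept)))

    # Rarity + consensus annotation; prioritized = passes both
    for cand in candidates:
        rarity, ok = _prioritize(cand, cfg.thresholds)
        cand.rarity = rarity
        cand.prioritized = ok
    n_prior = sum(1 for c in candidates if c.prioritized)
    trace.add("prioritization", len(candidates), n_prior)
    return candidates, trace
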