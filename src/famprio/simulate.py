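"""Seeded generator of quad-family exome-like datasets with known truth.

The generator emulates the statistical structure the filtering cascade
assumes: biallelic autosomal and X sites with population allele
frequencies from a rare/common mixture, parental genotypes drawn at
Hardy-Weinberg equilibrium, child genotypes by fair Mendelian
transmission (siblings independent given the parents - no linkage, so
sharing probabilities are analytic), optional per-call genotyping error,
and Poisson read depths with binomial allele-depth sampling.  Disease
configurations (compound het, homozygous recessive, de novo, X-linked)
are spiked in as extra sites with genotype patterns written directly and
recorded in a :class:`TruthSet`, so recall and false-positive behaviour
of the full pipeline can be measured exactly.

Depth defaults (28.1X for the sibship, 19.4X for the parents) mirror a
realistic exome design where parents are sequenced shallower than the
probands.  Spiked variants receive scores that all three tools call
damaging (Sift 0.0, Polyphen2 1.0, Fathmm -3.0); background variants
draw benign scores, with a configurable probability of drawing damaging
ones instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .family import (
    ANNOTATION_COLUMNS,
    Affection,
    AnnotatedVariant,
    Consequence,
    FamilyGenotypes,
    GenotypeCall,
    Pedigree,
    PedigreeEntry,
    Sex,
    SiteKey,
    VariantSite,
    is_x_chromosome,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "SpikeRecord",
    "TruthSet",
    "SCENARIOS",
    "make_quad_pedigree",
    "simulate_sites",
    "simulate_family",
    "simulate_quad",
    "simulate_cohort",
    "write_fixture",
]

SCENARIOS = ("compound_het", "hom_recessive", "de_novo", "x_linked")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated quad dataset.

    ``frac_rare`` of the background sites draw MAF log-uniformly on
    [1e-5, 1e-3] ("extremely rare" stratum); the remainder draw
    uniformly on [0.01, 0.5].  ``genotyping_error`` is the per-call
    probability that a diploid genotype is replaced by one of the other
    two genotypes (uniformly), or that a hemizygous allele flips.
    """

    n_sites: int = 1000
    seed: int = 0
    frac_rare: float = 0.3
    rare_maf_range: tuple[float, float] = (1e-5, 1e-3)
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    frac_x: float = 0.05
    genotyping_error: float = 0.0
    depth_mean_sibs: float = 28.1
    depth_mean_parents: float = 19.4
    min_parent_depth: int = 8
    sites_per_gene: int = 5
    background_damaging_prob: float = 0.0
    spike_ins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("frac_rare", "frac_x", "genotyping_error", "background_damaging_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for s in self.spike_ins:
            if s not in SCENARIOS:
                raise ValueError(f"unknown spike-in scenario {s!r}")


@dataclass(frozen=True)
class SpikeRecord:
    gene: str
    scenario: str
    site_keys: tuple[SiteKey, ...]


@dataclass
class TruthSet:
    spiked: list[SpikeRecord] = field(default_factory=list)

    def genes(self) -> set[str]:
        return {r.gene for r in self.spiked}

    def by_scenario(self, scenario: str) -> list[SpikeRecord]:
        return [r for r in self.spiked if r.scenario == scenario]


def make_quad_pedigree(
    sib_ids: tuple[str, str] = ("sibA", "sibB"),
    father_id: str = "father",
    mother_id: str = "mother",
    sib_sexes: tuple[Sex, Sex] = (Sex.MALE, Sex.MALE),
) -> Pedigree:
    """A quad: two affected sibs (male by default) and both parents."""
    entries = [
        PedigreeEntry(sib_ids[0], father_id, mother_id, sib_sexes[0], Affection.AFFECTED),
        PedigreeEntry(sib_ids[1], father_id, mother_id, sib_sexes[1], Affection.AFFECTED),
        PedigreeEntry(father_id, None, None, Sex.MALE, Affection.UNAFFECTED),
        PedigreeEntry(mother_id, None, None, Sex.FEMALE, Affection.UNAFFECTED),
    ]
    return Pedigree(entries)


# ---------------------------------------------------------------------------
# Site generation

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23}

_CONSEQ_CHOICES = [
    Consequence.MISSENSE,
    Consequence.SYNONYMOUS,
    Consequence.OTHER,
    Consequence.STOP_GAIN,
    Consequence.FRAMESHIFT,
]
_CONSEQ_PROBS = [0.60, 0.25, 0.09, 0.04, 0.02]

_BASES = ["A", "C", "G", "T"]

_DAMAGING_SCORES = {"sift": 0.0, "polyphen2": 1.0, "fathmm": -3.0, "siphy": 15.0}

# Positions reserved for spiked sites sit far above background positions.
_SPIKE_POS_BASE = 900_000_000


def _spike_plan(cfg: SimConfig) -> list[SpikeRecord]:
    """Deterministic sites/genes for each configured spike-in scenario."""
    plan: list[SpikeRecord] = []
    for i, scenario in enumerate(cfg.spike_ins):
        gene = f"SPIKE_{scenario.upper()}_{i}"
        base = _SPIKE_POS_BASE + 10_000 * i
        if scenario == "compound_het":
            keys = (
                ("1", base + 1, "A", "G"),
                ("1", base + 2, "C", "T"),
            )
        elif scenario == "hom_recessive":
            keys = (("2", base + 1, "G", "A"),)
        elif scenario == "de_novo":
            keys = (("3", base + 1, "T", "C"),)
        else:  # x_linked
            keys = (("X", base + 1, "G", "T"),)
        plan.append(SpikeRecord(gene=gene, scenario=scenario, site_keys=keys))
    return plan


def _spike_variants(cfg: SimConfig) -> list[AnnotatedVariant]:
    out: list[AnnotatedVariant] = []
    for rec in _spike_plan(cfg):
        for chrom, pos, ref, alt in rec.site_keys:
            site = VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt)
            if rec.scenario == "de_novo":
                freqs = dict(maf_1000g=None, maf_esp=None, q2_esp=None)
            elif rec.scenario == "hom_recessive":
                freqs = dict(maf_1000g=0.05, maf_esp=0.05, q2_esp=0.0025)
            else:
                freqs = dict(maf_1000g=5e-4, maf_esp=5e-4, q2_esp=None)
            out.append(
                AnnotatedVariant(
                    site=site,
                    gene=rec.gene,
                    consequence=Consequence.MISSENSE,
                    **freqs,
                    **_DAMAGING_SCORES,
                )
            )
    return out


def simulate_sites(cfg: SimConfig) -> list[AnnotatedVariant]:
    """Draw background sites from the MAF mixture, then append spikes.

    Returns annotated variants sorted by (chromosome, position).  The
    true population MAF of each background site is recorded in both
    database fields; the ESP homozygote frequency is its Hardy-Weinberg
    value.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    out: list[AnnotatedVariant] = []
    if n > 0:
        rare = rng.random(n) < cfg.frac_rare
        lo, hi = cfg.rare_maf_range
        mafs = np.where(
            rare,
            np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)),
            rng.uniform(*cfg.common_maf_range, size=n),
        )
        on_x = rng.random(n) < cfg.frac_x
        auto_chrom = rng.integers(1, 23, size=n)
        conseq_idx = rng.choice(len(_CONSEQ_CHOICES), size=n, p=_CONSEQ_PROBS)
        ref_idx = rng.integers(0, 4, size=n)
        alt_shift = rng.integers(1, 4, size=n)
        damaging = rng.random(n) < cfg.background_damaging_prob
        sift = rng.uniform(0.2, 1.0, size=n)
        polyphen2 = rng.uniform(0.0, 0.8, size=n)
        fathmm = rng.uniform(0.0, 5.0, size=n)
        siphy = rng.uniform(0.0, 20.0, size=n)
        pos_counter: dict[str, int] = {}
        n_genes = max(1, n // max(1, cfg.sites_per_gene))
        gene_idx = rng.integers(0, n_genes, size=n)
        for i in range(n):
            chrom = "X" if on_x[i] else str(auto_chrom[i])
            pos_counter[chrom] = pos_counter.get(chrom, 0) + 1
            pos = 1_000_000 + 137 * pos_counter[chrom]
            ref = _BASES[ref_idx[i]]
            alt = _BASES[(ref_idx[i] + alt_shift[i]) % 4]
            maf = float(mafs[i])
            # genes never span chromosomes: X sites get X-specific symbols
            gene = (f"GX{gene_idx[i]:04d}" if chrom == "X" else f"G{gene_idx[i]:04d}")
            scores = (
                dict(_DAMAGING_SCORES)
                if damaging[i]
                else {
                    "sift": round(float(sift[i]), 3),
                    "polyphen2": round(float(polyphen2[i]), 3),
                    "fathmm": round(float(fathmm[i]), 3),
                    "siphy": round(float(siphy[i]), 3),
                }
            )
            out.append(
                AnnotatedVariant(
                    site=VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt),
                    gene=gene,
                    consequence=_CONSEQ_CHOICES[conseq_idx[i]],
                    maf_1000g=round(maf, 6),
                    maf_esp=round(maf, 6),
                    q2_esp=round(maf * maf, 6),
                    **scores,
                )
            )
    out.extend(_spike_variants(cfg))
    out.sort(key=lambda v: (_CHROM_ORDER.get(v.site.chrom, 99), v.site.pos))
    return out


# ---------------------------------------------------------------------------
# Family genotypes


def _apply_error(alleles: tuple[int, ...], eps: float, rng) -> tuple[int, ...]:
    if eps <= 0.0 or rng.random() >= eps:
        return alleles
    if len(alleles) == 1:
        return (1 - alleles[0],)
    current = tuple(sorted(alleles))
    others = [g for g in ((0, 0), (0, 1), (1, 1)) if g != current]
    return others[rng.integers(0, len(others))]


def _depths(alleles: tuple[int, ...], mean: float, rng) -> tuple[int, int]:
    depth = int(rng.poisson(mean))
    if depth == 0:
        return 0, 0
    if len(alleles) == 1:
        frac = float(alleles[0])
    else:
        frac = sum(a != 0 for a in alleles) / 2.0
    alt_depth = int(rng.binomial(depth, frac)) if frac > 0 else 0
    return depth, alt_depth


def simulate_family(
    cfg: SimConfig,
    sites: Sequence[AnnotatedVariant],
    pedigree: Pedigree | None = None,
) -> tuple[FamilyGenotypes, TruthSet]:
    """Draw family genotypes at the given sites; overwrite spiked sites.

    Parents are Hardy-Weinberg draws at the site's true MAF; each sib
    receives one uniformly chosen allele per parent (maternal only on
    male X).  Per-call genotyping error is applied to background sites;
    spiked sites are overwritten afterwards with their scenario pattern,
    so they are error-free by construction.
    """
    ped = pedigree or make_quad_pedigree()
    father, mother = ped.shared_parents()
    sibs = ped.affected_sibs()
    male_sibs = [s for s in sibs if s.sex is Sex.MALE]
    plan = _spike_plan(cfg)
    if any(r.scenario == "x_linked" for r in plan) and len(male_sibs) != len(sibs):
        raise ValueError("x_linked spike-in requires an all-male affected sibship")
    spike_by_key: dict[SiteKey, SpikeRecord] = {
        k: rec for rec in plan for k in rec.site_keys
    }

    rng = np.random.default_rng((cfg.seed, 1))
    sex_by_id = {e.sample_id: e.sex for e in ped.entries}
    calls: dict[tuple[SiteKey, str], GenotypeCall] = {}
    site_objs: list[VariantSite] = []
    for v in sites:
        site = v.site
        site_objs.append(site)
        maf = v.maf_1000g if v.maf_1000g is not None else 0.0
        x = is_x_chromosome(site.chrom)
        f_alleles = (
            (int(rng.random() < maf),)
            if x
            else (int(rng.random() < maf), int(rng.random() < maf))
        )
        m_alleles = (int(rng.random() < maf), int(rng.random() < maf))
        genotypes: dict[str, tuple[int, ...]] = {
            father.sample_id: f_alleles,
            mother.sample_id: m_alleles,
        }
        for sib in sibs:
            m_gamete = m_alleles[rng.integers(0, 2)]
            if x and sex_by_id[sib.sample_id] is Sex.MALE:
                genotypes[sib.sample_id] = (m_gamete,)
            else:
                f_gamete = f_alleles[rng.integers(0, len(f_alleles))]
                genotypes[sib.sample_id] = tuple(sorted((f_gamete, m_gamete)))

        spike = spike_by_key.get(site.key)
        if spike is not None:
            genotypes = _spike_genotypes(
                spike, site, ped, sex_by_id
            )
        elif cfg.genotyping_error > 0:
            genotypes = {
                s: _apply_error(g, cfg.genotyping_error, rng)
                for s, g in genotypes.items()
            }

        for e in ped.entries:
            alleles = genotypes[e.sample_id]
            mean = (
                cfg.depth_mean_sibs
                if e.affected is Affection.AFFECTED
                else cfg.depth_mean_parents
            )
            depth, alt_depth = _depths(alleles, mean, rng)
            if spike is not None and e.sample_id in (
                father.sample_id,
                mother.sample_id,
            ):
                if spike.scenario == "de_novo":
                    # zero alt reads at adequate parental coverage
                    depth = max(depth, cfg.min_parent_depth)
                    alt_depth = 0
            calls[(site.key, e.sample_id)] = GenotypeCall(
                alleles=alleles, depth=depth, alt_depth=alt_depth
            )

    fam = FamilyGenotypes(
        sites=site_objs, calls=calls, sample_ids=[e.sample_id for e in ped.entries]
    )
    present = {s.key for s in site_objs}
    truth = TruthSet(
        spiked=[r for r in plan if all(k in present for k in r.site_keys)]
    )
    return fam, truth


def _spike_genotypes(
    spike: SpikeRecord,
    site: VariantSite,
    ped: Pedigree,
    sex_by_id: dict[str, Sex],
) -> dict[str, tuple[int, ...]]:
    father, mother = ped.shared_parents()
    sibs = ped.affected_sibs()
    g: dict[str, tuple[int, ...]] = {}
    if spike.scenario == "compound_het":
        paternal_site = site.key == spike.site_keys[0]
        g[father.sample_id] = (0, 1) if paternal_site else (0, 0)
        g[mother.sample_id] = (0, 0) if paternal_site else (0, 1)
        for s in sibs:
            g[s.sample_id] = (0, 1)
    elif spike.scenario == "hom_recessive":
        g[father.sample_id] = (0, 1)
        g[mother.sample_id] = (0, 1)
        for s in sibs:
            g[s.sample_id] = (1, 1)
    elif spike.scenario == "de_novo":
        g[father.sample_id] = (0, 0)
        g[mother.sample_id] = (0, 0)
        for s in sibs:
            g[s.sample_id] = (0, 1)
    else:  # x_linked
        g[father.sample_id] = (0,)
        g[mother.sample_id] = (0, 1)
        for s in sibs:
            g[s.sample_id] = (1,)
    return g


def simulate_quad(
    cfg: SimConfig, pedigree: Pedigree | None = None
) -> tuple[Pedigree, list[AnnotatedVariant], FamilyGenotypes, TruthSet]:
    """Convenience wrapper: sites + family genotypes + truth in one call."""
    ped = pedigree or make_quad_pedigree()
    sites = simulate_sites(cfg)
    fam, truth = simulate_family(cfg, sites, ped)
    return ped, sites, fam, truth


# ---------------------------------------------------------------------------
# Cohort simulation (for carrier-count lookups)


def simulate_cohort(
    sites: Sequence[AnnotatedVariant],
    n_trios: int,
    n_singletons: int,
    seed: int,
    double_het_spike: tuple[VariantSite, VariantSite] | None = None,
):
    """Hardy-Weinberg cohort genotypes at the given sites.

    With ``double_het_spike``, exactly one individual (the first) is
    forced heterozygous at both given sites and every other individual
    is forced out of the double-het pattern, so the spiked count is
    exactly one by construction.
    """
    from .panel import CohortRegistry

    rng = np.random.default_rng(seed)
    total = 3 * n_trios + n_singletons
    ids = [f"I{i:05d}" for i in range(total)]
    matrix: dict[tuple[SiteKey, str], GenotypeCall] = {}
    for v in sites:
        maf = v.maf_max if v.maf_max is not None else 0.0
        doses = rng.binomial(2, maf, size=total)
        for ind, dose in zip(ids, doses):
            alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(dose)]
            matrix[(v.site.key, ind)] = GenotypeCall(alleles=alleles)
    if double_het_spike is not None:
        s1, s2 = double_het_spike
        matrix[(s1.key, ids[0])] = GenotypeCall(alleles=(0, 1))
        matrix[(s2.key, ids[0])] = GenotypeCall(alleles=(0, 1))
        for ind in ids[1:]:
            if matrix[(s1.key, ind)].is_het and matrix[(s2.key, ind)].is_het:
                matrix[(s2.key, ind)] = GenotypeCall(alleles=(0, 0))
    return CohortRegistry(
        n_trios=n_trios,
        n_singletons=n_singletons,
        individual_ids=ids,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# Fixture writing


def _annotation_frame(sites: Sequence[AnnotatedVariant]) -> pd.DataFrame:
    rows = []
    for v in sites:
        rows.append(
            {
                "chrom": v.site.chrom,
                "pos": v.site.pos,
                "ref": v.site.ref,
                "alt": v.site.alt,
                "rsid": v.site.rsid or "-",
                "gene": v.gene or "-",
                "consequence": v.consequence.value if v.consequence else "-",
                "aa_change": v.aa_change or "-",
                **{
                    k: ("-" if getattr(v, k) is None else getattr(v, k))
                    for k in (
                        "maf_1000g",
                        "maf_esp",
                        "q2_esp",
                        "sift",
                        "polyphen2",
                        "fathmm",
                        "siphy",
                    )
                },
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_fixture(
    fam: FamilyGenotypes,
    sites: Sequence[AnnotatedVariant],
    pedigree: Pedigree,
    out_dir: str | Path,
    truth: TruthSet | None = None,
) -> dict[str, Path]:
    """Emit VCF + PED + annotation TSV (+ truth JSON); byte-stable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "family.vcf",
        "ped": out / "family.ped",
        "annotations": out / "annotations.tsv",
    }
    write_vcf(fam, pedigree, paths["vcf"])
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    pheno_code = {
        Affection.AFFECTED: "2",
        Affection.UNAFFECTED: "1",
        Affection.UNKNOWN: "0",
    }
    ped_lines = [
        "\t".join(
            [
                "FAM1",
                e.sample_id,
                e.father_id or "0",
                e.mother_id or "0",
                sex_code[e.sex],
                pheno_code[e.affected],
            ]
        )
        for e in pedigree.entries
    ]
    paths["ped"].write_text("\n".join(ped_lines) + "\n")
    _annotation_frame(sites).to_csv(paths["annotations"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = out / "truth.json"
        payload = [
            {
                "gene": r.gene,
                "scenario": r.scenario,
                "sites": [list(k) for k in r.site_keys],
            }
            for r in truth.spiked
        ]
        paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for byte-stability checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
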