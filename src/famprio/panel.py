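"""Gene-panel restriction, cohort carrier counting, risk-locus reporting.

The canonical panel is the 17 Fanconi anemia (FA) complementation-group
genes.  Several FA genes are better known by another symbol (FANCD1 is
BRCA2, FANCP is SLX4, ...), so membership tests resolve aliases and are
case-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .family import FamilyGenotypes, GenotypeCall, Pedigree, SiteKey, VariantSite
from .segregation import CandidateGene

__all__ = [
    "GenePanel",
    "CohortRegistry",
    "fa_panel",
    "restrict_to_panel",
    "count_carriers",
    "cohort_size",
    "susceptibility_report",
]


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols with alias resolution."""

    name: str
    genes: frozenset[str]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a gene panel must be non-empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))
        object.__setattr__(
            self, "aliases", {k.upper(): v.upper() for k, v in self.aliases.items()}
        )

    def canonical(self, symbol: str) -> str:
        """Resolve a symbol (or 'A/B' composite) to its canonical name."""
        s = symbol.upper().strip()
        if "/" in s:
            for part in s.split("/"):
                c = self.canonical(part)
                if c in self.genes:
                    return c
            return s
        return self.aliases.get(s, s)

    def __contains__(self, symbol: str) -> bool:
        return self.canonical(symbol) in self.genes

    def __len__(self) -> int:
        return len(self.genes)


# The 17 FA complementation groups and their common alternate symbols.
_FA_GENES = [
    "FANCA",
    "FANCB",
    "FANCC",
    "FANCD1",
    "FANCD2",
    "FANCE",
    "FANCF",
    "FANCG",
    "FANCI",
    "FANCJ",
    "FANCL",
    "FANCM",
    "FANCN",
    "FANCO",
    "FANCP",
    "FANCQ",
    "FANCS",
]

_FA_ALIASES = {
    "BRCA2": "FANCD1",
    "BRIP1": "FANCJ",
    "PALB2": "FANCN",
    "RAD51C": "FANCO",
    "SLX4": "FANCP",
    "XPF": "FANCQ",
    "ERCC4": "FANCQ",
    "BRCA1": "FANCS",
}


def fa_panel() -> GenePanel:
    """The 17-gene Fanconi anemia panel with alias mapping."""
    return GenePanel(name="fanconi_anemia", genes=frozenset(_FA_GENES), aliases=_FA_ALIASES)


def restrict_to_panel(
    candidates: Sequence[CandidateGene], panel: GenePanel
) -> list[CandidateGene]:
    """Subset candidates whose gene (or an alias of it) is on the panel."""
    return [c for c in candidates if c.gene in panel]


@dataclass
class CohortRegistry:
    """A reference cohort used for carrier lookups.

    ``matrix`` maps (site key, individual id) to a genotype call; absent
    or missing entries count as non-carriers, matching denominators that
    include incompletely covered samples.
    """

    n_trios: int = 0
    n_singletons: int = 0
    individual_ids: list[str] = field(default_factory=list)
    matrix: dict[tuple[SiteKey, str], GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_trios < 0 or self.n_singletons < 0:
            raise ValueError("cohort counts must be non-negative")

    @property
    def total_individuals(self) -> int:
        return 3 * self.n_trios + self.n_singletons

    def sites_present(self) -> set[SiteKey]:
        return {k for (k, _s) in self.matrix}


def cohort_size(registry: CohortRegistry) -> int:
    """Total individuals: three per trio plus the singleton patients."""
    return registry.total_individuals


_CARRIER_MODES = ("any_alt", "hom_alt", "het_at_all_sites")


def count_carriers(
    registry: CohortRegistry,
    sites: Sequence[VariantSite],
    mode: str = "any_alt",
) -> int:
    """Count cohort individuals matching a carrier pattern at the sites.

    ``any_alt``: carries an alternate allele at at least one queried
    site.  ``hom_alt``: homozygous (or hemizygous) alternate at every
    queried site.  ``het_at_all_sites``: heterozygous at every queried
    site (the double-heterozygote lookup).  Missing genotypes are
    non-carriers.
    """
    if mode not in _CARRIER_MODES:
        raise ValueError(f"mode must be one of {_CARRIER_MODES}")
    if not sites:
        raise ValueError("no query sites supplied")
    if not registry.individual_ids:
        return 0
    present = registry.sites_present()
    for s in sites:
        if s.key not in present:
            raise KeyError(f"site {s.key} absent from cohort genotype matrix")

    def _call(site: VariantSite, ind: str) -> GenotypeCall:
        return registry.matrix.get((site.key, ind), GenotypeCall(missing=True))

    n = 0
    for ind in registry.individual_ids:
        calls = [_call(s, ind) for s in sites]
        if mode == "any_alt":
            hit = any(not c.missing and c.carries_alt for c in calls)
        elif mode == "hom_alt":
            hit = all(not c.missing and c.is_hom_alt for c in calls)
        else:
            hit = all(not c.missing and c.is_het for c in calls)
        n += hit
    return n


def susceptibility_report(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    risk_loci: pd.DataFrame,
) -> pd.DataFrame:
    """Per-locus genotypes of the affected sibs at known risk loci.

    ``risk_loci`` needs columns ``gene``, ``rsid`` and ``ref``.  Loci
    absent from the family's genotypes (or missing-flagged) render as
    "-".  Genotypes are rendered as allele-letter strings (e.g. "GA").
    """
    for col in ("gene", "rsid", "ref"):
        if col not in risk_loci.columns:
            raise ValueError(f"risk locus table lacks column {col!r}")
    by_rsid = {s.rsid: s for s in fam.sites if s.rsid is not None}
    sibs = pedigree.affected_sibs()
    rows = []
    for _, locus in risk_loci.iterrows():
        row: dict[str, str] = {
            "gene": locus["gene"],
            "rsid": locus["rsid"],
            "ref": locus["ref"],
        }
        site = by_rsid.get(locus["rsid"])
        for sib in sibs:
            if site is None:
                row[sib.sample_id] = "-"
                continue
            call = fam.call(site, sib.sample_id)
            if call.missing:
                row[sib.sample_id] = "-"
            else:
                letters = {0: site.ref, 1: site.alt}
                row[sib.sample_id] = "".join(letters[a] for a in call.alleles)
        rows.append(row)
    cols = ["gene", "rsid", "ref"] + [s.sample_id for s in sibs]
    return pd.DataFrame(rows, columns=cols)
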