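"""Core data types and readers for family exome data.

Everything downstream of variant calling consumes these containers: a
:class:`Pedigree` describing a nuclear family (the canonical case is a quad
with two affected brothers and both parents), a :class:`FamilyGenotypes`
matrix of per-site, per-sample genotype calls with read depths, and
:class:`AnnotatedVariant` records carrying gene/consequence annotation,
population frequencies (1000 Genomes, ESP) and in-silico deleteriousness
scores (Sift, Polyphen2, Fathmm) plus the SiPhy conservation score.

Coordinates are 1-based throughout, as in VCF.  Genotypes are stored
unphased; parental origin is inferred later from transmission.  Multiallelic
VCF records are split into biallelic sites on load, so the alternate allele
always has index 1 downstream.
"""

from __future__ import annotations

import io
import os
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

__all__ = [
    "Sex",
    "Affection",
    "Consequence",
    "PedigreeEntry",
    "Pedigree",
    "GenotypeCall",
    "VariantSite",
    "AnnotatedVariant",
    "FamilyGenotypes",
    "PedigreeError",
    "load_pedigree",
    "load_variants",
    "merge_annotations",
    "write_vcf",
    "is_x_chromosome",
    "is_autosome",
]


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigrees."""


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Consequence(Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def is_x_chromosome(chrom: str) -> bool:
    return _norm_chrom(chrom).upper() == "X"


def is_autosome(chrom: str) -> bool:
    c = _norm_chrom(chrom)
    return c.isdigit() and 1 <= int(c) <= 22


@dataclass(frozen=True)
class PedigreeEntry:
    sample_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN


@dataclass
class Pedigree:
    """A nuclear (or extended) family; sample ids are unique.

    Validation rejects duplicate ids, parent ids that do not refer to an
    entry in the same pedigree, and ancestry cycles (no sample may be its
    own ancestor).
    """

    entries: list[PedigreeEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise PedigreeError("no samples in pedigree")
        ids = [e.sample_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PedigreeError(f"duplicate sample id(s): {sorted(dupes)}")
        known = set(ids)
        for e in self.entries:
            for pid in (e.father_id, e.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(
                        f"parent id {pid!r} of sample {e.sample_id!r} "
                        "is not in the pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        by_id = self.by_id()
        for start in by_id:
            seen: set[str] = set()
            frontier = [start]
            while frontier:
                cur = frontier.pop()
                e = by_id[cur]
                for pid in (e.father_id, e.mother_id):
                    if pid is None:
                        continue
                    if pid == start:
                        raise PedigreeError(
                            f"sample {start!r} is its own ancestor"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        frontier.append(pid)

    def by_id(self) -> dict[str, PedigreeEntry]:
        return {e.sample_id: e for e in self.entries}

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def affected_sibs(self) -> list[PedigreeEntry]:
        """Affected members with at least one parent in the pedigree."""
        return [
            e
            for e in self.entries
            if e.affected is Affection.AFFECTED
            and (e.father_id is not None or e.mother_id is not None)
        ]

    def parents_of(self, sample_id: str) -> tuple[PedigreeEntry | None, PedigreeEntry | None]:
        e = self.by_id()[sample_id]
        by_id = self.by_id()
        father = by_id.get(e.father_id) if e.father_id else None
        mother = by_id.get(e.mother_id) if e.mother_id else None
        return father, mother

    def shared_parents(self) -> tuple[PedigreeEntry, PedigreeEntry]:
        """Father and mother shared by every affected sib.

        The recessive-model analysis assumes a nuclear sibship; raises if
        the affected sibs do not share both parents.
        """
        sibs = self.affected_sibs()
        if not sibs:
            raise PedigreeError("no affected sibs with parent links")
        fids = {s.father_id for s in sibs}
        mids = {s.mother_id for s in sibs}
        if len(fids) != 1 or len(mids) != 1 or None in fids or None in mids:
            raise PedigreeError("affected sibs do not share both parents")
        by_id = self.by_id()
        return by_id[fids.pop()], by_id[mids.pop()]


_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PED_PHENO = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}


def load_pedigree(ped_text: str) -> Pedigree:
    """Parse 6-column PLINK PED text (FID IID PAT MAT SEX PHENO)."""
    entries: list[PedigreeEntry] = []
    for lineno, line in enumerate(ped_text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"PED line {lineno}: expected 6 whitespace-delimited fields, "
                f"got {len(fields)}"
            )
        _fid, iid, pat, mat, sex, pheno = fields[:6]
        entries.append(
            PedigreeEntry(
                sample_id=iid,
                father_id=None if pat in ("0", "") else pat,
                mother_id=None if mat in ("0", "") else mat,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                affected=_PED_PHENO.get(pheno, Affection.UNKNOWN),
            )
        )
    if not entries:
        raise PedigreeError("no samples in PED input")
    return Pedigree(entries)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one biallelic site.

    ``alleles`` holds allele indices (0 = reference, 1 = alternate), an
    unordered pair for diploid calls and a single index for hemizygous
    calls (male X).  ``alt_depth`` never exceeds ``depth``.  A missing call
    carries no allele information.
    """

    alleles: tuple[int, ...] = ()
    depth: int | None = None
    alt_depth: int | None = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.missing:
            object.__setattr__(self, "alleles", ())
            return
        if len(self.alleles) not in (1, 2):
            raise ValueError("a call is diploid or hemizygous")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if (
            self.depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.depth
        ):
            raise ValueError("alt_depth exceeds depth")

    @property
    def is_hemizygous(self) -> bool:
        return not self.missing and len(self.alleles) == 1

    @property
    def dose(self) -> int:
        """Count of alternate alleles carried (0 if missing)."""
        return sum(1 for a in self.alleles if a != 0)

    @property
    def carries_alt(self) -> bool:
        return self.dose > 0

    @property
    def is_het(self) -> bool:
        return len(self.alleles) == 2 and self.alleles[0] != self.alleles[1]

    @property
    def is_hom_ref(self) -> bool:
        return not self.missing and all(a == 0 for a in self.alleles)

    @property
    def is_hom_alt(self) -> bool:
        return (
            not self.missing
            and len(self.alleles) > 0
            and all(a != 0 for a in self.alleles)
        )


@dataclass(frozen=True, order=True)
class VariantSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A site plus gene/effect annotation, frequencies and scores.

    Frequencies are fractions in [0, 1]; ``q2_esp`` is the observed
    homozygote frequency in ESP and is *not* constrained to be below the
    MAF (database values may depart from Hardy-Weinberg expectations).
    Any field may be None when the databases hold no record.
    """

    site: VariantSite
    gene: str | None = None
    consequence: Consequence | None = None
    aa_change: str | None = None
    maf_1000g: float | None = None
    maf_esp: float | None = None
    q2_esp: float | None = None
    sift: float | None = None
    polyphen2: float | None = None
    fathmm: float | None = None
    siphy: float | None = None

    def __post_init__(self) -> None:
        for name in ("maf_1000g", "maf_esp", "q2_esp"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    @property
    def maf_max(self) -> float | None:
        """Largest MAF across the population databases that report one."""
        vals = [v for v in (self.maf_1000g, self.maf_esp) if v is not None]
        return max(vals) if vals else None


SiteKey = tuple[str, int, str, str]


@dataclass
class FamilyGenotypes:
    """Per-site, per-sample genotype calls for the sequenced family.

    Every (site, sequenced sample) pair has an entry, possibly
    missing-flagged; loaders and the simulator both guarantee this.
    """

    sites: list[VariantSite]
    calls: dict[tuple[SiteKey, str], GenotypeCall]
    sample_ids: list[str]

    def call(self, site: VariantSite, sample_id: str) -> GenotypeCall:
        return self.calls[(site.key, sample_id)]

    def validate_complete(self) -> None:
        for site in self.sites:
            for s in self.sample_ids:
                if (site.key, s) not in self.calls:
                    raise ValueError(
                        f"no call for sample {s!r} at {site.key}"
                    )

    def subset(self, sites: Iterable[VariantSite]) -> "FamilyGenotypes":
        sites = list(sites)
        calls = {
            (site.key, s): self.calls[(site.key, s)]
            for site in sites
            for s in self.sample_ids
        }
        return FamilyGenotypes(sites=sites, calls=calls, sample_ids=list(self.sample_ids))


# ---------------------------------------------------------------------------
# VCF reading / writing


def _normalize_male_x(call: GenotypeCall, chrom: str, sex: Sex) -> GenotypeCall:
    # Male X calls are hemizygous even if the VCF encodes them as a
    # diploid homozygote; a diploid-het male X call is left as-is and is
    # rejected later by the Mendelian check.
    if (
        sex is Sex.MALE
        and is_x_chromosome(chrom)
        and not call.missing
        and len(call.alleles) == 2
        and call.alleles[0] == call.alleles[1]
    ):
        return replace(call, alleles=(call.alleles[0],))
    return call


def load_variants(vcf: str | os.PathLike, pedigree: Pedigree) -> FamilyGenotypes:
    """Read a multi-sample VCF into a :class:`FamilyGenotypes`.

    ``vcf`` is a path, or raw VCF text (detected by a leading ``##``).
    Multiallelic records are split into biallelic sites with genotypes
    remapped (allele k -> 1 at the k-th derived site, every other allele
    -> 0), so downstream code only ever sees alt index 1.  Missing or
    malformed genotypes become missing-flagged calls.
    """
    text_input = isinstance(vcf, str) and vcf.lstrip().startswith("##")
    if text_input:
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False, encoding="utf-8"
        )
        tmp.write(vcf)
        tmp.close()
        path = tmp.name
    else:
        path = os.fspath(vcf)
    try:
        with pysam.VariantFile(path) as vf:
            header_samples = list(vf.header.samples)
            absent = [s for s in pedigree.sample_ids if s not in header_samples]
            if absent:
                raise ValueError(
                    f"pedigree sample(s) absent from VCF header: {absent}"
                )
            sample_ids = list(pedigree.sample_ids)
            sex_by_id = {e.sample_id: e.sex for e in pedigree.entries}
            sites: list[VariantSite] = []
            calls: dict[tuple[SiteKey, str], GenotypeCall] = {}
            for rec in vf:
                alts = rec.alts or ()
                for k, alt in enumerate(alts, start=1):
                    site = VariantSite(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        rsid=None if rec.id in (None, ".") else rec.id,
                    )
                    sites.append(site)
                    for s in sample_ids:
                        sd = rec.samples[s]
                        gt = sd.get("GT")
                        call = _decode_gt(sd, gt, k)
                        call = _normalize_male_x(call, rec.chrom, sex_by_id[s])
                        calls[(site.key, s)] = call
    finally:
        if text_input:
            os.unlink(path)
    return FamilyGenotypes(sites=sites, calls=calls, sample_ids=sample_ids)


def _decode_gt(sample_data, gt, alt_index: int) -> GenotypeCall:
    if gt is None or all(a is None for a in gt):
        return GenotypeCall(missing=True)
    if any(a is None for a in gt):
        warnings.warn("partially missing GT treated as missing", stacklevel=2)
        return GenotypeCall(missing=True)
    alleles = tuple(1 if a == alt_index else 0 for a in gt)
    depth = sample_data.get("DP")
    ad = sample_data.get("AD")
    alt_depth = None
    if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
        alt_depth = ad[alt_index]
        if depth is None and all(x is not None for x in ad):
            depth = sum(ad)
    if depth is not None and alt_depth is not None and alt_depth > depth:
        depth = None  # inconsistent FORMAT fields: keep GT, drop depths
        alt_depth = None
    return GenotypeCall(alleles=alleles, depth=depth, alt_depth=alt_depth)


def write_vcf(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    out: str | os.PathLike | io.TextIOBase,
) -> None:
    """Write biallelic sites back out as minimal VCF 4.2 text (GT:AD:DP)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    chroms = []
    for site in fam.sites:
        if site.chrom not in chroms:
            chroms.append(site.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(fam.sample_ids)
    )
    for site in fam.sites:
        cols = [
            site.chrom,
            str(site.pos),
            site.rsid or ".",
            site.ref,
            site.alt,
            ".",
            "PASS",
            ".",
            "GT:AD:DP",
        ]
        for s in fam.sample_ids:
            call = fam.calls[(site.key, s)]
            cols.append(_format_call(call))
        lines.append("\t".join(cols))
    text = "\n".join(lines) + "\n"
    if isinstance(out, (str, os.PathLike)):
        Path(out).write_text(text)
    else:
        out.write(text)


def _format_call(call: GenotypeCall) -> str:
    if call.missing:
        return "./.:.:."
    gt = "/".join(str(a) for a in call.alleles)
    if call.depth is None or call.alt_depth is None:
        return f"{gt}:.:."
    ref_d = call.depth - call.alt_depth
    return f"{gt}:{ref_d},{call.alt_depth}:{call.depth}"


# ---------------------------------------------------------------------------
# Annotation merging

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "rsid",
    "gene",
    "consequence",
    "aa_change",
    "maf_1000g",
    "maf_esp",
    "q2_esp",
    "sift",
    "polyphen2",
    "fathmm",
    "siphy",
]

_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "nonsynonymous": Consequence.MISSENSE,
    "stop_gain": Consequence.STOP_GAIN,
    "stopgain": Consequence.STOP_GAIN,
    "nonsense": Consequence.STOP_GAIN,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}


def _parse_optional_float(x) -> float | None:
    # "-" and empty cells mean missing, per the source-table convention.
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return None
    if isinstance(x, str):
        x = x.strip()
        if x in ("", "-", ".", "NA", "NaN"):
            return None
    return float(x)


def _parse_optional_str(x) -> str | None:
    if x is None or (isinstance(x, float) and pd.isna(x)):
        return None
    s = str(x).strip()
    return s if s not in ("", "-", ".") else None


def _parse_consequence(raw, aa_change: str | None) -> Consequence | None:
    s = _parse_optional_str(raw)
    if s is not None:
        cons = _CONSEQUENCE_ALIASES.get(s.lower())
        if cons is not None:
            if cons is Consequence.MISSENSE and aa_change and aa_change.endswith("*"):
                return Consequence.STOP_GAIN
            return cons
        return Consequence.OTHER
    # Infer a stop gain from the amino-acid change ("*" marks a stop codon).
    if aa_change is not None:
        if aa_change.endswith("*"):
            return Consequence.STOP_GAIN
        if len(aa_change) >= 3 and aa_change[0] != aa_change[-1]:
            return Consequence.MISSENSE
    return None


def merge_annotations(
    fam: FamilyGenotypes,
    table: str | os.PathLike | pd.DataFrame,
) -> list[AnnotatedVariant]:
    """Left-join an annotation TSV onto the family's sites.

    The table is keyed by (chrom, pos, ref, alt); rows lacking coordinates
    are matched by rsid.  Sites with no annotation row come back with every
    annotation field None.  Duplicate keys are a hard error.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        src = table
        if isinstance(table, str) and "\t" in table:
            src = io.StringIO(table)
        df = pd.read_csv(src, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"annotation table lacks column(s): {missing_cols}")

    by_key: dict[SiteKey, pd.Series] = {}
    by_rsid: dict[str, pd.Series] = {}
    for _, row in df.iterrows():
        chrom = _parse_optional_str(row["chrom"])
        pos = _parse_optional_str(row["pos"])
        rsid = _parse_optional_str(row["rsid"])
        if chrom is not None and pos is not None:
            key = (_norm_chrom(chrom), int(pos), str(row["ref"]), str(row["alt"]))
            if key in by_key:
                raise ValueError(f"duplicate annotation key {key}")
            by_key[key] = row
        elif rsid is not None:
            if rsid in by_rsid:
                raise ValueError(f"duplicate annotation rsid {rsid!r}")
            by_rsid[rsid] = row
        else:
            raise ValueError("annotation row lacks both coordinates and rsid")

    out: list[AnnotatedVariant] = []
    for site in fam.sites:
        key = (_norm_chrom(site.chrom), site.pos, site.ref, site.alt)
        row = by_key.get(key)
        if row is None and site.rsid is not None:
            row = by_rsid.get(site.rsid)
        if row is None:
            out.append(AnnotatedVariant(site=site))
            continue
        aa_change = _parse_optional_str(row["aa_change"])
        out.append(
            AnnotatedVariant(
                site=site,
                gene=_parse_optional_str(row["gene"]),
                consequence=_parse_consequence(row["consequence"], aa_change),
                aa_change=aa_change,
                maf_1000g=_parse_optional_float(row["maf_1000g"]),
                maf_esp=_parse_optional_float(row["maf_esp"]),
                q2_esp=_parse_optional_float(row["q2_esp"]),
                sift=_parse_optional_float(row["sift"]),
                polyphen2=_parse_optional_float(row["polyphen2"]),
                fathmm=_parse_optional_float(row["fathmm"]),
                siphy=_parse_optional_float(row["siphy"]),
            )
        )
    return out
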