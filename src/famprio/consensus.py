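"""Rarity filtering and deleteriousness consensus.

Three in-silico tools vote on each variant: Sift (damaging when the score
is <= 0.05), Polyphen2 (damaging when >= 0.957) and Fathmm (damaging when
strictly < -1.5).  The Fathmm boundary is strict and the other two are
inclusive; these are the published operating points of the tools, not
tunables of this package, though all three are exposed in
:class:`Thresholds` for sensitivity analyses.

Rarity follows a recessive-model logic.  Heterozygous candidates must be
extremely rare (max MAF across databases <= ``rare_maf``).  A compound-het
pair may pair one extremely rare allele with a moderately common partner
(each member capped at ``common_cap``): under a recessive model the pair
frequency, not each allele's frequency, is what must be small.  Homozygous
candidates are judged on the observed homozygote frequency q^2 rather than
the allele frequency.  A variant absent from every frequency database is
treated as rare - absence from large population databases is itself
evidence of rarity, the same logic that defines "private" de novo
candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .family import AnnotatedVariant, Consequence

__all__ = [
    "Thresholds",
    "ToolVerdict",
    "ConsensusVerdict",
    "RarityBasis",
    "RarityVerdict",
    "damaging_calls",
    "is_rare",
    "pair_is_rare",
    "consequence_filter",
    "conservation_flag",
]


@dataclass(frozen=True)
class Thresholds:
    """Filtering thresholds; defaults are the pipeline's operating point.

    rare_maf
        "Extremely rare" cutoff on the max population MAF (default 1e-3).
    common_cap
        Ceiling on every member of a compound-het pair (default 0.10).
    q2_cap
        Ceiling on the ESP homozygote frequency for homozygous candidates
        (default 0.05).
    sift_max / polyphen2_min / fathmm_max
        Tool operating points; Fathmm is a strict inequality.
    siphy_min
        Conservation reporting threshold (report-only, never filters).
    """

    rare_maf: float = 1e-3
    common_cap: float = 0.10
    q2_cap: float = 0.05
    sift_max: float = 0.05
    polyphen2_min: float = 0.957
    fathmm_max: float = -1.5
    siphy_min: float = 10.0

    def to_dict(self) -> dict[str, float]:
        return {
            "rare_maf": self.rare_maf,
            "common_cap": self.common_cap,
            "q2_cap": self.q2_cap,
            "sift_max": self.sift_max,
            "polyphen2_min": self.polyphen2_min,
            "fathmm_max": self.fathmm_max,
            "siphy_min": self.siphy_min,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "Thresholds":
        known = {k: float(v) for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown threshold key(s): {sorted(unknown)}")
        return cls(**known)


class ToolVerdict(Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    MISSING = "missing"


@dataclass(frozen=True)
class ConsensusVerdict:
    """Per-tool damaging/benign/missing calls for one variant."""

    per_tool: Mapping[str, ToolVerdict]

    @property
    def n_available(self) -> int:
        return sum(1 for v in self.per_tool.values() if v is not ToolVerdict.MISSING)

    @property
    def n_damaging(self) -> int:
        return sum(1 for v in self.per_tool.values() if v is ToolVerdict.DAMAGING)

    @property
    def putatively_damaging(self) -> bool:
        """At least one tool calls damaging, or no tool could score it."""
        return self.n_damaging >= 1 or self.n_available == 0


_SCORE_RANGES = {"sift": (0.0, 1.0), "polyphen2": (0.0, 1.0)}


def damaging_calls(
    v: AnnotatedVariant, thresholds: Thresholds | None = None
) -> ConsensusVerdict:
    """Score one variant against the three-tool consensus thresholds."""
    t = thresholds or Thresholds()
    for tool in ("sift", "polyphen2"):
        score = getattr(v, tool)
        lo, hi = _SCORE_RANGES[tool]
        if score is not None and not lo <= score <= hi:
            warnings.warn(
                f"{tool} score {score} outside [{lo}, {hi}] at "
                f"{v.site.chrom}:{v.site.pos}",
                stacklevel=2,
            )
    per_tool = {
        "sift": _verdict(v.sift, lambda s: s <= t.sift_max),
        "polyphen2": _verdict(v.polyphen2, lambda s: s >= t.polyphen2_min),
        "fathmm": _verdict(v.fathmm, lambda s: s < t.fathmm_max),
    }
    return ConsensusVerdict(per_tool=per_tool)


def _verdict(score, rule) -> ToolVerdict:
    if score is None:
        return ToolVerdict.MISSING
    return ToolVerdict.DAMAGING if rule(score) else ToolVerdict.BENIGN


class RarityBasis(Enum):
    MAF_MAX = "maf_max"
    Q2 = "q2"
    MISSING_TREATED_RARE = "missing_treated_rare"


@dataclass(frozen=True)
class RarityVerdict:
    is_rare: bool
    basis: RarityBasis
    values_used: tuple[float, ...] = ()


def is_rare(
    v: AnnotatedVariant,
    klass: "object" = None,
    thresholds: Thresholds | None = None,
) -> RarityVerdict:
    """Rarity verdict for a single variant under its inheritance class.

    Homozygous candidates (``klass`` with value ``homozygous_recessive``)
    use the q^2 rule; everything else uses the max-MAF rule.  Missing
    frequencies are treated as rare, with the basis recorded.
    """
    t = thresholds or Thresholds()
    klass_value = getattr(klass, "value", klass)
    if klass_value == "homozygous_recessive":
        if v.q2_esp is None:
            return RarityVerdict(True, RarityBasis.MISSING_TREATED_RARE)
        return RarityVerdict(v.q2_esp <= t.q2_cap, RarityBasis.Q2, (v.q2_esp,))
    m = v.maf_max
    if m is None:
        return RarityVerdict(True, RarityBasis.MISSING_TREATED_RARE)
    return RarityVerdict(m <= t.rare_maf, RarityBasis.MAF_MAX, (m,))


def _maf_or_none(v: AnnotatedVariant) -> float | None:
    return v.maf_max


def pair_is_rare(
    pair: Iterable[AnnotatedVariant], thresholds: Thresholds | None = None
) -> RarityVerdict:
    """Rarity of a compound-het pair (or larger trans set).

    Passes when at least one member is extremely rare (or database-absent)
    and every member's MAF is at or below ``common_cap``.
    """
    t = thresholds or Thresholds()
    members = list(pair)
    if not members:
        raise ValueError("empty compound-het set")
    mafs = [_maf_or_none(v) for v in members]
    any_rare = any(m is None or m <= t.rare_maf for m in mafs)
    all_capped = all(m is None or m <= t.common_cap for m in mafs)
    if all(m is None for m in mafs):
        return RarityVerdict(True, RarityBasis.MISSING_TREATED_RARE)
    used = tuple(m for m in mafs if m is not None)
    return RarityVerdict(any_rare and all_capped, RarityBasis.MAF_MAX, used)


def consequence_filter(v: AnnotatedVariant) -> bool:
    """Keep protein-altering classes: missense, stop gain, frameshift."""
    if v.consequence is None:
        return False
    return v.consequence in (
        Consequence.MISSENSE,
        Consequence.STOP_GAIN,
        Consequence.FRAMESHIFT,
    )


def conservation_flag(v: AnnotatedVariant, siphy_min: float = 10.0) -> bool:
    """Report-only flag for strongly conserved positions (SiPhy)."""
    return v.siphy is not None and v.siphy >= siphy_min
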