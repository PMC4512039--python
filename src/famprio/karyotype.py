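"""ISCN karyotype parsing and ploidy classification.

Handles the numeric-prefix form used in clinical reports, e.g.
``53,XY,+4,+6,+12,+15,+17,+18,+21``: a declared modal chromosome number,
the sex-chromosome complement, then whole-chromosome gains (``+N``) and
losses (``-N``).  Structural rearrangement tokens (inv, t, del, ...) are
carried verbatim as notes, never interpreted.

Ploidy bands follow cytogenetic convention: hypodiploid (<46), diploid
(46), low hyperdiploid (47-50), high hyperdiploid (51-67) and
near-triploid or above (>67).  The band edges are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "KaryotypeModel",
    "PLOIDY_BANDS",
    "parse_iscn",
    "chromosome_count",
    "classify_ploidy",
    "render_iscn",
]

_VALID_LABELS = {str(i) for i in range(1, 23)} | {"X", "Y"}

_GAIN_LOSS = re.compile(r"^([+\-−])([0-9XY]+)$")
_SEX = re.compile(r"^[XY]+$")


@dataclass
class KaryotypeModel:
    """A parsed whole-chromosome karyotype."""

    modal_number_declared: int | None
    sex_chromosomes: str
    gains: list[str] = field(default_factory=list)
    losses: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    raw: str = ""

    @property
    def declared_matches_computed(self) -> bool:
        if self.modal_number_declared is None:
            return True
        return self.modal_number_declared == chromosome_count(self)


def parse_iscn(s: str) -> KaryotypeModel:
    """Parse a comma-delimited ISCN numeric-prefix karyotype string."""
    if not s or not s.strip():
        raise ValueError("empty karyotype string")
    tokens = [t.strip() for t in s.strip().split(",") if t.strip()]
    if not tokens:
        raise ValueError(f"unparseable karyotype string: {s!r}")
    declared: int | None = None
    idx = 0
    if tokens[0].isdigit():
        declared = int(tokens[0])
        idx = 1
    sex = ""
    if idx < len(tokens) and _SEX.match(tokens[idx]):
        sex = tokens[idx]
        idx += 1
    if declared is None and not sex:
        raise ValueError(f"unparseable karyotype string: {s!r}")
    gains: list[str] = []
    losses: list[str] = []
    notes: list[str] = []
    for tok in tokens[idx:]:
        m = _GAIN_LOSS.match(tok)
        if m:
            sign, label = m.groups()
            if label not in _VALID_LABELS:
                raise ValueError(f"invalid chromosome label in token {tok!r}")
            (gains if sign == "+" else losses).append(label)
        else:
            # structural rearrangements etc.: recorded, not interpreted
            notes.append(tok)
    return KaryotypeModel(
        modal_number_declared=declared,
        sex_chromosomes=sex,
        gains=gains,
        losses=losses,
        notes=notes,
        raw=s,
    )


def chromosome_count(m: KaryotypeModel) -> int:
    """Modal chromosome number: 46 plus gains minus losses."""
    return 46 + len(m.gains) - len(m.losses)


PLOIDY_BANDS: list[tuple[int, int, str]] = [
    (1, 45, "hypodiploid"),
    (46, 46, "diploid"),
    (47, 50, "low-hyperdiploid"),
    (51, 67, "high-hyperdiploid"),
    (68, 10_000, "near-triploid+"),
]


def classify_ploidy(
    n: int, bands: list[tuple[int, int, str]] | None = None
) -> str:
    """Classify a modal chromosome number into a ploidy band."""
    if n < 1:
        raise ValueError("chromosome count must be >= 1")
    for lo, hi, name in bands or PLOIDY_BANDS:
        if lo <= n <= hi:
            return name
    raise ValueError(f"no ploidy band covers n={n}")


def render_iscn(m: KaryotypeModel) -> str:
    """Render a model back to ISCN text (declared number recomputed)."""
    parts = [str(chromosome_count(m))]
    if m.sex_chromosomes:
        parts.append(m.sex_chromosomes)
    parts += [f"+{g}" for g in m.gains]
    parts += [f"-{l}" for l in m.losses]
    parts += m.notes
    return ",".join(parts)
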