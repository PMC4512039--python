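"""Pipeline orchestration and report writing.

`run` wires the whole analysis together: load pedigree + VCF +
annotations, execute the reduction cascade, the de novo and X-linked
screens, the gene-panel restriction and (optionally) the
susceptibility-locus table and karyotype summaries, then write the
machine-readable report (JSON), the flat per-variant table (TSV) and the
per-stage filter trace (TSV).  A run has no unseeded randomness, so
re-running an identical configuration byte-reproduces the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import datasets
from .consensus import Thresholds, conservation_flag
from .family import (
    AnnotatedVariant,
    FamilyGenotypes,
    Pedigree,
    load_pedigree,
    load_variants,
    merge_annotations,
)
from .karyotype import chromosome_count, classify_ploidy, parse_iscn
from .panel import GenePanel, fa_panel, restrict_to_panel, susceptibility_report
from .segregation import (
    CandidateGene,
    FilterTrace,
    PipelineConfig,
    denovo_screen,
    run_reduction,
    x_linked_screen,
)

logger = logging.getLogger("famprio")

__all__ = ["RunConfig", "CandidateReport", "run", "run_case", "validate_report"]


@dataclass
class RunConfig:
    """File paths, thresholds and stage toggles for one pipeline run."""

    vcf: str
    ped: str
    annotations: str
    out_dir: str = "famprio_out"
    panel_genes: list[str] | None = None  # None -> Fanconi anemia panel
    karyotypes: dict[str, str] = field(default_factory=dict)
    risk_loci: str | None = None  # TSV with gene/rsid/ref; None -> built-in list
    thresholds: Thresholds = field(default_factory=Thresholds)
    shared_mode: str = "identity"
    missing_policy: str = "strict"
    min_parent_depth: int = 8
    run_denovo: bool = True
    run_x_screen: bool = True
    run_susceptibility: bool = False
    seed: int = 0

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            thresholds=self.thresholds,
            shared_mode=self.shared_mode,
            missing_policy=self.missing_policy,
            min_parent_depth=self.min_parent_depth,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["thresholds"] = self.thresholds.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and not isinstance(d["thresholds"], Thresholds):
            d["thresholds"] = Thresholds.from_dict(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class CandidateReport:
    candidates: list[CandidateGene]
    trace: FilterTrace
    panel_hits: list[CandidateGene]
    de_novo: list
    x_linked: list[CandidateGene]
    thresholds: Thresholds
    susceptibility: pd.DataFrame | None = None
    karyotypes: list[dict[str, Any]] = field(default_factory=list)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "thresholds": self.thresholds.to_dict(),
            "trace": [
                {"stage": n, "n_in": i, "n_out": o} for n, i, o in self.trace.stages
            ],
            "candidates": [
                _candidate_dict(c, self.thresholds) for c in self.candidates
            ],
            "panel": {
                "name": "fanconi_anemia",
                "hits": [c.gene for c in self.panel_hits],
            },
            "de_novo": [
                {
                    "chrom": s.chrom,
                    "pos": s.pos,
                    "ref": s.ref,
                    "alt": s.alt,
                    "rsid": s.rsid,
                }
                for s in self.de_novo
            ],
            "x_linked": [
                _candidate_dict(c, self.thresholds) for c in self.x_linked
            ],
            "susceptibility": (
                None
                if self.susceptibility is None
                else self.susceptibility.to_dict(orient="records")
            ),
            "karyotypes": self.karyotypes,
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat per-variant candidate table (the TSV report)."""
        rows = []
        for c in self.candidates:
            for v in c.variants:
                verdict = c.consensus.get(v.site.key)
                rows.append(
                    {
                        "gene": c.gene,
                        "class": c.klass.value,
                        "prioritized": c.prioritized,
                        "rare": None if c.rarity is None else c.rarity.is_rare,
                        "chrom": v.site.chrom,
                        "pos": v.site.pos,
                        "ref": v.site.ref,
                        "alt": v.site.alt,
                        "rsid": v.site.rsid,
                        "consequence": v.consequence.value if v.consequence else None,
                        "aa_change": v.aa_change,
                        "maf_1000g": v.maf_1000g,
                        "maf_esp": v.maf_esp,
                        "q2_esp": v.q2_esp,
                        "sift": v.sift,
                        "polyphen2": v.polyphen2,
                        "fathmm": v.fathmm,
                        "siphy": v.siphy,
                        "origin": (
                            c.origins[v.site.key].value
                            if v.site.key in c.origins
                            else None
                        ),
                        "n_damaging": None if verdict is None else verdict.n_damaging,
                        "conserved": conservation_flag(v, self.thresholds.siphy_min),
                    }
                )
        return pd.DataFrame(rows)


def _candidate_dict(c: CandidateGene, t: Thresholds) -> dict[str, Any]:
    return {
        "gene": c.gene,
        "class": c.klass.value,
        "prioritized": c.prioritized,
        "rarity": (
            None
            if c.rarity is None
            else {
                "is_rare": c.rarity.is_rare,
                "basis": c.rarity.basis.value,
                "values_used": list(c.rarity.values_used),
            }
        ),
        "variants": [
            {
                "chrom": v.site.chrom,
                "pos": v.site.pos,
                "ref": v.site.ref,
                "alt": v.site.alt,
                "rsid": v.site.rsid,
                "consequence": v.consequence.value if v.consequence else None,
                "aa_change": v.aa_change,
                "maf_1000g": v.maf_1000g,
                "maf_esp": v.maf_esp,
                "q2_esp": v.q2_esp,
                "sift": v.sift,
                "polyphen2": v.polyphen2,
                "fathmm": v.fathmm,
                "siphy": v.siphy,
                "origin": (
                    c.origins[v.site.key].value if v.site.key in c.origins else None
                ),
                "consensus": (
                    None
                    if v.site.key not in c.consensus
                    else {
                        **{
                            tool: verdict.value
                            for tool, verdict in c.consensus[v.site.key].per_tool.items()
                        },
                        "n_damaging": c.consensus[v.site.key].n_damaging,
                        "n_available": c.consensus[v.site.key].n_available,
                    }
                ),
                "conserved": conservation_flag(v, t.siphy_min),
            }
            for v in c.variants
        ],
    }


def run_case(
    fam: FamilyGenotypes,
    pedigree: Pedigree,
    annotations: Sequence[AnnotatedVariant],
    config: RunConfig | None = None,
) -> CandidateReport:
    """Run the analysis on already-loaded inputs."""
    cfg = config or RunConfig(vcf="", ped="", annotations="")
    pcfg = cfg.pipeline_config()
    candidates, trace = run_reduction(fam, pedigree, annotations, pcfg)
    for name, n_in, n_out in trace.stages:
        logger.info("stage %-22s %6d -> %6d (excluded %d)", name, n_in, n_out, n_in - n_out)

    if cfg.panel_genes:
        panel = GenePanel(name="custom", genes=frozenset(cfg.panel_genes))
    else:
        panel = fa_panel()
    panel_hits = restrict_to_panel(candidates, panel)

    de_novo = (
        denovo_screen(
            fam,
            pedigree,
            annotations,
            min_parent_depth=cfg.min_parent_depth,
            trace=trace,
        )
        if cfg.run_denovo
        else []
    )
    x_linked = (
        x_linked_screen(fam, pedigree, annotations) if cfg.run_x_screen else []
    )

    susceptibility = None
    if cfg.run_susceptibility:
        if cfg.risk_loci:
            loci = pd.read_csv(cfg.risk_loci, sep="\t", dtype=str)
        else:
            loci = datasets.susceptibility_loci()
        susceptibility = susceptibility_report(fam, pedigree, loci)

    karyo = []
    for label, s in cfg.karyotypes.items():
        m = parse_iscn(s)
        n = chromosome_count(m)
        karyo.append(
            {
                "label": label,
                "raw": m.raw,
                "modal_number_declared": m.modal_number_declared,
                "modal_number_computed": n,
                "ploidy": classify_ploidy(n),
                "declared_matches_computed": m.declared_matches_computed,
                "gains": list(m.gains),
                "losses": list(m.losses),
                "notes": list(m.notes),
            }
        )

    return CandidateReport(
        candidates=candidates,
        trace=trace,
        panel_hits=panel_hits,
        de_novo=de_novo,
        x_linked=x_linked,
        thresholds=cfg.thresholds,
        susceptibility=susceptibility,
        karyotypes=karyo,
    )


def run(config: RunConfig) -> CandidateReport:
    """Load inputs per the config, run the analysis, write the reports."""
    for name in ("vcf", "ped", "annotations"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"configured {name} path missing: {p!r}")
    pedigree = load_pedigree(Path(config.ped).read_text())
    fam = load_variants(config.vcf, pedigree)
    annotations = merge_annotations(fam, config.annotations)
    report = run_case(fam, pedigree, annotations, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_json_dict()
    validate_report(payload)
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"stage": n, "n_in": i, "n_out": o} for n, i, o in report.trace.stages]
    ).to_csv(out / "trace.tsv", sep="\t", index=False)
    return report


# ---------------------------------------------------------------------------
# Structural validation of the report payload

_REPORT_KEYS = {
    "thresholds": dict,
    "trace": list,
    "candidates": list,
    "panel": dict,
    "de_novo": list,
    "x_linked": list,
    "karyotypes": list,
}

_CANDIDATE_KEYS = {"gene": str, "class": str, "prioritized": bool, "variants": list}


def validate_report(d: Mapping[str, Any]) -> None:
    """Check the report payload's structure; raises ValueError if bad."""
    for key, typ in _REPORT_KEYS.items():
        if key not in d:
            raise ValueError(f"report lacks key {key!r}")
        if not isinstance(d[key], typ):
            raise ValueError(f"report key {key!r} has type {type(d[key]).__name__}")
    if "susceptibility" not in d:
        raise ValueError("report lacks key 'susceptibility'")
    for stage in d["trace"]:
        if not {"stage", "n_in", "n_out"} <= set(stage):
            raise ValueError("malformed trace entry")
        if stage["n_out"] > stage["n_in"]:
            raise ValueError("trace stage with n_out > n_in")
    for group in ("candidates", "x_linked"):
        for c in d[group]:
            for key, typ in _CANDIDATE_KEYS.items():
                if key not in c or not isinstance(c[key], typ):
                    raise ValueError(f"malformed candidate entry ({key})")
            if not c["variants"]:
                raise ValueError("candidate without variants")
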