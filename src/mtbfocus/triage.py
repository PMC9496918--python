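"""Short-variant triage: filtering, pathogenicity scoring, evidence tiering.

Called short-sequence variants are filtered on three predicates — read depth
strictly over 100x, variant allele frequency of at least 5%, and population
(gnomAD-style) frequency strictly below 5%, with a missing population
frequency treated as 0 (absence from population databases is evidence of
rarity). Pathogenicity is scored with a configurable criteria-and-points
scheme in the style of the VICC consortium SOP; the shipped point table is a
documented default the user must review against the published SOP.
Alterations are matched against a local knowledge base carrying ESCAT
actionability tiers and DKTK evidence levels, characteristic fusions can
reassign a cancer-of-unknown-primary entity, and recommendations are ranked
by evidence tier, DKTK level and label status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

ESCAT_ORDER = ("I-A", "I-B", "I-C", "II-A", "II-B", "III-A", "III-B",
               "IV-A", "IV-B", "V", "X")
DKTK_ORDER = ("m1a", "m1b", "m1c", "m2a", "m2b", "m3", "m4")
LABEL_ORDER = ("on", "off", "trial")

PATHOGENICITY_CATEGORIES = ("benign", "likely_benign", "VUS",
                            "likely_oncogenic", "oncogenic")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mtbfocus").joinpath("data", name)))


# ---------------------------------------------------------------------------
# filtering


@dataclass(frozen=True)
class ShortSequenceVariant:
    """A called SNV/indel with the quantities the filters act on."""

    gene: str
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    depth: int
    vaf: float
    popfreq: float | None = None
    protein_change: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.popfreq is not None and not math.isnan(self.popfreq):
            if not 0.0 <= self.popfreq <= 1.0:
                raise ValueError(f"population frequency {self.popfreq} outside [0, 1]")


@dataclass(frozen=True)
class FilterThresholds:
    """Filter boundary semantics: depth strictly over the cutoff, VAF
    inclusive, population frequency strictly below."""

    min_depth_exclusive: float = 100.0
    min_vaf: float = 0.05
    max_popfreq_exclusive: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth_exclusive < 0 or not 0 <= self.min_vaf <= 1 \
                or not 0 <= self.max_popfreq_exclusive <= 1:
            raise ValueError("thresholds out of range")


def filter_variants(variants: list[ShortSequenceVariant],
                    thresholds: FilterThresholds | None = None
                    ) -> tuple[list[ShortSequenceVariant], list[list[str]]]:
    """Apply the three filter predicates.

    Returns the passing variants and, aligned with the *input*, a list of
    fail reasons per variant (empty list = passed); every violated predicate
    is enumerated.
    """
    th = thresholds or FilterThresholds()
    passing: list[ShortSequenceVariant] = []
    reasons: list[list[str]] = []
    for v in variants:
        fails = []
        if not v.depth > th.min_depth_exclusive:
            fails.append(f"depth {v.depth} not over {th.min_depth_exclusive:g}x")
        if not v.vaf >= th.min_vaf:
            fails.append(f"VAF {v.vaf:g} below {th.min_vaf:g}")
        pf = 0.0 if v.popfreq is None or math.isnan(v.popfreq) else v.popfreq
        if not pf < th.max_popfreq_exclusive:
            fails.append(f"population frequency {pf:g} not below "
                         f"{th.max_popfreq_exclusive:g}")
        reasons.append(fails)
        if not fails:
            passing.append(v)
    return passing, reasons


def variants_from_frame(table: pd.DataFrame) -> list[ShortSequenceVariant]:
    """Build variants from a table with the documented TSV columns."""
    required = {"gene", "contig", "position", "ref", "alt", "depth", "vaf"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    out = []
    for rec in table.itertuples(index=False):
        pf = getattr(rec, "popfreq", None)
        pf = None if pf is None or (isinstance(pf, float) and math.isnan(pf)) else float(pf)
        out.append(ShortSequenceVariant(
            gene=rec.gene, contig=rec.contig, position=int(rec.position),
            ref=rec.ref, alt=rec.alt, depth=int(rec.depth), vaf=float(rec.vaf),
            popfreq=pf, protein_change=str(getattr(rec, "protein_change", "")),
        ))
    return out


# ---------------------------------------------------------------------------
# pathogenicity


@dataclass(frozen=True)
class PathogenicityAssessment:
    criteria: tuple[str, ...]
    points: tuple[int, ...]
    total: int
    category: str


def load_point_config(path: str | Path | None = None) -> tuple[dict, dict]:
    """Load (point_table, category_thresholds) from YAML (shipped default)."""
    path = Path(path) if path else _data_path("vicc_points.yaml")
    cfg = yaml.safe_load(path.read_text())
    return cfg["points"], cfg["categories"]


def classify_pathogenicity(criteria: list[str],
                           point_table: dict[str, int] | None = None,
                           category_thresholds: dict[str, int] | None = None
                           ) -> PathogenicityAssessment:
    """Sum criterion points and map the total onto a pathogenicity category.

    The category is the highest-threshold category whose threshold does not
    exceed the total; no criteria means score 0, i.e. variant of uncertain
    significance.
    """
    if point_table is None or category_thresholds is None:
        default_points, default_cats = load_point_config()
        point_table = point_table or default_points
        category_thresholds = category_thresholds or default_cats
    unknown = [c for c in criteria if c not in point_table]
    if unknown:
        raise KeyError(f"unknown criterion codes: {unknown}")
    points = tuple(int(point_table[c]) for c in criteria)
    total = sum(points)
    for category, threshold in sorted(category_thresholds.items(),
                                      key=lambda kv: -kv[1]):
        if total >= threshold:
            return PathogenicityAssessment(tuple(criteria), points, total, category)
    raise ValueError("category thresholds do not cover the score range")


# ---------------------------------------------------------------------------
# fusions


@dataclass(frozen=True)
class FusionCall:
    gene5: str
    gene3: str
    annotation: str = ""
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("both fusion gene symbols must be non-empty")


@dataclass(frozen=True)
class EntityReassignment:
    entity: str
    fusion: FusionCall
    rationale: str


def load_fusion_rules(path: str | Path | None = None) -> pd.DataFrame:
    path = Path(path) if path else _data_path("fusion_rules.tsv")
    rules = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene5", "gene3", "entity"}
    if not required <= set(rules.columns):
        raise ValueError(f"{path}: fusion rule table needs columns {sorted(required)}")
    return rules


def infer_entity_from_fusion(fusions: list[FusionCall],
                             rule_table: pd.DataFrame | None = None,
                             ordered: bool = False) -> EntityReassignment | None:
    """First fusion matching a characteristic-fusion rule reassigns the entity.

    With ``ordered`` False (default) the gene pair matches irrespective of
    5'/3' orientation. No match returns None (no reassignment).
    """
    rules = rule_table if rule_table is not None else load_fusion_rules()
    for fusion in fusions:
        for rule in rules.itertuples(index=False):
            pair = (fusion.gene5, fusion.gene3)
            rule_pair = (rule.gene5, rule.gene3)
            hit = pair == rule_pair or (not ordered and pair == rule_pair[::-1])
            if hit:
                return EntityReassignment(
                    entity=rule.entity, fusion=fusion,
                    rationale=(f"characteristic {fusion.gene5}-{fusion.gene3} "
                               f"fusion indicates {rule.entity}"),
                )
    return None


# ---------------------------------------------------------------------------
# evidence matching and ranking


@dataclass(frozen=True)
class EvidenceRecord:
    """A knowledge-base row: alteration pattern, entity, therapy and tiers."""

    gene: str
    alteration: str
    entity: str
    therapy: str
    escat: str | None
    dktk: str | None
    label: str  # on | off | trial
    early_phase_trial: bool = False
    cross_entity: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.escat is not None and self.escat not in ESCAT_ORDER:
            raise ValueError(f"unknown ESCAT tier {self.escat!r}")
        if self.dktk is not None and self.dktk not in DKTK_ORDER:
            raise ValueError(f"unknown DKTK level {self.dktk!r}")
        if self.label not in LABEL_ORDER:
            raise ValueError(f"label must be one of {LABEL_ORDER}")


def load_knowledge_base(path: str | Path | None = None) -> list[EvidenceRecord]:
    """Load and validate the evidence knowledge base TSV."""
    path = Path(path) if path else _data_path("knowledge_base.tsv")
    table = pd.read_csv(path, sep="\t", comment="#",
                        dtype=str, keep_default_na=False)
    records = []
    for i, rec in enumerate(table.itertuples(index=False), start=2):
        try:
            records.append(EvidenceRecord(
                gene=rec.gene, alteration=rec.alteration, entity=rec.entity,
                therapy=rec.therapy,
                escat=rec.escat or None, dktk=rec.dktk or None,
                label=rec.label,
                early_phase_trial=getattr(rec, "early_phase_trial", "0") == "1",
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def match_evidence(gene: str, alteration: str, tumor_entity: str,
                   knowledge_base: list[EvidenceRecord]) -> list[EvidenceRecord]:
    """Match an alteration against the knowledge base.

    Exact-entity matches come back at their stored tiers; matches of the same
    alteration in a different entity come back flagged ``cross_entity`` with
    the original entity in the provenance — tiers are never silently
    rewritten.
    """
    hits = []
    for row in knowledge_base:
        if row.gene.casefold() != gene.casefold():
            continue
        if row.alteration.casefold() not in (alteration.casefold(), "any"):
            continue
        if row.entity.casefold() == tumor_entity.casefold():
            hits.append(replace(row, provenance="exact entity match"))
        else:
            hits.append(replace(row, cross_entity=True,
                                provenance=f"evidence from {row.entity}"))
    hits.sort(key=lambda r: r.cross_entity)  # exact-entity matches first
    return hits


def recommendation_sort_key(record: EvidenceRecord,
                            timely_treatment_required: bool = False) -> tuple:
    escat = (ESCAT_ORDER.index(record.escat) if record.escat else len(ESCAT_ORDER))
    dktk = DKTK_ORDER.index(record.dktk) if record.dktk else len(DKTK_ORDER)
    label = LABEL_ORDER.index(record.label)
    demoted = int(timely_treatment_required and record.early_phase_trial)
    return (demoted, escat, dktk, label)


def rank_recommendations(records: list[EvidenceRecord],
                         timely_treatment_required: bool = False
                         ) -> list[EvidenceRecord]:
    """Total order on recommendations.

    ESCAT tier first (I-A best, X worst), ties broken by DKTK level (m1a
    best), then on-label before off-label before trial; early-phase-trial
    records are demoted wholesale when timely treatment is required. The sort
    is stable, so input order breaks remaining ties.
    """
    return sorted(records, key=lambda r: recommendation_sort_key(
        r, timely_treatment_required))
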