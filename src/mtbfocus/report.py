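"""Per-patient molecular tumor board report assembly.

The report collates, for one clinical case, the filtered short variants,
fusion findings (with any entity reassignment), the estimated numerical
karyotype with per-gene copy numbers, the panel-vs-genome concordance
summary, and the ranked therapy recommendations. Assays that were not
performed appear as explicit "not performed" sections rather than being
silently omitted, and immunohistochemistry findings (PD-L1, mismatch-repair
deficiency) can surface an immune-checkpoint rationale even when no variant
matched the knowledge base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .concordance import ConcordanceSummary
from .karyotype import KaryotypeResults
from .triage import EntityReassignment, EvidenceRecord, FusionCall, \
    ShortSequenceVariant, rank_recommendations

REPORT_SCHEMA_VERSION = "1"

MMR_GENES = ("MLH1", "PMS2", "MSH2", "MSH6")


@dataclass
class ClinicalCase:
    """Clinical context of one patient entering the board."""

    patient_id: str
    entity: str
    prior_lines: int = 0
    pd_l1_tps: float | None = None
    pd_l1_ic: float | None = None
    pd_l1_cps: float | None = None
    mmr_loss: dict[str, bool] = field(default_factory=dict)
    assays: dict[str, bool] = field(
        default_factory=lambda: {"vp": True, "fp": True, "ulcwgs": True})

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient id must be non-empty")
        for score in (self.pd_l1_tps, self.pd_l1_ic, self.pd_l1_cps):
            if score is not None and score < 0:
                raise ValueError("PD-L1 scores must be >= 0")
        unknown = set(self.mmr_loss) - set(MMR_GENES)
        if unknown:
            raise ValueError(f"unknown MMR proteins: {sorted(unknown)}")

    @property
    def msi_status(self) -> str:
        """'deficient' iff nuclear staining is lost for >= 1 MMR protein."""
        if not self.mmr_loss:
            return "not tested"
        return "deficient" if any(self.mmr_loss.values()) else "proficient"


@dataclass
class MtbReport:
    case: ClinicalCase
    variants: list[ShortSequenceVariant]
    fusions: list[FusionCall]
    entity_reassignment: EntityReassignment | None
    karyotype: KaryotypeResults | None
    concordance: ConcordanceSummary | None
    recommendations: list[EvidenceRecord]
    sections: dict[str, str]
    outcome: str

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "patient_id": self.case.patient_id,
            "entity": self.case.entity,
            "entity_reassigned_to": (self.entity_reassignment.entity
                                     if self.entity_reassignment else None),
            "msi_status": self.case.msi_status,
            "pd_l1": {"tps": self.case.pd_l1_tps, "ic": self.case.pd_l1_ic,
                      "cps": self.case.pd_l1_cps},
            "sections": self.sections,
            "variants": [vars(v) | {"popfreq": v.popfreq} for v in self.variants],
            "fusions": [f"{f.gene5}-{f.gene3}" for f in self.fusions],
            "karyotype": (self.karyotype.karyotype.string
                          if self.karyotype else None),
            "concordance": (self.concordance.to_dict()
                            if self.concordance else None),
            "recommendations": [{
                "therapy": r.therapy, "gene": r.gene, "alteration": r.alteration,
                "escat": r.escat, "dktk": r.dktk, "label": r.label,
                "cross_entity": r.cross_entity, "provenance": r.provenance,
            } for r in self.recommendations],
            "outcome": self.outcome,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         default=str) + "\n")


def assemble_report(case: ClinicalCase,
                    variants: list[ShortSequenceVariant] | None = None,
                    fusions: list[FusionCall] | None = None,
                    entity_reassignment: EntityReassignment | None = None,
                    recommendations: list[EvidenceRecord] | None = None,
                    karyotype: KaryotypeResults | None = None,
                    concordance: ConcordanceSummary | None = None,
                    timely_treatment_required: bool = False) -> MtbReport:
    """Assemble the per-patient report from the pipeline stages' outputs.

    At least one assay must be available. Recommendations are (re)ordered by
    the evidence ranking; a mismatch-repair-deficient case with no matched
    recommendation surfaces an immune-checkpoint rationale from the IHC
    section; a case with no findings at all reports "no actionable target".
    """
    if not any(case.assays.values()):
        raise ValueError("at least one assay's results must be present")
    variants = variants or []
    fusions = fusions or []
    ranked = rank_recommendations(recommendations or [],
                                  timely_treatment_required)

    sections = {}
    for assay, label in (("vp", "short variants / panel CNAs"),
                         ("fp", "fusion transcripts"),
                         ("ulcwgs", "genome-wide copy number")):
        sections[assay] = label if case.assays.get(assay) else "not performed"

    ihc_rationales = []
    if case.msi_status == "deficient":
        ihc_rationales.append(
            "mismatch-repair deficiency: rationale for immune-checkpoint inhibition")
    if case.pd_l1_cps and case.pd_l1_cps >= 1:
        ihc_rationales.append(
            f"PD-L1 positive (CPS {case.pd_l1_cps:g}): supports checkpoint inhibition")
    if ihc_rationales:
        sections["ihc"] = "; ".join(ihc_rationales)

    if ranked:
        outcome = "therapeutic suggestion issued"
    elif ihc_rationales:
        outcome = "IHC-based therapeutic rationale"
    elif not variants and not fusions and (
            karyotype is None or not karyotype.karyotype.events):
        outcome = "no actionable target"
    else:
        outcome = "findings without matched therapy"

    return MtbReport(case=case, variants=variants, fusions=fusions,
                     entity_reassignment=entity_reassignment,
                     karyotype=karyotype, concordance=concordance,
                     recommendations=ranked, sections=sections,
                     outcome=outcome)
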