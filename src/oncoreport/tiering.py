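"""Clinical tier assignment for somatic and germline findings.

Two independent tier systems are assigned:

* **Report tiers 1-4** (disease association): tumor type-specific
  actionable mutations (1); mutations in targetable pathways, actionable
  mutations from other tumor types, and known driver mutations in
  well-established cancer genes (2); other mutations in cancer genes (3);
  somatic variants of uncertain significance (4, the catch-all).
* **Actionability sub-tiers 1-5** (evidence level for targeting): clinical
  benefit, same tumor type and gene (1); clinical benefit, different tumor
  type (2); preclinical evidence, same tumor type (3); preclinical
  evidence, different tumor type (4); molecular-tumor-board discretion (5,
  only ever set by an explicit manual override, never auto-assigned).

Targetability requires (1) an approved or experimental drug against the
target or its downstream pathway, or (2) preclinical evidence of efficacy,
and (3) some age-appropriate dosing information. Germline variants of
uncertain significance are returned only when destructive, in a
well-validated cancer gene, and accompanied by a second somatic hit or
reduction to homozygosity in the tumor.

When several tier rules match, the lowest-numbered (strongest) tier wins;
assignments are pure functions of (finding, tumor-type context, knowledge
base). Adding evidence can only keep or lower a tier number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .classify import ClassifiedVariant
from .knowledgebase import DrugTarget, KnowledgeBase
from .variants import DISRUPTIVE_CONSEQUENCES, VariantCall

SOURCES = ("snv_indel", "fusion", "cnv", "expression", "germline")

GERMLINE_CATEGORIES = (
    "acmg_pathogenic",
    "non_acmg_cancer",
    "pharmacogenomic",
    "vous_returned",
    "n/a",
)

#: Catalog label → clinical-utility category.
_LABEL_UTILITY = {
    "diagnostic": "diagnostic",
    "prognostic": "prognostic",
    "pharmacogenomic": "other_impact",
    "other_impact": "other_impact",
    "health_maintenance": "health_maintenance",
}

REDUCTION_TO_HOM_VAF = 0.90


@dataclass(frozen=True)
class TieredFinding:
    """A reportable aberration with its tiers, categories, and evidence."""

    source: str  # snv_indel | fusion | cnv | expression | germline
    gene: str  # gene symbol, or fusion written GENE5-GENE3
    hgvs_p: str = ""
    hgvs_c: str = ""
    description: str = ""
    labels: Tuple[str, ...] = ()  # knowledge-base utility labels
    board_override: bool = False  # explicit tumor-board discretion flag
    report_tier: Optional[int] = None
    actionability_tier: Optional[int] = None
    germline_category: str = "n/a"
    utility: frozenset = frozenset()
    evidence: Tuple[str, ...] = ()
    payload: object = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.germline_category not in GERMLINE_CATEGORIES:
            raise ValueError(f"unknown germline category {self.germline_category!r}")


@dataclass(frozen=True)
class TargetabilityResult:
    targetable: bool
    drug_available: bool
    preclinical_evidence: bool
    pediatric_dosing: bool
    reasons: Tuple[str, ...] = ()
    entries: Tuple[DrugTarget, ...] = ()

    def __bool__(self) -> bool:
        return self.targetable


def _matching_entries(
    identifier: str, kb: KnowledgeBase, alteration: str = ""
) -> List[DrugTarget]:
    entries = kb.drug_targets.get(identifier, ())
    return [
        e for e in entries if e.alteration == "*" or (alteration and e.alteration == alteration)
    ]


def is_targetable(
    gene_or_fusion: str, kb: KnowledgeBase, alteration: str = ""
) -> TargetabilityResult:
    """Evaluate the three targetability criteria with a breakdown."""
    entries = _matching_entries(gene_or_fusion, kb, alteration)
    if not entries:
        return TargetabilityResult(
            False, False, False, False, reasons=("no catalog entry",)
        )
    drug_available = any(
        e.approval_status in {"approved", "experimental"} for e in entries
    )
    preclinical = any(e.evidence_class == "preclinical" for e in entries)
    dosing = any(e.pediatric_dosing_available for e in entries)
    targetable = (drug_available or preclinical) and dosing
    reasons = []
    if drug_available:
        reasons.append("approved or experimental drug available")
    if preclinical:
        reasons.append("preclinical efficacy evidence")
    reasons.append(
        "pediatric dosing information available"
        if dosing
        else "no pediatric dosing information"
    )
    return TargetabilityResult(
        targetable, drug_available, preclinical, dosing,
        reasons=tuple(reasons), entries=tuple(entries),
    )


def _is_known_driver(finding: TieredFinding, kb: KnowledgeBase) -> bool:
    if finding.source == "fusion":
        genes = tuple(finding.gene.split("-", 1))
        return len(genes) == 2 and genes in kb.known_fusions
    return (finding.gene, finding.hgvs_p) in kb.hotspots


def _in_cancer_gene(finding: TieredFinding, kb: KnowledgeBase) -> bool:
    return any(g in kb.cancer_genes for g in finding.gene.split("-"))


def assign_report_tier(
    finding: TieredFinding, context: str, kb: KnowledgeBase
) -> int:
    """Report tier 1-4; the lowest-numbered matching rule wins."""
    target = is_targetable(finding.gene, kb, finding.hgvs_p)
    driver = _is_known_driver(finding, kb)
    same_tumor_clinical = any(
        e.evidence_class == "clinical" and e.matches_tumor_type(context)
        for e in target.entries
    )
    if driver and target.targetable and same_tumor_clinical:
        return 1
    if target.targetable or (driver and _in_cancer_gene(finding, kb)):
        return 2
    if _in_cancer_gene(finding, kb):
        return 3
    return 4


def assign_actionability_tier(
    finding: TieredFinding, context: str, kb: KnowledgeBase
) -> int:
    """Actionability sub-tier 1-5 from the strongest available evidence."""
    if finding.board_override:
        return 5
    entries = _matching_entries(finding.gene, kb, finding.hgvs_p)
    if not entries:
        raise ValueError(f"evidence required: no catalog entry for {finding.gene}")
    best = 5
    for entry in entries:
        same = entry.matches_tumor_type(context)
        if entry.evidence_class == "clinical":
            tier = 1 if same else 2
        else:
            tier = 3 if same else 4
        best = min(best, tier)
    return best


def vous_return_decision(
    germline_vous: VariantCall,
    somatic_context: Sequence[ClassifiedVariant],
    kb: KnowledgeBase,
    tumor_vaf_at_site: Optional[float] = None,
) -> Tuple[bool, Dict[str, bool]]:
    """Return-to-family decision for a germline VOUS.

    All three criteria must hold: (1) predicted destructive, (2) in a
    well-validated cancer gene, (3) second somatic hit in the same gene or
    reduction to homozygosity (tumor VAF >= 0.9) at the germline site.
    """
    destructive = germline_vous.consequence in DISRUPTIVE_CONSEQUENCES
    cancer_gene = bool(germline_vous.gene) and germline_vous.gene in kb.cancer_genes
    somatic_hit = any(
        cv.call.gene == germline_vous.gene and "somatic" in cv.categories
        for cv in somatic_context
    )
    if tumor_vaf_at_site is None:
        for cv in somatic_context:
            if cv.call.key == germline_vous.key and cv.call.vaf is not None:
                tumor_vaf_at_site = cv.call.vaf
                break
    reduced_to_hom = (
        tumor_vaf_at_site is not None and tumor_vaf_at_site >= REDUCTION_TO_HOM_VAF
    )
    criteria = {
        "destructive": destructive,
        "cancer_gene": cancer_gene,
        "second_hit_or_reduction": somatic_hit or reduced_to_hom,
    }
    return all(criteria.values()), criteria


def categorize_utility(finding: TieredFinding, kb: KnowledgeBase) -> frozenset:
    """Clinical-utility categories from catalog labels; therapeutic_target
    iff the finding is targetable."""
    utility = {
        _LABEL_UTILITY[label] for label in finding.labels if label in _LABEL_UTILITY
    }
    if is_targetable(finding.gene, kb, finding.hgvs_p).targetable:
        utility.add("therapeutic_target")
    return frozenset(utility)


def tier_finding(finding: TieredFinding, context: str, kb: KnowledgeBase) -> TieredFinding:
    """Assign both tier systems and utility categories to a somatic finding."""
    target = is_targetable(finding.gene, kb, finding.hgvs_p)
    actionability = None
    if finding.board_override:
        actionability = 5
    elif target.targetable:
        actionability = assign_actionability_tier(finding, context, kb)
    return replace(
        finding,
        report_tier=assign_report_tier(finding, context, kb),
        actionability_tier=actionability,
        utility=categorize_utility(finding, kb),
        evidence=tuple(target.reasons),
    )
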