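"""Patient report rendering.

A report aggregates one patient's tiered findings into a fixed section
order: somatic tiers 1→4, then fusions, CNV, expression, germline
categories (ACMG pathogenic, non-ACMG cancer genes, pharmacogenomic,
returned VOUS). Rendering is deterministic — the same report object always
produces byte-identical output. Secondary (ACMG) findings are suppressed
from the document when the patient opted out, and routed to an audit log
instead; every other finding appears in exactly one section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .tiering import TieredFinding
from .variants import SampleMeta

SECTION_ORDER = (
    "somatic_tier_1",
    "somatic_tier_2",
    "somatic_tier_3",
    "somatic_tier_4",
    "fusions",
    "cnv",
    "expression",
    "germline_acmg_pathogenic",
    "germline_non_acmg_cancer",
    "germline_pharmacogenomic",
    "germline_vous_returned",
)

_SECTION_TITLES = {
    "somatic_tier_1": "Somatic mutations - Tier 1 (tumor type-specific, actionable)",
    "somatic_tier_2": "Somatic mutations - Tier 2 (targetable pathway / other tumor type / established cancer gene)",
    "somatic_tier_3": "Somatic mutations - Tier 3 (other mutations in cancer genes)",
    "somatic_tier_4": "Somatic mutations - Tier 4 (variants of uncertain significance)",
    "fusions": "Fusion transcripts",
    "cnv": "Copy number variation",
    "expression": "Expression outliers",
    "germline_acmg_pathogenic": "Germline findings - ACMG secondary findings",
    "germline_non_acmg_cancer": "Germline findings - cancer genes (non-ACMG)",
    "germline_pharmacogenomic": "Germline findings - pharmacogenomic",
    "germline_vous_returned": "Germline findings - returned VOUS",
}


@dataclass(frozen=True)
class ClinicalReport:
    patient: SampleMeta
    findings: Tuple[TieredFinding, ...]
    secondary_findings_optin: bool = True


def _section_of(finding: TieredFinding) -> str:
    if finding.source == "germline":
        return f"germline_{finding.germline_category}"
    if finding.source == "snv_indel":
        tier = finding.report_tier or 4
        return f"somatic_tier_{tier}"
    return {"fusion": "fusions", "cnv": "cnv", "expression": "expression"}[
        finding.source
    ]


def _finding_dict(finding: TieredFinding) -> dict:
    return {
        "source": finding.source,
        "gene": finding.gene,
        "hgvs_c": finding.hgvs_c,
        "hgvs_p": finding.hgvs_p,
        "description": finding.description,
        "report_tier": finding.report_tier,
        "actionability_tier": finding.actionability_tier,
        "germline_category": finding.germline_category,
        "utility": sorted(finding.utility),
        "evidence": list(finding.evidence),
    }


def report_sections(report: ClinicalReport) -> Tuple[Dict[str, List[dict]], List[dict]]:
    """Partition findings into ordered sections; return (sections, suppressed).

    ACMG secondary findings are suppressed (returned separately for the
    audit log) when the patient opted out.
    """
    sections: Dict[str, List[dict]] = {name: [] for name in SECTION_ORDER}
    suppressed: List[dict] = []
    for finding in report.findings:
        section = _section_of(finding)
        entry = _finding_dict(finding)
        if (
            section == "germline_acmg_pathogenic"
            and not report.secondary_findings_optin
        ):
            suppressed.append(entry)
            continue
        sections[section].append(entry)
    for name in sections:
        sections[name].sort(key=lambda e: (e["gene"], e["hgvs_c"], e["hgvs_p"]))
    return sections, suppressed


def render_report(report: ClinicalReport, format: str = "json") -> str:
    """Render the report as JSON or markdown; deterministic byte-for-byte."""
    sections, _ = report_sections(report)
    if format == "json":
        doc = {
            "patient_id": report.patient.patient_id,
            "diagnosis": report.patient.diagnosis,
            "disease_group": report.patient.disease_group,
            "assay": report.patient.assay,
            "secondary_findings_optin": report.secondary_findings_optin,
            "sections": [
                {
                    "name": name,
                    "title": _SECTION_TITLES[name],
                    "findings": sections[name],
                }
                for name in SECTION_ORDER
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        lines = [
            f"# Clinical sequencing report — patient {report.patient.patient_id}",
            "",
            f"Diagnosis: {report.patient.diagnosis or 'n/a'}",
            f"Assay: {report.patient.assay}",
            "",
        ]
        for name in SECTION_ORDER:
            lines.append(f"## {_SECTION_TITLES[name]}")
            if not sections[name]:
                lines.append("")
                lines.append("No findings.")
                lines.append("")
                continue
            lines.append("")
            for entry in sections[name]:
                detail = " ".join(
                    x for x in (entry["gene"], entry["hgvs_c"], entry["hgvs_p"]) if x
                )
                tier_bits = []
                if entry["report_tier"] is not None:
                    tier_bits.append(f"report tier {entry['report_tier']}")
                if entry["actionability_tier"] is not None:
                    tier_bits.append(
                        f"actionability tier {entry['actionability_tier']}"
                    )
                if entry["utility"]:
                    tier_bits.append("utility: " + ", ".join(entry["utility"]))
                suffix = f" ({'; '.join(tier_bits)})" if tier_bits else ""
                lines.append(f"- {detail}{suffix}")
            lines.append("")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}")


def audit_log(report: ClinicalReport) -> str:
    """TSV log of findings suppressed by the opt-out preference."""
    _, suppressed = report_sections(report)
    lines = ["patient_id\tgene\thgvs_c\thgvs_p\tgermline_category\treason"]
    for entry in suppressed:
        lines.append(
            "\t".join(
                [
                    report.patient.patient_id,
                    entry["gene"],
                    entry["hgvs_c"],
                    entry["hgvs_p"],
                    entry["germline_category"],
                    "secondary findings opt-out",
                ]
            )
        )
    return "\n".join(lines) + "\n"
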