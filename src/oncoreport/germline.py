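"""Germline (normal-tissue) variant filtering.

Normal-sample calls pass through three layers:

* **reference-range filter** — genes on the cancer-predisposition /
  pharmacogenomics list, plus an explicit allow-list of variants relevant
  to patient care;
* **reportable-range filter** — variants carrying a cataloged COSMIC
  identifier, or falling in an ACMG secondary-findings gene;
* **frequency filter** — retains variants whose reference-population minor
  allele frequency is below the threshold (default 1%); a variant with no
  recorded frequency is retained, since a novel variant cannot be excluded
  as common.

A call is retained iff at least one retention layer (reference or
reportable range) emits it AND it passes the frequency filter. The layers
are order-independent; the frequency filter can only remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Set

from .knowledgebase import KnowledgeBase
from .variants import VariantCall


@dataclass(frozen=True)
class FilterDecision:
    call: VariantCall
    passed_layers: frozenset = frozenset()
    retained: bool = False
    reasons: tuple = ()


def reference_range_filter(call: VariantCall, kb: KnowledgeBase) -> bool:
    """True iff the call's gene is on the reference-range list, or the
    (gene, coding change) pair is an explicit patient-care variant."""
    if not call.gene:
        return False
    if call.gene in kb.reference_range_genes:
        return True
    return (call.gene, call.hgvs_c) in kb.patient_care_variants


def reportable_range_filter(call: VariantCall, kb: KnowledgeBase) -> bool:
    """True iff the call has a cataloged COSMIC id or is in an ACMG gene."""
    if call.cosmic_id and call.cosmic_id in kb.cosmic_ids:
        return True
    return bool(call.gene) and call.gene in kb.acmg_genes


def frequency_filter(call: VariantCall, kb: KnowledgeBase) -> bool:
    """Retain iff population AF < threshold, or no frequency is recorded."""
    if call.population_af is None:
        return True
    return call.population_af < kb.af_threshold


def run_germline_pipeline(
    calls: List[VariantCall], kb: KnowledgeBase
) -> List[FilterDecision]:
    """Evaluate all three layers for every call.

    retained set = (reference_range ∪ reportable_range) ∩ frequency-pass.
    """
    decisions = []
    for call in calls:
        layers: Set[str] = set()
        reasons = []
        if reference_range_filter(call, kb):
            layers.add("reference_range")
            reasons.append("reference_range")
        if reportable_range_filter(call, kb):
            layers.add("reportable_range")
            reasons.append("reportable_range")
        freq_ok = frequency_filter(call, kb)
        if freq_ok:
            layers.add("frequency")
        else:
            reasons.append(
                f"removed: population_af {call.population_af} >= "
                f"{kb.af_threshold}"
            )
        retained = bool(layers & {"reference_range", "reportable_range"}) and freq_ok
        decisions.append(
            FilterDecision(
                call=call,
                passed_layers=frozenset(layers),
                retained=retained,
                reasons=tuple(reasons),
            )
        )
    return decisions
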