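"""Targetability, report tiers, actionability sub-tiers, VOUS return."""

import numpy as np
import pytest

from oncoreport.classify import classify
from oncoreport.tiering import (
    TieredFinding,
    assign_actionability_tier,
    assign_report_tier,
    categorize_utility,
    is_targetable,
    tier_finding,
    vous_return_decision,
)
from oncoreport.variants import VariantCall


def finding(gene, hgvs_p="", source="snv_indel", **kw):
    return TieredFinding(source=source, gene=gene, hgvs_p=hgvs_p, **kw)


def germline(gene, consequence, pos=100, vaf=0.5):
    return VariantCall(
        chrom="1", pos=pos, ref="A", alt="T", depth=100, alt_depth=int(vaf * 100),
        vaf=vaf, gene=gene, consequence=consequence, zygosity="het",
    )


class TestTargetability:
    def test_kinase_with_approved_drug_and_dosing(self, kb):
        result = is_targetable("KIT", kb, "p.Asn655Lys")
        assert result.targetable and result.drug_available and result.pediatric_dosing

    def test_drug_without_pediatric_dosing_fails(self, kb):
        result = is_targetable("EGFR", kb)
        assert not result.targetable
        assert "no pediatric dosing information" in result.reasons

    def test_gene_absent_from_catalog(self, kb):
        result = is_targetable("NOTAGENE", kb)
        assert not result.targetable and result.reasons == ("no catalog entry",)


class TestReportTier:
    def test_same_tumor_actionable_hotspot_is_tier_1(self, kb):
        f = finding("IDH1", "p.R132C")
        assert assign_report_tier(f, "AML", kb) == 1

    def test_cancer_gene_not_targetable_not_hotspot_is_tier_3(self, kb):
        f = finding("TP53", "p.R175L")
        assert assign_report_tier(f, "AML", kb) == 3

    def test_unknown_gene_vous_is_tier_4(self, kb):
        f = finding("NOTAGENE", "p.A1B")
        assert assign_report_tier(f, "AML", kb) == 4

    def test_targetable_without_same_tumor_clinical_is_tier_2(self, kb):
        f = finding("SMARCA4", "p.R1192C")
        assert assign_report_tier(f, "Hepatic rhabdoid tumor", kb) == 2

    def test_matches_independent_rule_reevaluation(self, kb):
        rng = np.random.default_rng(19)
        genes = sorted(kb.cancer_genes) + ["ZZZ1", "ZZZ2", "KIT", "IDH1"]
        hgvs = ["p.R132C", "p.Asn655Lys", "p.Q61K", "p.X1Y", ""]
        contexts = ["AML", "ALL", "Neuroblastoma", "Osteosarcoma"]
        for _ in range(200):
            f = finding(str(rng.choice(genes)), str(rng.choice(hgvs)))
            context = str(rng.choice(contexts))
            tier = assign_report_tier(f, context, kb)
            # independent re-evaluation of the ordered rule table
            target = is_targetable(f.gene, kb, f.hgvs_p)
            hotspot = (f.gene, f.hgvs_p) in kb.hotspots
            same_clin = any(
                e.evidence_class == "clinical" and e.matches_tumor_type(context)
                for e in target.entries
            )
            in_cg = f.gene in kb.cancer_genes
            if hotspot and target.targetable and same_clin:
                expected = 1
            elif target.targetable or (hotspot and in_cg):
                expected = 2
            elif in_cg:
                expected = 3
            else:
                expected = 4
            assert tier == expected


class TestActionabilityTier:
    @pytest.mark.parametrize(
        "gene,hgvs_p,source,context,tier",
        [
            ("BCR-ABL1", "", "fusion", "CML", 1),  # clinical benefit, same tumor
            ("SMARCA4", "p.R1192C", "snv_indel", "Hepatic rhabdoid tumor", 2),
            ("NRAS", "p.Q61K", "snv_indel", "Neuroblastoma", 3),  # preclinical, same
            ("ALK", "p.Q1146K", "snv_indel", "Adrenocortical carcinoma", 4),
        ],
    )
    def test_printed_exemplar_subtiers(self, kb, gene, hgvs_p, source, context, tier):
        f = finding(gene, hgvs_p, source=source)
        assert assign_actionability_tier(f, context, kb) == tier

    def test_board_override_is_tier_5_never_auto(self, kb):
        f = finding("EML4-NTRK3", source="fusion", board_override=True)
        assert assign_actionability_tier(f, "Congenital fibrosarcoma", kb) == 5

    def test_no_evidence_record_errors(self, kb):
        with pytest.raises(ValueError, match="evidence required"):
            assign_actionability_tier(finding("NOTAGENE"), "AML", kb)

    def test_adding_evidence_only_lowers_tier(self, kb):
        # same-tumor clinical evidence dominates different-tumor preclinical
        f = finding("KIT", "p.D816H")
        aml = assign_actionability_tier(f, "AML", kb)
        other = assign_actionability_tier(f, "Osteosarcoma", kb)
        assert aml <= other


class TestVousReturn:
    def test_all_three_criteria_met(self, kb):
        vous = germline("SDHC", "splice_site")
        somatic = classify([germline("SDHC", "missense", pos=500)], {("1", 500, "A", "T")})
        returned, criteria = vous_return_decision(vous, somatic, kb)
        assert returned and all(criteria.values())

    def test_non_destructive_missense_withheld(self, kb):
        vous = germline("SDHC", "missense")
        somatic = classify([germline("SDHC", "missense", pos=500)], {("1", 500, "A", "T")})
        returned, criteria = vous_return_decision(vous, somatic, kb)
        assert not returned and not criteria["destructive"]

    def test_gene_outside_cancer_catalog_withheld(self, kb):
        vous = germline("NOTAGENE", "frameshift")
        returned, criteria = vous_return_decision(vous, [], kb, tumor_vaf_at_site=0.95)
        assert not returned and not criteria["cancer_gene"]

    def test_reduction_to_homozygosity_satisfies_second_hit(self, kb):
        vous = germline("APC", "nonsense")
        returned, criteria = vous_return_decision(vous, [], kb, tumor_vaf_at_site=0.92)
        assert returned and criteria["second_hit_or_reduction"]

    def test_no_second_event_withheld(self, kb):
        vous = germline("APC", "nonsense")
        returned, criteria = vous_return_decision(vous, [], kb, tumor_vaf_at_site=0.5)
        assert not returned


class TestUtility:
    def test_resistance_allele_is_other_impact(self, kb):
        f = finding("NT5C2", labels=("pharmacogenomic",))
        assert categorize_utility(f, kb) == frozenset({"other_impact"})

    def test_diagnostic_prognostic_fusion(self, kb):
        f = finding("PAX7-FOXO1", source="fusion", labels=("diagnostic", "prognostic"))
        assert categorize_utility(f, kb) == frozenset({"diagnostic", "prognostic"})

    def test_no_labels_no_target_empty(self, kb):
        assert categorize_utility(finding("NOTAGENE"), kb) == frozenset()

    def test_therapeutic_target_iff_targetable(self, kb):
        assert "therapeutic_target" in categorize_utility(
            finding("KIT", "p.Asn655Lys"), kb
        )


class TestDeterminism:
    def test_tier_finding_is_a_pure_function(self, kb):
        f = finding("NRAS", "p.Q61K")
        first = tier_finding(f, "Neuroblastoma", kb)
        second = tier_finding(f, "Neuroblastoma", kb)
        assert first == second
        assert first.report_tier == 2  # preclinical-only evidence, so not tier 1
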