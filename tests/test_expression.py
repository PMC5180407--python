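"""Expression normalization, reference model, outlier flags, fusions."""

import math

import numpy as np
import pytest

from oncoreport.expression import (
    FusionCall,
    annotate_fusions,
    build_reference_model,
    flag_outliers,
    make_profile,
)
from oncoreport.simulate import SimulationConfig, simulate_expression_panel

HK = ["HK_A", "HK_B", "HK_C"]


def profile(sample_id, values, hk=(10.0, 10.0, 10.0)):
    fpkm = dict(zip(HK, hk))
    fpkm.update(values)
    return make_profile(sample_id, fpkm, HK)


class TestNormalization:
    def test_housekeeping_median_divides_everything(self):
        p = profile("s", {"G1": 25.0}, hk=(5.0, 10.0, 20.0))
        assert p.hk_median == 10.0
        assert p.normalized["G1"] == pytest.approx(2.5)

    def test_global_scaling_leaves_normalized_unchanged(self):
        p1 = profile("s", {"G1": 25.0, "G2": 3.0})
        p2 = make_profile("s", {g: v * 10 for g, v in p1.fpkm.items()}, HK)
        for gene in p1.normalized:
            assert p2.normalized[gene] == pytest.approx(p1.normalized[gene])

    def test_no_housekeeping_genes_errors(self):
        with pytest.raises(ValueError, match="housekeeping"):
            make_profile("s", {"G1": 1.0}, HK)


class TestReferenceModel:
    def test_identical_profiles_have_zero_scale(self):
        panel = [profile(f"n{i}", {"G1": 7.0}) for i in range(5)]
        model = build_reference_model(panel)
        assert model.scale["G1"] == 0.0

    def test_two_profile_location_is_median(self):
        panel = [profile("a", {"G1": 10.0}), profile("b", {"G1": 30.0})]
        model = build_reference_model(panel)
        assert model.location["G1"] == pytest.approx(2.0)  # normalized 1 and 3

    def test_panel_of_one_rejected(self):
        with pytest.raises(ValueError):
            build_reference_model([profile("a", {"G1": 1.0})])

    def test_gene_missing_from_one_profile_counts_as_zero(self):
        panel = [profile("a", {"G1": 10.0}), profile("b", {}), profile("c", {})]
        model = build_reference_model(panel)
        assert model.location["G1"] == 0.0

    def test_location_recovered_on_simulated_lognormal_panel(self):
        rng = np.random.default_rng(31)
        true_norm = 5.0
        panel = []
        for i in range(50):
            scale = math.exp(rng.normal(0, 0.1))
            panel.append(
                profile(
                    f"n{i}",
                    {"G1": true_norm * 10.0 * scale * math.exp(rng.normal(0, 0.05))},
                    hk=(10.0 * scale,) * 3,
                )
            )
        model = build_reference_model(panel)
        assert model.location["G1"] == pytest.approx(true_norm, rel=0.05)


class TestOutlierFlags:
    def test_sample_at_model_location_not_flagged(self):
        panel = [
            profile(f"n{i}", {"G1": 10.0 * (1 + 0.01 * i), "G2": 2.0}) for i in range(10)
        ]
        model = build_reference_model(panel)
        assert flag_outliers(panel[5], model) == []

    def test_planted_twenty_fold_outlier_flagged_over(self):
        cfg = SimulationConfig(seed=13, outlier_genes=(("MYCN", 20.0),))
        panel, case, truth = simulate_expression_panel(cfg)
        flags = flag_outliers(case, build_reference_model(panel))
        assert ("MYCN", "over") in {(g, d) for g, d, _ in flags}

    def test_underexpression_flagged_under(self):
        cfg = SimulationConfig(seed=13, outlier_genes=(("G0001", 0.01),))
        panel, case, _ = simulate_expression_panel(cfg)
        flags = flag_outliers(case, build_reference_model(panel))
        assert ("G0001", "under") in {(g, d) for g, d, _ in flags}

    def test_case_scaling_invariance_of_flags(self):
        cfg = SimulationConfig(seed=14, outlier_genes=(("MYCN", 20.0),))
        panel, case, _ = simulate_expression_panel(cfg)
        model = build_reference_model(panel)
        scaled = make_profile(
            "scaled", {g: v * 10 for g, v in case.fpkm.items()},
            [g for g in case.fpkm if g.startswith("HK_")],
        )
        original = flag_outliers(case, model)
        rescaled = flag_outliers(scaled, model)
        assert [(g, d) for g, d, _ in rescaled] == [(g, d) for g, d, _ in original]
        for (_, _, z1), (_, _, z2) in zip(rescaled, original):
            assert z1 == pytest.approx(z2)

    def test_zero_scale_genes_use_epsilon_not_infinity(self):
        panel = [profile(f"n{i}", {"G1": 10.0}) for i in range(5)]
        model = build_reference_model(panel)
        sample = profile("case", {"G1": 10.4})  # normalized 1.04 vs location 1.0
        (flag,) = flag_outliers(sample, model)
        assert flag[2] == pytest.approx(0.04 / 0.01)

    def test_gene_absent_from_model_skipped_with_warning(self):
        panel = [profile(f"n{i}", {"G1": 10.0 + i}) for i in range(5)]
        model = build_reference_model(panel)
        sample = profile("case", {"G1": 10.0, "NEW": 99.0})
        with pytest.warns(UserWarning, match="absent"):
            flags = flag_outliers(sample, model)
        assert all(g != "NEW" for g, _, _ in flags)


class TestFusions:
    def test_exact_catalog_match(self, kb):
        (out,) = annotate_fusions([FusionCall("BCR", "ABL1")], kb)
        assert out.known and out.match_type == "exact"
        assert "targetable" in out.annotation

    def test_partner_gene_match(self, kb):
        # novel 5' partner, known 3' kinase partner
        (out,) = annotate_fusions([FusionCall("EML4", "NTRK3")], kb)
        assert out.known and out.match_type == "partner"

    def test_unknown_pair(self, kb):
        (out,) = annotate_fusions([FusionCall("AAAA", "BBBB")], kb)
        assert not out.known and out.annotation == ()

    def test_five_prime_three_prime_order_preserved(self, kb):
        out = annotate_fusions([FusionCall("ABL1", "BCR")], kb)
        assert (out[0].gene5, out[0].gene3) == ("ABL1", "BCR")
        assert out[0].match_type == "partner"  # reversed order is not the exact entry

    def test_invalid_fusion_rejected(self):
        with pytest.raises(ValueError):
            FusionCall("", "ABL1")
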