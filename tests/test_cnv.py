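"""CNV gates, segment states, LOH detection, and the fallback segmenter."""

import numpy as np
import pytest

from oncoreport.cnv import (
    AllelicSite,
    CoverageProfile,
    SegmentCall,
    call_segment_states,
    copy_neutral_loh,
    coverage_gate,
    detect_loh,
    find_loh_runs,
    simple_segmenter,
)
from oncoreport.simulate import SimulationConfig, simulate_ballele_track


def profile(role, f10, f30):
    return CoverageProfile(sample_role=role, fraction_targets_10x=f10, fraction_targets_30x=f30)


def seg(start=1, end=10**6, log2=0.0, state="neutral", chrom="1"):
    return SegmentCall(chrom=chrom, start=start, end=end, log2_ratio=log2, state=state)


def het_site(pos, tumor_vaf, chrom="1", normal_vaf=0.5):
    return AllelicSite(chrom=chrom, pos=pos, normal_vaf=normal_vaf, tumor_vaf=tumor_vaf)


class TestCoverageGate:
    @pytest.mark.parametrize(
        "n10,t30,expected",
        [
            (0.96, 0.91, True),
            (0.94, 0.95, False),  # normal below the >95% requirement
            (0.95, 0.95, False),  # boundary is strict for the normal
            (0.96, 0.90, True),  # tumor boundary is inclusive
            (0.96, 0.89, False),
        ],
    )
    def test_thresholds(self, n10, t30, expected):
        normal = profile("normal", n10, 1.0)
        tumor = profile("tumor", 1.0, t30)
        assert coverage_gate(normal, tumor) is expected


class TestSegmentStates:
    @pytest.mark.parametrize(
        "log2,state",
        [(-0.25, "loss"), (-0.2, "loss"), (0.0, "neutral"), (0.19, "neutral"),
         (0.2, "gain"), (-0.19, "neutral")],
    )
    def test_state_assignment(self, log2, state):
        (out,) = call_segment_states([seg(log2=log2)])
        assert out.state == state

    def test_states_partition(self):
        rng = np.random.default_rng(3)
        segments = [seg(log2=float(x)) for x in rng.normal(0, 0.4, size=100)]
        out = call_segment_states(segments)
        assert all(s.state in {"loss", "neutral", "gain"} for s in out)

    def test_loss_calls_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        segments = [seg(log2=float(x)) for x in rng.normal(-0.1, 0.2, size=200)]
        previous = set()
        for cutoff in (-0.4, -0.3, -0.2, -0.1):
            losses = {
                (s.start, s.end)
                for s in call_segment_states(segments, loss_cutoff=cutoff)
                if s.state == "loss"
            }
            assert previous <= losses
            previous = losses


class TestDetectLoh:
    def test_copy_neutral_loh_on_fully_shifted_segment(self):
        sites = [het_site(pos, 0.95) for pos in range(1000, 21000, 1000)]
        (out,) = detect_loh(sites, [seg(log2=0.0)])
        assert out.loh
        assert copy_neutral_loh([out]) == [out]

    def test_balanced_sites_do_not_flag(self):
        sites = [het_site(pos, 0.5) for pos in range(1000, 21000, 1000)]
        (out,) = detect_loh(sites, [seg()])
        assert not out.loh

    def test_mirroring_tumor_vafs_is_invariant(self):
        rng = np.random.default_rng(8)
        sites = [het_site(1000 * (i + 1), float(v)) for i, v in
                 enumerate(rng.uniform(0, 1, size=40))]
        mirrored = [
            AllelicSite(s.chrom, s.pos, s.normal_vaf, 1.0 - s.tumor_vaf) for s in sites
        ]
        (a,) = detect_loh(sites, [seg()])
        (b,) = detect_loh(mirrored, [seg()])
        assert a.loh == b.loh

    def test_segment_without_informative_sites_flagged_uninformative(self):
        hom = AllelicSite("1", 5000, normal_vaf=0.98, tumor_vaf=0.99)
        (out,) = detect_loh([hom], [seg()])
        assert not out.loh
        assert out.annotations["uninformative"]

    def test_min_sites_threshold(self):
        sites = [het_site(pos, 0.9) for pos in range(1000, 10000, 1000)]  # 9 sites
        (out,) = detect_loh(sites, [seg()], min_sites=10)
        assert not out.loh
        (out,) = detect_loh(sites, [seg()], min_sites=9)
        assert out.loh

    def test_runs_locate_the_shifted_stretch(self):
        sites = (
            [het_site(p, 0.5) for p in range(1000, 11000, 1000)]
            + [het_site(p, 0.92) for p in range(11000, 31000, 1000)]
            + [het_site(p, 0.5) for p in range(31000, 41000, 1000)]
        )
        (interval,) = find_loh_runs(sites)
        assert interval == ("1", 11000, 30000)


class TestSimpleSegmenter:
    @staticmethod
    def bins(values, chrom="1"):
        return [
            ((chrom, 1 + i * 100, (i + 1) * 100), float(v)) for i, v in enumerate(values)
        ]

    def test_constant_track_single_segment(self):
        (out,) = simple_segmenter(self.bins([0.01] * 50))
        assert (out.start, out.end, out.n_targets) == (1, 5000, 50)

    def test_step_track_two_segments_at_the_step(self):
        segments = simple_segmenter(self.bins([0.0] * 50 + [-0.5] * 50))
        assert len(segments) == 2
        assert segments[0].end == 5000 and segments[1].start == 5001
        assert segments[1].log2_ratio == pytest.approx(-0.5)

    def test_noisy_step_boundary_within_two_bins(self):
        rng = np.random.default_rng(12)
        values = np.concatenate(
            [rng.normal(0, 0.05, 50), rng.normal(-0.5, 0.05, 50)]
        )
        segments = simple_segmenter(self.bins(values))
        # boundary between bins 50/51 -> positions 5000/5001, +/- 2 bins
        boundaries = [s.start for s in segments[1:]]
        assert any(abs(b - 5001) <= 200 for b in boundaries)

    def test_unordered_bins_rejected(self):
        bins = [(("1", 200, 300), 0.0), (("1", 100, 150), 0.0)]
        with pytest.raises(ValueError, match="unordered"):
            simple_segmenter(bins)


class TestSimulatedRecovery:
    def test_planted_copy_neutral_loh_recovered(self):
        cfg = SimulationConfig(seed=2, loh_segments=(("1", 300_000, 700_000),))
        sites, bins, truth = simulate_ballele_track(cfg)
        (detected,) = find_loh_runs(sites)
        chrom, a, b = truth.loh_intervals[0]
        inter = max(0, min(b, detected[2]) - max(a, detected[1]))
        union = max(b, detected[2]) - min(a, detected[1])
        assert detected[0] == chrom
        assert inter / union >= 0.9

    def test_planted_loss_called_loss(self):
        cfg = SimulationConfig(seed=2, loss_segments=(("2", 200_000, 600_000, -0.5),))
        sites, bins, _ = simulate_ballele_track(cfg)
        segments = call_segment_states(simple_segmenter(bins))
        loss_cover = sum(
            seg.end - seg.start for seg in segments
            if seg.chrom == "2" and seg.state == "loss"
            and seg.start >= 190_000 and seg.end <= 610_000
        )
        assert loss_cover > 0.9 * 400_000 * 0.1  # bins cover 10% of the span
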