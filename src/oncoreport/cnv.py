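"""Exome CNV quality gates, segment state calls, and (copy-neutral) LOH.

The module operates on segment-level inputs produced upstream (an external
segmentation tool in production; :func:`simple_segmenter` for synthetic
end-to-end runs). CNV analysis is gated on coverage quality: more than 95%
of targeted nucleotides at >= 10X in the normal, and at least 90% at 30X in
the tumor. Segment loss state uses an inclusive log2-ratio cutoff of -0.2;
a symmetric +0.2 gain cutoff (not dictated upstream) is the configurable
default, with gains reported as supporting evidence only.

LOH detection uses heterozygous sites classified in the normal sample
(VAF 45-55% het; 90-100% hom). In the tumor, a het site whose allelic
fraction shifts away from 0.5 by at least ``tumor_shift`` supports LOH;
with tumor purity 0.8, a true copy-neutral LOH site sits near
0.5 +/- 0.4, so the default shift of 0.25 detects it with margin while
binomial noise around 0.5 stays well inside. Copy-neutral LOH is an
LOH-flagged segment whose copy-number state is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

DEFAULT_LOSS_CUTOFF = -0.2
DEFAULT_GAIN_CUTOFF = 0.2
DEFAULT_MIN_SITES = 10
DEFAULT_TUMOR_SHIFT = 0.25
DEFAULT_TUMOR_PURITY = 0.8


@dataclass(frozen=True)
class CoverageProfile:
    """Fraction of targeted nucleotides covered at 10X / 30X in one sample."""

    sample_role: str
    fraction_targets_10x: float
    fraction_targets_30x: float

    def __post_init__(self) -> None:
        for frac in (self.fraction_targets_10x, self.fraction_targets_30x):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"coverage fraction out of [0,1]: {frac}")


@dataclass(frozen=True)
class SegmentCall:
    """One CNV segment; 1-based, fully closed coordinates."""

    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_targets: int = 0
    state: str = "neutral"  # loss | neutral | gain
    loh: bool = False
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


@dataclass(frozen=True)
class AllelicSite:
    """One high-quality site with allelic fractions in both samples."""

    chrom: str
    pos: int
    normal_vaf: float
    tumor_vaf: float

    @property
    def class_in_normal(self) -> str:
        if 0.45 <= self.normal_vaf <= 0.55:
            return "het"
        if 0.90 <= self.normal_vaf <= 1.00:
            return "hom"
        return "other"


def coverage_gate(normal: CoverageProfile, tumor: CoverageProfile) -> bool:
    """True iff normal >95% at 10X (strict) and tumor >=90% at 30X."""
    return normal.fraction_targets_10x > 0.95 and tumor.fraction_targets_30x >= 0.90


def call_segment_states(
    segments: Sequence[SegmentCall],
    loss_cutoff: float = DEFAULT_LOSS_CUTOFF,
    gain_cutoff: float = DEFAULT_GAIN_CUTOFF,
) -> List[SegmentCall]:
    """Assign exactly one state per segment: loss if log2 <= loss_cutoff
    (inclusive), gain if >= gain_cutoff, else neutral."""
    out = []
    for seg in segments:
        if seg.log2_ratio <= loss_cutoff:
            state = "loss"
        elif seg.log2_ratio >= gain_cutoff:
            state = "gain"
        else:
            state = "neutral"
        out.append(replace(seg, state=state))
    return out


def _is_shifted(site: AllelicSite, tumor_shift: float) -> bool:
    return abs(site.tumor_vaf - 0.5) >= tumor_shift


def detect_loh(
    sites: Sequence[AllelicSite],
    segments: Sequence[SegmentCall],
    min_sites: int = DEFAULT_MIN_SITES,
    tumor_shift: float = DEFAULT_TUMOR_SHIFT,
) -> List[SegmentCall]:
    """Flag segments containing >= ``min_sites`` shifted normal-het sites.

    Symmetric in allele labeling: mirroring tumor VAFs around 0.5 leaves
    the flags unchanged. A segment with no informative (normal-het) sites
    is flagged ``uninformative`` with loh=False.
    """
    het_sites = [s for s in sites if s.class_in_normal == "het"]
    out = []
    for seg in segments:
        inside = [
            s for s in het_sites if s.chrom == seg.chrom and seg.start <= s.pos <= seg.end
        ]
        annotations = dict(seg.annotations)
        if not inside:
            annotations["uninformative"] = True
            out.append(replace(seg, loh=False, annotations=annotations))
            continue
        n_shifted = sum(_is_shifted(s, tumor_shift) for s in inside)
        annotations["n_het_sites"] = len(inside)
        annotations["n_shifted_sites"] = n_shifted
        out.append(replace(seg, loh=n_shifted >= min_sites, annotations=annotations))
    return out


def copy_neutral_loh(segments: Sequence[SegmentCall]) -> List[SegmentCall]:
    """Segments with LOH but neutral copy-number state."""
    return [s for s in segments if s.loh and s.state == "neutral"]


def find_loh_runs(
    sites: Sequence[AllelicSite],
    min_sites: int = DEFAULT_MIN_SITES,
    tumor_shift: float = DEFAULT_TUMOR_SHIFT,
) -> List[Tuple[str, int, int]]:
    """Locate LOH intervals as maximal runs of shifted normal-het sites.

    Complements :func:`detect_loh`: segment boundaries follow the log2
    track, which is flat across copy-neutral LOH, so interval-accurate LOH
    boundaries must come from the allelic-fraction track itself. A run is
    a maximal stretch of consecutive shifted het sites (ordered by
    position) containing at least ``min_sites`` sites; the interval spans
    the first to the last site of the run.
    """
    intervals = []
    by_chrom = {}
    for site in sites:
        if site.class_in_normal == "het":
            by_chrom.setdefault(site.chrom, []).append(site)
    for chrom in sorted(by_chrom):
        run: List[AllelicSite] = []
        for site in sorted(by_chrom[chrom], key=lambda s: s.pos):
            if _is_shifted(site, tumor_shift):
                run.append(site)
            else:
                if len(run) >= min_sites:
                    intervals.append((chrom, run[0].pos, run[-1].pos))
                run = []
        if len(run) >= min_sites:
            intervals.append((chrom, run[0].pos, run[-1].pos))
    return intervals


def simple_segmenter(
    binned_log2: Sequence[Tuple[Tuple[str, int, int], float]],
) -> List[SegmentCall]:
    """Merge ordered, non-overlapping log2 bins into segments.

    Adjacent bins join the current segment while the new bin's ratio is
    within 0.1 of the segment's running mean; each output segment carries
    the mean ratio of its bins. A stand-in for external segmentation, used
    for synthetic end-to-end tests only. Raises on unordered or
    overlapping bins.
    """
    segments: List[SegmentCall] = []
    current: List[Tuple[Tuple[str, int, int], float]] = []
    prev: Optional[Tuple[str, int, int]] = None

    def flush():
        if not current:
            return
        ratios = [r for _, r in current]
        (chrom, start, _), _ = current[0]
        (_, _, end), _ = current[-1]
        segments.append(
            SegmentCall(
                chrom=chrom,
                start=start,
                end=end,
                log2_ratio=sum(ratios) / len(ratios),
                n_targets=len(current),
            )
        )

    for (chrom, start, end), ratio in binned_log2:
        if start > end:
            raise ValueError(f"bin start {start} > end {end}")
        if prev is not None and chrom == prev[0] and start <= prev[2]:
            raise ValueError(
                f"bins unordered or overlapping at {chrom}:{start}-{end}"
            )
        new_chrom = prev is not None and chrom != prev[0]
        if current and not new_chrom:
            mean = sum(r for _, r in current) / len(current)
            if abs(ratio - mean) < 0.1:
                current.append((((chrom, start, end)), ratio))
                prev = (chrom, start, end)
                continue
        flush()
        current = [(((chrom, start, end)), ratio)]
        prev = (chrom, start, end)
    flush()
    return segments
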