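"""Tumor variant characterization and mutational-load statistics.

Tumor variants are characterized into four (non-exclusive) categories:
homozygous, compound heterozygous, somatic, and "disruptive" (loss of
function: nonsense, frameshift, or splice site). The mutational-load
statistic counts tumor-specific variants passing a coverage/quality
filter: at least 30X tumor coverage, and either a caller quality score
of >= 20 or a variant allelic fraction of >= 25%.
"""

from __future__ import annotations

import statistics
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

from .variants import DISRUPTIVE_CONSEQUENCES, SampleMeta, VariantCall

#: VAF at or above which (with adequate depth) a call is treated as
#: homozygous when the caller gave no zygosity; conventional exome practice.
HOMOZYGOUS_VAF = 0.90
HOMOZYGOUS_MIN_DEPTH = 30


@dataclass(frozen=True)
class ClassifiedVariant:
    call: VariantCall
    categories: frozenset
    load_eligible: bool


@dataclass(frozen=True)
class LoadFilterConfig:
    """Coverage/quality gate for mutational-load counting."""

    min_coverage: int = 30
    min_quality: float = 20.0
    alt_vaf: float = 0.25

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_quality, self.alt_vaf) <= 0:
            raise ValueError("all load-filter thresholds must be positive")


def load_filter(call: VariantCall, cfg: LoadFilterConfig = LoadFilterConfig()) -> bool:
    """True iff depth >= 30 AND (quality >= 20 OR vaf >= 0.25)."""
    if call.depth is None or call.depth < cfg.min_coverage:
        return False
    if call.quality_score is None and call.vaf is None:
        warnings.warn(
            f"call at {call.chrom}:{call.pos} has neither quality nor VAF; "
            "excluded from load",
            UserWarning,
            stacklevel=2,
        )
        return False
    quality_ok = call.quality_score is not None and call.quality_score >= cfg.min_quality
    vaf_ok = call.vaf is not None and call.vaf >= cfg.alt_vaf
    return quality_ok or vaf_ok


def _is_homozygous(call: VariantCall) -> bool:
    if call.zygosity == "hom":
        return True
    return (
        call.vaf is not None
        and call.vaf >= HOMOZYGOUS_VAF
        and call.depth is not None
        and call.depth >= HOMOZYGOUS_MIN_DEPTH
    )


def classify(
    calls: List[VariantCall],
    somatic_keys: Set[Tuple],
    load_cfg: LoadFilterConfig = LoadFilterConfig(),
) -> List[ClassifiedVariant]:
    """Tag each call with every applicable category.

    Compound heterozygosity is phase-unknown co-occurrence: assigned when
    at least two distinct het calls share a gene. Assignment is
    deterministic and independent of input order.
    """
    het_per_gene: Dict[str, Set[Tuple]] = defaultdict(set)
    for call in calls:
        if call.gene and call.zygosity == "het":
            het_per_gene[call.gene].add(call.key)
    compound_genes = {g for g, keys in het_per_gene.items() if len(keys) >= 2}

    out = []
    for call in calls:
        categories = set()
        if _is_homozygous(call):
            categories.add("homozygous")
        if call.gene in compound_genes and call.zygosity == "het":
            categories.add("compound_het")
        if call.key in somatic_keys:
            categories.add("somatic")
        if call.consequence in DISRUPTIVE_CONSEQUENCES:
            categories.add("disruptive")
        out.append(
            ClassifiedVariant(
                call=call,
                categories=frozenset(categories),
                load_eligible=load_filter(call, load_cfg),
            )
        )
    return out


def _summary(counts: List[int]) -> dict:
    summary = {
        "n": len(counts),
        "mean": statistics.fmean(counts),
        "median": statistics.median(counts),
        "min": min(counts),
        "max": max(counts),
        "sd_convention": "sample (n-1)",
    }
    if len(counts) > 1:
        summary["sd"] = statistics.stdev(counts)
        summary["sd_degenerate"] = False
    else:
        summary["sd"] = 0.0
        summary["sd_degenerate"] = True
    return summary


def cohort_load_stats(per_sample_counts: Iterable[Tuple[SampleMeta, int]]) -> dict:
    """Mean/SD/median/range of per-sample mutational load, overall and per
    disease group. SD uses the sample (n-1) convention; n=1 reports 0 with
    a degenerate flag. Raises on empty input."""
    items = list(per_sample_counts)
    if not items:
        raise ValueError("no per-sample counts supplied")
    result = {"overall": _summary([c for _, c in items]), "by_group": {}}
    groups: Dict[str, List[int]] = defaultdict(list)
    for meta, count in items:
        if meta.disease_group:
            groups[meta.disease_group].append(count)
    for group, counts in sorted(groups.items()):
        result["by_group"][group] = _summary(counts)
    return result
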