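"""Tumor-normal somatic subtraction.

Somatic variants are identified by subtracting all variants called in the
normal sample from those called in the tumor. The caller outputs normal
calls at a variant allelic fraction of >= 5% and tumor calls at >= 10%,
each backed by at least 10 total reads and 3 variant-supporting reads;
those output thresholds define eligibility here. Matching is by exact
(chrom, pos, ref, alt) key after normalization — the subtraction operates
on caller output, with no re-genotyping and no fuzzy indel matching.

Normal evidence below the 5% output threshold does not veto a tumor call
(it was never "called" in normal) but is recorded on the somatic call as a
``normal_vaf`` annotation for reviewer caution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Tuple

from .variants import VariantCall, sort_calls


@dataclass(frozen=True)
class SubtractionConfig:
    """Caller output thresholds for the tumor-normal pair."""

    tumor_min_vaf: float = 0.10
    normal_min_vaf: float = 0.05
    min_depth: int = 10
    min_alt_reads: int = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.normal_min_vaf <= self.tumor_min_vaf < 1.0):
            raise ValueError(
                "require 0 < normal_min_vaf <= tumor_min_vaf < 1, got "
                f"{self.normal_min_vaf}/{self.tumor_min_vaf}"
            )

    def min_vaf(self, role: str) -> float:
        if role == "tumor":
            return self.tumor_min_vaf
        if role == "normal":
            return self.normal_min_vaf
        raise ValueError(f"unknown sample role {role!r}")


def call_eligible(call: VariantCall, role: str, cfg: SubtractionConfig = SubtractionConfig()) -> bool:
    """True iff the call meets read-support and role-specific VAF minimums."""
    if call.depth is None or call.alt_depth is None or call.vaf is None:
        warnings.warn(
            f"call at {call.chrom}:{call.pos} lacks depth fields; "
            "treated as ineligible",
            UserWarning,
            stacklevel=2,
        )
        return False
    return (
        call.depth >= cfg.min_depth
        and call.alt_depth >= cfg.min_alt_reads
        and call.vaf >= cfg.min_vaf(role)
    )


def _collapse_duplicates(calls: Iterable[VariantCall]) -> Dict[Tuple, VariantCall]:
    """Collapse duplicate keys to the record with the highest depth."""
    best: Dict[Tuple, VariantCall] = {}
    for call in calls:
        prev = best.get(call.key)
        if prev is None or (call.depth or 0) > (prev.depth or 0):
            best[call.key] = call
    return best


def subtract(
    tumor: List[VariantCall],
    normal: List[VariantCall],
    cfg: SubtractionConfig = SubtractionConfig(),
) -> List[VariantCall]:
    """Eligible tumor calls whose key is absent from eligible normal calls.

    Somatic calls with any sub-threshold normal evidence at the same key are
    annotated with the normal-side VAF. Output is sorted by key.
    """
    tumor_by_key = _collapse_duplicates(
        c for c in tumor if call_eligible(c, "tumor", cfg)
    )
    normal_by_key = _collapse_duplicates(normal)
    normal_called = {
        k for k, c in normal_by_key.items() if call_eligible(c, "normal", cfg)
    }
    somatic = []
    for key, call in tumor_by_key.items():
        if key in normal_called:
            continue
        sub_threshold = normal_by_key.get(key)
        if sub_threshold is not None and sub_threshold.vaf is not None:
            annotations = dict(call.annotations)
            annotations["normal_vaf"] = sub_threshold.vaf
            call = replace(call, annotations=annotations)
        somatic.append(call)
    return sort_calls(somatic)
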