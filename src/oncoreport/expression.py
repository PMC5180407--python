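"""Housekeeping-normalized expression outliers and fusion annotation.

Per-gene FPKM values are normalized by the median FPKM over a housekeeping
gene list (nominally ~8000 genes; a bundled subset serves for testing), so
that flags are invariant to global scaling of a sample. Each gene's
normalized expression is compared to a panel-of-normals reference model
(median location, median-absolute-deviation scale per gene, built from
normal transcriptomes of mixed tissues); a robust z beyond the cutoff
(default 3) flags the gene over- or under-expressed. The numeric cutoff for
"significantly overexpressed" is not externally fixed and is a parameter.

Fusion calls (from an upstream discovery tool) are annotated against a
known-fusion catalog, either as exact 5'/3' pairs or via single-partner
matching (a novel fusion sharing one partner gene with a cataloged fusion
is expected to have the same effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from statistics import median
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .knowledgebase import KnowledgeBase

#: Floor on the per-gene scale, in normalized units, guarding zero-MAD genes.
SCALE_EPSILON = 0.01
DEFAULT_Z_CUTOFF = 3.0


@dataclass(frozen=True)
class ExpressionProfile:
    sample_id: str
    fpkm: Dict[str, float]
    hk_median: float
    normalized: Dict[str, float]


def make_profile(
    sample_id: str, fpkm: Dict[str, float], housekeeping_genes
) -> ExpressionProfile:
    """Normalize a sample's FPKMs by its housekeeping-gene median."""
    hk_values = [fpkm[g] for g in housekeeping_genes if g in fpkm]
    if not hk_values:
        raise ValueError(f"sample {sample_id} has no housekeeping genes")
    hk_median = median(hk_values)
    if hk_median <= 0:
        raise ValueError(f"sample {sample_id} housekeeping median is not positive")
    normalized = {g: v / hk_median for g, v in fpkm.items()}
    return ExpressionProfile(sample_id, dict(fpkm), hk_median, normalized)


@dataclass(frozen=True)
class ReferenceModel:
    """Per-gene robust location/scale of normalized expression in a panel."""

    location: Dict[str, float]
    scale: Dict[str, float]
    panel_size: int
    tissue_composition: Dict[str, int] = field(default_factory=dict)


def build_reference_model(
    panel: Sequence[ExpressionProfile],
    tissue_of: Dict[str, str] | None = None,
) -> ReferenceModel:
    """Median/MAD per gene across panel profiles.

    Genes absent from a profile contribute 0 in that profile. Requires a
    panel of at least 2 profiles.
    """
    if len(panel) < 2:
        raise ValueError("reference panel must contain at least 2 profiles")
    genes = set()
    for profile in panel:
        genes.update(profile.normalized)
    location, scale = {}, {}
    for gene in genes:
        values = [p.normalized.get(gene, 0.0) for p in panel]
        loc = median(values)
        location[gene] = loc
        scale[gene] = median([abs(v - loc) for v in values])
    composition: Dict[str, int] = {}
    if tissue_of:
        for profile in panel:
            tissue = tissue_of.get(profile.sample_id, "unknown")
            composition[tissue] = composition.get(tissue, 0) + 1
    return ReferenceModel(location, scale, len(panel), composition)


def flag_outliers(
    sample: ExpressionProfile,
    model: ReferenceModel,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> List[Tuple[str, str, float]]:
    """Genes whose robust z exceeds the cutoff, as (gene, direction, z).

    z = (normalized - location) / max(scale, epsilon). Genes absent from
    the model are skipped with a warning. Deterministic gene order.
    """
    flags = []
    skipped = []
    for gene in sorted(sample.normalized):
        if gene not in model.location:
            skipped.append(gene)
            continue
        z = (sample.normalized[gene] - model.location[gene]) / max(
            model.scale[gene], SCALE_EPSILON
        )
        if z >= z_cutoff:
            flags.append((gene, "over", z))
        elif z <= -z_cutoff:
            flags.append((gene, "under", z))
    if skipped:
        warnings.warn(
            f"{len(skipped)} genes absent from reference model were skipped "
            f"(e.g. {skipped[:3]})",
            UserWarning,
            stacklevel=2,
        )
    return flags


@dataclass(frozen=True)
class FusionCall:
    gene5: str
    gene3: str
    break5: str = ""
    break3: str = ""
    supporting_reads: int = 1
    known: bool = False
    match_type: str = ""  # exact | partner | ""
    annotation: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene5:
            raise ValueError("gene5 must be non-empty")
        if self.supporting_reads < 1:
            raise ValueError("supporting_reads must be >= 1")


def annotate_fusions(calls: Sequence[FusionCall], kb: KnowledgeBase) -> List[FusionCall]:
    """Mark fusions known via exact pair or partner-gene catalog match.

    Partner matching is symmetric over the catalog but output preserves
    each call's 5'/3' order. ``match_type`` distinguishes exact from
    partner matches; annotations carry the catalog's labels.
    """
    partner_labels: Dict[str, set] = {}
    for (g5, g3), labels in kb.known_fusions.items():
        partner_labels.setdefault(g5, set()).update(labels)
        partner_labels.setdefault(g3, set()).update(labels)
    out = []
    for call in calls:
        pair = (call.gene5, call.gene3)
        if pair in kb.known_fusions:
            out.append(
                replace(
                    call,
                    known=True,
                    match_type="exact",
                    annotation=tuple(sorted(kb.known_fusions[pair])),
                )
            )
        elif call.gene5 in partner_labels or call.gene3 in partner_labels:
            labels = partner_labels.get(call.gene5, set()) | partner_labels.get(
                call.gene3, set()
            )
            out.append(
                replace(
                    call, known=True, match_type="partner", annotation=tuple(sorted(labels))
                )
            )
        else:
            out.append(replace(call, known=False, match_type="", annotation=()))
    return out


def read_expression_table(path: str) -> Dict[str, float]:
    """Two-column TSV (gene_id, FPKM) → dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "fpkm"], comment="#")
    return dict(zip(df["gene"].astype(str), df["fpkm"].astype(float)))


def read_fusion_table(path: str) -> List[FusionCall]:
    """TSV (gene5, gene3, break5, break3, reads) → fusion calls."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return [
        FusionCall(
            gene5=row["gene5"],
            gene3=row["gene3"],
            break5=row.get("break5", ""),
            break3=row.get("break3", ""),
            supporting_reads=int(row.get("reads", 1)),
        )
        for _, row in df.iterrows()
    ]
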