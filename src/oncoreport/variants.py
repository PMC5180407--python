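"""Core variant domain types and normalization.

A :class:`VariantCall` is one normalized variant observation in one sample,
as emitted by an upstream caller: locus, alleles, read support, a caller
quality score, and the annotations (gene, consequence, population frequency,
catalog identifiers) that downstream filters and tier rules consume.

Coordinates are 1-based and fully closed throughout. Chromosome names are
normalized by stripping any ``chr`` prefix; the reference build (GRCh37) is
carried as metadata only — no sequence access is needed or performed, so
indel normalization is parsimony trimming of shared allele context rather
than reference-based left-shifting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

#: Consequence vocabulary understood by the classifiers.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "synonymous",
        "inframe_indel",
        "other",
    }
)

#: Loss-of-function consequence classes ("disruptive" variants).
DISRUPTIVE_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site"})

#: Allowed zygosity annotations.
ZYGOSITIES = frozenset({"het", "hom", "unknown"})

#: Tolerance for agreement between a reported VAF and alt_depth/depth.
VAF_CONSISTENCY_TOL = 0.01


class VariantNormalizationWarning(UserWarning):
    """Raised when a reported VAF disagrees with the allele depths."""


@dataclass(frozen=True)
class VariantCall:
    """One variant observation in one sample.

    Parameters mirror the fields a clinical caller outputs. ``depth`` /
    ``alt_depth`` may be ``None`` when the caller omitted them (such calls
    are retained but flagged by eligibility checks downstream). ``vaf`` is
    the variant allelic fraction in [0, 1].
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: Optional[int] = None
    alt_depth: Optional[int] = None
    vaf: Optional[float] = None
    quality_score: Optional[float] = None
    gene: str = ""
    consequence: str = "other"
    hgvs_c: str = ""
    hgvs_p: str = ""
    population_af: Optional[float] = None
    cosmic_id: str = ""
    zygosity: str = "unknown"
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if (
            self.depth is not None
            and self.alt_depth is not None
            and self.alt_depth > self.depth
        ):
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds depth {self.depth}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.zygosity not in ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.population_af is not None and not (
            0.0 <= self.population_af <= 1.0
        ):
            raise ValueError(
                f"population_af must be in [0, 1], got {self.population_af}"
            )

    @property
    def key(self) -> tuple:
        """Exact matching key: (chrom, pos, ref, alt) after normalization."""
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_chrom(chrom: str) -> str:
    """Strip any ``chr``/``Chr`` prefix from a chromosome name."""
    if chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple:
    # Right-trim shared suffix, then left-trim shared prefix, keeping at
    # least one base of each allele. Left trimming advances pos.
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_call(call: VariantCall) -> VariantCall:
    """Return the parsimony-normalized form of ``call``.

    Normalization strips the ``chr`` prefix, trims shared allele context,
    and fills ``vaf`` from allele depths when absent. When both a reported
    VAF and allele depths are present and disagree by more than 0.01, the
    reported value wins (caller output is authoritative) and a
    :class:`VariantNormalizationWarning` is issued.

    Idempotent: normalizing an already-normalized call is the identity.
    """
    chrom = normalize_chrom(call.chrom)
    pos, ref, alt = _trim_alleles(call.pos, call.ref.upper(), call.alt.upper())
    if ref == alt:
        raise ValueError(
            f"ref equals alt after normalization at {chrom}:{pos} ({ref})"
        )
    vaf = call.vaf
    if call.depth and call.alt_depth is not None:
        depth_vaf = call.alt_depth / call.depth
        if vaf is None:
            vaf = depth_vaf
        elif abs(vaf - depth_vaf) > VAF_CONSISTENCY_TOL:
            warnings.warn(
                f"reported VAF {vaf:.4f} disagrees with alt_depth/depth "
                f"{depth_vaf:.4f} at {chrom}:{pos}; keeping reported value",
                VariantNormalizationWarning,
                stacklevel=2,
            )
    return replace(call, chrom=chrom, pos=pos, ref=ref, alt=alt, vaf=vaf)


def sort_calls(calls) -> list:
    """Stable sort by (chrom, pos, ref, alt); numeric chromosomes first."""

    def chrom_rank(chrom: str) -> tuple:
        return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)

    return sorted(calls, key=lambda c: (chrom_rank(c.chrom), c.pos, c.ref, c.alt))


@dataclass(frozen=True)
class SampleMeta:
    """Identity and context of one sequenced sample."""

    patient_id: str
    sample_role: str = "tumor"  # tumor | normal
    disease_group: str = ""  # solid | hematologic
    diagnosis: str = ""
    timepoint: str = "primary"  # primary | relapse_refractory
    assay: str = "cWES"  # cWES | WES | panel | rnaseq

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sample_role not in {"tumor", "normal"}:
            raise ValueError(f"unknown sample_role {self.sample_role!r}")
        if self.sample_role == "tumor" and self.disease_group not in {
            "solid",
            "hematologic",
        }:
            raise ValueError("disease_group required for tumor samples")
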