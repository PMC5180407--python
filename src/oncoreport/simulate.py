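"""Synthetic inputs with known planted truth.

Generates everything the pipeline stages consume — paired tumor/normal
variant call sets, B-allele-fraction tracks with planted (copy-neutral)
LOH, binned log2 coverage tracks with planted losses, and expression
panels with planted outliers — deterministically from a seed.

The noise models are deliberately simple (binomial read sampling for
allelic fractions, Gaussian log2 bin noise, log-normal expression): the
goal is validation of the pipeline stages against planted truth, not
biological realism. Planted variant calls emulate *caller output*: a
caller only emits a call when it clears its own output threshold, so the
observed alternate read count of a planted call is floored at its planted
allelic fraction. Depths are drawn with a floor of 30 reads, emulating
loci that pass coverage review.

Positions are drawn without replacement from a synthetic exome target map
(2 chromosomes x 500 targets of 200 bp every 2 kb), generated by a pure
function so every run sees the identical map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .expression import ExpressionProfile, make_profile
from .cnv import AllelicSite
from .variants import VariantCall

N_TARGETS_PER_CHROM = 500
TARGET_LENGTH = 200
TARGET_SPACING = 2000
TARGET_OFFSET = 100_000

_CONSEQUENCE_POOL = (
    "missense",
    "missense",
    "missense",
    "synonymous",
    "nonsense",
    "frameshift",
    "splice_site",
    "inframe_indel",
    "other",
)
_BASES = ("A", "C", "G", "T")


def exome_targets() -> List[Tuple[str, int, int]]:
    """The synthetic exome target map (deterministic, 1000 targets)."""
    targets = []
    for chrom in ("1", "2"):
        for i in range(N_TARGETS_PER_CHROM):
            start = TARGET_OFFSET + i * TARGET_SPACING
            targets.append((chrom, start, start + TARGET_LENGTH - 1))
    return targets


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_germline: int = 200
    n_somatic: int = 50
    somatic_vaf_range: Tuple[float, float] = (0.15, 0.5)
    germline_hom_fraction: float = 0.3
    coverage_mean: float = 100.0
    min_depth: int = 30
    tumor_purity: float = 0.8
    n_genes: int = 1000
    n_housekeeping: int = 30
    outlier_genes: Tuple[Tuple[str, float], ...] = ()
    loh_segments: Tuple[Tuple[str, int, int], ...] = ()
    loss_segments: Tuple[Tuple[str, int, int, float], ...] = ()
    panel_size: int = 124
    panel_log_sd: float = 0.25
    bin_log2_sd: float = 0.05
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.n_germline < 0 or self.n_somatic < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.somatic_vaf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("somatic_vaf_range must lie within (0,1)")
        if not (0.0 < self.tumor_purity <= 1.0):
            raise ValueError("tumor_purity must be in (0,1]")
        for gene, fold in self.outlier_genes:
            if fold <= 0:
                raise ValueError(f"fold-change for {gene} must be positive")


@dataclass
class TruthSet:
    somatic_keys: set = field(default_factory=set)
    germline_keys: set = field(default_factory=set)
    loh_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    loss_intervals: List[Tuple[str, int, int]] = field(default_factory=list)
    outlier_genes: Dict[str, float] = field(default_factory=dict)
    expected_counts: Dict[str, int] = field(default_factory=dict)


def _depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    return int(max(cfg.min_depth, rng.poisson(cfg.coverage_mean)))


def _emitted_alt(rng: np.random.Generator, depth: int, p: float) -> int:
    # Caller-output emulation: observed support never falls below the
    # planted fraction the caller emitted the call at.
    alt = int(rng.binomial(depth, p))
    return min(depth, max(alt, math.ceil(p * depth)))


def _base_call(
    rng: np.random.Generator, chrom: str, start: int, end: int, gene: str
) -> dict:
    pos = int(rng.integers(start, end + 1))
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return {
        "chrom": chrom,
        "pos": pos,
        "ref": str(ref),
        "alt": str(alt),
        "gene": gene,
        "consequence": str(rng.choice(_CONSEQUENCE_POOL)),
        "quality_score": float(np.round(rng.uniform(20.0, 60.0), 1)),
    }


def simulate_paired_calls(
    cfg: SimulationConfig,
) -> Tuple[List[VariantCall], List[VariantCall], TruthSet]:
    """Paired tumor/normal call sets with disjoint planted truth.

    Germline variants appear in both samples (het at ~50% or hom at 100%);
    somatic variants appear only in the tumor at a VAF drawn from
    ``somatic_vaf_range`` scaled by tumor purity. Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    targets = exome_targets()
    total = cfg.n_germline + cfg.n_somatic
    if total > len(targets):
        raise ValueError("more planted variants than exome targets")
    idx = rng.choice(len(targets), size=total, replace=False)
    truth = TruthSet()
    tumor: List[VariantCall] = []
    normal: List[VariantCall] = []

    for j in range(cfg.n_germline):
        chrom, start, end = targets[idx[j]]
        base = _base_call(rng, chrom, start, end, gene=f"G{idx[j]:04d}")
        hom = rng.random() < cfg.germline_hom_fraction
        p = 1.0 if hom else 0.5
        population_af = (
            float(np.round(rng.uniform(0.0001, 0.009), 6))
            if rng.random() < 0.5
            else None
        )
        for sample, target_list in (("normal", normal), ("tumor", tumor)):
            depth = _depth(rng, cfg)
            alt_reads = depth if hom else int(rng.binomial(depth, p))
            alt_reads = max(1, alt_reads)
            target_list.append(
                VariantCall(
                    depth=depth,
                    alt_depth=alt_reads,
                    vaf=alt_reads / depth,
                    population_af=population_af,
                    zygosity="hom" if hom else "het",
                    **base,
                )
            )
        truth.germline_keys.add(tumor[-1].key)

    lo, hi = cfg.somatic_vaf_range
    for j in range(cfg.n_germline, total):
        chrom, start, end = targets[idx[j]]
        base = _base_call(rng, chrom, start, end, gene=f"G{idx[j]:04d}")
        planted_vaf = float(rng.uniform(lo, hi)) * cfg.tumor_purity
        depth = _depth(rng, cfg)
        alt_reads = _emitted_alt(rng, depth, planted_vaf)
        call = VariantCall(
            depth=depth,
            alt_depth=alt_reads,
            vaf=alt_reads / depth,
            zygosity="het",
            **base,
        )
        tumor.append(call)
        truth.somatic_keys.add(call.key)

    truth.expected_counts = {
        "germline": cfg.n_germline,
        "somatic": cfg.n_somatic,
        "tumor_calls": len(tumor),
        "normal_calls": len(normal),
    }
    return tumor, normal, truth


def simulate_ballele_track(
    cfg: SimulationConfig,
) -> Tuple[List[AllelicSite], List[Tuple[Tuple[str, int, int], float]], TruthSet]:
    """Allelic-fraction sites and a binned log2 track with planted truth.

    One het site per exome target: normal VAF ~ N(0.5, 0.02) truncated to
    [0.45, 0.55]; tumor VAF is binomially sampled around 0.5, except inside
    planted LOH intervals where the retained-allele fraction under tumor
    purity rho is 0.5 + rho/2 (or 0.5 - rho/2, random allele). log2 bins
    (one per target) are 0 plus Gaussian noise, shifted inside planted
    loss intervals.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = TruthSet(
        loh_intervals=list(cfg.loh_segments),
        loss_intervals=[(c, s, e) for c, s, e, _ in cfg.loss_segments],
    )
    sites: List[AllelicSite] = []
    bins: List[Tuple[Tuple[str, int, int], float]] = []
    site_depth = max(int(cfg.coverage_mean), cfg.min_depth)

    def in_interval(chrom, pos, intervals):
        return any(c == chrom and s <= pos <= e for c, s, e in intervals)

    for chrom, start, end in exome_targets():
        mid = (start + end) // 2
        if cfg.noiseless:
            normal_vaf = 0.5
        else:
            normal_vaf = float(np.clip(rng.normal(0.5, 0.02), 0.45, 0.55))
        if in_interval(chrom, mid, cfg.loh_segments):
            shift = cfg.tumor_purity / 2.0
            center = 0.5 + shift if rng.random() < 0.5 else 0.5 - shift
        else:
            center = normal_vaf
        if cfg.noiseless:
            tumor_vaf = center
        else:
            tumor_vaf = float(rng.binomial(site_depth, center) / site_depth)
        sites.append(
            AllelicSite(chrom=chrom, pos=mid, normal_vaf=normal_vaf, tumor_vaf=tumor_vaf)
        )
        log2 = 0.0
        for c, s, e, value in cfg.loss_segments:
            if c == chrom and s <= mid <= e:
                log2 = value
                break
        if not cfg.noiseless:
            log2 += float(rng.normal(0.0, cfg.bin_log2_sd))
        bins.append(((chrom, start, end), log2))
    return sites, bins, truth


def simulate_expression_panel(
    cfg: SimulationConfig,
) -> Tuple[List[ExpressionProfile], ExpressionProfile, TruthSet]:
    """Panel-of-normals expression profiles plus one case profile.

    Per-gene baselines are log-normal across genes and shared by panel and
    case. Panel profiles carry inter-sample biological noise
    (``panel_log_sd`` in natural-log space; housekeeping genes at one fifth
    of that, emulating their stability). The case profile is the baseline
    with planted outlier genes multiplied by their fold-changes — and
    nothing else: in a planted-truth design every deviation of the case
    from baseline must be in the truth set, otherwise "false flag" is
    ill-defined. ``noiseless`` zeroes the panel noise as well, making the
    reference scale degenerate. Default panel size is 124, the size of the
    normal-transcriptome panel this emulates.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    hk_genes = [f"HK_{i:03d}" for i in range(cfg.n_housekeeping)]
    null_genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    outliers = dict(cfg.outlier_genes)
    extra = [g for g in outliers if g not in set(null_genes)]
    genes = hk_genes + null_genes + extra
    if cfg.n_genes < cfg.n_housekeeping:
        raise ValueError("n_genes must be >= housekeeping subset size")

    baseline = {}
    for gene in genes:
        mu = 3.0 if gene.startswith("HK_") else 2.0
        sd = 0.3 if gene.startswith("HK_") else 1.0
        baseline[gene] = float(np.exp(rng.normal(mu, sd)))

    def noisy(profile_sd_map, sample_id, fold_map=None):
        fpkm = {}
        for gene in genes:
            sd = profile_sd_map(gene)
            noise = 0.0 if cfg.noiseless or sd == 0 else float(rng.normal(0.0, sd))
            value = baseline[gene] * math.exp(noise)
            if fold_map and gene in fold_map:
                value *= fold_map[gene]
            fpkm[gene] = value
        return make_profile(sample_id, fpkm, hk_genes)

    panel = [
        noisy(
            lambda g: cfg.panel_log_sd / 5.0 if g.startswith("HK_") else cfg.panel_log_sd,
            f"N{i:03d}",
        )
        for i in range(cfg.panel_size)
    ]
    case = noisy(lambda g: 0.0, "CASE", fold_map=outliers)
    truth = TruthSet(outlier_genes=outliers)
    return panel, case, truth


def simulate_germline_calls(
    seed: int,
    n: int,
    reference_genes: Sequence[str],
    acmg_genes: Sequence[str],
    other_genes: Sequence[str],
    cosmic_ids: Sequence[str],
    af_threshold: float = 0.01,
) -> List[VariantCall]:
    """Normal-sample calls with randomized catalog memberships and
    population frequencies, for exercising the germline filter cascade."""
    rng = np.random.default_rng(seed)
    targets = exome_targets()
    idx = rng.choice(len(targets), size=min(n, len(targets)), replace=False)
    pools = (list(reference_genes), list(acmg_genes), list(other_genes))
    calls = []
    for j in range(len(idx)):
        chrom, start, end = targets[idx[j]]
        pool = pools[int(rng.integers(0, 3))]
        gene = str(pool[int(rng.integers(0, len(pool)))])
        base = _base_call(rng, chrom, start, end, gene=gene)
        u = rng.random()
        if u < 1 / 3:
            population_af = None
        elif u < 2 / 3:
            population_af = float(np.round(rng.uniform(0.0, af_threshold), 6))
        else:
            population_af = float(np.round(rng.uniform(af_threshold, 0.5), 6))
        cosmic = str(rng.choice(list(cosmic_ids))) if rng.random() < 0.3 else ""
        if rng.random() < 0.15:
            cosmic = f"COSM{int(rng.integers(10**6, 10**7))}"  # uncataloged id
        depth = int(max(30, rng.poisson(100)))
        alt_reads = max(1, int(rng.binomial(depth, 0.5)))
        calls.append(
            VariantCall(
                depth=depth,
                alt_depth=alt_reads,
                vaf=alt_reads / depth,
                population_af=population_af,
                cosmic_id=cosmic,
                zygosity="het",
                **base,
            )
        )
    return calls
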