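"""Reading and writing variant call files (VCF v4.x).

Reading is backed by cyvcf2/htslib. Records are normalized on the way in:
multi-allelic records are split into one :class:`~oncoreport.variants.VariantCall`
per alternate allele, alleles are parsimony-trimmed, and the VAF is computed
from allele depths when the caller did not report one. Output order is
stable by (chrom, pos, ref, alt).

Writing emits single-sample VCF v4.2 text with GT:DP:AD sample fields and
the annotation set this package consumes in INFO. A written file read back
reproduces the call list exactly.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Optional

from cyvcf2 import VCF

from .variants import VariantCall, normalize_call, sort_calls

_INFO_HEADERS = [
    ('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">'),
    ('##INFO=<ID=HGVSC,Number=1,Type=String,Description="Coding change">'),
    ('##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein change">'),
    ('##INFO=<ID=PAF,Number=1,Type=Float,Description="Population minor allele frequency">'),
    ('##INFO=<ID=COSMIC,Number=1,Type=String,Description="COSMIC identifier">'),
    ('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity annotation">'),
    ('##INFO=<ID=NVAF,Number=1,Type=Float,Description="Sub-threshold normal-side VAF annotation">'),
]


class MalformedVariantFileError(ValueError):
    """A record could not be parsed; the message names the offending line."""


def _count_header_lines(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_variant_file(path: str, sample_role: Optional[str] = None) -> List[VariantCall]:
    """Read a VCF into normalized, sorted :class:`VariantCall` records.

    Multi-allelic records are split per alternate allele. Records whose
    depth fields are absent are retained with ``depth``/``alt_depth`` set to
    ``None`` and ``annotations['depth_missing']`` flagged.

    Raises :class:`MalformedVariantFileError` naming the line number when a
    record cannot be parsed.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header_lines = _count_header_lines(path)
    calls: List[VariantCall] = []
    vcf = VCF(path)
    record_index = 0
    try:
        while True:
            try:
                variant = next(vcf)
            except StopIteration:
                break
            except Exception as exc:  # htslib parse failure
                raise MalformedVariantFileError(
                    f"malformed record at line {header_lines + record_index + 1} "
                    f"of {path}: {exc}"
                ) from exc
            record_index += 1
            try:
                calls.extend(_split_record(variant, sample_role))
            except Exception as exc:
                raise MalformedVariantFileError(
                    f"malformed record at line {header_lines + record_index} "
                    f"of {path}: {exc}"
                ) from exc
    finally:
        vcf.close()
    return sort_calls(calls)


def _info_str(variant, key: str) -> str:
    value = variant.INFO.get(key)
    return "" if value is None else str(value)


def _f32(value) -> float:
    # htslib stores floats in 32 bits; snap back to the 6 significant
    # digits the writer serializes so round trips are exact.
    return float(f"{float(value):.6g}")


def _split_record(variant, sample_role: Optional[str]) -> List[VariantCall]:
    alts = list(variant.ALT)
    depth = None
    allele_depths = None
    if len(variant.gt_depths) and variant.gt_depths[0] >= 0:
        depth = int(variant.gt_depths[0])
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is not None and ad.shape[1] == len(alts) + 1 and int(ad[0][0]) >= 0:
        allele_depths = [int(x) for x in ad[0]]
        if depth is None:
            depth = sum(allele_depths)
    paf = variant.INFO.get("PAF")
    zyg = _info_str(variant, "ZYG") or "unknown"
    csq = _info_str(variant, "CSQ") or "other"
    nvaf = variant.INFO.get("NVAF")
    out = []
    for i, alt in enumerate(alts):
        alt_depth = allele_depths[i + 1] if allele_depths else None
        annotations = {}
        if depth is None:
            annotations["depth_missing"] = True
        if sample_role is not None:
            annotations["sample_role"] = sample_role
        if nvaf is not None:
            annotations["normal_vaf"] = _f32(nvaf)
        call = VariantCall(
            chrom=str(variant.CHROM),
            pos=int(variant.POS),
            ref=str(variant.REF),
            alt=str(alt),
            depth=depth,
            alt_depth=alt_depth,
            vaf=None,
            quality_score=_f32(variant.QUAL) if variant.QUAL is not None else None,
            gene=_info_str(variant, "GENE"),
            consequence=csq,
            hgvs_c=_info_str(variant, "HGVSC"),
            hgvs_p=_info_str(variant, "HGVSP"),
            population_af=_f32(paf) if paf is not None else None,
            cosmic_id=_info_str(variant, "COSMIC"),
            zygosity=zyg if zyg in {"het", "hom"} else "unknown",
            annotations=annotations,
        )
        out.append(normalize_call(call))
    return out


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def write_variant_file(
    calls: Iterable[VariantCall], path: str, sample_name: str = "SAMPLE"
) -> None:
    """Write calls as single-sample VCF v4.2; inverse of :func:`read_variant_file`."""
    calls = sort_calls(calls)
    contigs = []
    for call in calls:
        if call.chrom not in contigs:
            contigs.append(call.chrom)
    lines = ["##fileformat=VCFv4.2", "##reference=GRCh37"]
    lines += [f"##contig=<ID={c}>" for c in sorted(contigs)]
    lines += _INFO_HEADERS
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t" + f"FORMAT\t{sample_name}",
    ]
    for call in calls:
        info = []
        if call.gene:
            info.append(f"GENE={call.gene}")
        if call.consequence and call.consequence != "other":
            info.append(f"CSQ={call.consequence}")
        if call.hgvs_c:
            info.append(f"HGVSC={call.hgvs_c}")
        if call.hgvs_p:
            info.append(f"HGVSP={call.hgvs_p}")
        if call.population_af is not None:
            info.append(f"PAF={_fmt_float(call.population_af)}")
        if call.cosmic_id:
            info.append(f"COSMIC={call.cosmic_id}")
        if call.zygosity != "unknown":
            info.append(f"ZYG={call.zygosity}")
        if "normal_vaf" in call.annotations:
            info.append(f"NVAF={_fmt_float(call.annotations['normal_vaf'])}")
        gt = {"het": "0/1", "hom": "1/1"}.get(call.zygosity, "./.")
        if call.depth is not None and call.alt_depth is not None:
            sample = f"{gt}:{call.depth}:{call.depth - call.alt_depth},{call.alt_depth}"
            fmt = "GT:DP:AD"
        elif call.depth is not None:
            sample = f"{gt}:{call.depth}"
            fmt = "GT:DP"
        else:
            sample = gt
            fmt = "GT"
        qual = _fmt_float(call.quality_score) if call.quality_score is not None else "."
        lines.append(
            "\t".join(
                [
                    call.chrom,
                    str(call.pos),
                    ".",
                    call.ref,
                    call.alt,
                    qual,
                    "PASS",
                    ";".join(info) if info else ".",
                    fmt,
                    sample,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
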