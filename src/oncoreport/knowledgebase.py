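"""Knowledge-base catalogs that parameterize filters and tier rules.

Every filtering and tiering decision in this package is driven by an
explicit, externally supplied catalog: reference-range genes (cancer
predisposition + pharmacogenomics), ACMG secondary-findings genes, COSMIC
identifiers, well-established cancer genes, mutation hotspots, known
fusions, a drug-target catalog with evidence annotations, and the
housekeeping gene list used for expression normalization. Small bundled
default catalogs (sufficient for testing and the worked examples) ship with
the package; production deployments point the YAML config at their own
curated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Tuple

import yaml

#: Filters/rules and the catalog each one requires.
FILTER_REQUIREMENTS = {
    "reference_range": "reference_range_genes",
    "reportable_range_cosmic": "cosmic_ids",
    "reportable_range_acmg": "acmg_genes",
    "hotspot_tiering": "hotspots",
    "cancer_gene_tiering": "cancer_genes",
    "fusion_annotation": "known_fusions",
    "targetability": "drug_targets",
    "housekeeping_normalization": "housekeeping_genes",
}

DEFAULT_AF_THRESHOLD = 0.01  # minor allele frequency < 1% retains a variant


@dataclass(frozen=True)
class DrugTarget:
    """One drug-target catalog row.

    ``target`` is a gene symbol or a fusion written ``GENE5-GENE3``.
    ``alteration`` restricts the entry to a specific protein change
    (``"*"`` matches any alteration of the target). ``evidence_class`` is
    ``clinical`` or ``preclinical``; ``tumor_types`` lists the diseases the
    evidence was generated in (lower-case; ``("*",)`` matches any).
    """

    target: str
    drug: str
    approval_status: str  # approved | experimental | preclinical_only
    pediatric_dosing_available: bool
    evidence_class: str  # clinical | preclinical
    tumor_types: Tuple[str, ...] = ("*",)
    alteration: str = "*"

    def matches_tumor_type(self, tumor_type: str) -> bool:
        return "*" in self.tumor_types or tumor_type.strip().lower() in self.tumor_types


@dataclass(frozen=True)
class KnowledgeBase:
    reference_range_genes: FrozenSet[str] = frozenset()
    acmg_genes: FrozenSet[str] = frozenset()
    cosmic_ids: FrozenSet[str] = frozenset()
    cancer_genes: FrozenSet[str] = frozenset()
    hotspots: FrozenSet[Tuple[str, str]] = frozenset()
    known_fusions: Dict[Tuple[str, str], Tuple[str, ...]] = field(default_factory=dict)
    drug_targets: Dict[str, Tuple[DrugTarget, ...]] = field(default_factory=dict)
    housekeeping_genes: FrozenSet[str] = frozenset()
    patient_care_variants: FrozenSet[Tuple[str, str]] = frozenset()
    af_threshold: float = DEFAULT_AF_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold < 1.0):
            raise ValueError(f"af_threshold must be in (0,1), got {self.af_threshold}")


class MissingCatalogError(ValueError):
    """An enabled filter's catalog is absent or empty; names the filter."""


def _read_gene_list(path) -> FrozenSet[str]:
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return frozenset(genes)


def _read_pair_tsv(path) -> FrozenSet[Tuple[str, str]]:
    pairs = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            pairs.add((cols[0], cols[1]))
    return frozenset(pairs)


def _read_fusion_catalog(path) -> Dict[Tuple[str, str], Tuple[str, ...]]:
    catalog: Dict[Tuple[str, str], Tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            labels = tuple(cols[2].split(";")) if len(cols) > 2 and cols[2] else ()
            catalog[(cols[0], cols[1])] = labels
    return catalog


def _read_drug_targets(path) -> Dict[str, Tuple[DrugTarget, ...]]:
    entries: Dict[str, List[DrugTarget]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                continue
            row = dict(zip(header, cols))
            entry = DrugTarget(
                target=row["target"],
                drug=row["drug"],
                approval_status=row["approval_status"],
                pediatric_dosing_available=row["pediatric_dosing"].lower()
                in {"1", "true", "yes"},
                evidence_class=row["evidence_class"],
                tumor_types=tuple(
                    t.strip().lower() for t in row["tumor_types"].split(";")
                ),
                alteration=row.get("alteration", "*") or "*",
            )
            entries.setdefault(entry.target, []).append(entry)
    return {k: tuple(v) for k, v in entries.items()}


def load_knowledge_base(
    config_path: str, enabled_filters: Optional[List[str]] = None
) -> KnowledgeBase:
    """Load catalogs named by a YAML config.

    The config maps catalog names to file paths (relative paths resolve
    against the config file's directory) plus optional ``af_threshold``.
    ``enabled_filters`` lists the filters/rules the caller intends to run
    (default: all); a missing or empty catalog that an enabled filter
    requires raises :class:`MissingCatalogError` naming that filter.
    """
    import os

    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(config_path))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    loaders = {
        "reference_range_genes": _read_gene_list,
        "acmg_genes": _read_gene_list,
        "cosmic_ids": _read_gene_list,
        "cancer_genes": _read_gene_list,
        "housekeeping_genes": _read_gene_list,
        "hotspots": _read_pair_tsv,
        "patient_care_variants": _read_pair_tsv,
        "known_fusions": _read_fusion_catalog,
        "drug_targets": _read_drug_targets,
    }
    loaded = {}
    for name, loader in loaders.items():
        if name in config and config[name]:
            path = resolve(config[name])
            if os.path.exists(path):
                loaded[name] = loader(path)
    kb = KnowledgeBase(
        af_threshold=float(config.get("af_threshold", DEFAULT_AF_THRESHOLD)),
        **loaded,
    )
    if enabled_filters is None:
        enabled_filters = list(FILTER_REQUIREMENTS)
    for filt in enabled_filters:
        catalog_name = FILTER_REQUIREMENTS.get(filt)
        if catalog_name is None:
            raise ValueError(f"unknown filter {filt!r}")
        if not getattr(kb, catalog_name):
            raise MissingCatalogError(
                f"filter {filt!r} is enabled but catalog "
                f"{catalog_name!r} is missing or empty"
            )
    return kb


def default_knowledge_base() -> KnowledgeBase:
    """The small bundled catalogs used in tests and worked examples."""
    data = resources.files("oncoreport.data")
    with resources.as_file(data.joinpath("kb.yaml")) as cfg:
        return load_knowledge_base(str(cfg))
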