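"""Cohort-level counts and proportions from the fixture tables.

Patients recur across tier sections (flagged by the same-patient footnote),
so every headline number is a distinct-patient count. Denominators come
from the cohort composition: 101 patients overall (65 solid, 36
hematologic), 90 with germline tissue sequenced (57 solid, 33
hematologic), and 60 with full tumor/normal exome plus transcriptome.
"""

from __future__ import annotations

from typing import Callable, Dict, Tuple

import pandas as pd

from .fixtures import load_disease_groups, load_fixture_table

#: Cohort denominators (patient counts by category).
DENOMINATORS: Dict[str, int] = {
    "all": 101,
    "solid": 65,
    "hematologic": 36,
    "germline_tested": 90,
    "solid_germline": 57,
    "hematologic_germline": 33,
    "cwes_full": 60,
}


def distinct_patients(rows: pd.DataFrame) -> int:
    """Count unique patient ids; idempotent under row duplication."""
    if len(rows) == 0:
        return 0
    return int(rows["patient_id"].nunique())


def tally(
    rows: pd.DataFrame,
    predicate: Callable[[pd.Series], bool],
    denominator: int,
) -> Tuple[int, int, float]:
    """(numerator, denominator, proportion) where the numerator is the
    distinct-patient count among rows matching the predicate."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    matching = rows[rows.apply(predicate, axis=1)]
    numerator = distinct_patients(matching)
    return numerator, denominator, numerator / denominator


def _group_of(diagnosis: str, groups: Dict[str, str]) -> str:
    try:
        return groups[diagnosis]
    except KeyError:
        raise KeyError(f"diagnosis {diagnosis!r} missing from disease-group lookup")


def summarize() -> Dict[str, Tuple[int, int, float]]:
    """Headline cohort metrics recomputed from the fixture tables.

    Each value is (numerator, denominator, proportion).
    """
    groups = load_disease_groups()
    table2 = load_fixture_table("table2")
    table4 = load_fixture_table("table4")

    metrics: Dict[str, Tuple[int, int, float]] = {}

    n = distinct_patients(table2)
    metrics["targetable_patients"] = (n, DENOMINATORS["all"], n / DENOMINATORS["all"])
    metrics["targetable_solid"] = tally(
        table2, lambda r: _group_of(r["diagnosis"], groups) == "solid",
        DENOMINATORS["solid"],
    )
    metrics["targetable_hematologic"] = tally(
        table2, lambda r: _group_of(r["diagnosis"], groups) == "hematologic",
        DENOMINATORS["hematologic"],
    )
    therapy_n = distinct_patients(table2[table2["therapy_received"]])
    metrics["matched_therapy"] = (therapy_n, n, therapy_n / n)

    g = distinct_patients(table4)
    metrics["germline_impactful"] = (
        g, DENOMINATORS["germline_tested"], g / DENOMINATORS["germline_tested"]
    )
    metrics["germline_solid"] = tally(
        table4, lambda r: _group_of(r["diagnosis"], groups) == "solid",
        DENOMINATORS["solid_germline"],
    )
    metrics["germline_hematologic"] = tally(
        table4, lambda r: _group_of(r["diagnosis"], groups) == "hematologic",
        DENOMINATORS["hematologic_germline"],
    )
    metrics["acmg_secondary_findings"] = tally(
        table4, lambda r: r["section"] == "acmg", DENOMINATORS["germline_tested"]
    )
    return metrics
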