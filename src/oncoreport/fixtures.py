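"""Bundled fixture tables of reported findings, transcribed row-for-row
from the program's printed results tables (targetable somatic alterations,
clinical-utility findings, and clinically impactful germline mutations),
including the same-patient and therapy-received footnote flags.
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

FIXTURE_TABLES = ("table2", "table3", "table4")

#: Patient identifiers follow a two-digit year, hyphen, five-digit serial.
PATIENT_ID_PATTERN = re.compile(r"^\d{2}-\d{5}$")

_BOOL_COLUMNS = ("same_patient", "therapy_received")


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load one of the bundled fixture tables (``table2``/``table3``/``table4``).

    Rows carry the patient id, tier/section, alteration, diagnosis, and the
    footnote flags. Raises ``ValueError`` for an unknown table name.
    """
    if name not in FIXTURE_TABLES:
        raise ValueError(
            f"unknown fixture table {name!r}; expected one of {FIXTURE_TABLES}"
        )
    path = resources.files("oncoreport.data").joinpath(f"{name}.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int).astype(bool)
    bad = [pid for pid in df["patient_id"] if not PATIENT_ID_PATTERN.match(pid)]
    if bad:
        raise ValueError(f"fixture {name} has malformed patient ids: {bad}")
    return df


def load_disease_groups() -> dict:
    """Diagnosis → disease-group (solid/hematologic) lookup table."""
    path = resources.files("oncoreport.data").joinpath("disease_groups.tsv")
    mapping = {}
    with resources.as_file(path) as p, open(p) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            diagnosis, group = line.split("\t")
            mapping[diagnosis] = group
    return mapping
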