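"""Reading and writing the lesion table (CSV, UTF-8, header row).

The on-disk layout is a single tidy table with one row per lesion; patient
covariates, when present, are denormalised onto the lesion rows and
extracted into a separate patient frame on read.  Column names are
configurable through a schema mapping because no fixed layout is
prescribed for this kind of trial export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .records import (
    DiagnosisClass,
    DxBasis,
    LESION_COLUMNS,
    MANAGEMENT_TOKENS,
    MANDATORY_LESION_COLUMNS,
    ManagementDecision,
    PATIENT_COLUMNS,
)


class SchemaError(ValueError):
    """A mandatory column is missing from the input file."""


@dataclass(frozen=True)
class RowError:
    """A row-level parse failure; the offending row is dropped, others kept."""

    row: int  # 0-based data-row index
    column: str
    token: str
    message: str


_DX_TOKENS = {c.value: c.value for c in DiagnosisClass}
_MGMT_TOKENS = {m.value: m.value for m in ManagementDecision}
_MGMT_TOKENS.update({k: v.value for k, v in MANAGEMENT_TOKENS.items()})
_BASIS_TOKENS = {b.value: b.value for b in DxBasis}
_BOOL_TOKENS = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(token: str, default: bool = True) -> bool:
    if token == "":
        return default
    try:
        return _BOOL_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(token)


def read_lesion_table(
    path, schema: Optional[Dict[str, str]] = None
) -> Tuple[pd.DataFrame, pd.DataFrame, List[RowError]]:
    """Read a lesion CSV into (lesions, patients, row_errors).

    ``schema`` maps file column names to canonical names.  Rows with
    unknown enum tokens are reported in ``row_errors`` and excluded; all
    other rows are retained.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=schema)
    missing = [c for c in MANDATORY_LESION_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    errors: List[RowError] = []
    bad_rows: set = set()

    def parse_column(col, mapping, optional_empty=True):
        out = []
        for i, tok in enumerate(raw[col].tolist()):
            tok = tok.strip()
            if tok == "" and optional_empty:
                out.append(None)
                continue
            try:
                out.append(mapping[tok])
            except KeyError:
                errors.append(
                    RowError(i, col, tok, f"unknown token {tok!r} in {col}")
                )
                bad_rows.add(i)
                out.append(None)
        return out

    parsed = pd.DataFrame(index=raw.index)
    for col in ("lesion_id", "patient_id", "attendance_id"):
        parsed[col] = raw[col].astype(str)
    parsed["final_dx"] = parse_column("final_dx", _DX_TOKENS)
    parsed["dx_basis"] = parse_column("dx_basis", _BASIS_TOKENS)
    parsed["soc_management"] = parse_column(
        "soc_management", _MGMT_TOKENS, optional_empty=False
    )
    parsed["soc_suspected_dx"] = (
        parse_column("soc_suspected_dx", _DX_TOKENS)
        if "soc_suspected_dx" in raw.columns
        else None
    )
    for col in ("ai_label_a", "ai_label_b", "ai_label_rws"):
        parsed[col] = parse_column(col, _DX_TOKENS)
    for col, default in (
        ("image_captured", True),
        ("image_qc_passed", True),
        ("eligible", True),
    ):
        vals = []
        for i, tok in enumerate(raw[col].tolist()):
            try:
                vals.append(_parse_bool(tok, default))
            except ValueError:
                errors.append(RowError(i, col, tok, f"unknown flag {tok!r}"))
                bad_rows.add(i)
                vals.append(default)
        parsed[col] = vals
    if "unconfirmed_malignant" in raw.columns:
        parsed["unconfirmed_malignant"] = [
            _parse_bool(t, False) for t in raw["unconfirmed_malignant"]
        ]
    else:
        parsed["unconfirmed_malignant"] = False
    parsed["benign_subtype"] = (
        raw["benign_subtype"] if "benign_subtype" in raw.columns else ""
    )
    parsed["ineligible_reason"] = (
        raw["ineligible_reason"] if "ineligible_reason" in raw.columns else ""
    )
    phases = []
    for i, tok in enumerate(raw["phase"].tolist()):
        if tok.strip() in ("1", "2"):
            phases.append(int(tok))
        else:
            errors.append(RowError(i, "phase", tok, f"phase must be 1 or 2"))
            bad_rows.add(i)
            phases.append(1)
    parsed["phase"] = phases

    patient_cols = [c for c in PATIENT_COLUMNS if c != "patient_id" and c in raw.columns]
    for col in patient_cols:
        parsed[col] = raw[col]

    if bad_rows:
        parsed = parsed.drop(index=sorted(bad_rows)).reset_index(drop=True)

    lesions = parsed[LESION_COLUMNS].copy()
    if patient_cols:
        patients = (
            parsed[["patient_id"] + patient_cols]
            .drop_duplicates("patient_id")
            .reset_index(drop=True)
        )
        if "age" in patients.columns:
            patients["age"] = pd.to_numeric(patients["age"])
        if "fitzpatrick" in patients.columns:
            patients["fitzpatrick"] = pd.to_numeric(patients["fitzpatrick"]).astype(int)
    else:
        patients = pd.DataFrame(columns=PATIENT_COLUMNS)
    return lesions, patients, errors


def write_lesion_table(
    lesions: pd.DataFrame, path, patients: Optional[pd.DataFrame] = None
) -> Path:
    """Write the lesion table as CSV; absent labels serialise as empty fields.

    If a patient frame is given its covariates are denormalised onto the
    lesion rows so that ``read_lesion_table`` round-trips both frames.
    """
    path = Path(path)
    out = lesions.reindex(columns=LESION_COLUMNS).copy()
    if patients is not None and len(patients):
        out = out.merge(patients, on="patient_id", how="left")
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].map({True: "true", False: "false"})
    out = out.fillna("")
    out.to_csv(path, index=False)
    return path
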