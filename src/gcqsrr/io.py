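"""Readers and writers for the pipeline's table and structure formats.

Canonical table dialect: comma-separated, UTF-8, header row, "." decimal.
Known columns of the compound table are routed to :class:`CompoundRecord`
fields; every other numeric column becomes a descriptor. Structures with
response data fields travel as SDF (RDKit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable

log = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ParseReport",
    "RESPONSE_COLUMNS",
    "read_compound_table",
    "write_compound_table",
    "read_structures_sdf",
    "write_structures_sdf",
    "records_to_frame",
]

#: response column name -> CompoundRecord attribute
RESPONSE_COLUMNS = {"t1R_s": "t1r", "t2R_s": "t2r", "LRI": "lri", "PEG2I": "peg2i"}

_KNOWN = {"compound_id", "name", "smiles", "group", "chlorination_level", "set"} | set(
    RESPONSE_COLUMNS
)


@dataclass
class CompoundRecord:
    """One analyte: identity, structure, class labels and responses.

    Responses: first/second-dimension retention times in seconds (t1r, t2r)
    and the derived retention indices (lri, peg2i). ``group`` is the local-
    model group label (1 fluorinated, 2 chlorinated/brominated, 3 long
    carbon chain, 4 remainder); PCB congeners additionally carry their
    chlorination level.
    """

    compound_id: str
    name: str = ""
    smiles: str | None = None
    group: int | None = None
    chlorination_level: int | None = None
    set_assignment: str | None = None
    t1r: float | None = None
    t2r: float | None = None
    lri: float | None = None
    peg2i: float | None = None

    def responses(self) -> dict:
        out = {}
        for col, attr in RESPONSE_COLUMNS.items():
            v = getattr(self, attr)
            if v is not None:
                out[col] = v
        return out


@dataclass
class ParseReport:
    rows_read: int = 0
    rows_dropped: int = 0
    missing_values: int = 0
    warnings: list[str] = field(default_factory=list)


def _opt_int(v):
    return None if pd.isna(v) else int(v)


def _opt_float(v):
    return None if pd.isna(v) else float(v)


def read_compound_table(path) -> tuple[list[CompoundRecord], DescriptorTable, ParseReport]:
    """Read the delimited compound table.

    Unknown columns become descriptors; non-numeric descriptor cells are
    flagged as missing values. Duplicate compound ids are an error.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise ValueError("compound table must have a compound_id column")
    dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate compound ids: {dupes}")

    report = ParseReport(rows_read=len(df))
    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(row.get("name", "")) if pd.notna(row.get("name", "")) else "",
                smiles=None if pd.isna(row.get("smiles", np.nan)) else str(row["smiles"]),
                group=_opt_int(row.get("group", np.nan)),
                chlorination_level=_opt_int(row.get("chlorination_level", np.nan)),
                set_assignment=None
                if pd.isna(row.get("set", np.nan))
                else str(row["set"]),
                t1r=_opt_float(row.get("t1R_s", np.nan)),
                t2r=_opt_float(row.get("t2R_s", np.nan)),
                lri=_opt_float(row.get("LRI", np.nan)),
                peg2i=_opt_float(row.get("PEG2I", np.nan)),
            )
        )

    desc_cols = [c for c in df.columns if c not in _KNOWN]
    desc = df[desc_cols].apply(pd.to_numeric, errors="coerce")
    n_bad = int(desc.isna().sum().sum() - df[desc_cols].isna().sum().sum())
    if n_bad:
        report.missing_values += n_bad
        report.warnings.append(f"{n_bad} non-numeric descriptor cells treated as missing")
    report.missing_values += int(df[desc_cols].isna().sum().sum())
    desc.index = df["compound_id"]
    return records, DescriptorTable(desc), report


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "smiles": r.smiles,
                "group": r.group,
                "chlorination_level": r.chlorination_level,
                "set": r.set_assignment,
                "t1R_s": r.t1r,
                "t2R_s": r.t2r,
                "LRI": r.lri,
                "PEG2I": r.peg2i,
            }
        )
    return pd.DataFrame(rows)


def write_compound_table(
    records: list[CompoundRecord], table: DescriptorTable | None, path
) -> None:
    df = records_to_frame(records)
    if table is not None:
        desc = table.values.reindex(df["compound_id"]).reset_index(drop=True)
        df = pd.concat([df, desc], axis=1)
    df.to_csv(path, index=False)


def write_structures_sdf(records: list[CompoundRecord], path) -> int:
    """Write records with structures to an SDF; responses go to data fields.

    Returns the number of records written (structureless records are
    skipped with a warning).
    """
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    n = 0
    for r in records:
        if not r.smiles:
            log.warning("record %s has no structure; not written to SDF", r.compound_id)
            continue
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:
            log.warning("record %s has unparseable SMILES; skipped", r.compound_id)
            continue
        mol.SetProp("_Name", r.name or r.compound_id)
        mol.SetProp("compound_id", r.compound_id)
        for col, val in r.responses().items():
            mol.SetProp(col, repr(float(val)))
        writer.write(mol)
        n += 1
    writer.close()
    return n


def read_structures_sdf(path, field_map: dict | None = None) -> tuple[list[CompoundRecord], int]:
    """Read an SDF whose data fields carry retention responses.

    ``field_map`` maps SDF field names to canonical response columns
    (default: identity on t1R_s/t2R_s/LRI/PEG2I). Unparseable molecule
    blocks are skipped; the skip count is returned alongside the records.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    field_map = field_map or {c: c for c in RESPONSE_COLUMNS}
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records, skipped = [], 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            log.warning("SDF record %d unparseable; skipped", i)
            continue
        cid = (
            mol.GetProp("compound_id")
            if mol.HasProp("compound_id")
            else (mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}")
        )
        rec = CompoundRecord(
            compound_id=str(cid),
            name=mol.GetProp("_Name") if mol.HasProp("_Name") else "",
            smiles=Chem.MolToSmiles(mol),
        )
        for fname, col in field_map.items():
            if mol.HasProp(fname):
                setattr(rec, RESPONSE_COLUMNS[col], float(mol.GetProp(fname)))
        records.append(rec)
    return records, skipped
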