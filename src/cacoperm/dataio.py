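"""Reading and writing compound tables, descriptor matrices and property
tables; duplicate removal by canonical SMILES; raw-measurement conversion
to log Papp.

CSV files follow the RFC-4180 dialect with UTF-8 text and '.' decimal
separator. Missing numeric cells are written empty; empty cells, "NA" and
"NaN" are accepted as missing on read.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "CompoundRecord",
    "PermeabilityMeasurement",
    "DedupResult",
    "read_compound_table",
    "read_smiles_file",
    "deduplicate_compounds",
    "compute_log_papp",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
    "read_property_table",
    "write_property_table",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}

RDLogger.DisableLog("rdApp.*")  # parse failures are reported via DedupResult


@dataclass
class CompoundRecord:
    """One compound: opaque id, SMILES structure, optional measured log Papp."""

    id: str
    structure: str
    log_papp: Optional[float] = None
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """Raw Caco-2 transport measurement.

    dqdt: drug permeation rate, umol/s; c0: donor concentration,
    umol/cm^3; area: monolayer area, cm^2.
    """

    dqdt: float
    c0: float
    area: float


@dataclass
class DedupResult:
    kept: list[CompoundRecord]
    n_removed: int
    failed: list[CompoundRecord] = field(default_factory=list)


def _open_source(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, newline="", encoding="utf-8")
    return source


def read_compound_table(
    source: Union[str, Path, TextIO],
    column_map: Optional[dict[str, str]] = None,
) -> list[CompoundRecord]:
    """Read a compound CSV into records.

    ``column_map`` maps the field names {'id', 'structure', 'log_papp'} to
    CSV column names (defaults: 'id', 'smiles', 'log_papp'; the log Papp
    column is optional). All unmapped columns go into record metadata.
    Blank log Papp cells yield records without a measured value. Duplicate
    ids and unparseable numeric cells are reported with their row numbers.
    """
    cmap = {"id": "id", "structure": "smiles", "log_papp": "log_papp"}
    if column_map:
        cmap.update(column_map)
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        reader = csv.DictReader(stream)
        if reader.fieldnames is None:
            raise ValueError("compound table has no header row")
        for key in ("id", "structure"):
            if cmap[key] not in reader.fieldnames:
                raise ValueError(f"mapped column {cmap[key]!r} for {key!r} not in header")
        has_response = cmap["log_papp"] in reader.fieldnames
        records: list[CompoundRecord] = []
        seen: dict[str, int] = {}
        for row_no, row in enumerate(reader, start=2):  # header is row 1
            cid = (row.get(cmap["id"]) or "").strip()
            if not cid:
                raise ValueError(f"row {row_no}: empty compound id")
            if cid in seen:
                raise ValueError(
                    f"duplicate id {cid!r} on rows {seen[cid]} and {row_no}"
                )
            seen[cid] = row_no
            log_papp = None
            if has_response:
                cell = (row.get(cmap["log_papp"]) or "").strip()
                if cell not in _MISSING_TOKENS:
                    try:
                        log_papp = float(cell)
                    except ValueError as exc:
                        raise ValueError(
                            f"row {row_no}: cannot parse log Papp cell {cell!r}"
                        ) from exc
                    if not math.isfinite(log_papp):
                        raise ValueError(f"row {row_no}: non-finite log Papp {cell!r}")
            mapped = {cmap["id"], cmap["structure"], cmap["log_papp"]}
            metadata = {k: v for k, v in row.items() if k not in mapped and v not in (None, "")}
            records.append(
                CompoundRecord(
                    id=cid,
                    structure=(row.get(cmap["structure"]) or "").strip(),
                    log_papp=log_papp,
                    metadata=metadata,
                )
            )
        return records
    finally:
        if close:
            stream.close()


def read_smiles_file(source: Union[str, Path, TextIO]) -> list[CompoundRecord]:
    """Read a .smi file: one 'SMILES [id]' per line; ids default to row order."""
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        records = []
        for i, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            records.append(CompoundRecord(id=cid, structure=smiles))
        return records
    finally:
        if close:
            stream.close()


def canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical SMILES via RDKit, or None when the structure fails to parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def deduplicate_compounds(records: Sequence[CompoundRecord]) -> DedupResult:
    """Remove duplicate molecules, compared by canonical SMILES.

    The first occurrence of each structure is kept and input order is
    otherwise preserved. Structures that fail to parse are excluded from
    the kept list and counted separately in ``failed``; duplicates among
    valid structures are counted in ``n_removed`` so that
    len(kept) + n_removed + len(failed) equals the input size.
    """
    kept: list[CompoundRecord] = []
    failed: list[CompoundRecord] = []
    seen: set[str] = set()
    n_removed = 0
    for rec in records:
        if not rec.structure:
            failed.append(rec)
            continue
        canon = canonical_smiles(rec.structure)
        if canon is None:
            failed.append(rec)
            continue
        if canon in seen:
            n_removed += 1
            continue
        seen.add(canon)
        kept.append(rec)
    return DedupResult(kept=kept, n_removed=n_removed, failed=failed)


def compute_log_papp(m: PermeabilityMeasurement) -> float:
    """log10 apparent permeability from a raw transport measurement.

    Papp = (dQ/dt) / (C0 * A) in cm/s, with C0 in umol/cm^3; the returned
    value is log10(Papp).
    """
    if m.dqdt <= 0 or m.c0 <= 0 or m.area <= 0:
        raise ValueError("dQ/dt, C0 and A must all be strictly positive")
    return math.log10(m.dqdt / (m.c0 * m.area))


def read_descriptor_matrix(source: Union[str, Path, TextIO]) -> pd.DataFrame:
    """Read a descriptor CSV (first column = compound id) into a DataFrame.

    Empty cells, "NA" and "NaN" become NaN. Ragged rows, duplicate ids and
    duplicate column names are rejected.
    """
    stream = _open_source(source)
    close = isinstance(source, (str, Path))
    try:
        reader = csv.reader(stream)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError("descriptor matrix is empty") from None
        names = header[1:]
        dupes = {c for c in names if names.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate descriptor column names: {sorted(dupes)}")
        ids, rows = [], []
        for row_no, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"row {row_no}: expected {len(header)} fields, got {len(row)}"
                )
            ids.append(row[0])
            parsed = []
            for name, cell in zip(names, row[1:]):
                cell = cell.strip()
                if cell in _MISSING_TOKENS:
                    parsed.append(np.nan)
                else:
                    try:
                        parsed.append(float(cell))
                    except ValueError as exc:
                        raise ValueError(
                            f"row {row_no}, column {name!r}: cannot parse {cell!r}"
                        ) from exc
            rows.append(parsed)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound ids in descriptor matrix")
        return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=names, dtype=float)
    finally:
        if close:
            stream.close()


def write_descriptor_matrix(matrix: pd.DataFrame, sink: Union[str, Path, TextIO]) -> None:
    """Write a descriptor matrix as CSV; round-trips values exactly (repr
    precision) and missing entries as empty cells."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _write_matrix(matrix, fh)
    else:
        _write_matrix(matrix, sink)


def _write_matrix(matrix: pd.DataFrame, fh: TextIO) -> None:
    writer = csv.writer(fh)
    writer.writerow(["id", *matrix.columns])
    for cid, row in zip(matrix.index, matrix.to_numpy()):
        writer.writerow([cid] + ["" if (isinstance(v, float) and math.isnan(v)) else repr(float(v)) for v in row])


def read_property_table(source: Union[str, Path, TextIO]) -> pd.DataFrame:
    """Read a physicochemical property table (id-indexed CSV)."""
    if isinstance(source, (str, Path)):
        return pd.read_csv(source, index_col=0, na_values=["NA", "NaN"])
    return pd.read_csv(io.StringIO(source.read()), index_col=0, na_values=["NA", "NaN"])


def write_property_table(table: pd.DataFrame, sink: Union[str, Path, TextIO]) -> None:
    table.to_csv(sink)
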