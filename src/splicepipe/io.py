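"""Tabular I/O: ranked PSM exports and the 23-column product database.

Two PSM CSV dialects are supported.  The *canonical* dialect is this
package's documented interchange format; the *mascot-export* dialect is a
thin column mapping onto the CSV export of a Mascot Server search (exact
export layouts are version-dependent, so the mapping can be overridden).

The product database schema is fixed: 23 named columns in a fixed order
(sample and run metadata, substrate, peptide, search-engine scores,
classification, positions, charge, PTM).  Readers and writers round-trip
losslessly and deterministically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .positions import parse_positions
from .substrates import validate_sequence

logger = logging.getLogger(__name__)

#: The 23 database columns, in their fixed order.
DATABASE_COLUMNS = [
    "sampleID", "sampleName", "runID", "protIsotype", "digestTime",
    "species", "sampleDate", "instrument", "fragmentation",
    "substrateOrigin", "location", "substrateSeq", "substrateID",
    "pepSeq", "scanNum", "rankMS", "ionScore", "qValue",
    "productType", "spliceType", "positions", "charge", "PTM",
]

#: spliceType sentinels normalised to "" for non-spliced rows on read.
_SPLICE_SENTINELS = {"", "none", "None", "NA", "na", "-", "NULL"}

PSM_MANDATORY = ["scanNum", "rankMS", "pepSeq", "ionScore", "qValue"]
PSM_COLUMNS = [
    "sampleID", "runID", "substrateID", "scanNum", "rankMS", "pepSeq",
    "ionScore", "qValue", "charge", "PTM", "instrument", "fragmentation",
]

#: Default Mascot CSV export -> canonical column mapping.
MASCOT_EXPORT_MAP = {
    "pep_query": "scanNum",
    "pep_rank": "rankMS",
    "pep_seq": "pepSeq",
    "pep_score": "ionScore",
    "pep_q_value": "qValue",
    "pep_exp_z": "charge",
    "pep_var_mod": "PTM",
}


class SchemaError(ValueError):
    """A mandatory column is missing or a row violates the schema."""


# --- PSM records -----------------------------------------------------------

_MOD_RE = re.compile(r"[\(\[]([^\)\]]+)[\)\]]")


def strip_modifications(annotated: str) -> tuple[str, list[tuple[int, str]]]:
    """Split ``"ACM(Oxidation)DE"`` into ``("ACMDE", [(3, "Oxidation")])``.

    Annotations in round or square brackets follow the modified residue;
    positions are 1-based in the stripped sequence.
    """
    mods: list[tuple[int, str]] = []
    plain: list[str] = []
    i = 0
    for m in _MOD_RE.finditer(annotated):
        plain.append(annotated[i : m.start()])
        mods.append((len("".join(plain)), m.group(1)))
        i = m.end()
    plain.append(annotated[i:])
    return "".join(plain), mods


def format_ptm(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def parse_ptm(text: str) -> list[tuple[int, str]]:
    text = (text or "").strip()
    if not text:
        return []
    out = []
    for part in text.split(";"):
        pos, _, name = part.partition(":")
        out.append((int(pos), name))
    return out


@dataclass
class PSMRecord:
    """One ranked peptide-spectrum match."""

    scan_num: int
    rank: int
    pep_seq: str
    ion_score: float
    q_value: float
    charge: int = 0
    ptm: list[tuple[int, str]] = field(default_factory=list)
    sample_id: str = ""
    run_id: str = ""
    substrate_id: str = ""
    instrument: str = ""
    fragmentation: str = ""

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise SchemaError(f"rank must be >= 1, got {self.rank}")
        if not 0.0 <= self.q_value <= 1.0:
            raise SchemaError(f"q_value must be in [0, 1], got {self.q_value}")
        validate_sequence(self.pep_seq, "pep_seq")


@dataclass
class ScanGroup:
    """All ranked PSMs of one MS/MS query, sorted by (rank, -ion_score)."""

    key: tuple[str, str, int]  # (sample_id, run_id, scan_num)
    records: list[PSMRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SchemaError(f"scan group {self.key} has no records")
        self.records.sort(key=lambda r: (r.rank, -r.ion_score, r.pep_seq))


def read_psm_csv(
    path: str | Path,
    dialect: str = "canonical",
    column_map: dict[str, str] | None = None,
) -> list[ScanGroup]:
    """Read a ranked PSM table into :class:`ScanGroup` objects.

    ``dialect`` is ``"canonical"`` or ``"mascot-export"``; ``column_map``
    (source column -> canonical name) overrides/extends the dialect mapping.
    Malformed rows are logged and skipped; a missing mandatory column raises
    :class:`SchemaError` naming it.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping: dict[str, str] = {}
    if dialect == "mascot-export":
        mapping.update(MASCOT_EXPORT_MAP)
    elif dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    if column_map:
        mapping.update(column_map)
    if mapping:
        df = df.rename(columns=mapping)
    for col in PSM_MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")

    groups: dict[tuple[str, str, int], list[PSMRecord]] = {}
    skipped = 0
    for idx, row in df.iterrows():
        try:
            seq, mods = strip_modifications(str(row["pepSeq"]).strip())
            mods.extend(parse_ptm(str(row.get("PTM", ""))))
            rec = PSMRecord(
                scan_num=int(row["scanNum"]),
                rank=int(row["rankMS"]),
                pep_seq=seq,
                ion_score=float(row["ionScore"]),
                q_value=float(row["qValue"]),
                charge=int(row["charge"]) if str(row.get("charge", "")).strip() else 0,
                ptm=mods,
                sample_id=str(row.get("sampleID", "")),
                run_id=str(row.get("runID", "")),
                substrate_id=str(row.get("substrateID", "")),
                instrument=str(row.get("instrument", "")),
                fragmentation=str(row.get("fragmentation", "")),
            )
        except (ValueError, SchemaError) as exc:
            skipped += 1
            logger.warning("skipping malformed PSM row %d: %s", idx, exc)
            continue
        groups.setdefault((rec.sample_id, rec.run_id, rec.scan_num), []).append(rec)
    if skipped:
        logger.warning("skipped %d malformed rows while reading %s", skipped, path)
    return [ScanGroup(key, recs) for key, recs in sorted(groups.items())]


def write_psm_csv(records: list[PSMRecord], path: str | Path) -> None:
    """Write PSM records in the canonical dialect (deterministic order)."""
    rows = [
        {
            "sampleID": r.sample_id,
            "runID": r.run_id,
            "substrateID": r.substrate_id,
            "scanNum": r.scan_num,
            "rankMS": r.rank,
            "pepSeq": r.pep_seq,
            "ionScore": r.ion_score,
            "qValue": r.q_value,
            "charge": r.charge,
            "PTM": format_ptm(r.ptm),
            "instrument": r.instrument,
            "fragmentation": r.fragmentation,
        }
        for r in sorted(records, key=lambda r: (r.sample_id, r.run_id, r.scan_num, r.rank, -r.ion_score, r.pep_seq))
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, index=False)


# --- the 23-column product database ---------------------------------------


@dataclass
class DatabaseRow:
    """One record of the product database (23 attributes, fixed order)."""

    sampleID: str
    sampleName: str
    runID: str
    protIsotype: str
    digestTime: str
    species: str
    sampleDate: str
    instrument: str
    fragmentation: str
    substrateOrigin: str
    location: str
    substrateSeq: str
    substrateID: str
    pepSeq: str
    scanNum: int
    rankMS: int
    ionScore: float
    qValue: float
    productType: str
    spliceType: str
    positions: str
    charge: int
    PTM: str

    def validate(self) -> None:
        from .substrates import Substrate  # local to avoid import cycle at module load

        if self.productType not in ("PCP", "PSP"):
            raise SchemaError(f"productType must be PCP or PSP, got {self.productType!r}")
        if self.productType == "PCP" and self.spliceType not in ("", "none"):
            raise SchemaError("spliceType must be empty for PCP rows")
        if self.productType == "PSP" and self.spliceType not in ("cis", "revCis", "trans"):
            raise SchemaError(f"invalid spliceType {self.spliceType!r} for PSP")
        if self.rankMS < 1:
            raise SchemaError("rankMS must be >= 1")
        if not 0.0 <= self.qValue <= 1.0:
            raise SchemaError("qValue must be in [0, 1]")
        asg = parse_positions(self.positions)
        sub = Substrate(self.substrateID or "sub", self.substrateSeq)
        if asg.read_sequence(sub) != self.pepSeq:
            raise SchemaError(
                f"positions {self.positions!r} do not reconstruct pepSeq {self.pepSeq!r}"
            )

    def as_list(self) -> list:
        return [getattr(self, f.name) for f in fields(self)]


def write_database_csv(rows: list[DatabaseRow], path: str | Path) -> None:
    """Write rows as CSV with the fixed 23-column header.

    Rows are sorted by (sampleID, scanNum, rankMS); any invariant violation
    raises :class:`SchemaError` carrying the offending row index.
    """
    for i, row in enumerate(rows):
        try:
            row.validate()
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    ordered = sorted(rows, key=lambda r: (r.sampleID, r.scanNum, r.rankMS, r.pepSeq))
    df = pd.DataFrame([r.as_list() for r in ordered], columns=DATABASE_COLUMNS)
    df.to_csv(path, index=False)


def read_database_csv(path: str | Path) -> list[DatabaseRow]:
    """Read a product-database CSV, normalising spliceType sentinels."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DATABASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing database columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        splice = r["spliceType"].strip()
        if splice in _SPLICE_SENTINELS:
            splice = ""
        rows.append(
            DatabaseRow(
                sampleID=r["sampleID"], sampleName=r["sampleName"], runID=r["runID"],
                protIsotype=r["protIsotype"], digestTime=r["digestTime"],
                species=r["species"], sampleDate=r["sampleDate"],
                instrument=r["instrument"], fragmentation=r["fragmentation"],
                substrateOrigin=r["substrateOrigin"], location=r["location"],
                substrateSeq=r["substrateSeq"], substrateID=r["substrateID"],
                pepSeq=r["pepSeq"], scanNum=int(r["scanNum"]), rankMS=int(r["rankMS"]),
                ionScore=float(r["ionScore"]), qValue=float(r["qValue"]),
                productType=r["productType"], spliceType=splice,
                positions=r["positions"], charge=int(r["charge"]), PTM=r["PTM"],
            )
        )
    return rows


# --- SQL dump --------------------------------------------------------------

_SQL_TYPES = {
    "scanNum": "INTEGER", "rankMS": "INTEGER", "charge": "INTEGER",
    "ionScore": "REAL", "qValue": "REAL",
}
SQL_TABLE = "peptide_products"


def _sql_literal(value) -> str:
    if isinstance(value, (int, float)):
        return repr(value)
    return "'" + str(value).replace("'", "''") + "'"


def write_sql_dump(rows: list[DatabaseRow], path: str | Path) -> None:
    """Write a plain-text SQL dump (one CREATE TABLE + one INSERT per row)
    loadable by a standard SQL engine such as sqlite3."""
    for i, row in enumerate(rows):
        try:
            row.validate()
        except SchemaError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    ordered = sorted(rows, key=lambda r: (r.sampleID, r.scanNum, r.rankMS, r.pepSeq))
    cols = ",\n  ".join(f"{c} {_SQL_TYPES.get(c, 'TEXT')}" for c in DATABASE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"CREATE TABLE {SQL_TABLE} (\n  {cols}\n);\n")
        for row in ordered:
            values = ", ".join(_sql_literal(v) for v in row.as_list())
            fh.write(f"INSERT INTO {SQL_TABLE} VALUES ({values});\n")
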