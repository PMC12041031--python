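"""Reading and writing FAERS Quarterly Data Extract ASCII tables.

The FDA distributes FAERS as one ``$``-delimited text file per table per
quarter (DEMO, DRUG, REAC, OUTC, THER, INDI; first line is the header).
FAERS exports never quote the delimiter, so no quoting/escaping is
assumed. This layer is deliberately dumb: payload strings are preserved
verbatim apart from surrounding whitespace, field names are lower-cased
internally (the original header is kept for round-tripping), and no
normalisation of drug names or dates happens here — that belongs to the
cohort layer.

Referential integrity against DEMO is advisory: real FAERS quarters
contain DRUG/REAC rows whose primaryid has no DEMO row, so orphans are
recorded on the bundle, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, TextIO, Tuple

__all__ = [
    "TABLES",
    "MANDATORY_TABLES",
    "RawRow",
    "QuarterBundle",
    "FaersFormatError",
    "parse_delimited_table",
    "write_delimited_table",
    "load_quarters",
    "quarter_file_name",
]

log = logging.getLogger(__name__)

DELIM = "$"
TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")


class FaersFormatError(ValueError):
    """A FAERS file violates the quarterly-extract dialect."""


@dataclass
class RawRow:
    """One data line of one FAERS table, field-for-field as on disk."""

    table: str
    payload: Dict[str, str]  # lower-cased field name -> verbatim value
    header: Tuple[str, ...] = ()  # original header spelling, for round-trip

    @property
    def primaryid(self) -> str:
        return self.payload.get("primaryid", "")

    @property
    def caseid(self) -> str:
        return self.payload.get("caseid", "")


@dataclass
class QuarterBundle:
    """All tables of one FAERS quarter."""

    quarter_label: str
    rows_by_table: Dict[str, List[RawRow]] = field(default_factory=dict)
    headers: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    orphans: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def row_counts(self) -> Dict[str, int]:
        return {t: len(rows) for t, rows in self.rows_by_table.items()}

    def check_referential_integrity(self) -> Dict[str, List[str]]:
        """Record primaryids in child tables absent from DEMO (advisory)."""
        demo_ids = {r.primaryid for r in self.rows_by_table.get("DEMO", [])}
        self.orphans = {}
        for table, rows in self.rows_by_table.items():
            if table == "DEMO":
                continue
            missing = sorted({r.primaryid for r in rows} - demo_ids)
            if missing:
                self.orphans[table] = missing
                log.warning(
                    "%s %s: %d primaryid(s) without DEMO row (kept)",
                    self.quarter_label, table, len(missing),
                )
        return self.orphans


def parse_delimited_table(
    stream: TextIO | Iterable[str],
    table_kind: str,
    strict: bool = True,
) -> List[RawRow]:
    """Parse one ``$``-delimited FAERS table into RawRows.

    The first line must be a header containing PRIMARYID (any case). In
    strict mode a row whose field count differs from the header's is an
    error naming the line number; in lenient mode it is skipped with a log
    line — real quarters occasionally contain mangled rows.
    """
    it = iter(stream)
    try:
        header_line = next(it)
    except StopIteration:
        raise FaersFormatError(f"{table_kind}: empty file, no header")
    header = tuple(h.strip() for h in header_line.rstrip("\r\n").split(DELIM))
    names = tuple(h.lower() for h in header)
    if "primaryid" not in names:
        raise FaersFormatError(f"{table_kind}: header lacks PRIMARYID: {header!r}")
    rows: List[RawRow] = []
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\r\n")
        if not line:
            continue
        fields = line.split(DELIM)
        if len(fields) != len(header):
            msg = (f"{table_kind} line {lineno}: {len(fields)} fields "
                   f"under a {len(header)}-column header")
            if strict:
                raise FaersFormatError(msg)
            log.warning("%s (skipped)", msg)
            continue
        payload = {n: v.strip() for n, v in zip(names, fields)}
        rows.append(RawRow(table=table_kind, payload=payload, header=header))
    return rows


def write_delimited_table(rows: Sequence[RawRow], stream: TextIO,
                          header: Sequence[str] | None = None) -> None:
    """Inverse of :func:`parse_delimited_table` (string-identical round trip)."""
    if header is None:
        if not rows:
            raise ValueError("cannot infer header from zero rows")
        header = rows[0].header or tuple(rows[0].payload)
    names = [h.lower() for h in header]
    stream.write(DELIM.join(header) + "\n")
    for row in rows:
        stream.write(DELIM.join(row.payload.get(n, "") for n in names) + "\n")


def quarter_file_name(table: str, quarter_label: str) -> str:
    """Canonical FAERS file name, e.g. ('DEMO', '2024Q1') -> 'DEMO24Q1.txt'."""
    year, q = quarter_label.upper().split("Q")
    return f"{table.upper()}{int(year) % 100:02d}Q{int(q)}.txt"


def _find_table_file(directory: Path, table: str, quarter_label: str) -> Path | None:
    want = quarter_file_name(table, quarter_label).lower()
    for p in sorted(directory.iterdir()):
        if p.is_file() and p.name.lower() == want:
            return p
    return None


def load_quarters(
    directory: str | Path,
    quarter_labels: Sequence[str],
    strict: bool = True,
) -> List[QuarterBundle]:
    """Load the named quarters from a directory of FAERS ASCII files.

    File-name resolution is case-insensitive (``DEMO24Q1.txt`` and
    ``demo24q1.txt`` both work). DEMO/DRUG/REAC are mandatory per quarter;
    a missing OUTC/THER/INDI file only warns, and analyses that need it
    treat the affected reports as missing. Bundles come back in
    chronological order regardless of the order of ``quarter_labels``.
    """
    directory = Path(directory)
    bundles: List[QuarterBundle] = []
    for label in sorted(quarter_labels, key=lambda s: (int(s[:4]), int(s.split("Q")[1]))):
        bundle = QuarterBundle(quarter_label=label)
        for table in TABLES:
            path = _find_table_file(directory, table, label)
            if path is None:
                if table in MANDATORY_TABLES:
                    raise FileNotFoundError(
                        f"quarter {label}: mandatory table {table} not found in {directory}"
                    )
                log.warning("quarter %s: optional table %s absent", label, table)
                continue
            with open(path, encoding="utf-8", errors="replace") as fh:
                rows = parse_delimited_table(fh, table, strict=strict)
            bundle.rows_by_table[table] = rows
            bundle.headers[table] = rows[0].header if rows else ()
        bundle.check_referential_integrity()
        log.info("quarter %s rows: %s", label, bundle.row_counts)
        bundles.append(bundle)
    return bundles
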